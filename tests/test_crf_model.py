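"""Feature vectors, neighborhoods, local potentials and conditionals."""

import numpy as np
import pytest

from rbcontact.alignments import PROTEIN_ALPHABET
from rbcontact.coevolution import GroupingScheme, IDENTITY_GROUPING, base_index
from rbcontact.crf import (
    ContactGrid,
    CRFParams,
    FeatureConfig,
    delta_vector,
    feature_f,
    feature_g,
    local_conditional,
    local_potential,
    neighbors,
)


def oracle_feature_f(config, r, m, a, b):
    """Independent element-wise construction of f (triple loops, no kron)."""
    grouping = config.grouping
    out = []
    for s in (r, 1 - r):
        if config.family == 1:
            out += [s, s * m]
            continue
        for gi in range(grouping.group_count):
            for bi in range(4):
                d = float(grouping.index_of(a) == gi and base_index(b, False) == bi)
                if config.family == 2:
                    out += [s * d, s * d * m]
                else:
                    out += [s * d]
    return np.array(out, dtype=float)


def oracle_feature_g(config, r_ij, r_kl, m_kl, a_k, b_l):
    grouping = config.grouping
    out = []
    for s1 in (r_ij, 1 - r_ij):
        for s2 in (r_kl, 1 - r_kl):
            pair = s1 * s2
            if config.family == 1:
                out += [pair, pair * m_kl]
                continue
            for gi in range(grouping.group_count):
                for bi in range(4):
                    d = float(grouping.index_of(a_k) == gi and base_index(b_l, False) == bi)
                    if config.family == 2:
                        out += [pair * d, pair * d * m_kl]
                    else:
                        out += [pair * d]
    return np.array(out, dtype=float)


class TestNeighbors:
    def test_interior(self):
        assert neighbors(2, 2, 5, 5) == [(1, 2), (3, 2), (2, 1), (2, 3)]

    def test_corner(self):
        assert set(neighbors(0, 0, 3, 3)) == {(1, 0), (0, 1)}

    def test_degenerate_grid(self):
        assert neighbors(0, 0, 1, 1) == []

    def test_out_of_bounds(self):
        with pytest.raises(IndexError):
            neighbors(5, 0, 3, 3)


class TestFeatureDimensions:
    def test_ungrouped_delta_is_eighty(self):
        assert len(delta_vector(IDENTITY_GROUPING, "A", "C")) == 20 * 4

    @pytest.mark.parametrize(
        "family,groups,f_dim,g_dim",
        [(1, 20, 4, 8), (2, 20, 320, 640), (3, 20, 160, 320), (2, 8, 128, 256), (3, 2, 16, 32)],
    )
    def test_dimensions(self, family, groups, f_dim, g_dim):
        config = FeatureConfig(family=family, grouping=GroupingScheme.from_name(groups))
        assert config.f_dim == f_dim
        assert config.g_dim == g_dim
        assert len(feature_f(config, 1, 0.3, "M", "G")) == f_dim
        assert len(feature_g(config, 1, 0, 0.3, "M", "G")) == g_dim

    def test_nonzero_counts(self):
        for family, expected in [(1, 2), (2, 2), (3, 1)]:
            config = FeatureConfig(family=family, grouping=GroupingScheme.from_name(4))
            f = feature_f(config, 1, 0.5, "W", "U")
            g = feature_g(config, 0, 1, 0.5, "W", "U")
            assert np.count_nonzero(f) == expected
            assert np.count_nonzero(g) == expected


class TestFeatureValues:
    def test_family1_explicit_form(self):
        config = FeatureConfig(family=1)
        np.testing.assert_allclose(feature_f(config, 1, 0.5), [1, 0.5, 0, 0])
        np.testing.assert_allclose(feature_f(config, 0, 0.5), [0, 0, 1, 0.5])

    def test_family1_edge_explicit(self):
        config = FeatureConfig(family=1)
        np.testing.assert_allclose(
            feature_g(config, 1, 0, 0.3), [0, 0, 1, 0.3, 0, 0, 0, 0]
        )
        np.testing.assert_allclose(
            feature_g(config, 0, 0, 0.0), [0, 0, 0, 0, 0, 0, 1, 0]
        )

    @pytest.mark.parametrize("family", [1, 2, 3])
    @pytest.mark.parametrize("groups", [2, 8, 20])
    def test_against_elementwise_oracle(self, family, groups):
        config = FeatureConfig(family=family, grouping=GroupingScheme.from_name(groups))
        rng = np.random.default_rng(family * 100 + groups)
        for _ in range(5):
            a = rng.choice(list(PROTEIN_ALPHABET))
            b = rng.choice(list("ACGU"))
            m = float(rng.normal())
            r1, r2 = int(rng.integers(2)), int(rng.integers(2))
            np.testing.assert_allclose(
                feature_f(config, r1, m, a, b), oracle_feature_f(config, r1, m, a, b)
            )
            np.testing.assert_allclose(
                feature_g(config, r1, r2, m, a, b),
                oracle_feature_g(config, r1, r2, m, a, b),
            )

    def test_family2_collapses_to_family1(self):
        # with all residues in one group the δ block is a pure base indicator;
        # the nonzero entries of the family-2 vector coincide with family 1's
        one_group = GroupingScheme(name=1, groups=(PROTEIN_ALPHABET,))
        cfg2 = FeatureConfig(family=2, grouping=one_group)
        cfg1 = FeatureConfig(family=1)
        for r in (0, 1):
            f2 = feature_f(cfg2, r, 0.7, "K", "A")
            f1 = feature_f(cfg1, r, 0.7)
            assert sorted(f2[f2 != 0]) == sorted(f1[f1 != 0])


class TestLocalPotential:
    def _instance(self, seed, n_p=3, n_r=3):
        from conftest import PROTEIN
        from rbcontact.coevolution import MIMatrix
        from rbcontact.crf import ProteinRNAInstance

        rng = np.random.default_rng(seed)
        return ProteinRNAInstance(
            a="".join(rng.choice(list(PROTEIN), n_p)),
            b="".join(rng.choice(list("ACGU"), n_r)),
            m=MIMatrix(rng.random((n_p, n_r))),
            r=ContactGrid(rng.integers(0, 2, (n_p, n_r))),
        )

    def test_zero_params_zero_potential(self):
        inst = self._instance(0)
        config = FeatureConfig(family=2, grouping=GroupingScheme.from_name(4))
        params = CRFParams.zeros(config)
        assert local_potential(params, config, inst, inst.r, 1, 1) == 0.0

    def test_picks_single_coordinate(self):
        inst = self._instance(1)
        config = FeatureConfig(family=1)
        params = CRFParams(w_f=[1, 0, 0, 0], w_g=np.zeros(8))
        grid = ContactGrid(np.ones((3, 3), dtype=int))
        assert local_potential(params, config, inst, grid, 1, 1) == pytest.approx(1.0)

    @pytest.mark.parametrize("family,groups", [(1, 20), (2, 4), (3, 8)])
    def test_against_dot_product_oracle(self, family, groups):
        config = FeatureConfig(family=family, grouping=GroupingScheme.from_name(groups))
        inst = self._instance(7)
        rng = np.random.default_rng(13)
        params = CRFParams(
            w_f=rng.normal(size=config.f_dim), w_g=rng.normal(size=config.g_dim)
        )
        r = inst.r.r
        m = inst.m.values
        for i in range(3):
            for j in range(3):
                expected = float(
                    params.w_f
                    @ oracle_feature_f(config, int(r[i, j]), m[i, j], inst.a[i], inst.b[j])
                )
                for k, l in neighbors(i, j, 3, 3):
                    expected += float(
                        params.w_g
                        @ oracle_feature_g(
                            config, int(r[i, j]), int(r[k, l]), m[k, l], inst.a[k], inst.b[l]
                        )
                    )
                got = local_potential(params, config, inst, inst.r, i, j)
                assert got == pytest.approx(expected, abs=1e-12)

    def test_linear_in_params(self):
        config = FeatureConfig(family=1)
        inst = self._instance(3)
        rng = np.random.default_rng(8)
        params = CRFParams(w_f=rng.normal(size=4), w_g=rng.normal(size=8))
        doubled = CRFParams(w_f=2 * params.w_f, w_g=2 * params.w_g)
        u1 = local_potential(params, config, inst, inst.r, 1, 2)
        u2 = local_potential(doubled, config, inst, inst.r, 1, 2)
        assert u2 == pytest.approx(2 * u1, rel=1e-12)


class TestLocalConditional:
    def test_uniform_at_zero_params(self, make_instance):
        inst = make_instance(0)
        config = FeatureConfig(family=1)
        params = CRFParams.zeros(config)
        for v in (0, 1):
            assert local_conditional(params, config, inst, inst.r, 0, 0, v) == pytest.approx(0.5)

    def test_logistic_form(self, make_instance):
        # U(1) - U(0) = ln 3  =>  Pr(r=1) = 1/(1+3) = 0.25
        inst = make_instance(2, n_p=1, n_r=1)
        config = FeatureConfig(family=1)
        m = inst.m.values[0, 0]
        # w_f = (c, 0, 0, 0) gives U(1)=c, U(0)=0
        params = CRFParams(w_f=[np.log(3), 0, 0, 0], w_g=np.zeros(8))
        assert local_conditional(params, config, inst, inst.r, 0, 0, 1) == pytest.approx(0.25)
        del m

    def test_normalization(self, make_instance, make_params):
        config = FeatureConfig(family=2, grouping=GroupingScheme.from_name(8))
        inst = make_instance(5)
        for seed in range(100):
            params = make_params(seed, config, scale=1.0)
            total = sum(
                local_conditional(params, config, inst, inst.r, 1, 1, v) for v in (0, 1)
            )
            assert total == pytest.approx(1.0, abs=1e-12)


def test_contact_grid_validation_and_tsv(tmp_path):
    with pytest.raises(ValueError):
        ContactGrid(np.array([[0, 2]]))
    grid = ContactGrid(np.array([[0, 1, 1], [1, 0, 0]]))
    path = tmp_path / "g.tsv"
    grid.to_tsv(path)
    assert (ContactGrid.from_tsv(path).r == grid.r).all()
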