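"""Pseudo-likelihood value, analytic gradients, and lasso-regularized fitting."""

import math

import numpy as np
import pytest

from rbcontact.coevolution import GroupingScheme
from rbcontact.crf import CRFParams, FeatureConfig, local_conditional
from rbcontact.errors import MissingLabelError
from rbcontact.synthetic import GeneratorConfig, make_instances
from rbcontact.training import (
    TrainingConfig,
    fit,
    objective,
    pll_gradient,
    pseudo_log_likelihood,
)


def _flat(params):
    return np.concatenate([params.w_f, params.w_g])


def _unflat(x, config):
    return CRFParams(w_f=x[: config.f_dim], w_g=x[config.f_dim :])


def fd_gradient(params, config, instances, h=1e-6):
    """Central finite differences of the pseudo-log-likelihood."""
    x0 = _flat(params)
    out = np.empty_like(x0)
    for k in range(len(x0)):
        xp, xm = x0.copy(), x0.copy()
        xp[k] += h
        xm[k] -= h
        out[k] = (
            pseudo_log_likelihood(_unflat(xp, config), config, instances)
            - pseudo_log_likelihood(_unflat(xm, config), config, instances)
        ) / (2 * h)
    return out


class TestPseudoLogLikelihood:
    def test_uniform_value_at_zero(self, make_instance):
        inst = make_instance(0, n_p=2, n_r=2)
        config = FeatureConfig(family=1)
        value = pseudo_log_likelihood(CRFParams.zeros(config), config, [inst])
        assert value == pytest.approx(4 * math.log(0.5), abs=1e-12)

    def test_always_nonpositive(self, make_instance, make_params):
        config = FeatureConfig(family=2, grouping=GroupingScheme.from_name(4))
        insts = [make_instance(s) for s in range(3)]
        for seed in range(5):
            assert pseudo_log_likelihood(make_params(seed, config), config, insts) <= 0

    @pytest.mark.parametrize("family,groups", [(1, 20), (2, 8), (3, 4)])
    def test_matches_per_cell_conditionals(self, family, groups, make_instance, make_params):
        config = FeatureConfig(family=family, grouping=GroupingScheme.from_name(groups))
        inst = make_instance(1, n_p=3, n_r=3)
        params = make_params(2, config)
        want = sum(
            math.log(local_conditional(params, config, inst, inst.r, i, j))
            for i in range(3)
            for j in range(3)
        )
        got = pseudo_log_likelihood(params, config, [inst])
        assert got == pytest.approx(want, abs=1e-10)

    def test_missing_label_rejected(self, make_instance):
        config = FeatureConfig(family=1)
        inst = make_instance(0, labeled=False)
        with pytest.raises(MissingLabelError):
            pseudo_log_likelihood(CRFParams.zeros(config), config, [inst])


class TestGradient:
    @pytest.mark.parametrize("family,groups", [(1, 20), (2, 4), (3, 15)])
    def test_matches_finite_differences(self, family, groups, make_instance, make_params):
        config = FeatureConfig(family=family, grouping=GroupingScheme.from_name(groups))
        insts = [make_instance(family * 10 + k, n_p=3, n_r=4) for k in range(2)]
        params = make_params(family, config)
        gf, gg = pll_gradient(params, config, insts)
        analytic = np.concatenate([gf, gg])
        numeric = fd_gradient(params, config, insts)
        rel = np.abs(analytic - numeric) / np.maximum(
            1.0, np.maximum(np.abs(analytic), np.abs(numeric))
        )
        assert rel.max() < 1e-5

    def test_additive_over_instances(self, make_instance, make_params):
        config = FeatureConfig(family=1)
        a, b = make_instance(1), make_instance(2)
        params = make_params(3, config)
        gf_both, gg_both = pll_gradient(params, config, [a, b])
        gf_a, gg_a = pll_gradient(params, config, [a])
        gf_b, gg_b = pll_gradient(params, config, [b])
        np.testing.assert_allclose(gf_both, gf_a + gf_b, atol=1e-12)
        np.testing.assert_allclose(gg_both, gg_a + gg_b, atol=1e-12)

    def test_zero_at_balanced_labels(self, make_instance):
        # at θ=0 each conditional is 1/2, so the gradient reduces to
        # (expectation - observation); a label grid with equally many 0s and
        # 1s in a family-1 instance with constant MI balances the state
        # blocks and the bias coordinates cancel
        from rbcontact.coevolution import MIMatrix
        from rbcontact.crf import ContactGrid, ProteinRNAInstance

        inst = ProteinRNAInstance(
            a="AC",
            b="GU",
            m=MIMatrix(np.ones((2, 2))),
            r=ContactGrid(np.array([[0, 1], [1, 0]])),
        )
        config = FeatureConfig(family=1)
        gf, _ = pll_gradient(CRFParams.zeros(config), config, [inst])
        # r and r̄ indicator coordinates: expectation 1/2 per cell per state,
        # observations two 1s and two 0s -> exactly zero
        assert gf[0] == pytest.approx(0.0, abs=1e-12)
        assert gf[2] == pytest.approx(0.0, abs=1e-12)


class TestObjective:
    def test_c_zero_is_pll(self, make_instance, make_params):
        config = FeatureConfig(family=1)
        insts = [make_instance(0)]
        params = make_params(1, config)
        assert objective(params, config, insts, 0.0) == pytest.approx(
            pseudo_log_likelihood(params, config, insts)
        )

    def test_zero_params_penalty_free(self, make_instance):
        config = FeatureConfig(family=1)
        insts = [make_instance(0)]
        z = CRFParams.zeros(config)
        assert objective(z, config, insts, 5.0) == pytest.approx(
            pseudo_log_likelihood(z, config, insts)
        )

    def test_penalty_arithmetic(self, make_instance):
        config = FeatureConfig(family=1)
        insts = [make_instance(0)]
        params = CRFParams(w_f=[1.0, -2.0, 0.5, 0.0], w_g=np.zeros(8))
        want = pseudo_log_likelihood(params, config, insts) - 1.0 * 3.5
        assert objective(params, config, insts, 1.0) == pytest.approx(want)


def _synthetic_training_set(seed, n=3):
    config = GeneratorConfig(
        Np=8, Nr=10, n_pairs=60, contact_density=0.15, coupling=0.9, seed=seed
    )
    return make_instances(config, n)


class TestFit:
    def test_recovers_coevolution_sign(self):
        # high MI should favor contact: the MI coefficient of the r=1 block
        # must end below the r=0 block's (exp(-U) convention)
        insts = _synthetic_training_set(10)
        config = FeatureConfig(family=1)
        params = fit(insts, config, TrainingConfig())
        assert params.w_f[1] < params.w_f[3]

    def test_large_c_returns_exact_zero(self, make_instance):
        config = FeatureConfig(family=1)
        insts = [make_instance(0)]
        gf, gg = pll_gradient(CRFParams.zeros(config), config, insts)
        c_big = float(np.abs(np.concatenate([gf, gg])).max()) + 1.0
        params = fit(insts, config, TrainingConfig(lasso_C=c_big))
        assert (params.w_f == 0.0).all()
        assert (params.w_g == 0.0).all()

    def test_sparsity_nondecreasing_in_c(self):
        insts = _synthetic_training_set(21)
        config = FeatureConfig(family=2, grouping=GroupingScheme.from_name(4))
        zero_counts = []
        for c in (0.0, 1.0, 2.0):
            p = fit(insts, config, TrainingConfig(lasso_C=c))
            zero_counts.append(int((p.w_f == 0).sum() + (p.w_g == 0).sum()))
        assert zero_counts[0] <= zero_counts[1] <= zero_counts[2]

    def test_l1_norm_shrinks_with_penalty(self):
        insts = _synthetic_training_set(5)
        config = FeatureConfig(family=1)
        free = fit(insts, config, TrainingConfig(lasso_C=0.0))
        shrunk = fit(insts, config, TrainingConfig(lasso_C=2.0))
        norm = lambda p: np.abs(p.w_f).sum() + np.abs(p.w_g).sum()
        assert norm(shrunk) <= norm(free) + 1e-8

    def test_monotone_objective_trace(self):
        insts = _synthetic_training_set(3, n=2)
        config = FeatureConfig(family=1)
        for c in (0.0, 1.0):
            _, info = fit(insts, config, TrainingConfig(lasso_C=c), return_info=True)
            trace = info.objective_trace
            assert len(trace) >= 2
            assert all(trace[k + 1] >= trace[k] - 1e-8 for k in range(len(trace) - 1))

    def test_restarts_find_no_better_optimum(self):
        # the per-cell objective is concave, so random initializations must
        # agree with the deterministic zero-start fit up to tolerance
        insts = _synthetic_training_set(8, n=2)
        config = FeatureConfig(family=1)
        base, info = fit(insts, config, TrainingConfig(), return_info=True)
        best = objective(base, config, insts, 0.0)
        rng = np.random.default_rng(0)
        for _ in range(10):
            start = CRFParams(
                w_f=rng.normal(0, 1, config.f_dim), w_g=rng.normal(0, 1, config.g_dim)
            )
            alt = fit(insts, config, TrainingConfig(initial_params=start))
            assert objective(alt, config, insts, 0.0) <= best + 1e-6

    def test_deterministic(self):
        insts = _synthetic_training_set(4, n=2)
        config = FeatureConfig(family=1)
        p1 = fit(insts, config, TrainingConfig())
        p2 = fit(insts, config, TrainingConfig())
        np.testing.assert_array_equal(p1.w_f, p2.w_f)
        np.testing.assert_array_equal(p1.w_g, p2.w_g)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            fit([], FeatureConfig(family=1), TrainingConfig())
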