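"""Synthetic paired alignments with planted coevolution at contact cells.

The generator emulates the coevolution premise behind MI-based contact
prediction: at a planted contact (i, j) the base distribution of RNA column
j depends on the amino-acid group of protein column i, while non-contact
columns are independent.  For each homolog row the residue at column i is
uniform over the 20 amino acids; a contacted base copies the group image of
one of its contacting residue columns with probability ``coupling`` (chosen
uniformly per row when several protein columns contact the same RNA column,
so every planted contact carries signal) and is uniform otherwise.

The coupled joint has closed-form MI (`analytic_coupled_mi`), used to
calibrate tests.  Defaults reflect the benchmark conditions used throughout
the test suite: 40x60 grids, 300 paired homologs, contact density 0.05,
coupling 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .alignments import Alignment, PROTEIN_ALPHABET, RNA_ALPHABET, SequenceRecord, pair_by_organism
from .coevolution import GroupingScheme, N_BASES
from .crf import ContactGrid, ProteinRNAInstance, build_instance


@dataclass(frozen=True)
class GeneratorConfig:
    """Dimensions, sample size and coupling strength of the generator."""

    Np: int = 40
    Nr: int = 60
    n_pairs: int = 300
    contact_density: float = 0.05
    coupling: float = 0.9
    grouping: int = 4
    seed: int = 0
    gap_rate: float = 0.0
    mi_kind: str = "mi"

    def __post_init__(self) -> None:
        if not 0.0 <= self.contact_density <= 1.0:
            raise ValueError("contact_density must be in [0, 1]")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must be in [0, 1]")
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be at least 2")
        if not 0.0 <= self.gap_rate < 1.0:
            raise ValueError("gap_rate must be in [0, 1)")

    @property
    def grouping_scheme(self) -> GroupingScheme:
        return GroupingScheme.from_name(self.grouping)


def _group_base_map(scheme: GroupingScheme) -> np.ndarray:
    """Deterministic image base for each amino-acid code (via its group)."""
    mapping = scheme.mapping
    return np.array(
        [mapping[aa] % N_BASES for aa in PROTEIN_ALPHABET], dtype=np.int64
    )


def plant_contacts(config: GeneratorConfig) -> ContactGrid:
    """Bernoulli(contact_density) grid from the seeded stream."""
    rng = np.random.default_rng([config.seed, 11])
    grid = rng.random((config.Np, config.Nr)) < config.contact_density
    return ContactGrid(r=grid.astype(np.int8))


def sample_paired_alignment(
    config: GeneratorConfig, contacts: ContactGrid
) -> "PairedAlignmentSet":
    """Paired alignments whose contact columns have coupled joint distributions.

    Row 0 of each alignment is the (gap-free) target sequence; organism tags
    are unique per row so `pair_by_organism` pairs all rows one-to-one.
    """
    from .alignments import PairedAlignmentSet  # local alias for the return type

    rng = np.random.default_rng([config.seed, 23])
    n, n_p, n_r = config.n_pairs, config.Np, config.Nr
    scheme = config.grouping_scheme
    base_of = _group_base_map(scheme)

    prot = rng.integers(0, 20, size=(n, n_p))
    rna = rng.integers(0, N_BASES, size=(n, n_r))
    for j in range(n_r):
        partners = np.flatnonzero(contacts.r[:, j])
        if partners.size == 0:
            continue
        choice = partners[rng.integers(0, partners.size, size=n)]
        coupled = rng.random(n) < config.coupling
        picked = prot[np.arange(n), choice]
        rna[coupled, j] = base_of[picked[coupled]]

    prot_chars = np.array(list(PROTEIN_ALPHABET))
    rna_chars = np.array(list(RNA_ALPHABET))
    prot_rows = ["".join(row) for row in prot_chars[prot]]
    rna_rows = ["".join(row) for row in rna_chars[rna]]

    if config.gap_rate > 0.0:
        # gaps only in non-reference rows, to exercise the gap symbol in MI
        def gapped(rows, length):
            out = [rows[0]]
            mask = rng.random((len(rows) - 1, length)) < config.gap_rate
            for k, row in enumerate(rows[1:]):
                chars = np.array(list(row))
                chars[mask[k]] = "-"
                out.append("".join(chars))
            return out

        prot_rows = gapped(prot_rows, n_p)
        rna_rows = gapped(rna_rows, n_r)

    def records(rows, prefix):
        return [
            SequenceRecord(
                identifier=f"{prefix}{k:04d}_ORG{k:04d}/1-{len(rows[k])}",
                organism_tag=f"ORG{k:04d}",
                residues=rows[k],
            )
            for k in range(len(rows))
        ]

    protein_aln = Alignment(records(prot_rows, "P"), "protein", reference_index=0)
    rna_aln = Alignment(records(rna_rows, "R"), "rna", reference_index=0)
    return pair_by_organism(protein_aln, rna_aln)


def make_instances(
    config: GeneratorConfig, n_instances: int
) -> list[ProteinRNAInstance]:
    """End-to-end labeled instances: contacts, alignments, MI, bundled labels.

    Deterministic per (seed, index); instance k uses the derived seed
    ``(seed * 1000 + k) mod 2^31``.
    """
    instances = []
    for k in range(n_instances):
        sub = replace(config, seed=(config.seed * 1000 + k) % (2**31))
        contacts = plant_contacts(sub)
        paired = sample_paired_alignment(sub, contacts)
        instances.append(
            build_instance(
                paired, sub.grouping_scheme, kind=sub.mi_kind, contacts=contacts
            )
        )
    return instances


def analytic_coupled_mi(grouping: GroupingScheme, coupling: float) -> float:
    """Closed-form MI (nats) of the generator's coupled (group, base) joint.

    Residues are uniform over 20 amino acids; the base equals the group's
    image base with probability ``coupling`` and is uniform otherwise.
    Computed on the grouped alphabet, matching MI counted under the same
    grouping (with no gaps the gap symbol has zero mass).
    """
    sizes = np.array([len(g) for g in grouping.groups], dtype=float)
    p_g = sizes / sizes.sum()
    n_groups = len(sizes)
    joint = np.zeros((n_groups, N_BASES))
    for gi in range(n_groups):
        image = gi % N_BASES
        for b in range(N_BASES):
            cond = coupling * (1.0 if b == image else 0.0) + (1.0 - coupling) / N_BASES
            joint[gi, b] = p_g[gi] * cond
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(joint > 0, joint * np.log(joint / (pa * pb)), 0.0)
    return float(terms.sum())
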