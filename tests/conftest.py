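"""Shared fixtures: small hand-built alignments and random CRF instances."""

from __future__ import annotations

import numpy as np
import pytest

from rbcontact.alignments import Alignment, SequenceRecord, pair_by_organism
from rbcontact.coevolution import GroupingScheme, MIMatrix
from rbcontact.crf import ContactGrid, CRFParams, FeatureConfig, ProteinRNAInstance

PROTEIN = "ACDEFGHIKLMNPQRSTVWY"
BASES = "ACGU"


def build_alignment(rows, kind, organisms=None, reference_index=0):
    """Alignment from raw row strings; organisms default to one per row."""
    if organisms is None:
        organisms = [f"ORG{k}" for k in range(len(rows))]
    records = [
        SequenceRecord(
            identifier=f"seq{k}_{org}/1-{len(row)}", organism_tag=org, residues=row
        )
        for k, (row, org) in enumerate(zip(rows, organisms))
    ]
    return Alignment(records, kind, reference_index)


def paired_from_columns(protein_rows, rna_rows):
    """PairedAlignmentSet with rows paired one-to-one in order."""
    return pair_by_organism(
        build_alignment(protein_rows, "protein"),
        build_alignment(rna_rows, "rna"),
    )


@pytest.fixture
def make_paired():
    return paired_from_columns


@pytest.fixture
def make_instance():
    """Factory for random labeled instances with arbitrary MI matrices."""

    def _make(seed, n_p=3, n_r=4, labeled=True):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list(PROTEIN), n_p))
        b = "".join(rng.choice(list(BASES), n_r))
        m = MIMatrix(rng.random((n_p, n_r)))
        r = ContactGrid(rng.integers(0, 2, (n_p, n_r))) if labeled else None
        return ProteinRNAInstance(a=a, b=b, m=m, r=r)

    return _make


@pytest.fixture
def make_params():
    def _make(seed, config: FeatureConfig, scale=0.5):
        rng = np.random.default_rng(seed)
        return CRFParams(
            w_f=rng.normal(0, scale, config.f_dim),
            w_g=rng.normal(0, scale, config.g_dim),
        )

    return _make


@pytest.fixture
def grouping():
    return GroupingScheme.from_name
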