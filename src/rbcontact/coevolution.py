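"""Coevolution scores between protein and RNA alignment columns.

Interacting residues and bases are under pressure to mutate in a coordinated
way, so the mutual information (MI) between the amino-acid distribution of a
protein column and the base distribution of an RNA column — counted over
organism-paired homolog rows — is a signal for contact.  The average-product
correction (APC) removes the background component shared by whole rows and
columns of the MI matrix, giving the corrected score MIp.

Frequencies are raw counts over paired rows divided by the number of pairs;
both alphabets include the gap character as an ordinary symbol, and amino
acids may first be collapsed onto a reduced alphabet (Murphy groupings).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .alignments import GAP, PROTEIN_ALPHABET, RNA_ALPHABET, PairedAlignmentSet
from .errors import AlphabetError

# Murphy reduced amino-acid alphabets, keyed by group count; 20 is the
# identity partition (alphabetical order).
_MURPHY_GROUPS: dict[int, list[str]] = {
    2: ["MLVICGATSPFYW", "DENQRKH"],
    4: ["MLVIC", "GATSP", "FYW", "DENQRKH"],
    8: ["MLVIC", "GA", "TS", "P", "FYW", "DENQ", "RK", "H"],
    10: ["MLVI", "C", "G", "A", "TS", "P", "FYW", "DENQ", "RK", "H"],
    15: ["MLVI", "C", "G", "A", "T", "S", "P", "FY", "W", "D", "E", "N", "Q", "RK", "H"],
    20: list(PROTEIN_ALPHABET),
}

N_BASES = 4
_BASE_INDEX = {b: k for k, b in enumerate(RNA_ALPHABET)}


@dataclass(frozen=True)
class GroupingScheme:
    """A partition of the 20 amino acids into labelled groups.

    The gap character maps to its own extra group (index ``group_count``),
    so the grouped MI alphabet has ``group_count + 1`` symbols.
    """

    name: int
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        covered = "".join(self.groups)
        if sorted(covered) != sorted(PROTEIN_ALPHABET):
            raise ValueError(f"grouping {self.name} does not partition the 20 amino acids")

    @classmethod
    def from_name(cls, name: int) -> "GroupingScheme":
        if name not in _MURPHY_GROUPS:
            raise ValueError(f"no grouping with {name} groups; choose from {sorted(_MURPHY_GROUPS)}")
        return cls(name=name, groups=tuple(_MURPHY_GROUPS[name]))

    @property
    def group_count(self) -> int:
        return len(self.groups)

    @property
    def gap_index(self) -> int:
        return self.group_count

    @property
    def mapping(self) -> dict[str, int]:
        table = {}
        for gi, members in enumerate(self.groups):
            for aa in members:
                table[aa] = gi
        return table

    def index_of(self, ch: str) -> int:
        """Group index of an amino-acid character (gap -> extra group)."""
        if ch == GAP:
            return self.gap_index
        try:
            return self.mapping[ch]
        except KeyError:
            raise AlphabetError(f"unknown amino acid {ch!r}") from None


IDENTITY_GROUPING = GroupingScheme.from_name(20)


def base_index(ch: str, allow_gap: bool = True) -> int:
    """Index of an RNA base; gap is symbol 4 when allowed."""
    if ch == GAP:
        if allow_gap:
            return N_BASES
        raise AlphabetError("gap base not allowed here")
    try:
        return _BASE_INDEX[ch]
    except KeyError:
        raise AlphabetError(f"unknown base {ch!r}") from None


@dataclass
class FrequencyTables:
    """Observed single-column and joint frequencies at one (i, j) pair."""

    P_i: np.ndarray  # grouped amino acids + gap
    P_j: np.ndarray  # A, C, G, U, gap
    P_ij: np.ndarray

    def __post_init__(self) -> None:
        for tab in (self.P_i, self.P_j, self.P_ij):
            if abs(float(tab.sum()) - 1.0) > 1e-12:
                raise ValueError("frequency table does not sum to 1")


@dataclass
class MIMatrix:
    """An Np x Nr matrix of coevolution scores (raw MI or APC-corrected)."""

    values: np.ndarray
    kind: str = "mi"  # "mi" | "mip"

    def __post_init__(self) -> None:
        if self.kind not in ("mi", "mip"):
            raise ValueError(f"unknown MIMatrix kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("MIMatrix.values must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tsv(self, path: str | os.PathLike) -> None:
        n_p, nr = self.shape
        header = "pos\t" + "\t".join(str(j + 1) for j in range(nr))
        with open(path, "w") as fh:
            fh.write(f"# kind={self.kind}\n{header}\n")
            for i in range(n_p):
                row = "\t".join(f"{v:.10g}" for v in self.values[i])
                fh.write(f"{i + 1}\t{row}\n")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "MIMatrix":
        with open(path) as fh:
            first = fh.readline().strip()
            kind = "mi"
            if first.startswith("#"):
                kind = first.split("kind=", 1)[1].strip()
                fh.readline()  # header row
            else:
                pass
            rows = [line.rstrip("\n").split("\t")[1:] for line in fh if line.strip()]
        return cls(values=np.array(rows, dtype=float), kind=kind)


def _encoded_columns(paired: PairedAlignmentSet, grouping: GroupingScheme):
    """Integer-coded paired rows: (n_pairs, Np) grouped codes, (n_pairs, Nr) base codes."""
    p_idx = [p for p, _ in paired.pairs]
    r_idx = [r for _, r in paired.pairs]
    prot = np.array(
        [[grouping.index_of(ch) for ch in paired.protein.records[p].residues] for p in p_idx],
        dtype=np.int64,
    )
    rna = np.array(
        [[base_index(ch) for ch in paired.rna.records[r].residues] for r in r_idx],
        dtype=np.int64,
    )
    return prot, rna


def joint_frequencies(
    paired: PairedAlignmentSet,
    i: int,
    j: int,
    grouping: GroupingScheme = IDENTITY_GROUPING,
) -> FrequencyTables:
    """Observed joint and marginal frequencies at protein position i, RNA position j.

    Counts run over the organism-paired rows only and are divided by the
    number of pairs, so the joint marginals equal the single-column tables
    exactly.
    """
    if not 0 <= i < paired.protein.length:
        raise IndexError(f"protein position {i} out of range")
    if not 0 <= j < paired.rna.length:
        raise IndexError(f"rna position {j} out of range")
    na = grouping.group_count + 1
    nb = N_BASES + 1
    joint = np.zeros((na, nb))
    for p_row, r_row in paired.pairs:
        a = grouping.index_of(paired.protein.records[p_row].residues[i])
        b = base_index(paired.rna.records[r_row].residues[j])
        joint[a, b] += 1.0
    joint /= paired.n_pairs
    return FrequencyTables(P_i=joint.sum(axis=1), P_j=joint.sum(axis=0), P_ij=joint)


def _mi_from_joint(joint: np.ndarray) -> np.ndarray:
    """MI for a stack of joint tables (..., A, B); 0*log 0 := 0, natural log."""
    pa = joint.sum(axis=-1, keepdims=True)
    pb = joint.sum(axis=-2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = joint / (pa * pb)
        terms = joint * np.log(ratio)
    terms = np.where(joint > 0, terms, 0.0)
    return terms.sum(axis=(-2, -1))


def mutual_information(
    paired: PairedAlignmentSet,
    grouping: GroupingScheme = IDENTITY_GROUPING,
) -> MIMatrix:
    """Mutual information between every protein column and every RNA column.

    ``m[i, j] = sum_ab P_ij(a,b) log( P_ij(a,b) / (P_i(a) P_j(b)) )`` in nats,
    over the grouped amino-acid alphabet plus gap and the four bases plus gap.
    """
    prot, rna = _encoded_columns(paired, grouping)
    n, np_len = prot.shape
    nr_len = rna.shape[1]
    na = grouping.group_count + 1
    nb = N_BASES + 1
    values = np.empty((np_len, nr_len))
    offsets = np.arange(nr_len) * (na * nb)
    for i in range(np_len):
        combined = prot[:, i : i + 1] * nb + rna  # (n, Nr)
        flat = (combined + offsets[None, :]).ravel()
        counts = np.bincount(flat, minlength=nr_len * na * nb).reshape(nr_len, na, nb)
        values[i] = _mi_from_joint(counts / n)
    return MIMatrix(values=values, kind="mi")


def apc_correction(mi: MIMatrix) -> MIMatrix:
    """Average-product correction adapted to the rectangular residue-base grid.

    ``m_ij - (sum_k m_ik)(sum_k m_kj) / (sum_ij m_ij)``; when the grand total
    is zero the correction term is defined as zero.  The corrected matrix sums
    to zero whenever the total MI is positive.
    """
    if mi.kind != "mi":
        raise ValueError("apc_correction expects a raw MI matrix")
    m = mi.values
    total = m.sum()
    if total == 0.0:
        return MIMatrix(values=np.zeros_like(m), kind="mip")
    row = m.sum(axis=1, keepdims=True)
    col = m.sum(axis=0, keepdims=True)
    return MIMatrix(values=m - row * col / total, kind="mip")
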