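"""Multiple sequence alignments and organism-based cross-alignment pairing.

A contact-prediction instance starts from two alignments — one of protein
homologs, one of RNA homologs — each containing the target sequence as a
reference row.  Columns where the reference carries a gap are deleted so that
alignment coordinates coincide with target-sequence positions, and rows from
the two alignments are paired by organism so joint column statistics can be
counted over matched homolog pairs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

from Bio import AlignIO

from .errors import AlignmentFormatError, EmptyInputError, EmptyPairingError

GAP = "-"
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
RNA_ALPHABET = "ACGU"

_ALPHABETS = {"protein": set(PROTEIN_ALPHABET), "rna": set(RNA_ALPHABET)}


def normalize_residues(residues: str, alphabet_kind: str) -> str:
    """Upper-case, map '.'/unknown codes to the gap character, T->U for RNA."""
    if alphabet_kind not in _ALPHABETS:
        raise ValueError(f"unknown alphabet_kind {alphabet_kind!r}")
    allowed = _ALPHABETS[alphabet_kind]
    out = []
    for ch in residues.upper():
        if ch == "." or ch == "_":
            ch = GAP
        if alphabet_kind == "rna" and ch == "T":
            ch = "U"
        if ch != GAP and ch not in allowed:
            # Unknown codes (X, B, Z, ...) are treated as gaps so that real
            # Pfam/Rfam files parse instead of failing on rare annotations.
            ch = GAP
        out.append(ch)
    return "".join(out)


def organism_from_identifier(identifier: str) -> str:
    """Extract the species token from a ``NAME_SPECIES/start-end`` identifier.

    Follows the mnemonic convention of UniProt/Pfam entry names (e.g. the
    ``THETH`` in ``RL18_THETH/1-110``).  Identifiers without an underscore
    fall back to the identifier itself (minus any ``/range`` suffix).
    """
    head = identifier.split("/", 1)[0]
    if "_" in head:
        return head.rsplit("_", 1)[1]
    return head


@dataclass
class SequenceRecord:
    identifier: str
    organism_tag: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("SequenceRecord.residues must be nonempty")


@dataclass
class Alignment:
    """An equal-length set of sequence rows with a designated reference row."""

    records: list[SequenceRecord]
    alphabet_kind: str
    reference_index: int = 0

    def __post_init__(self) -> None:
        if not self.records:
            raise EmptyInputError("alignment has no records")
        lengths = {len(rec.residues) for rec in self.records}
        if len(lengths) != 1:
            raise AlignmentFormatError(
                f"alignment rows have unequal lengths: {sorted(lengths)}"
            )
        if not 0 <= self.reference_index < len(self.records):
            raise ValueError("reference_index out of range")
        allowed = _ALPHABETS[self.alphabet_kind] | {GAP}
        for rec in self.records:
            bad = set(rec.residues) - allowed
            if bad:
                raise AlignmentFormatError(
                    f"characters {sorted(bad)} outside the "
                    f"{self.alphabet_kind} alphabet in {rec.identifier!r}"
                )

    @property
    def length(self) -> int:
        return len(self.records[0].residues)

    @property
    def reference(self) -> SequenceRecord:
        return self.records[self.reference_index]


@dataclass
class PairedAlignmentSet:
    """Two degapped alignments plus the organism-based row pairing."""

    protein: Alignment
    rna: Alignment
    pairs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise EmptyPairingError("no paired rows")
        p_rows = [p for p, _ in self.pairs]
        r_rows = [r for _, r in self.pairs]
        if len(set(p_rows)) != len(p_rows) or len(set(r_rows)) != len(r_rows):
            raise ValueError("a row index appears more than once in pairs")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def read_alignment(
    path: str | os.PathLike,
    format: str,
    alphabet_kind: str,
    reference_id: str | None = None,
) -> Alignment:
    """Read a Stockholm or aligned-FASTA alignment.

    ``#=GS <seq> OS`` organism annotations are honored when present
    (Pfam/Rfam dialect); otherwise the organism tag is taken from the
    mnemonic token of the identifier.  The reference row is the row whose
    identifier equals ``reference_id``, or row 0 when no id is supplied.
    """
    if format not in ("stockholm", "fasta"):
        raise ValueError(f"unsupported format {format!r}")
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:
        msg = str(exc)
        if "No records" in msg or "Empty file" in msg or "none" in msg.lower():
            raise EmptyInputError(f"{path}: no alignment records") from exc
        raise AlignmentFormatError(f"{path}: {msg}") from exc
    records = []
    for rec in msa:
        organism = rec.annotations.get("organism")
        if organism:
            organism = str(organism).strip()
        else:
            organism = organism_from_identifier(rec.id)
        records.append(
            SequenceRecord(
                identifier=rec.id,
                organism_tag=organism,
                residues=normalize_residues(str(rec.seq), alphabet_kind),
            )
        )
    if not records:
        raise EmptyInputError(f"{path}: no alignment records")
    reference_index = 0
    if reference_id is not None:
        matches = [i for i, r in enumerate(records) if r.identifier == reference_id]
        if matches:
            reference_index = matches[0]
    return Alignment(records, alphabet_kind, reference_index)


def write_alignment(aln: Alignment, path: str | os.PathLike) -> None:
    """Write an alignment as aligned FASTA (row order preserved)."""
    with open(path, "w") as fh:
        for rec in aln.records:
            fh.write(f">{rec.identifier} OS={rec.organism_tag}\n{rec.residues}\n")


def degap_to_reference(aln: Alignment) -> Alignment:
    """Delete every column where the reference row carries a gap.

    After degapping the alignment length equals the ungapped length of the
    target sequence, so column indices are target-sequence positions.
    """
    ref = aln.reference.residues
    keep = [k for k, ch in enumerate(ref) if ch != GAP]
    if not keep:
        raise EmptyInputError("reference row consists only of gaps")
    if len(keep) == len(ref):
        return aln
    records = [
        replace(rec, residues="".join(rec.residues[k] for k in keep))
        for rec in aln.records
    ]
    return Alignment(records, aln.alphabet_kind, aln.reference_index)


def pair_by_organism(protein: Alignment, rna: Alignment) -> PairedAlignmentSet:
    """Pair protein rows with RNA rows sharing an organism tag.

    The two reference rows are always paired with each other.  Every other
    organism present on both sides contributes one pair, formed from its
    first occurrence in each alignment; duplicate rows for the same organism
    are dropped.  Rows whose organism appears on only one side are ignored.
    """
    p_tags = {rec.organism_tag for rec in protein.records}
    r_tags = {rec.organism_tag for rec in rna.records}
    if not (p_tags & r_tags):
        raise EmptyPairingError("no organism occurs in both alignments")

    pairs = [(protein.reference_index, rna.reference_index)]
    used = {protein.reference.organism_tag, rna.reference.organism_tag}

    first_rna: dict[str, int] = {}
    for idx, rec in enumerate(rna.records):
        if idx != rna.reference_index and rec.organism_tag not in first_rna:
            first_rna[rec.organism_tag] = idx
    for idx, rec in enumerate(protein.records):
        if idx == protein.reference_index or rec.organism_tag in used:
            continue
        partner = first_rna.get(rec.organism_tag)
        if partner is not None:
            pairs.append((idx, partner))
            used.add(rec.organism_tag)
    return PairedAlignmentSet(protein=protein, rna=rna, pairs=pairs)
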