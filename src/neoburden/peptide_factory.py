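"""Mutant / wild-type peptide enumeration for MHC class I prediction.

A somatic missense mutation substitutes a single residue in a protein.
Every 8-, 9- and 10-mer window of the mutant protein that covers the
substituted position is a candidate epitope, and its coordinate-matched
window in the unmutated protein is the wild-type comparator.  An interior
mutation in a sufficiently long protein therefore yields 8 + 9 + 10 = 27
mutant/wild-type peptide pairs; mutations near a protein terminus, or in
short proteins, yield fewer.

Coordinates are 1-based and windows are closed intervals, matching the
protein-position convention of somatic mutation tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import SeqIO

from .exceptions import ReferenceMismatchError, SchemaError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AMINO_ACID_SET = frozenset(AMINO_ACIDS)

#: Peptide lengths presented by MHC class I considered throughout.
PEPTIDE_LENGTHS = (8, 9, 10)

#: Upper bound on pairs a single missense mutation can generate (8+9+10).
MAX_PAIRS_PER_MUTATION = sum(PEPTIDE_LENGTHS)

#: Gene-symbol prefixes identifying immunoglobulin loci.
IG_PREFIXES = ("IGH", "IGK", "IGL")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein product: gene symbol, residue sequence, IG flag."""

    gene: str
    sequence: str
    is_immunoglobulin: bool = False

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


@dataclass(frozen=True)
class PeptidePair:
    """A mutant k-mer and its coordinate-matched wild-type k-mer.

    ``window_start`` is the 1-based index of the first residue of the
    window in the protein; the mutated residue sits at offset
    ``protein_pos - window_start`` within both sequences.
    """

    gene: str
    protein_pos: int
    ref_aa: str
    alt_aa: str
    length: int
    window_start: int
    mutant_seq: str
    wt_seq: str


def apply_missense(
    protein_seq: str, protein_pos: int, ref_aa: str, alt_aa: str, gene: str = "?"
) -> str:
    """Return ``protein_seq`` with the single-residue substitution applied.

    Raises
    ------
    ValueError
        If the position is out of range or ``alt_aa == ref_aa`` (not a
        missense change).
    ReferenceMismatchError
        If the residue found at ``protein_pos`` is not ``ref_aa``.
    """
    if not 1 <= protein_pos <= len(protein_seq):
        raise ValueError(
            f"protein_pos {protein_pos} outside 1..{len(protein_seq)} for {gene}"
        )
    if ref_aa == alt_aa:
        raise ValueError(
            f"{gene} p.{protein_pos}{ref_aa}>{alt_aa}: ref == alt is not missense"
        )
    found = protein_seq[protein_pos - 1]
    if found != ref_aa:
        raise ReferenceMismatchError(
            f"{gene} position {protein_pos}: expected {ref_aa}, found {found}"
        )
    return protein_seq[: protein_pos - 1] + alt_aa + protein_seq[protein_pos:]


def window_starts(protein_len: int, protein_pos: int, k: int) -> list[int]:
    """1-based start positions of every k-mer window containing the mutation.

    A start ``s`` qualifies iff ``s <= protein_pos <= s + k - 1`` and the
    window fits inside the protein.  Empty when ``protein_len < k``.
    """
    if k < 1:
        raise ValueError(f"window length must be >= 1, got {k}")
    lo = max(1, protein_pos - k + 1)
    hi = min(protein_pos, protein_len - k + 1)
    return list(range(lo, hi + 1))


def enumerate_peptide_pairs(
    mutation, protein: ProteinRecord, lengths: Sequence[int] = PEPTIDE_LENGTHS
) -> list[PeptidePair]:
    """All mutant/wild-type k-mer pairs tiling across one missense mutation.

    ``mutation`` needs attributes ``gene``, ``protein_pos``, ``ref_aa`` and
    ``alt_aa`` (any object with that shape, typically a
    :class:`~neoburden.variant_ingest.MutationRecord`).  The wild-type
    member of each pair is taken from the unmutated protein at identical
    coordinates; other somatic mutations in the same protein are *not*
    composited into the window.
    """
    wt = protein.sequence
    mut = apply_missense(
        wt, mutation.protein_pos, mutation.ref_aa, mutation.alt_aa, gene=mutation.gene
    )
    pairs: list[PeptidePair] = []
    for k in lengths:
        for start in window_starts(len(wt), mutation.protein_pos, k):
            pairs.append(
                PeptidePair(
                    gene=mutation.gene,
                    protein_pos=mutation.protein_pos,
                    ref_aa=mutation.ref_aa,
                    alt_aa=mutation.alt_aa,
                    length=k,
                    window_start=start,
                    mutant_seq=mut[start - 1 : start - 1 + k],
                    wt_seq=wt[start - 1 : start - 1 + k],
                )
            )
    return pairs


def is_ig_gene(gene: str) -> bool:
    """Whether a gene symbol belongs to an immunoglobulin locus by prefix."""
    return gene.startswith(IG_PREFIXES)


def read_proteome(path) -> dict[str, ProteinRecord]:
    """Read a proteome FASTA into a mapping gene symbol -> ProteinRecord.

    The record id is the gene symbol; an ``IG=1`` tag in the description,
    or an IGH/IGK/IGL symbol prefix, marks immunoglobulin genes.  Sequences
    must use the 20 standard amino acids.
    """
    proteome: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise SchemaError(f"{path}: empty sequence for {rec.id}")
        bad = set(seq) - AMINO_ACID_SET
        if bad:
            raise SchemaError(
                f"{path}: non-standard residues {sorted(bad)} in {rec.id}"
            )
        if rec.id in proteome:
            raise SchemaError(f"{path}: duplicate gene symbol {rec.id}")
        ig = "IG=1" in rec.description.split() or is_ig_gene(rec.id)
        proteome[rec.id] = ProteinRecord(gene=rec.id, sequence=seq, is_immunoglobulin=ig)
    return proteome


def write_proteome(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    """Write protein records as FASTA (header: gene symbol + IG tag)."""
    with open(path, "w") as fh:
        for rec in records:
            tag = " IG=1" if rec.is_immunoglobulin else ""
            fh.write(f">{rec.gene}{tag}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
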