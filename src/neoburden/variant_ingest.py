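"""Somatic mutation table ingestion, candidate filtering, and load summaries.

The mutation table is a simplified MAF-like TSV with one row per somatic
mutation call: ``patient_id, gene, protein_pos (1-based), ref_aa, alt_aa,
classification``.  Parsing is strict: malformed rows are reported with
their line numbers rather than silently coerced.

Neoantigen candidacy follows the rule used throughout the package: only
missense mutations, in genes whose protein product is at least 8 residues
long, excluding nonstop mutations, and optionally excluding immunoglobulin
genes (IGH/IGK/IGL loci are hypermutated and subject to immune tolerance).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .peptide_factory import AMINO_ACID_SET, ProteinRecord, is_ig_gene

CLASSIFICATIONS = frozenset(
    {"missense", "nonsense", "frameshift", "silent", "nonstop", "other"}
)

MUTATION_COLUMNS = (
    "patient_id",
    "gene",
    "protein_pos",
    "ref_aa",
    "alt_aa",
    "classification",
)

#: Minimum protein length for a gene to enter neoantigen prediction.
MIN_PROTEIN_LEN = 8


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation call for one patient."""

    patient_id: str
    gene: str
    protein_pos: int
    ref_aa: str
    alt_aa: str
    classification: str


def _validate_record(row: Mapping[str, str], lineno: int) -> MutationRecord:
    try:
        pos = int(row["protein_pos"])
    except (TypeError, ValueError):
        raise SchemaError(f"line {lineno}: protein_pos {row['protein_pos']!r} is not an integer")
    if pos < 1:
        raise SchemaError(f"line {lineno}: protein_pos must be >= 1, got {pos}")
    ref, alt = str(row["ref_aa"]), str(row["alt_aa"])
    for label, aa in (("ref_aa", ref), ("alt_aa", alt)):
        if len(aa) != 1 or aa not in AMINO_ACID_SET:
            raise SchemaError(f"line {lineno}: {label} {aa!r} is not a standard amino acid")
    cls = str(row["classification"])
    if cls not in CLASSIFICATIONS:
        raise SchemaError(
            f"line {lineno}: unknown classification {cls!r}; "
            f"expected one of {sorted(CLASSIFICATIONS)}"
        )
    if cls == "missense" and ref == alt:
        raise SchemaError(f"line {lineno}: missense mutation with ref_aa == alt_aa ({ref})")
    return MutationRecord(
        patient_id=str(row["patient_id"]),
        gene=str(row["gene"]),
        protein_pos=pos,
        ref_aa=ref,
        alt_aa=alt,
        classification=cls,
    )


def read_mutation_table(path, collapse_duplicates: bool = True) -> list[MutationRecord]:
    """Parse a mutation TSV into validated :class:`MutationRecord` objects.

    Duplicate rows (same patient, gene, position, alt residue) are
    collapsed to a single mutation by default — mutations are counted,
    not calls.  All schema violations are collected and raised together.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    records: list[MutationRecord] = []
    problems: list[str] = []
    for i, row in enumerate(df.to_dict("records")):
        try:
            records.append(_validate_record(row, lineno=i + 2))  # +2: header is line 1
        except SchemaError as exc:
            problems.append(str(exc))
    if problems:
        raise SchemaError(f"{path}: {len(problems)} malformed rows:\n" + "\n".join(problems))
    if collapse_duplicates:
        seen: dict[tuple, MutationRecord] = {}
        for rec in records:
            seen.setdefault((rec.patient_id, rec.gene, rec.protein_pos, rec.alt_aa), rec)
        records = list(seen.values())
    return records


def select_neoantigen_candidates(
    records: Iterable[MutationRecord],
    proteome: Mapping[str, ProteinRecord],
    exclude_ig: bool = False,
    min_protein_len: int = MIN_PROTEIN_LEN,
) -> tuple[list[MutationRecord], Counter]:
    """Filter mutations down to neoantigen candidates.

    Returns the retained records plus a tally of drop reasons
    (``nonstop``, ``non_missense``, ``unknown_gene``, ``short_protein``,
    ``ig_gene``).  Idempotent: reapplying to its own output changes
    nothing.
    """
    kept: list[MutationRecord] = []
    tally: Counter = Counter()
    for rec in records:
        if rec.classification == "nonstop":
            tally["nonstop"] += 1
            continue
        if rec.classification != "missense":
            tally["non_missense"] += 1
            continue
        protein = proteome.get(rec.gene)
        if protein is None:
            tally["unknown_gene"] += 1
            continue
        if len(protein.sequence) < min_protein_len:
            tally["short_protein"] += 1
            continue
        if exclude_ig and (protein.is_immunoglobulin or is_ig_gene(rec.gene)):
            tally["ig_gene"] += 1
            continue
        kept.append(rec)
    return kept, tally


def _record_is_ig(rec: MutationRecord, proteome: Mapping[str, ProteinRecord] | None) -> bool:
    if proteome is not None and rec.gene in proteome:
        return proteome[rec.gene].is_immunoglobulin
    return is_ig_gene(rec.gene)


def mutation_load_summary(
    records: Iterable[MutationRecord],
    proteome: Mapping[str, ProteinRecord] | None = None,
    patient_ids: Sequence[str] | None = None,
    exclude_ig: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Per-patient mutation loads and cohort-level statistics.

    The returned frame has one row per patient with counts per
    classification, ``total_somatic``, ``missense`` and
    ``missense_non_ig``.  ``patient_ids`` may list patients with zero
    mutations so they are retained with count 0 (they fall in the "low"
    stratum downstream).

    Cohort statistics use the sample standard deviation (n-1).  The mean
    of log-transformed missense counts uses ln(count) for counts >= 1;
    zero-count patients are excluded from that average (and their number
    reported), mirroring a log-histogram of strictly positive counts.
    When ``exclude_ig`` the headline missense statistics are computed on
    the non-IG counts.
    """
    counts: dict[str, Counter] = {}
    for rec in records:
        per = counts.setdefault(rec.patient_id, Counter())
        per[rec.classification] += 1
        per["total_somatic"] += 1
        if rec.classification == "missense" and not _record_is_ig(rec, proteome):
            per["missense_non_ig"] += 1
    if patient_ids is not None:
        for pid in patient_ids:
            counts.setdefault(str(pid), Counter())
    rows = []
    for pid in sorted(counts):
        per = counts[pid]
        row = {"patient_id": pid}
        for cls in sorted(CLASSIFICATIONS):
            row[cls] = per.get(cls, 0)
        row["total_somatic"] = per.get("total_somatic", 0)
        row["missense_non_ig"] = per.get("missense_non_ig", 0)
        rows.append(row)
    df = pd.DataFrame(
        rows,
        columns=["patient_id", *sorted(CLASSIFICATIONS), "total_somatic", "missense_non_ig"],
    )
    if df.empty:
        raise ValueError("no mutation records and no patient_ids given")

    missense_col = "missense_non_ig" if exclude_ig else "missense"
    missense = df[missense_col].to_numpy(dtype=float)
    total = df["total_somatic"].to_numpy(dtype=float)
    positive = missense[missense >= 1]
    stats = {
        "n_patients": int(len(df)),
        "missense_mean": float(np.mean(missense)),
        "missense_sd": float(np.std(missense, ddof=1)) if len(df) > 1 else 0.0,
        "total_mean": float(np.mean(total)),
        "total_sd": float(np.std(total, ddof=1)) if len(df) > 1 else 0.0,
        "log_missense_mean": float(np.mean(np.log(positive))) if positive.size else float("nan"),
        "n_zero_missense_excluded_from_log": int((missense < 1).sum()),
        "exclude_ig": bool(exclude_ig),
    }
    return df, stats
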