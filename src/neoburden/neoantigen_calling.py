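"""Differential-binding neoantigen calling and per-patient burden tables.

A predicted neoantigen is any unique combination of mutant peptide
sequence and HLA allele, within one patient, whose mutant peptide is a
predicted binder (IC50 < 500 nM) while the coordinate-matched wild-type
peptide is not (IC50 > 500 nM).  The wild-type condition guards against
peptides the immune system is already tolerant to.  Values exactly at 500
nM fail both conditions (strict inequalities).  An *expressed* neoantigen
additionally has RNA-seq evidence (count >= 1) for at least one of its
source genes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import math

import numpy as np
import pandas as pd
from scipy import stats

from .binding import AffinityPredictor, BINDER_THRESHOLD_NM
from .exceptions import DataIntegrityError, DegenerateRegressionError, UnsupportedAlleleError
from .peptide_factory import PeptidePair


@dataclass(frozen=True)
class BindingCall:
    """Predicted affinities for one peptide pair on one allele."""

    patient_id: str
    pair: PeptidePair
    allele: str
    ic50_mut: float
    ic50_wt: float


@dataclass(frozen=True)
class Neoantigen:
    """A unique (mutant peptide, HLA allele) combination for a patient."""

    patient_id: str
    mutant_peptide: str
    allele: str
    source_genes: frozenset[str]
    ic50_mut: float
    ic50_wt: float
    expressed: bool = False


def score_peptide_pairs(
    patient_id: str,
    pairs: Sequence[PeptidePair],
    alleles: Iterable[str],
    predictor: AffinityPredictor,
) -> tuple[list[BindingCall], list[str]]:
    """Query the predictor for every pair x unique allele combination.

    The patient's allele multiset is reduced to its unique set first
    (homozygous alleles cannot create distinct peptide:allele
    combinations).  Alleles the predictor does not support are skipped and
    returned for the run log.
    """
    unique_alleles = sorted(set(alleles))
    supported = [a for a in unique_alleles if a in predictor.supported_alleles]
    skipped = [a for a in unique_alleles if a not in predictor.supported_alleles]
    calls: list[BindingCall] = []
    if pairs and supported:
        peptides: list[str] = []
        query_alleles: list[str] = []
        for pair in pairs:
            for allele in supported:
                peptides.extend((pair.mutant_seq, pair.wt_seq))
                query_alleles.extend((allele, allele))
        try:
            ic50 = predictor.predict_batch(peptides, query_alleles)
        except UnsupportedAlleleError:
            # Table predictors may support an allele for some peptides only;
            # fall back to per-query calls, skipping the gaps.
            ic50 = np.full(len(peptides), np.nan)
            for i, (pep, allele) in enumerate(zip(peptides, query_alleles)):
                try:
                    ic50[i] = predictor.predict(pep, allele)
                except UnsupportedAlleleError:
                    pass
        i = 0
        for pair in pairs:
            for allele in supported:
                mut, wt = ic50[i], ic50[i + 1]
                i += 2
                if math.isnan(mut) and math.isnan(wt):
                    continue
                calls.append(
                    BindingCall(
                        patient_id=patient_id,
                        pair=pair,
                        allele=allele,
                        ic50_mut=float(mut),
                        ic50_wt=float(wt),
                    )
                )
    return calls, skipped


def call_neoantigens(
    calls: Iterable[BindingCall],
    mut_threshold: float = BINDER_THRESHOLD_NM,
    wt_threshold: float = BINDER_THRESHOLD_NM,
) -> list[Neoantigen]:
    """Apply the differential-binding filter (pre-deduplication).

    Retains exactly the calls with ``ic50_mut < mut_threshold`` and
    ``ic50_wt > wt_threshold``.  A call missing either affinity raises
    :class:`DataIntegrityError`.
    """
    if not (mut_threshold > 0 and wt_threshold > 0):
        raise ValueError("thresholds must be positive")
    out: list[Neoantigen] = []
    for call in calls:
        if call.ic50_mut is None or call.ic50_wt is None or math.isnan(call.ic50_mut) or math.isnan(call.ic50_wt):
            raise DataIntegrityError(
                f"patient {call.patient_id}: incomplete affinity pair for "
                f"{call.pair.mutant_seq}:{call.allele}"
            )
        if call.ic50_mut < mut_threshold and call.ic50_wt > wt_threshold:
            out.append(
                Neoantigen(
                    patient_id=call.patient_id,
                    mutant_peptide=call.pair.mutant_seq,
                    allele=call.allele,
                    source_genes=frozenset({call.pair.gene}),
                    ic50_mut=call.ic50_mut,
                    ic50_wt=call.ic50_wt,
                )
            )
    return out


def dedup_unique(neoantigens: Sequence[Neoantigen]) -> list[Neoantigen]:
    """Collapse to one record per (mutant peptide, allele) within a patient.

    Source genes are unioned across collapsed records; the retained IC50
    pair is that of the best-binding (lowest mutant IC50) instance.
    Idempotent and independent of input order (output sorted by key).
    """
    if not neoantigens:
        return []
    patients = {n.patient_id for n in neoantigens}
    if len(patients) > 1:
        raise ValueError(f"dedup_unique is per patient; got {sorted(patients)}")
    best: dict[tuple[str, str], Neoantigen] = {}
    genes: dict[tuple[str, str], set[str]] = {}
    for n in neoantigens:
        key = (n.mutant_peptide, n.allele)
        genes.setdefault(key, set()).update(n.source_genes)
        cur = best.get(key)
        if cur is None or n.ic50_mut < cur.ic50_mut:
            best[key] = n
    return [
        replace(best[key], source_genes=frozenset(genes[key]))
        for key in sorted(best)
    ]


def apply_expression_filter(
    neoantigens: Iterable[Neoantigen],
    expression: Mapping[str, float],
    min_count: float = 1.0,
) -> list[Neoantigen]:
    """Flag neoantigens whose source gene shows RNA evidence.

    ``expressed`` is True iff *any* source gene has a count >= min_count;
    genes absent from the expression table count as zero.  Expression is
    gene-level — mutant-allele-specific read support is a non-goal.
    """
    return [
        replace(
            n,
            expressed=any(expression.get(g, 0) >= min_count for g in n.source_genes),
        )
        for n in neoantigens
    ]


BURDEN_COUNT_COLUMNS = (
    "total_somatic",
    "missense",
    "neoantigens",
    "expressed_neoantigens",
)


def burden_table(counts: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Label per-patient burdens as high/low and summarize the cohort.

    ``counts`` needs a ``patient_id`` column plus count columns (at least
    ``total_somatic, missense, neoantigens, expressed_neoantigens``;
    ``*_non_ig`` variants are labelled too when present).  "High" means
    strictly greater than the cohort arithmetic mean of that metric.
    Returns the labelled frame and a stats dict with mean/sd (sample sd)
    per metric.
    """
    if "patient_id" not in counts.columns:
        raise ValueError("counts must have a patient_id column")
    missing = [c for c in BURDEN_COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"counts missing columns {missing}")
    df = counts.copy()
    if (df[list(BURDEN_COUNT_COLUMNS)] < 0).any().any():
        raise ValueError("burden counts must be non-negative")
    if (df["expressed_neoantigens"] > df["neoantigens"]).any():
        raise ValueError("expressed_neoantigens exceeds neoantigens for some patient")
    if (df["missense"] > df["total_somatic"]).any():
        raise ValueError("missense exceeds total_somatic for some patient")
    metrics = [c for c in df.columns if c != "patient_id" and df[c].dtype.kind in "if"]
    stats_out: dict = {"n_patients": int(len(df))}
    for metric in metrics:
        values = df[metric].to_numpy(dtype=float)
        mean = float(np.mean(values))
        df[f"{metric}_high"] = values > mean
        stats_out[f"{metric}_mean"] = mean
        stats_out[f"{metric}_sd"] = float(np.std(values, ddof=1)) if len(df) > 1 else 0.0
    return df, stats_out


def mutation_neoantigen_regression(
    missense: Sequence[float], neoantigens: Sequence[float]
) -> dict:
    """OLS of neoantigen count on missense count: slope, intercept, R^2."""
    x = np.asarray(missense, dtype=float)
    y = np.asarray(neoantigens, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("missense and neoantigen vectors must be 1-D and equal length")
    if x.size < 3:
        raise ValueError(f"need >= 3 patients for regression, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateRegressionError("missense counts are constant; R^2 undefined")
    fit = stats.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
    }
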