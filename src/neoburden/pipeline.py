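"""End-to-end orchestration: ingest -> tile -> predict -> call -> survive.

`run_pipeline` executes the stages in order on the file bundle a cohort
provides (real or synthetic), writes per-stage outputs, and returns a run
report: versions, seeds, per-stage record counts, drop-reason tallies,
and the headline statistics (cohort burden means, mutation-neoantigen
R-squared, per-stratum two-year PFS, log-rank p, Cox table).  Stage
outputs are pure functions of the inputs and the config, so rerunning the
same config yields an identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

import lifelines
import scipy

from . import __version__
from .binding import (
    BINDER_THRESHOLD_NM,
    AffinityPredictor,
    SyntheticPSSMPredictor,
    TableAffinityPredictor,
)
from .exceptions import DegenerateRegressionError, NeoburdenError
from .neoantigen_calling import (
    apply_expression_filter,
    burden_table,
    call_neoantigens,
    dedup_unique,
    mutation_neoantigen_regression,
    score_peptide_pairs,
)
from .peptide_factory import enumerate_peptide_pairs, read_proteome
from .survival_analysis import (
    TWO_YEARS_DAYS,
    cox_fit,
    cox_nested_test,
    km_estimate,
    logrank_test,
    stratify_by_mean,
    stratify_by_quartiles,
    subgroup_survival,
    survival_rate_at,
)
from .variant_ingest import (
    mutation_load_summary,
    read_mutation_table,
    select_neoantigen_candidates,
)

logger = logging.getLogger(__name__)

HLA_COLUMNS = ("a1", "a2", "b1", "b2", "c1", "c2")


@dataclass
class RunConfig:
    """One reproducible pipeline run."""

    proteome: str
    mutations: str
    hla: str
    expression: str
    clinical: str
    out_dir: str
    predictor: str = "synthetic"  # "synthetic" | "table"
    affinity_table: str | None = None
    seed: int = 0
    binder_fraction: float = 0.02
    ic50_mut_threshold: float = BINDER_THRESHOLD_NM
    ic50_wt_threshold: float = BINDER_THRESHOLD_NM
    expression_min: float = 1.0
    exclude_ig: bool = False
    stratify: str = "mean"  # "mean" | "quartile"
    stratify_metric: str = "missense"
    subgroup_keys: Sequence[str] = field(default_factory=tuple)

    def validate(self) -> None:
        for name in ("ic50_mut_threshold", "ic50_wt_threshold", "expression_min"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.predictor not in ("synthetic", "table"):
            raise ValueError(f"unknown predictor {self.predictor!r}")
        if self.predictor == "table" and not self.affinity_table:
            raise ValueError("predictor 'table' requires affinity_table")
        if self.stratify not in ("mean", "quartile"):
            raise ValueError(f"unknown stratify mode {self.stratify!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _build_predictor(config: RunConfig, alleles: Sequence[str]) -> AffinityPredictor:
    if config.predictor == "table":
        return TableAffinityPredictor.from_tsv(config.affinity_table)
    return SyntheticPSSMPredictor(
        sorted(set(alleles)), seed=config.seed, binder_fraction=config.binder_fraction
    )


def _curve_payload(curve) -> dict:
    return {
        "timeline": [float(x) for x in curve.timeline],
        "survival": [float(x) for x in curve.survival],
    }


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if hasattr(obj, "timeline") and hasattr(obj, "survival"):
        return _curve_payload(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return (and write) the run report."""
    config.validate()
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "versions": {
            "neoburden": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "lifelines": lifelines.__version__,
        },
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    t0 = time.monotonic()

    # --- ingest ---------------------------------------------------------
    proteome = read_proteome(config.proteome)
    records = read_mutation_table(config.mutations)
    hla = pd.read_csv(config.hla, sep="\t", dtype=str)
    expression = pd.read_csv(config.expression, sep="\t")
    clinical = pd.read_csv(config.clinical, sep="\t")
    patient_ids = [str(p) for p in clinical["patient_id"]]
    loads, load_stats = mutation_load_summary(
        records, proteome, patient_ids=patient_ids, exclude_ig=config.exclude_ig
    )
    report["stages"]["ingest"] = {
        "n_proteins": len(proteome),
        "n_mutation_records": len(records),
        "n_patients": len(patient_ids),
        "load_stats": load_stats,
    }
    logger.info("ingest: %d mutations across %d patients", len(records), len(patient_ids))

    # --- tile + predict + call -----------------------------------------
    candidates, drop_tally = select_neoantigen_candidates(
        records, proteome, exclude_ig=config.exclude_ig
    )
    # IG-inclusive candidate set for the non-IG columns of the burden table
    candidates_all, _ = select_neoantigen_candidates(records, proteome, exclude_ig=False)
    hla_by_patient = {
        str(row["patient_id"]): [row[c] for c in HLA_COLUMNS if pd.notna(row[c])]
        for _, row in hla.iterrows()
    }
    all_alleles = sorted({a for alleles in hla_by_patient.values() for a in alleles})
    predictor = _build_predictor(config, all_alleles)

    expr_by_patient = {
        str(pid): dict(zip(sub["gene"].astype(str), sub["count"]))
        for pid, sub in expression.groupby("patient_id")
    }
    by_patient: dict[str, list] = {}
    for rec in candidates:
        by_patient.setdefault(rec.patient_id, []).append(rec)

    skipped_alleles: Counter = Counter()
    neo_rows, count_rows = [], []
    for pid in patient_ids:
        pairs = []
        for rec in by_patient.get(pid, []):
            pairs.extend(enumerate_peptide_pairs(rec, proteome[rec.gene]))
        calls, skipped = score_peptide_pairs(pid, pairs, hla_by_patient.get(pid, []), predictor)
        skipped_alleles.update(skipped)
        neos = dedup_unique(call_neoantigens(calls, config.ic50_mut_threshold, config.ic50_wt_threshold))
        neos = apply_expression_filter(neos, expr_by_patient.get(pid, {}), config.expression_min)
        n_ig_free = sum(
            1 for n in neos
            if not any(proteome[g].is_immunoglobulin for g in n.source_genes if g in proteome)
        )
        n_expr_ig_free = sum(
            1 for n in neos
            if n.expressed
            and not any(proteome[g].is_immunoglobulin for g in n.source_genes if g in proteome)
        )
        for n in neos:
            neo_rows.append(
                {
                    "patient_id": pid,
                    "peptide": n.mutant_peptide,
                    "allele": n.allele,
                    "ic50_mut": n.ic50_mut,
                    "ic50_wt": n.ic50_wt,
                    "genes": ";".join(sorted(n.source_genes)),
                    "expressed": int(n.expressed),
                }
            )
        count_rows.append(
            {
                "patient_id": pid,
                "neoantigens": len(neos),
                "expressed_neoantigens": sum(n.expressed for n in neos),
                "neoantigens_non_ig": n_ig_free,
                "expressed_neoantigens_non_ig": n_expr_ig_free,
            }
        )
    neo_df = pd.DataFrame(
        neo_rows,
        columns=["patient_id", "peptide", "allele", "ic50_mut", "ic50_wt", "genes", "expressed"],
    )
    counts = loads[["patient_id", "total_somatic", "missense", "missense_non_ig"]].merge(
        pd.DataFrame(count_rows), on="patient_id", how="right"
    )
    burdens, burden_stats = burden_table(counts)
    report["stages"]["neoantigen_calling"] = {
        "n_candidates": len(candidates),
        "drop_tally": dict(drop_tally),
        "n_candidates_with_ig": len(candidates_all),
        "skipped_alleles": dict(skipped_alleles),
        "n_neoantigen_records": int(len(neo_df)),
        "burden_stats": burden_stats,
    }

    try:
        regression = mutation_neoantigen_regression(burdens["missense"], burdens["neoantigens"])
    except (DegenerateRegressionError, ValueError) as exc:
        regression = {"error": str(exc)}
    report["stages"]["regression"] = regression

    # --- survival -------------------------------------------------------
    merged = burdens.merge(clinical, on="patient_id")
    metric = config.stratify_metric
    if metric not in merged.columns:
        raise NeoburdenError(f"stratification metric {metric!r} not in burden table")
    if config.stratify == "mean":
        labels, threshold = stratify_by_mean(merged[metric])
    else:
        labels, threshold = stratify_by_quartiles(merged[metric]), None
    merged["burden_label"] = labels
    survival_report: dict = {"metric": metric, "mode": config.stratify, "threshold": threshold}

    curves, two_year, groups = {}, {}, []
    for label, sub in merged.groupby("burden_label", sort=True):
        curve = km_estimate(sub["pfs_days"], sub["pfs_event"])
        curves[str(label)] = _curve_payload(curve)
        two_year[str(label)] = survival_rate_at(curve, TWO_YEARS_DAYS)
        groups.append((sub["pfs_days"].to_numpy(), sub["pfs_event"].to_numpy()))
    survival_report["two_year_pfs"] = two_year
    if len(groups) >= 2:
        survival_report["logrank"] = logrank_test(groups)

    if config.stratify == "mean":
        merged["high_burden"] = (merged["burden_label"] == "high").astype(int)
        try:
            univariate = cox_fit(merged, ["high_burden"])
            survival_report["cox_univariate"] = _jsonable(univariate)
        except (ValueError, NeoburdenError) as exc:
            survival_report["cox_univariate"] = {"error": str(exc)}
        cov_cols = []
        merged["iss_II"] = (merged["iss_stage"] == "II").astype(int)
        merged["iss_III"] = (merged["iss_stage"] == "III").astype(int)
        for c in ("iss_II", "iss_III", "cyto_high_risk", "age", "ldh_elevated", "chr1_amp"):
            if c in merged.columns and merged[c].nunique() > 1:
                cov_cols.append(c)
        if cov_cols:
            try:
                reduced = cox_fit(merged, cov_cols)
                full = cox_fit(merged, cov_cols + ["high_burden"])
                survival_report["cox_multivariate"] = _jsonable(full)
                survival_report["burden_added_benefit"] = cox_nested_test(full, reduced)
            except (ValueError, NeoburdenError) as exc:
                survival_report["cox_multivariate"] = {"error": str(exc)}

    subgroups = {}
    for key in config.subgroup_keys:
        subgroups[key] = _jsonable(
            subgroup_survival(merged, merged["burden_label"], key)
        )
    if subgroups:
        survival_report["subgroups"] = subgroups
    report["stages"]["survival"] = survival_report

    # --- write outputs --------------------------------------------------
    neo_df.to_csv(outdir / "neoantigens.tsv", sep="\t", index=False)
    burdens.to_csv(outdir / "burden.tsv", sep="\t", index=False)
    report_path = outdir / "report.json"
    payload = _jsonable(report)
    with open(report_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    # wall time stays out of the report so identical runs are byte-identical
    logger.info("pipeline finished in %.1fs; report at %s", time.monotonic() - t0, report_path)
    return payload
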