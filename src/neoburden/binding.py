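"""Peptide-MHC binding affinity: predictor contract, synthetic predictor,
and the 500 nM binder rule.

External neural-network affinity predictors are out of scope here; the
package instead defines a minimal predictor *contract* (strictly positive,
finite, deterministic IC50 in nanomolar for a supported HLA allele) with
two implementations:

``SyntheticPSSMPredictor``
    A deterministic position-specific scoring matrix predictor.  For each
    allele a 10 x 20 score matrix is drawn reproducibly from the
    construction seed; a peptide's score is the sum of its positional
    scores, and a monotone logistic map converts the standardized score
    into an IC50 on (0, 50000] nM.  A calibration knob fixes the marginal
    fraction of random peptides scoring under 500 nM (default 2%).

``TableAffinityPredictor``
    A lookup table loaded from a TSV produced by an external predictor run
    offline (columns: peptide, allele, ic50_nm).
"""

from __future__ import annotations

import abc
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .exceptions import InputInconsistencyError, SchemaError, UnsupportedAlleleError
from .peptide_factory import AMINO_ACIDS, AMINO_ACID_SET, PEPTIDE_LENGTHS

#: IC50 below which a peptide is a predicted binder (strict inequality).
BINDER_THRESHOLD_NM = 500.0

#: Cap on reported IC50, mirroring common predictor output conventions.
IC50_MAX_NM = 50000.0

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def is_binder(ic50: float, threshold: float = BINDER_THRESHOLD_NM) -> bool:
    """True iff ``ic50 < threshold`` (strict: exactly 500 is not a binder)."""
    if not ic50 > 0:
        raise ValueError(f"ic50 must be positive, got {ic50}")
    return ic50 < threshold


def _validate_query(peptide: str, allele: str, supported: frozenset[str]) -> None:
    if len(peptide) not in PEPTIDE_LENGTHS:
        raise ValueError(
            f"peptide length must be one of {PEPTIDE_LENGTHS}, got {len(peptide)}"
        )
    bad = set(peptide) - AMINO_ACID_SET
    if bad:
        raise ValueError(f"peptide {peptide!r} contains non-standard residues {sorted(bad)}")
    if allele not in supported:
        raise UnsupportedAlleleError(f"allele {allele!r} not supported by this predictor")


class AffinityPredictor(abc.ABC):
    """Contract: deterministic IC50 (nM) for an (8-10-mer, HLA allele) query."""

    @property
    @abc.abstractmethod
    def supported_alleles(self) -> frozenset[str]:
        """Alleles this predictor can score."""

    @abc.abstractmethod
    def predict(self, peptide: str, allele: str) -> float:
        """IC50 in nM, strictly positive and finite; purely a function of
        (peptide, allele) and the predictor's construction."""

    def predict_batch(self, peptides: Sequence[str], alleles: Sequence[str]) -> np.ndarray:
        """Vectorized convenience; default implementation loops."""
        if len(peptides) != len(alleles):
            raise ValueError("peptides and alleles must have equal length")
        return np.array([self.predict(p, a) for p, a in zip(peptides, alleles)])


class SyntheticPSSMPredictor(AffinityPredictor):
    """Deterministic PSSM predictor with calibrated binder rate.

    Per allele, a (10 positions x 20 residues) matrix of scores is drawn
    from ``SeedSequence([seed, *allele bytes])`` and each positional row is
    standardized to mean 0, sd 1 over the 20 residues.  A k-mer's score is
    ``z = sum(row[pos][residue]) / sqrt(k)``, so for residues drawn
    uniformly at random z has exactly zero mean and unit variance and is
    approximately standard normal.  The IC50 map

        ic50(z) = IC50_MAX / (1 + exp(slope * (z - c)))

    is strictly decreasing and anchored so that ic50 = 500 nM exactly at
    the (1 - binder_fraction) normal quantile: the marginal fraction of
    random peptides called binders is ``binder_fraction``.

    Parameters
    ----------
    allele_pool : iterable of str
        Alleles the predictor supports.
    seed : int
        Construction seed; together with the allele name it fully
        determines every output.
    binder_fraction : float
        Target marginal probability that a random peptide has IC50 < 500
        nM (default 0.02).
    slope : float
        Steepness of the logistic score-to-IC50 map.
    """

    def __init__(
        self,
        allele_pool: Iterable[str],
        seed: int = 0,
        binder_fraction: float = 0.02,
        slope: float = 3.0,
    ):
        alleles = list(dict.fromkeys(allele_pool))
        if not alleles:
            raise ValueError("allele_pool must be non-empty")
        if not 0.0 < binder_fraction < 1.0:
            raise ValueError(f"binder_fraction must be in (0, 1), got {binder_fraction}")
        self.seed = int(seed)
        self.binder_fraction = float(binder_fraction)
        self.slope = float(slope)
        z_crit = float(ndtri(1.0 - binder_fraction))
        # ic50(z_crit) == BINDER_THRESHOLD_NM exactly.
        self._center = z_crit - math.log(IC50_MAX_NM / BINDER_THRESHOLD_NM - 1.0) / slope
        self._matrices: dict[str, np.ndarray] = {}
        for allele in alleles:
            ss = np.random.SeedSequence([self.seed, *allele.encode("utf-8")])
            m = np.random.default_rng(ss).standard_normal((max(PEPTIDE_LENGTHS), 20))
            m -= m.mean(axis=1, keepdims=True)
            m /= m.std(axis=1, keepdims=True)
            self._matrices[allele] = m

    @property
    def supported_alleles(self) -> frozenset[str]:
        return frozenset(self._matrices)

    def _scores(self, encoded: np.ndarray, allele: str) -> np.ndarray:
        # encoded: (n, k) residue indices
        k = encoded.shape[1]
        m = self._matrices[allele]
        z = m[np.arange(k), encoded].sum(axis=1) / math.sqrt(k)
        return IC50_MAX_NM * expit(-self.slope * (z - self._center))

    def predict(self, peptide: str, allele: str) -> float:
        _validate_query(peptide, allele, self.supported_alleles)
        enc = np.array([[_AA_INDEX[aa] for aa in peptide]])
        return float(self._scores(enc, allele)[0])

    def predict_batch(self, peptides: Sequence[str], alleles: Sequence[str]) -> np.ndarray:
        if len(peptides) != len(alleles):
            raise ValueError("peptides and alleles must have equal length")
        out = np.empty(len(peptides))
        order = np.argsort(np.fromiter(map(len, peptides), int, len(peptides)), kind="stable")
        by_group: dict[tuple[str, int], list[int]] = {}
        for i in order:
            _validate_query(peptides[i], alleles[i], self.supported_alleles)
            by_group.setdefault((alleles[i], len(peptides[i])), []).append(int(i))
        for (allele, _k), idx in by_group.items():
            enc = np.array([[_AA_INDEX[aa] for aa in peptides[i]] for i in idx])
            out[idx] = self._scores(enc, allele)
        return out


def external_affinity_reader(path) -> dict[tuple[str, str], float]:
    """Load offline predictor output into a (peptide, allele) -> IC50 map.

    Duplicate keys with identical values collapse to one entry; duplicate
    keys with conflicting values raise :class:`InputInconsistencyError`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "allele": str})
    missing = [c for c in ("peptide", "allele", "ic50_nm") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    table: dict[tuple[str, str], float] = {}
    for pep, allele, ic50 in df[["peptide", "allele", "ic50_nm"]].itertuples(index=False):
        ic50 = float(ic50)
        if not 0 < ic50 <= IC50_MAX_NM:
            raise SchemaError(f"{path}: ic50 {ic50} for ({pep}, {allele}) outside (0, {IC50_MAX_NM}]")
        key = (str(pep), str(allele))
        if key in table and table[key] != ic50:
            raise InputInconsistencyError(
                f"{path}: conflicting ic50 for {key}: {table[key]} vs {ic50}"
            )
        table[key] = ic50
    return table


class TableAffinityPredictor(AffinityPredictor):
    """Predictor backed by a (peptide, allele) -> IC50 lookup table.

    A query for an allele absent from the table — or for a supported
    allele but an unseen peptide — raises
    :class:`~neoburden.exceptions.UnsupportedAlleleError`, mirroring how
    unsupported alleles are skipped upstream.
    """

    def __init__(self, table: Mapping[tuple[str, str], float]):
        self._table = dict(table)
        self._alleles = frozenset(a for _, a in self._table)

    @classmethod
    def from_tsv(cls, path) -> "TableAffinityPredictor":
        return cls(external_affinity_reader(path))

    @property
    def supported_alleles(self) -> frozenset[str]:
        return self._alleles

    def predict(self, peptide: str, allele: str) -> float:
        _validate_query(peptide, allele, self.supported_alleles)
        try:
            return self._table[(peptide, allele)]
        except KeyError:
            raise UnsupportedAlleleError(
                f"no affinity entry for peptide {peptide!r} with allele {allele!r}"
            ) from None
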