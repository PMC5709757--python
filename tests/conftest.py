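"""Shared fixtures: a hand-sized proteome/mutation/affinity micro-cohort.

The micro-cohort is small enough to check by literal brute force: every
8/9/10-mer of every wild-type and mutant protein is enumerated and given
an affinity from a short list of hand-picked IC50 values spanning both
sides of the 500 nM threshold, so the differential-binding definition can
be applied literally and compared against the pipeline.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import settings

from neoburden.peptide_factory import ProteinRecord, apply_missense
from neoburden.variant_ingest import MutationRecord

settings.register_profile("det", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("det")

#: IC50 values straddling the 500 nM rule, including exact-threshold ties.
HAND_IC50_CHOICES = (50.0, 250.0, 450.0, 499.0, 500.0, 501.0, 600.0, 1200.0, 5000.0, 30000.0)

MICRO_ALLELES = ("HLA-A*01:01", "HLA-B*07:02", "HLA-C*04:01")


def _seq(rng, n):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))


@pytest.fixture(scope="session")
def micro_proteome() -> dict[str, ProteinRecord]:
    rng = np.random.default_rng(2024)
    records = [
        ProteinRecord("GENE_A", _seq(rng, 15)),
        ProteinRecord("GENE_B", _seq(rng, 12)),
        ProteinRecord("GENE_C", _seq(rng, 9)),
        ProteinRecord("IGHV1-1", _seq(rng, 20), is_immunoglobulin=True),
        ProteinRecord("SHORT", _seq(rng, 7)),  # below the 8-residue floor
    ]
    return {p.gene: p for p in records}


@pytest.fixture(scope="session")
def micro_mutations(micro_proteome) -> list[MutationRecord]:
    """Three patients covering every filter branch."""

    def mut(pid, gene, pos, alt, cls="missense"):
        ref = micro_proteome[gene].sequence[pos - 1]
        if cls == "missense" and alt == ref:
            alt = "W" if ref != "W" else "Y"
        return MutationRecord(pid, gene, pos, ref, alt, cls)

    return [
        mut("PT1", "GENE_A", 8, "K"),
        mut("PT1", "GENE_B", 3, "L"),
        mut("PT1", "SHORT", 2, "A"),          # dropped: protein < 8 aa
        mut("PT2", "GENE_A", 8, "K"),          # same peptide as PT1's first
        mut("PT2", "IGHV1-1", 10, "D"),        # dropped only under exclude_ig
        mut("PT2", "GENE_C", 5, "H", cls="nonstop"),   # dropped: nonstop
        mut("PT3", "GENE_C", 5, "H"),
        mut("PT3", "GENE_A", 2, "M"),
        mut("PT3", "GENE_A", 14, "G"),
    ]


@pytest.fixture(scope="session")
def micro_hla() -> dict[str, list[str]]:
    a, b, c = MICRO_ALLELES
    return {
        "PT1": [a, a, b, b, c, c],   # homozygous everywhere
        "PT2": [a, b, b, c, c, c],
        "PT3": [a, a, a, b, c, b],
    }


@pytest.fixture(scope="session")
def micro_expression() -> dict[str, dict[str, int]]:
    return {
        "PT1": {"GENE_A": 12, "GENE_B": 0, "GENE_C": 3, "IGHV1-1": 40, "SHORT": 1},
        "PT2": {"GENE_A": 0, "IGHV1-1": 7, "GENE_C": 1},   # GENE_B/SHORT absent -> 0
        "PT3": {"GENE_A": 1, "GENE_C": 0},
    }


@pytest.fixture(scope="session")
def micro_affinity(micro_proteome, micro_mutations) -> dict[tuple[str, str], float]:
    """A complete hand-scale affinity table over every peptide the micro
    cohort could ever query, with IC50s drawn from the hand-picked list."""
    rng = np.random.default_rng(777)
    sequences = {p.gene: {p.sequence} for p in micro_proteome.values()}
    for m in micro_mutations:
        if m.classification != "missense":
            continue
        sequences[m.gene].add(
            apply_missense(micro_proteome[m.gene].sequence, m.protein_pos, m.ref_aa, m.alt_aa)
        )
    peptides = set()
    for seqs in sequences.values():
        for seq in seqs:
            for k in (8, 9, 10):
                for s in range(len(seq) - k + 1):
                    peptides.add(seq[s : s + k])
    table = {}
    for pep, allele in itertools.product(sorted(peptides), MICRO_ALLELES):
        table[(pep, allele)] = float(rng.choice(HAND_IC50_CHOICES))
    return table
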