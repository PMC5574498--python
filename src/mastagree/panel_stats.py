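"""Cutoff sweeps, per-analyzer positivity profiles, multi-positive summaries."""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .agreement import (
    DEFAULT_CUTOFF,
    concordant_positive_rate,
    tabulate,
    total_agreement,
    validate_cutoff,
)
from .model import Dataset, Panel
from .pairing import PairSet


@dataclass(frozen=True)
class SweepCell:
    agreement_pct: float
    concordant_positive_pct: float


@dataclass(frozen=True)
class SweepResult:
    """Agreement and CPR per (cutoff, allergen), from one pass over the pairs."""

    analyzer_a: str
    analyzer_b: str
    panel: Panel
    cells: Mapping[int, Mapping[str, SweepCell]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cutoff": cutoff,
                "allergen": allergen,
                "agreement_pct": cell.agreement_pct,
                "cpr_pct": cell.concordant_positive_pct,
            }
            for cutoff, by_allergen in sorted(self.cells.items())
            for allergen, cell in sorted(by_allergen.items())
        ]
        return pd.DataFrame(rows, columns=["cutoff", "allergen", "agreement_pct", "cpr_pct"])


def cutoff_sweep(pair_set: PairSet, cutoffs: Sequence[int]) -> SweepResult:
    """Recompute agreement and CPR for each cutoff from the same pairs.

    Cutoffs are applied to the stored class levels in a single pass per
    cutoff, so all sweep rows derive from one dataset; the concordant
    positive rate is non-increasing in the cutoff by construction.
    """
    if not cutoffs:
        raise ValueError("cutoffs must be non-empty")
    cutoffs = [validate_cutoff(t) for t in cutoffs]
    by_allergen_pairs = {
        allergen: [p for p in pair_set.pairs if p.allergen == allergen]
        for allergen in pair_set.allergens
    }
    cells: dict[int, dict[str, SweepCell]] = {}
    for t in cutoffs:
        cells[t] = {}
        for allergen, pairs in by_allergen_pairs.items():
            table = tabulate(pairs, t)
            cells[t][allergen] = SweepCell(
                agreement_pct=total_agreement(table),
                concordant_positive_pct=concordant_positive_rate(table),
            )
    return SweepResult(pair_set.analyzer_a, pair_set.analyzer_b, pair_set.panel, cells)


@dataclass(frozen=True)
class PositivityProfile:
    """Per-allergen positive counts and rates for one analyzer and panel."""

    analyzer_id: str
    panel: Panel
    cutoff: int
    n_patients: int
    counts: Mapping[str, int]

    def rate(self, allergen: str) -> float:
        if self.n_patients == 0:
            raise ZeroDivisionError("no patients tested")
        return self.counts.get(allergen, 0) * 100.0 / self.n_patients

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"allergen": allergen, "positive": count, "rate_pct": self.rate(allergen)}
            for allergen, count in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["allergen", "positive", "rate_pct"])


def positivity_profile(
    dataset: Dataset, analyzer: str, panel: Panel | str, cutoff: int = 1
) -> PositivityProfile:
    """Count patients with class >= *cutoff* per allergen for one analyzer.

    ``n_patients`` is the number of distinct patients with any record for
    this analyzer and panel.
    """
    panel = Panel(panel)
    t = validate_cutoff(cutoff)
    records = [r for r in dataset if r.analyzer_id == analyzer and r.panel == panel]
    patients = {r.patient_id for r in records}
    counts: Counter[str] = Counter()
    for rec in records:
        counts[rec.allergen] += 0  # register every tested allergen
        if rec.class_level >= t:
            counts[rec.allergen] += 1
    return PositivityProfile(
        analyzer_id=analyzer,
        panel=panel,
        cutoff=t,
        n_patients=len(patients),
        counts=dict(counts),
    )


@dataclass(frozen=True)
class MultiPositiveSummary:
    """How many patients have two or more positive allergens, and the maximum."""

    analyzer_id: str
    panel: Panel
    cutoff: int
    per_patient: Mapping[str, int]
    patients_with_multiple: int
    max_positive_allergens: int


def multi_positive_summary(
    dataset: Dataset, analyzer: str, panel: Panel | str, cutoff: int = DEFAULT_CUTOFF
) -> MultiPositiveSummary:
    """Per-patient positive-allergen counts at *cutoff* for one analyzer."""
    panel = Panel(panel)
    t = validate_cutoff(cutoff)
    per_patient: Counter[str] = Counter()
    for rec in dataset:
        if rec.analyzer_id != analyzer or rec.panel != panel:
            continue
        per_patient[rec.patient_id] += 0
        if rec.class_level >= t:
            per_patient[rec.patient_id] += 1
    counts = dict(per_patient)
    return MultiPositiveSummary(
        analyzer_id=analyzer,
        panel=panel,
        cutoff=t,
        per_patient=counts,
        patients_with_multiple=sum(1 for c in counts.values() if c >= 2),
        max_positive_allergens=max(counts.values(), default=0),
    )


def write_sweep_tsv(sweep: SweepResult, path: os.PathLike | str) -> None:
    sweep.to_frame().to_csv(path, sep="\t", index=False)
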