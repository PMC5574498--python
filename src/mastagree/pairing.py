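"""Matched-pair construction between two analyzers.

The unit of analysis is the matched pair: one (patient, allergen) with a
class-level reading from both analyzers under comparison.  Readings without
a counterpart on the other analyzer are excluded and logged, never imputed.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .model import Dataset, MastError, Panel


class EmptyComparisonError(MastError):
    """A comparison produced zero matched pairs."""


@dataclass(frozen=True)
class MatchedPair:
    """Class levels for one (patient, allergen) under analyzers A and B."""

    patient_id: str
    allergen: str
    class_a: int
    class_b: int


@dataclass(frozen=True)
class DroppedRecord:
    """A one-sided reading excluded by the matched-pair rule."""

    patient_id: str
    allergen: str
    present_on: str


@dataclass(frozen=True)
class PairSet:
    """All matched pairs for one (analyzer A, analyzer B, panel) comparison."""

    analyzer_a: str
    analyzer_b: str
    panel: Panel
    pairs: tuple[MatchedPair, ...]
    dropped: tuple[DroppedRecord, ...] = ()

    @property
    def n_patients(self) -> int:
        return len({p.patient_id for p in self.pairs})

    @property
    def allergens(self) -> tuple[str, ...]:
        return tuple(sorted({p.allergen for p in self.pairs}))

    def per_allergen_n(self) -> dict[str, int]:
        """Pair count per allergen; may vary when availability is unequal."""
        return dict(sorted(Counter(p.allergen for p in self.pairs).items()))

    def transposed(self) -> "PairSet":
        """Swap analyzers A and B (and every pair's readings)."""
        return PairSet(
            analyzer_a=self.analyzer_b,
            analyzer_b=self.analyzer_a,
            panel=self.panel,
            pairs=tuple(
                MatchedPair(p.patient_id, p.allergen, p.class_b, p.class_a)
                for p in self.pairs
            ),
            dropped=self.dropped,
        )


def build_pair_set(
    dataset: Dataset, analyzer_a: str, analyzer_b: str, panel: Panel | str
) -> PairSet:
    """Pair every (patient, allergen) read by both analyzers in *panel*.

    One-sided readings are dropped and recorded in the drop log.  Raises
    :class:`EmptyComparisonError` when no pair can be formed.
    """
    panel = Panel(panel)
    if analyzer_a == analyzer_b:
        raise ValueError("analyzer_a and analyzer_b must differ")
    present = {r.analyzer_id for r in dataset if r.panel == panel}
    for analyzer in (analyzer_a, analyzer_b):
        if analyzer not in present:
            raise EmptyComparisonError(
                f"analyzer {analyzer!r} has no {panel.value}-panel records"
            )

    side_a: dict[tuple[str, str], int] = {}
    side_b: dict[tuple[str, str], int] = {}
    for rec in dataset:
        if rec.panel != panel:
            continue
        if rec.analyzer_id == analyzer_a:
            side_a[(rec.patient_id, rec.allergen)] = rec.class_level
        elif rec.analyzer_id == analyzer_b:
            side_b[(rec.patient_id, rec.allergen)] = rec.class_level

    matched = sorted(side_a.keys() & side_b.keys())
    pairs = tuple(
        MatchedPair(patient, allergen, side_a[(patient, allergen)], side_b[(patient, allergen)])
        for patient, allergen in matched
    )
    dropped = tuple(
        DroppedRecord(patient, allergen, analyzer)
        for side, analyzer in ((side_a, analyzer_a), (side_b, analyzer_b))
        for patient, allergen in sorted(side.keys() - (side_a.keys() & side_b.keys()))
    )
    if not pairs:
        raise EmptyComparisonError(
            f"no matched pairs between {analyzer_a!r} and {analyzer_b!r} "
            f"on the {panel.value} panel"
        )
    return PairSet(analyzer_a, analyzer_b, panel, pairs, dropped)


def pairs_for_allergen(pair_set: PairSet, allergen: str) -> tuple[MatchedPair, ...]:
    """Pairs of *pair_set* for one canonical allergen (possibly empty)."""
    return tuple(p for p in pair_set.pairs if p.allergen == allergen)


def write_drop_log(pair_set: PairSet, path: os.PathLike | str) -> None:
    """Write the excluded one-sided readings as a TSV audit trail."""
    frame = pd.DataFrame(
        [
            {"patient_id": d.patient_id, "allergen": d.allergen, "present_on": d.present_on}
            for d in pair_set.dropped
        ],
        columns=["patient_id", "allergen", "present_on"],
    )
    frame.to_csv(path, sep="\t", index=False)
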