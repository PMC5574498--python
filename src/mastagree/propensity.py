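"""Directional positive-propensity statistic for paired comparisons.

One analyzer may systematically call positives the other does not.  The
propensity of analyzer A over B for an allergen is the signed excess of
one-sided discordance::

    (n_pn - n_np) * 100 / N

Positive values favor A, negative favor B.  Interpretation is by two
thresholds: an excess of at least ``presence`` percent (default 10) is a
declared positive propensity; below ``ns`` percent (default 5) the
discrepancy is not significant (NS); values in between are reported
without the propensity interpretation.  Both thresholds are configuration,
not hard-coded, because the listing convention between 5% and 10% is a
judgment call.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .agreement import DEFAULT_CUTOFF, PairedTable, tabulate
from .pairing import PairSet


class PropensityCategory(str, Enum):
    NS = "NS"
    REPORTED = "reported"
    POSITIVE_PROPENSITY = "positive_propensity"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class PropensityThresholds:
    """Interpretation thresholds in percent: ``ns <= presence``."""

    presence: float = 10.0
    ns: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ns <= self.presence <= 100.0:
            raise ValueError(
                f"need 0 <= ns ({self.ns}) <= presence ({self.presence}) <= 100"
            )


@dataclass(frozen=True)
class PropensitySummary:
    """Two one-sided views of one signed propensity value for an allergen."""

    allergen: str
    n: float
    prop_a_pct: float
    prop_b_pct: float
    category_a: PropensityCategory
    category_b: PropensityCategory

    @property
    def signed_pct(self) -> float:
        return self.prop_a_pct - self.prop_b_pct


def positive_propensity(table: PairedTable) -> float:
    """Signed propensity percentage; positive favors analyzer A."""
    n = table._require_nonempty()
    return (table.n_pn - table.n_np) * 100.0 / n


def classify_propensity(
    value: float, thresholds: PropensityThresholds = PropensityThresholds()
) -> tuple[PropensityCategory, PropensityCategory]:
    """Categorize the signed propensity for (analyzer A, analyzer B).

    The analyzer with the positive excess gets POSITIVE_PROPENSITY at
    ``|value| >= presence``, REPORTED in ``[ns, presence)``, else NS.  The
    other analyzer is always NS.
    """
    magnitude = abs(value)
    if magnitude >= thresholds.presence:
        winner = PropensityCategory.POSITIVE_PROPENSITY
    elif magnitude >= thresholds.ns:
        winner = PropensityCategory.REPORTED
    else:
        winner = PropensityCategory.NS
    if value > 0:
        return winner, PropensityCategory.NS
    if value < 0:
        return PropensityCategory.NS, winner
    return PropensityCategory.NS, PropensityCategory.NS


def summarize_propensity(
    allergen: str,
    table: PairedTable,
    thresholds: PropensityThresholds = PropensityThresholds(),
) -> PropensitySummary:
    value = positive_propensity(table)
    cat_a, cat_b = classify_propensity(value, thresholds)
    return PropensitySummary(
        allergen=allergen,
        n=table.n,
        prop_a_pct=max(value, 0.0),
        prop_b_pct=max(-value, 0.0),
        category_a=cat_a,
        category_b=cat_b,
    )


def propensity_report(
    pair_set: PairSet,
    cutoff: int = DEFAULT_CUTOFF,
    thresholds: PropensityThresholds = PropensityThresholds(),
    include_ns: bool = False,
) -> list[PropensitySummary]:
    """Per-allergen propensity summaries for a whole comparison.

    By default only allergens with at least one non-NS side are listed
    (mirroring how flagged-allergen tables are published); pass
    ``include_ns=True`` for the complete list.
    """
    out: list[PropensitySummary] = []
    for allergen in pair_set.allergens:
        pairs = [p for p in pair_set.pairs if p.allergen == allergen]
        summary = summarize_propensity(allergen, tabulate(pairs, cutoff), thresholds)
        if include_ns or (
            summary.category_a is not PropensityCategory.NS
            or summary.category_b is not PropensityCategory.NS
        ):
            out.append(summary)
    return out


def write_propensity_tsv(
    summaries: list[PropensitySummary],
    pair_set: PairSet,
    path: os.PathLike | str,
) -> None:
    """Serialize a propensity report with one one-sided column per analyzer."""
    from ._format import round_half_up

    rows = []
    for s in summaries:
        rows.append(
            {
                "allergen": s.allergen,
                "n": s.n,
                f"{pair_set.analyzer_a}_propensity_pct": (
                    round_half_up(s.prop_a_pct, 1) if s.prop_a_pct > 0 else "NS"
                ),
                f"{pair_set.analyzer_b}_propensity_pct": (
                    round_half_up(s.prop_b_pct, 1) if s.prop_b_pct > 0 else "NS"
                ),
                "category_a": s.category_a.value,
                "category_b": s.category_b.value,
                "signed_pct_full": s.signed_pct,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "allergen",
            "n",
            f"{pair_set.analyzer_a}_propensity_pct",
            f"{pair_set.analyzer_b}_propensity_pct",
            "category_a",
            "category_b",
            "signed_pct_full",
        ],
    )
    frame.to_csv(path, sep="\t", index=False)
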