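"""Dichotomization, 2x2 tabulation, agreement statistics and Cohen's kappa.

Class levels are dichotomized against a cutoff (minimal class counted as
positive).  For each allergen the paired positives/negatives form a 2x2
table from which four statistics are computed:

* total agreement percentage: ``(N - discordant) * 100 / N``
* concordant positive rate: ``n_pp * 100 / N`` — guards against agreement
  that is inflated purely by rare positives
* Cohen's kappa, chance-corrected agreement; UNDEFINED (``None``) exactly
  when the expected agreement ``p_e`` equals 1 (both marginals degenerate
  on the same side)
* a large-sample delta-method standard error for kappa
  (Fleiss-Cohen-Everitt) and the corresponding normal-approximation
  confidence interval.

Confidence bounds are *not* truncated to [-1, 1] by default; the
clinical-laboratory convention this package mirrors reports untruncated
bounds (upper bounds above 1 are possible for sparse tables).  Pass
``clip=True`` to :func:`kappa_ci` for conventional output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import norm

from .model import CLASS_MAX, CLASS_MIN, MastError, validate_class_level
from .pairing import EmptyComparisonError, MatchedPair, PairSet

CUTOFF_MIN = 1
CUTOFF_MAX = CLASS_MAX
DEFAULT_CUTOFF = 2


class UndefinedStatisticError(MastError):
    """Requested a statistic that is UNDEFINED for the given table."""


def validate_cutoff(cutoff: object) -> int:
    try:
        t = int(cutoff)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise ValueError(f"cutoff {cutoff!r} is not an integer")
    if not CUTOFF_MIN <= t <= CUTOFF_MAX:
        raise ValueError(f"cutoff {t} outside allowed range {CUTOFF_MIN}-{CUTOFF_MAX}")
    return t


def dichotomize(class_level: int, cutoff: int) -> bool:
    """True iff *class_level* counts as positive at *cutoff* (``>=``)."""
    return validate_class_level(class_level) >= validate_cutoff(cutoff)


@dataclass(frozen=True)
class PairedTable:
    """2x2 counts of dichotomized matched pairs.

    ``n_pp``: both positive; ``n_pn``: A positive / B negative;
    ``n_np``: A negative / B positive; ``n_nn``: both negative.
    Counts may be non-negative reals so that exact cell probabilities can be
    pushed through the same formulas.
    """

    n_pp: float
    n_pn: float
    n_np: float
    n_nn: float

    def __post_init__(self) -> None:
        for name in ("n_pp", "n_pn", "n_np", "n_nn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> float:
        return self.n_pp + self.n_pn + self.n_np + self.n_nn

    def transposed(self) -> "PairedTable":
        return PairedTable(self.n_pp, self.n_np, self.n_pn, self.n_nn)

    def _require_nonempty(self) -> float:
        if self.n <= 0:
            raise EmptyComparisonError("statistic undefined for an empty table")
        return self.n


def tabulate(pairs: Iterable[MatchedPair], cutoff: int = DEFAULT_CUTOFF) -> PairedTable:
    """Dichotomize *pairs* at *cutoff* and count the four concordance cells."""
    t = validate_cutoff(cutoff)
    n_pp = n_pn = n_np = n_nn = 0
    empty = True
    for pair in pairs:
        empty = False
        a, b = pair.class_a >= t, pair.class_b >= t
        if a and b:
            n_pp += 1
        elif a:
            n_pn += 1
        elif b:
            n_np += 1
        else:
            n_nn += 1
    if empty:
        raise EmptyComparisonError("cannot tabulate an empty pair collection")
    return PairedTable(n_pp, n_pn, n_np, n_nn)


def total_agreement(table: PairedTable) -> float:
    """Total agreement percentage: (N - discordant) * 100 / N."""
    n = table._require_nonempty()
    return (n - table.n_pn - table.n_np) * 100.0 / n


def concordant_positive_rate(table: PairedTable) -> float:
    """Both-positive percentage: n_pp * 100 / N."""
    n = table._require_nonempty()
    return table.n_pp * 100.0 / n


def _proportions(table: PairedTable) -> tuple[float, float, float, float, float, float]:
    n = table._require_nonempty()
    p_pp, p_pn, p_np, p_nn = (table.n_pp / n, table.n_pn / n, table.n_np / n, table.n_nn / n)
    pa = p_pp + p_pn  # P(A positive)
    pb = p_pp + p_np  # P(B positive)
    return p_pp, p_pn, p_np, p_nn, pa, pb


def expected_agreement(table: PairedTable) -> float:
    """Chance agreement p_e under independent marginals."""
    _, _, _, _, pa, pb = _proportions(table)
    return pa * pb + (1.0 - pa) * (1.0 - pb)


def cohen_kappa(table: PairedTable) -> float | None:
    """Cohen's kappa for the dichotomized table; ``None`` when p_e = 1.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement
    proportion and p_e the chance agreement from the marginals.
    """
    p_pp, _, _, p_nn, _, _ = _proportions(table)
    p_o = p_pp + p_nn
    p_e = expected_agreement(table)
    if p_e >= 1.0:
        return None
    return (p_o - p_e) / (1.0 - p_e)


def kappa_se(table: PairedTable, kappa: float | None = None) -> float:
    """Large-sample delta-method SE of kappa (Fleiss-Cohen-Everitt).

    With cell proportions p_ij, row marginals p_i., column marginals p_.j:

        SE = sqrt(T1 + T2 - T3) / ((1 - p_e) * sqrt(N))
        T1 = sum_i p_ii * [1 - (p_i. + p_.i)(1 - kappa)]^2
        T2 = (1 - kappa)^2 * sum_{i!=j} p_ij * (p_.i + p_j.)^2
        T3 = [kappa - p_e (1 - kappa)]^2

    Raises :class:`UndefinedStatisticError` when kappa is UNDEFINED.
    """
    if kappa is None:
        kappa = cohen_kappa(table)
    if kappa is None:
        raise UndefinedStatisticError("kappa SE undefined when kappa is undefined")
    p_pp, p_pn, p_np, p_nn, pa, pb = _proportions(table)
    p_e = expected_agreement(table)
    one_minus_k = 1.0 - kappa
    t1 = (
        p_pp * (1.0 - (pa + pb) * one_minus_k) ** 2
        + p_nn * (1.0 - ((1.0 - pa) + (1.0 - pb)) * one_minus_k) ** 2
    )
    # i=+, j=-: (p_.+ + p_-.)^2 ; i=-, j=+: (p_.- + p_+.)^2
    t2 = one_minus_k**2 * (
        p_pn * (pb + (1.0 - pa)) ** 2 + p_np * ((1.0 - pb) + pa) ** 2
    )
    t3 = (kappa - p_e * one_minus_k) ** 2
    inner = t1 + t2 - t3
    if inner < 0.0:  # numerical cancellation; exact value is >= 0
        inner = 0.0
    return math.sqrt(inner) / ((1.0 - p_e) * math.sqrt(table.n))


def kappa_ci(
    kappa: float,
    se: float,
    level: float = 0.95,
    clip: bool = False,
) -> tuple[float, float]:
    """Normal-approximation CI ``kappa +/- z * se``.

    Bounds are untruncated by default (upper bounds > 1 are reported as
    such); set ``clip=True`` to clamp to [-1, 1].
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    if se < 0:
        raise ValueError("se must be non-negative")
    z = norm.ppf(0.5 + level / 2.0)
    low, high = kappa - z * se, kappa + z * se
    if clip:
        low, high = max(low, -1.0), min(high, 1.0)
    return low, high


@dataclass(frozen=True)
class AgreementSummary:
    """Full-precision agreement statistics for one collection of pairs.

    ``kappa``/``kappa_se``/``ci_low``/``ci_high`` are ``None`` when kappa is
    UNDEFINED (p_e = 1; e.g. every pair concordant-negative).  Rounding to
    the reporting precision happens in the report layer only.
    """

    table: PairedTable
    agreement_pct: float
    concordant_positive_pct: float
    kappa: float | None
    kappa_se: float | None
    ci_low: float | None
    ci_high: float | None
    z: float
    level: float = 0.95

    @property
    def n(self) -> float:
        return self.table.n

    @property
    def kappa_defined(self) -> bool:
        return self.kappa is not None


def summarize_table(
    table: PairedTable, level: float = 0.95, clip_ci: bool = False
) -> AgreementSummary:
    """All agreement statistics for an already-tabulated 2x2 table."""
    kappa = cohen_kappa(table)
    if kappa is None:
        se = lo = hi = None
    else:
        se = kappa_se(table, kappa)
        lo, hi = kappa_ci(kappa, se, level=level, clip=clip_ci)
    return AgreementSummary(
        table=table,
        agreement_pct=total_agreement(table),
        concordant_positive_pct=concordant_positive_rate(table),
        kappa=kappa,
        kappa_se=se,
        ci_low=lo,
        ci_high=hi,
        z=float(norm.ppf(0.5 + level / 2.0)),
        level=level,
    )


def summarize_agreement(
    pairs: Sequence[MatchedPair],
    cutoff: int = DEFAULT_CUTOFF,
    level: float = 0.95,
    clip_ci: bool = False,
) -> AgreementSummary:
    """Tabulate *pairs* at *cutoff* and compute all agreement statistics."""
    return summarize_table(tabulate(pairs, cutoff), level=level, clip_ci=clip_ci)


def agreement_by_allergen(
    pair_set: PairSet,
    cutoff: int = DEFAULT_CUTOFF,
    level: float = 0.95,
    clip_ci: bool = False,
) -> dict[str, AgreementSummary]:
    """Per-allergen agreement summaries for a whole comparison."""
    out: dict[str, AgreementSummary] = {}
    for allergen in pair_set.allergens:
        pairs = [p for p in pair_set.pairs if p.allergen == allergen]
        out[allergen] = summarize_agreement(pairs, cutoff, level=level, clip_ci=clip_ci)
    return out
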