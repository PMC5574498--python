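"""Tabular report rendering at publication precision.

Percent columns are rounded to 1 decimal place and kappa-scale columns to
2 (half-up); full-precision machine-readable columns ride alongside so the
rounded view never has to be re-parsed for downstream numerics.
"""

from __future__ import annotations

import os

import pandas as pd

from ._format import fmt_kappa, fmt_pct
from .agreement import AgreementSummary
from .pairing import PairSet


def agreement_frame(summaries: dict[str, AgreementSummary]) -> pd.DataFrame:
    """One row per allergen, rounded display columns + full-precision columns."""
    rows = []
    for allergen, s in summaries.items():
        rows.append(
            {
                "allergen": allergen,
                "n": s.n,
                "agreement_pct": fmt_pct(s.agreement_pct),
                "concordant_positive_pct": fmt_pct(s.concordant_positive_pct),
                "kappa": fmt_kappa(s.kappa),
                "ci_low": fmt_kappa(s.ci_low),
                "ci_high": fmt_kappa(s.ci_high),
                "agreement_pct_full": s.agreement_pct,
                "cpr_pct_full": s.concordant_positive_pct,
                "kappa_full": s.kappa,
                "kappa_se_full": s.kappa_se,
                "ci_low_full": s.ci_low,
                "ci_high_full": s.ci_high,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "allergen",
            "n",
            "agreement_pct",
            "concordant_positive_pct",
            "kappa",
            "ci_low",
            "ci_high",
            "agreement_pct_full",
            "cpr_pct_full",
            "kappa_full",
            "kappa_se_full",
            "ci_low_full",
            "ci_high_full",
        ],
    )


def write_agreement_tsv(
    summaries: dict[str, AgreementSummary], pair_set: PairSet, path: os.PathLike | str
) -> None:
    frame = agreement_frame(summaries)
    frame.insert(1, "analyzer_a", pair_set.analyzer_a)
    frame.insert(2, "analyzer_b", pair_set.analyzer_b)
    frame.insert(3, "panel", pair_set.panel.value)
    frame.to_csv(path, sep="\t", index=False)
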