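"""Threshold benchmarking and group summaries of TBC and CC.

A colostrum sample *fails* when its total bacterial count exceeds
100,000 cfu/ml or its coliform count exceeds 10,000 cfu/ml (strict
inequalities), the conventional hygiene thresholds for colostrum.
Percentages are reported to one decimal place with half-up rounding for
parity with published benchmark tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

TBC_THRESHOLD = 100_000.0
CC_THRESHOLD = 10_000.0


@dataclass(frozen=True)
class ThresholdRule:
    tbc_threshold: float = TBC_THRESHOLD
    cc_threshold: float = CC_THRESHOLD

    def __post_init__(self) -> None:
        if self.tbc_threshold <= 0 or self.cc_threshold <= 0:
            raise ValueError("thresholds must be positive")


DEFAULT_RULE = ThresholdRule()


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (so 29.55 -> 29.6, not banker's 29.5)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Percentage to *ndigits* decimals, half-up; requires denominator > 0."""
    if denominator <= 0:
        raise ValueError("percentage of an empty group is undefined")
    return round_half_up(100.0 * numerator / denominator, ndigits)


def classify_failure(tbc, cc, rule: ThresholdRule = DEFAULT_RULE):
    """Flag threshold failures; strict comparison so the threshold itself
    passes.  Accepts scalars or arrays."""
    tbc_arr = np.asarray(tbc, dtype=float)
    cc_arr = np.asarray(cc, dtype=float)
    if np.any(tbc_arr < 0) or np.any(cc_arr < 0):
        raise ValueError("counts must be >= 0")
    tbc_fail = tbc_arr > rule.tbc_threshold
    cc_fail = cc_arr > rule.cc_threshold
    if np.isscalar(tbc) and np.isscalar(cc):
        return bool(tbc_fail), bool(cc_fail)
    return tbc_fail, cc_fail


def _summary_row(label: str, sub: pd.DataFrame, rule: ThresholdRule) -> dict:
    n = len(sub)
    tbc_fail, cc_fail = classify_failure(
        sub["tbc"].to_numpy(dtype=float), sub["cc"].to_numpy(dtype=float), rule
    )
    either = tbc_fail | cc_fail
    row: dict = {"group": label, "n": n}
    if n == 0:
        row.update(
            mean_tbc=np.nan, median_tbc=np.nan, mean_cc=np.nan, median_cc=np.nan,
            pct_tbc_fail=np.nan, pct_cc_fail=np.nan, pct_either_fail=np.nan,
            pct_zero_cc=np.nan,
        )
        return row
    row.update(
        mean_tbc=float(sub["tbc"].mean()),
        median_tbc=float(sub["tbc"].median()),
        mean_cc=float(sub["cc"].mean()),
        median_cc=float(sub["cc"].median()),
        pct_tbc_fail=pct(int(tbc_fail.sum()), n),
        pct_cc_fail=pct(int(cc_fail.sum()), n),
        pct_either_fail=pct(int(either.sum()), n),
        pct_zero_cc=pct(int((sub["cc"] == 0).sum()), n),
    )
    return row


def summarize_by_group(
    df: pd.DataFrame, grouping: str | None, rule: ThresholdRule = DEFAULT_RULE
) -> pd.DataFrame:
    """One summary row per level of *grouping* (``None`` for the whole table):
    n, mean/median counts, failure percentages and the zero-CC share."""
    if grouping is None:
        return pd.DataFrame([_summary_row("all", df, rule)])
    if grouping not in df.columns:
        raise KeyError(f"grouping variable not in table: {grouping}")
    rows = [
        _summary_row(str(level), sub, rule)
        for level, sub in df.groupby(grouping, sort=True, observed=True)
    ]
    return pd.DataFrame(rows)


def farm_failure_rates(
    df: pd.DataFrame, rule: ThresholdRule = DEFAULT_RULE
) -> pd.DataFrame:
    """Per-farm failure percentages for TBC, CC and either threshold."""
    rows = []
    for farm, sub in df.groupby("farm_id", sort=True):
        n = len(sub)
        tbc_fail, cc_fail = classify_failure(
            sub["tbc"].to_numpy(dtype=float), sub["cc"].to_numpy(dtype=float), rule
        )
        rows.append(
            {
                "farm_id": farm,
                "n": n,
                "n_tbc_fail": int(tbc_fail.sum()),
                "n_cc_fail": int(cc_fail.sum()),
                "pct_tbc_fail": pct(int(tbc_fail.sum()), n),
                "pct_cc_fail": pct(int(cc_fail.sum()), n),
                "pct_either_fail": pct(int((tbc_fail | cc_fail).sum()), n),
            }
        )
    return pd.DataFrame(rows)
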