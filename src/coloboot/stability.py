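"""Bootstrap stability selection: the package's core inferential loop.

For each of B replicates a bootstrap sample of the records (with replacement,
same size as the original table) is drawn, backward AIC elimination is run on
the resample, and the surviving terms and their per-level coefficients are
archived.  The archive is summarised per variable level as:

* **stability** — percentage of replicates in which the term survived,
* **mean coefficient** and the 2.5th/97.5th-percentile bootstrap confidence
  interval over the replicates where the term was selected,
* a **bootstrap p-value** — one minus the proportion of selected-replicate
  coefficients on the majority (mean's) side of zero.

Terms with stability > 10% and bootstrap p < 0.025 (strict) are deemed both
relatively stable and of reasonable effect size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import LMMResults
from .preprocess import Dataset
from .schema import MODEL_TERMS, VARIABLES_BY_NAME, term_label
from .stepwise import StepResult, backward_step, record_selection

DEFAULT_B = 1000
STABILITY_MIN = 10.0
P_MAX = 0.025
_MAX_REDRAWS = 100


@dataclass
class ReplicateResult:
    """One bootstrap replicate's selection outcome."""

    index: int
    seed: int
    selected: dict[str, bool]
    coefs: dict[str, float]
    converged: bool
    n_redraws: int = 0


def bootstrap_p(coefficients) -> float:
    """One minus the proportion of coefficients on the majority side of zero.

    The majority side is the side of zero where the mean lies (proportion
    below zero if the mean is above zero and vice versa); exact zeros count
    toward the minority side, making the value conservative.
    """
    c = np.asarray(list(coefficients), dtype=float)
    if c.size == 0:
        raise ValueError("bootstrap_p needs at least one coefficient")
    pos = float((c > 0).mean())
    neg = float((c < 0).mean())
    mean = c.mean()
    if mean > 0:
        q = pos
    elif mean < 0:
        q = neg
    else:
        q = max(pos, neg)
    return 1.0 - q


def stability_pct(replicates, term: str) -> float:
    """Percentage of replicates selecting *term* (denominator: all B)."""
    reps = list(replicates)
    if not reps:
        raise ValueError("no replicates")
    if any(term not in r.selected for r in reps):
        raise KeyError(f"unknown term: {term}")
    return 100.0 * sum(r.selected[term] for r in reps) / len(reps)


def summarize_coefficients(replicates, level_key: str):
    """Mean and percentile 95% interval of a level's coefficient over the
    replicates where it was recorded (linear-interpolation quantile rule)."""
    vals = np.array(
        [r.coefs[level_key] for r in replicates if level_key in r.coefs], dtype=float
    )
    if vals.size == 0:
        raise ValueError(f"level never selected: {level_key}")
    lo, hi = np.quantile(vals, [0.025, 0.975], method="linear")
    return float(vals.mean()), float(lo), float(hi)


def bootstrap_replicate(
    dataset: Dataset,
    outcome: str,
    candidate_terms,
    replicate_seed: int,
    index: int = 0,
    mode: str = "record",
) -> ReplicateResult:
    """Draw one bootstrap resample and run backward elimination on it.

    ``mode="record"`` resamples rows (the default, matching a same-size
    with-replacement sample of the records); ``mode="farm"`` resamples whole
    farms (cluster bootstrap).  Resamples with fewer than 2 distinct farms
    are redrawn from the next substream.
    """
    rng = np.random.default_rng(replicate_seed)
    n = dataset.n
    farms = dataset.frame["farm_id"].to_numpy()
    unique_farms = np.unique(farms)
    for redraw in range(_MAX_REDRAWS):
        if mode == "record":
            idx = rng.integers(0, n, size=n)
        elif mode == "farm":
            chosen = rng.choice(unique_farms, size=len(unique_farms), replace=True)
            idx = np.concatenate([np.flatnonzero(farms == f) for f in chosen])
        else:
            raise ValueError(f"unknown bootstrap mode: {mode}")
        if len(np.unique(farms[idx])) >= 2:
            break
    else:
        return ReplicateResult(index, replicate_seed, {}, {}, False, _MAX_REDRAWS)

    resample = dataset.subset(idx)
    try:
        step = backward_step(resample, outcome, candidate_terms)
    except Exception:
        return ReplicateResult(index, replicate_seed, {}, {}, False, redraw)
    selected, coefs = record_selection(step)
    return ReplicateResult(index, replicate_seed, selected, coefs, True, redraw)


def run_stability(
    dataset: Dataset,
    outcome: str,
    candidate_terms,
    n_boot: int = DEFAULT_B,
    master_seed: int = 0,
    mode: str = "record",
) -> list[ReplicateResult]:
    """Run *n_boot* independent replicates with substream seeds derived from
    *master_seed*."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    seeds = np.random.SeedSequence(master_seed).generate_state(n_boot) % (2**31)
    return [
        bootstrap_replicate(dataset, outcome, candidate_terms, int(s), i, mode)
        for i, s in enumerate(seeds)
    ]


def _level_keys_for_term(term: str) -> list[str]:
    var = VARIABLES_BY_NAME.get(term)
    if var is None or var.kind == "continuous":
        return [term]
    return [term_label(term, l) for l in var.nonref_levels]


def _n_at_level(dataset: Dataset, term: str, level: str | None) -> int:
    if level is None:
        return dataset.n
    return int((dataset.frame[term] == level).sum())


def summarize_stability(
    replicates,
    dataset: Dataset,
    candidate_terms,
) -> pd.DataFrame:
    """Build the per-level stability summary table.

    Stability and (term-level) selection counts are shared by all levels of a
    categorical term; coefficients, intervals and bootstrap p-values are per
    level.  Levels never recorded in any replicate yield no row.  Replicate
    order does not affect the output.
    """
    reps = list(replicates)
    B = len(reps)
    n_nonconverged = sum(not r.converged for r in reps)
    rows = []
    for term in candidate_terms:
        stab = 100.0 * sum(r.selected.get(term, False) for r in reps) / B
        n_selected = sum(r.selected.get(term, False) for r in reps)
        var = VARIABLES_BY_NAME.get(term)
        for key in _level_keys_for_term(term):
            _, level = (key.split(":", 1) + [None])[:2] if ":" in key else (key, None)
            vals = np.array([r.coefs[key] for r in reps if key in r.coefs])
            if vals.size == 0:
                continue
            mean, lo, hi = summarize_coefficients(reps, key)
            rows.append(
                {
                    "term": term,
                    "level": level,
                    "label": key,
                    "n_at_level": _n_at_level(dataset, term, level),
                    "stability": stab,
                    "n_selected": n_selected,
                    "n_coef": int(vals.size),
                    "mean_coef": mean,
                    "bci_low": lo,
                    "bci_high": hi,
                    "boot_p": bootstrap_p(vals),
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["n_boot"] = B
    df.attrs["n_nonconverged"] = n_nonconverged
    return df


def select_influential(
    summary: pd.DataFrame,
    stability_min: float = STABILITY_MIN,
    p_max: float = P_MAX,
) -> pd.DataFrame:
    """Rows of terms with stability > *stability_min* and bootstrap p <
    *p_max* (both strict).  All levels of a kept term are kept together: a
    term qualifies if any of its levels meets the p criterion."""
    if summary.empty:
        return summary.copy()
    ok_terms = set(
        summary.loc[
            (summary["stability"] > stability_min) & (summary["boot_p"] < p_max),
            "term",
        ]
    )
    return summary[summary["term"].isin(ok_terms)].copy()


def replicate_archive(replicates) -> pd.DataFrame:
    """Long-format archive: one row per replicate x recorded level."""
    rows = []
    for r in replicates:
        if not r.coefs:
            rows.append(
                {
                    "replicate": r.index, "seed": r.seed, "term": None,
                    "level": None, "label": None, "coefficient": np.nan,
                    "selected": False, "converged": r.converged,
                }
            )
            continue
        for key, val in r.coefs.items():
            term = key.split(":", 1)[0]
            level = key.split(":", 1)[1] if ":" in key else None
            rows.append(
                {
                    "replicate": r.index, "seed": r.seed, "term": term,
                    "level": level, "label": key, "coefficient": val,
                    "selected": True, "converged": r.converged,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# model / results objects


class ColostrumStabilityModel:
    """Bootstrap stability-selection model for one log-count outcome.

    Built from a prepared :class:`Dataset` (or a raw table via
    :meth:`from_dataframe`); ``fit()`` runs the full loop and returns a
    :class:`StabilityResults`.

    Parameters
    ----------
    dataset : Dataset
    outcome : str
        ``"log_tbc"`` or ``"log_cc"``.
    terms : sequence of str, optional
        Candidate fixed-effect terms (default: all 13 management variables).
    bootstrap_mode : {"record", "farm"}
        Record-level (default) or cluster (farm-level) resampling.
    """

    def __init__(
        self,
        dataset: Dataset,
        outcome: str = "log_tbc",
        terms=None,
        bootstrap_mode: str = "record",
    ):
        dataset.validate()
        self.dataset = dataset
        self.outcome = outcome
        self.terms = tuple(terms) if terms is not None else MODEL_TERMS
        if bootstrap_mode not in ("record", "farm"):
            raise ValueError(f"unknown bootstrap mode: {bootstrap_mode}")
        self.bootstrap_mode = bootstrap_mode

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str = "log_tbc", **kw):
        from .preprocess import prepare

        dataset, _ = prepare(df)
        return cls(dataset, outcome, **kw)

    def fit(
        self, n_boot: int = DEFAULT_B, seed: int = 0
    ) -> "StabilityResults":
        replicates = run_stability(
            self.dataset, self.outcome, self.terms, n_boot, seed,
            self.bootstrap_mode,
        )
        full_step = backward_step(self.dataset, self.outcome, self.terms)
        summary = summarize_stability(replicates, self.dataset, self.terms)
        return StabilityResults(
            model=self,
            replicates=replicates,
            summary_frame=summary,
            full_step=full_step,
            n_boot=n_boot,
            seed=seed,
        )


@dataclass
class StabilityResults:
    """Archive and summaries of one bootstrap stability-selection run."""

    model: ColostrumStabilityModel
    replicates: list[ReplicateResult]
    summary_frame: pd.DataFrame
    full_step: StepResult
    n_boot: int
    seed: int

    @property
    def full_model_fit(self) -> LMMResults:
        """Backward-eliminated fit on the original (non-resampled) table."""
        return self.full_step.final_fit

    def select_influential(
        self, stability_min: float = STABILITY_MIN, p_max: float = P_MAX
    ) -> pd.DataFrame:
        return select_influential(self.summary_frame, stability_min, p_max)

    def archive(self) -> pd.DataFrame:
        return replicate_archive(self.replicates)

    def summary_table(self) -> pd.DataFrame:
        """Display table with the published column layout (coefficients to
        2 dp, stability to 1 dp)."""
        from .descriptive import round_half_up

        df = self.summary_frame.sort_values(
            ["stability", "term", "label"], ascending=[False, True, True]
        )
        out = pd.DataFrame(
            {
                "Variable": df["label"],
                "N": df["n_at_level"],
                "Stability (%)": [round_half_up(s, 1) for s in df["stability"]],
                "Mean coefficient": [round_half_up(c, 2) for c in df["mean_coef"]],
                "95% bootstrap confidence interval": [
                    f"({round_half_up(lo, 2):.2f} to {round_half_up(hi, 2):.2f})"
                    for lo, hi in zip(df["bci_low"], df["bci_high"])
                ],
                "Bootstrap P-value": [
                    "<0.01" if p < 0.01 else f"{round_half_up(p, 2):.2f}"
                    for p in df["boot_p"]
                ],
            }
        )
        return out.reset_index(drop=True)

    def summary(self) -> str:
        n_bad = self.summary_frame.attrs.get("n_nonconverged", 0)
        head = [
            "Bootstrap stability selection (random-intercept LMM, backward AIC)",
            f"  outcome: {self.model.outcome}   n = {self.model.dataset.n}, "
            f"farms = {self.model.dataset.n_farms}",
            f"  replicates: {self.n_boot} ({n_bad} non-converged)   "
            f"master seed: {self.seed}   mode: {self.model.bootstrap_mode}",
            "",
        ]
        return "\n".join(head) + self.summary_table().to_string(index=False)

    def plot_coefficient_distributions(self, stability_min: float = STABILITY_MIN,
                                       ax=None):
        from .plots import plot_coefficient_distributions

        return plot_coefficient_distributions(
            self.archive(), self.summary_frame, stability_min, ax=ax
        )

    def plot_stability_vs_p(self, stability_min: float = STABILITY_MIN,
                            p_max: float = P_MAX, ax=None):
        from .plots import plot_stability_vs_p

        return plot_stability_vs_p(self.summary_frame, stability_min, p_max, ax=ax)
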