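"""Model checking: repeated cross-validation, correlation screen,
interaction screen and a detectable-difference power calculation.

These diagnostics accompany the full (non-bootstrapped) model: repeated
k-fold cross-validation guards against overfitting, the predictor-correlation
screen guards against collinearity-driven instability of coefficients, the
interaction screen tests pairwise interactions between selected predictors by
likelihood-ratio test, and the power calculation gives the conventional
two-sample detectable difference at the study's size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import INTERCEPT, build_design
from .lmm import LinearMixedModel, fit_lmm
from .preprocess import Dataset


@dataclass
class CvResult:
    """Internal vs cross-validated fit metrics for one model."""

    internal_r2: float
    cv_r2: float
    internal_mae: float
    cv_mae: float
    k: int
    repeats: int
    seed: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _r2(y, yhat) -> float:
    """1 - SSE/SST around the evaluated records' own mean; may be negative."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    sst = float(((y - y.mean()) ** 2).sum())
    sse = float(((y - yhat) ** 2).sum())
    if sst == 0.0:
        return 1.0 if sse == 0.0 else -np.inf
    return 1.0 - sse / sst


def repeated_kfold_cv(
    dataset: Dataset,
    outcome: str,
    terms,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> CvResult:
    """Record-level repeated k-fold CV of the full fixed-effect model.

    Held-out predictions use the fixed part plus the training-data BLUP for
    farms present in the training folds (0 for unseen farms).  R² and MAE are
    computed per repeat over the pooled out-of-fold predictions and averaged
    over repeats; internal metrics come from the full-data fit.
    """
    n = dataset.n
    if k > n:
        raise ValueError("k exceeds the number of records")
    full = fit_lmm(dataset, outcome, terms)
    y = dataset.frame[outcome].to_numpy(dtype=float)
    yhat_internal = full.predict(mode="with_farm_effect")
    internal_r2 = _r2(y, yhat_internal)
    internal_mae = float(np.abs(y - yhat_internal).mean())

    from sklearn.model_selection import KFold

    rng = np.random.SeedSequence(seed).generate_state(repeats) % (2**31)
    r2s, maes = [], []
    for rep in range(repeats):
        kf = KFold(n_splits=k, shuffle=True, random_state=int(rng[rep]))
        yhat = np.full(n, np.nan)
        for train_idx, test_idx in kf.split(np.arange(n)):
            train = dataset.subset(train_idx)
            fit = fit_lmm(train, outcome, terms)
            test_records = dataset.frame.iloc[test_idx]
            yhat[test_idx] = fit.predict(test_records, mode="with_farm_effect")
        assert not np.isnan(yhat).any()
        r2s.append(_r2(y, yhat))
        maes.append(float(np.abs(y - yhat).mean()))
    return CvResult(
        internal_r2=internal_r2,
        cv_r2=float(np.mean(r2s)),
        internal_mae=internal_mae,
        cv_mae=float(np.mean(maes)),
        k=k,
        repeats=repeats,
        seed=seed,
    )


def predictor_correlations(dataset: Dataset, terms) -> tuple[pd.DataFrame, float]:
    """Pearson correlations over the numeric design encoding.

    Returns the full pairwise table over non-intercept design columns and the
    maximum absolute correlation between columns of *distinct* variables
    (within-term dummy correlations are structural and ignored for the
    maximum).  Constant columns yield NaN rows.
    """
    design = build_design(dataset, "log_tbc" if "log_tbc" in dataset.frame else
                          dataset.frame.columns[0], terms)
    cols = [i for i, c in enumerate(design.columns) if c.term != INTERCEPT]
    names = [design.columns[i].name for i in cols]
    terms_of = [design.columns[i].term for i in cols]
    X = design.X[:, cols]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    table = pd.DataFrame(corr, index=names, columns=names)
    max_abs = 0.0
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            if terms_of[a] == terms_of[b]:
                continue
            v = abs(corr[a, b])
            if np.isfinite(v):
                max_abs = max(max_abs, v)
    return table, float(max_abs)


def interaction_screen(
    dataset: Dataset,
    outcome: str,
    selected_terms,
    alpha: float = 0.05,
) -> list[dict]:
    """Likelihood-ratio screen of all pairwise interactions among
    *selected_terms*.

    For each pair the model with the interaction block is compared to the
    no-interaction model by ML likelihood-ratio test (chi-square reference,
    df = number of independent added columns); pairs with p < *alpha* are
    returned.  Pairs whose interaction block adds no independent column
    (structurally confounded pairs) are skipped.
    """
    selected_terms = list(selected_terms)
    if len(selected_terms) < 2:
        return []
    base = fit_lmm(dataset, outcome, selected_terms)
    hits = []
    for a_i in range(len(selected_terms)):
        for b_i in range(a_i + 1, len(selected_terms)):
            a, b = selected_terms[a_i], selected_terms[b_i]
            try:
                model = LinearMixedModel(
                    dataset, outcome, selected_terms, interactions=[(a, b)]
                )
            except ValueError:
                continue
            fit = model.fit()
            inter = a + "#" + b
            df_added = sum(1 for c in fit.columns if c.term == inter)
            if df_added == 0:
                continue
            lr = 2.0 * (fit.llf - base.llf)
            p = float(stats.chi2.sf(max(lr, 0.0), df_added))
            if p < alpha:
                hits.append({"pair": (a, b), "lr": lr, "df": df_added, "p": p})
    return hits


@dataclass(frozen=True)
class PowerSpec:
    """Two-sample detectable-difference specification on the log scale."""

    sd: float
    detectable_difference: float
    alpha: float = 0.05
    total_n: int = 328

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.total_n < 4:
            raise ValueError("total_n must be >= 4")


def detectable_difference_power(spec: PowerSpec) -> float:
    """Two-sided two-sample normal-approximation power with equal allocation:

        power = Phi( |delta| / (sd * sqrt(2 / (n/2))) - z_{1-alpha/2} ).

    At delta = 0 this returns alpha/2 (the one-sided rejection mass).
    """
    n_group = spec.total_n / 2.0
    se = spec.sd * np.sqrt(2.0 / n_group)
    z_crit = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    return float(stats.norm.cdf(abs(spec.detectable_difference) / se - z_crit))


def diagnostics_report(
    dataset: Dataset,
    outcome: str,
    terms,
    cv_seed: int = 0,
    k: int = 10,
    repeats: int = 10,
) -> dict:
    """Bundle CV metrics, the correlation screen and the interaction screen
    for the full model into one JSON-serialisable report."""
    cv = repeated_kfold_cv(dataset, outcome, terms, k=k, repeats=repeats, seed=cv_seed)
    _, max_corr = predictor_correlations(dataset, terms)
    from .lmm import residual_normality

    full = fit_lmm(dataset, outcome, terms)
    norm = residual_normality(full)
    return {
        "outcome": outcome,
        "cv": cv.to_dict(),
        "max_abs_predictor_correlation": max_corr,
        "residual_skewness": norm["skewness"],
        "residual_kurtosis_excess": norm["kurtosis_excess"],
        "residual_check_unreliable": norm["unreliable"],
    }
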