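"""Maximum-likelihood fitting of the random-intercept linear mixed model.

The model for sample *i* on farm *j* is

    y_ij = x_ij' beta + U_j + eps_ij,
    U_j ~ N(0, theta_U),  eps_ij ~ N(0, theta_eps),

giving a block compound-symmetric marginal covariance by farm.  The ML
optimum is found by profiling the variance ratio lambda = theta_U/theta_eps:
for fixed lambda, beta is the GLS solution and theta_eps has a closed form,
so the whole fit is a bounded one-dimensional search over lambda (coarse
log-scale grid followed by derivative-free refinement to a 1e-8
log-likelihood tolerance).  theta_U is floored at zero; boundary fits are
allowed and flagged.  ML (not REML) is used throughout because the stepwise
routine compares models with different fixed effects by AIC.

AIC counts the fixed coefficients plus the two variance components:
``aic = -2*loglik + 2*(n_fixed + 2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .design import INTERCEPT, Column, CrossProducts, DesignMatrix, build_design
from .preprocess import Dataset

_LOG2PI = np.log(2.0 * np.pi)
_LAM_GRID = np.concatenate([[0.0], np.logspace(-6, 3, 40)])
_LAM_MAX = 1e4


class RankDeficientDesignError(ValueError):
    def __init__(self, collinear_columns):
        self.collinear_columns = list(collinear_columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(self.collinear_columns)
        )


class NotConvergedError(RuntimeError):
    pass


@dataclass
class _ProfileEval:
    nll: float
    beta: np.ndarray
    theta_eps: float
    A: np.ndarray


def _profile(lam: float, XtX, Xty, yty, M, s_y, nj, n) -> _ProfileEval:
    """Profile negative log-likelihood at variance ratio *lam*; beta and
    theta_eps are solved in closed form per farm block."""
    c = lam / (1.0 + lam * nj)                    # (G,)
    A = XtX - (M.T * c) @ M
    b = Xty - M.T @ (c * s_y)
    try:
        cho = linalg.cho_factor(A, lower=True, check_finite=False)
        beta = linalg.cho_solve(cho, b, check_finite=False)
    except linalg.LinAlgError:
        return _ProfileEval(np.inf, np.full(len(Xty), np.nan), np.nan, A)
    rss = yty - float((c * s_y**2).sum()) - float(b @ beta)
    if rss <= 0.0:
        return _ProfileEval(np.inf, beta, 0.0, A)
    theta_eps = rss / n
    logdet = float(np.log1p(lam * nj).sum())
    nll = 0.5 * (n * (_LOG2PI + 1.0) + n * np.log(theta_eps) + logdet)
    return _ProfileEval(nll, beta, theta_eps, A)


@dataclass
class LMMResults:
    """ML fit of the random-intercept model.

    Carries the fixed-effect estimates with their asymptotic standard errors,
    the variance components, the maximised ML log-likelihood and AIC, plus
    enough of the design to compute fitted values, residuals and farm BLUPs.
    """

    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    theta_U: float
    theta_eps: float
    llf: float
    n: int
    k_fixed: int
    converged: bool
    boundary: bool
    columns: list[Column]
    col_indices: list[int]
    dropped_columns: list[str]
    design: DesignMatrix = field(repr=False)

    @property
    def k_params(self) -> int:
        return self.k_fixed + 2  # fixed coefficients + theta_U + theta_eps

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k_params

    @property
    def lam(self) -> float:
        return self.theta_U / self.theta_eps

    @property
    def selected_terms(self) -> tuple[str, ...]:
        return tuple(
            dict.fromkeys(c.term for c in self.columns if c.term != INTERCEPT)
        )

    # -- predictions -------------------------------------------------------

    def _X(self) -> np.ndarray:
        return self.design.X[:, self.col_indices]

    @property
    def fittedvalues(self) -> np.ndarray:
        """Fixed part plus the farm BLUP (conditional fitted values)."""
        fixed = self._X() @ self.params.to_numpy()
        return fixed + self.blup_values[self.design.farm_codes]

    @property
    def resid(self) -> np.ndarray:
        """Conditional residuals eps-hat = y - X beta - U-hat."""
        return self.design.y - self.fittedvalues

    @property
    def blup_values(self) -> np.ndarray:
        """Shrunken farm-intercept predictions, ordered by ``design.farm_ids``."""
        r = self.design.y - self._X() @ self.params.to_numpy()
        G = self.design.n_farms
        s = np.bincount(self.design.farm_codes, weights=r, minlength=G)
        nj = np.bincount(self.design.farm_codes, minlength=G).astype(float)
        lam = self.lam
        return lam / (1.0 + lam * nj) * s

    def blup(self) -> pd.Series:
        return pd.Series(self.blup_values, index=self.design.farm_ids, name="U_hat")

    def predict(self, records: pd.DataFrame | None = None, mode: str = "fixed_only"):
        """Predict log counts for *records* (default: training records).

        ``fixed_only`` returns X beta; ``with_farm_effect`` adds the BLUP for
        farms seen in training and 0 for unseen farms.
        """
        if mode not in ("fixed_only", "with_farm_effect"):
            raise ValueError(f"unknown prediction mode: {mode}")
        if records is None:
            X = self._X()
            farms = np.asarray(self.design.farm_codes)
            fixed = X @ self.params.to_numpy()
            if mode == "fixed_only":
                return fixed
            return fixed + self.blup_values[farms]
        X = _encode_records(records, self.columns, self.design, self._std)
        fixed = X @ self.params.to_numpy()
        if mode == "fixed_only":
            return fixed
        blup = dict(zip(self.design.farm_ids, self.blup_values))
        u = np.array([blup.get(f, 0.0) for f in records["farm_id"]])
        return fixed + u

    _std: dict = field(default_factory=dict, repr=False)

    def summary(self) -> str:
        lines = [
            "Random-intercept linear mixed model (ML)",
            f"  outcome: {self.design.outcome}   n = {self.n}, farms = {self.design.n_farms}",
            f"  loglik = {self.llf:.4f}   AIC = {self.aic:.4f}   k = {self.k_params}",
            f"  theta_U = {self.theta_U:.4f}   theta_eps = {self.theta_eps:.4f}"
            + ("   [boundary]" if self.boundary else ""),
            "",
            f"  {'coefficient':40s} {'estimate':>10s} {'se':>8s}",
        ]
        for name, est in self.params.items():
            lines.append(f"  {name:40s} {est:10.4f} {self.bse[name]:8.4f}")
        if self.dropped_columns:
            lines.append("")
            lines.append("  dropped columns: " + ", ".join(self.dropped_columns))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "outcome": self.design.outcome,
            "params": dict(self.params),
            "bse": dict(self.bse),
            "theta_U": self.theta_U,
            "theta_eps": self.theta_eps,
            "loglik": self.llf,
            "aic": self.aic,
            "n": self.n,
            "k_params": self.k_params,
            "converged": self.converged,
            "dropped_columns": list(self.dropped_columns),
        }


def _encode_records(records, columns, design, std):
    from .schema import VARIABLES_BY_NAME

    cols = []
    for c in columns:
        if c.term == INTERCEPT:
            cols.append(np.ones(len(records)))
        elif c.level is None:
            x = records[c.term].to_numpy(dtype=float)
            if c.term in std:
                mean, sd = std[c.term]
                x = (x - mean) / sd
            cols.append(x)
        else:
            var = VARIABLES_BY_NAME[c.term]
            vals = records[c.term].to_numpy()
            unseen = set(vals) - set(var.levels)
            if unseen:
                raise ValueError(f"{c.term}: unseen levels {sorted(unseen)}")
            cols.append((vals == c.level).astype(float))
    return np.column_stack(cols)


def fit_from_crossproducts(
    design: DesignMatrix,
    cp: CrossProducts,
    col_indices,
    dropped: list[str] | None = None,
    std: dict | None = None,
) -> LMMResults:
    """Fit the model restricted to *col_indices* (assumed full rank)."""
    S = list(col_indices)
    XtX = cp.XtX[np.ix_(S, S)]
    Xty = cp.Xty[S]
    M = cp.M[:, S]
    args = (XtX, Xty, cp.yty, M, cp.s_y, cp.nj, cp.n)

    evals = {lam: _profile(lam, *args) for lam in _LAM_GRID}
    best_lam = min(evals, key=lambda l: evals[l].nll)
    if not np.isfinite(evals[best_lam].nll):
        raise NotConvergedError("profile likelihood not finite on the grid")

    i = int(np.where(_LAM_GRID == best_lam)[0][0])
    converged = True
    if i == 0:
        lo, hi = 0.0, _LAM_GRID[1]
        res = optimize.minimize_scalar(
            lambda l: _profile(l, *args).nll,
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12},
        )
        cand = float(res.x)
        converged = bool(res.success)
    else:
        lo = _LAM_GRID[max(i - 1, 1)] if i > 1 else _LAM_GRID[1] / 10.0
        hi = _LAM_GRID[min(i + 1, len(_LAM_GRID) - 1)]
        if hi <= lo:
            hi = min(lo * 10.0, _LAM_MAX)
        res = optimize.minimize_scalar(
            lambda t: _profile(np.exp(t), *args).nll,
            bounds=(np.log(lo), np.log(hi)), method="bounded",
            options={"xatol": 1e-12},
        )
        cand = float(np.exp(res.x))
        converged = bool(res.success)
    cand_eval = _profile(cand, *args)
    if cand_eval.nll <= evals[best_lam].nll:
        lam_hat, ev = cand, cand_eval
    else:
        lam_hat, ev = best_lam, evals[best_lam]
    # variance-ratio floor: accept the exact boundary when it is at least as good
    ev0 = evals[0.0]
    if ev0.nll <= ev.nll + 1e-10:
        lam_hat, ev = 0.0, ev0

    names = [design.columns[j].name for j in S]
    cov = ev.theta_eps * np.linalg.inv(ev.A)
    params = pd.Series(ev.beta, index=names)
    bse = pd.Series(np.sqrt(np.clip(np.diag(cov), 0.0, None)), index=names)
    return LMMResults(
        params=params,
        bse=bse,
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        theta_U=lam_hat * ev.theta_eps,
        theta_eps=ev.theta_eps,
        llf=-ev.nll,
        n=cp.n,
        k_fixed=len(S),
        converged=converged,
        boundary=lam_hat == 0.0,
        columns=[design.columns[j] for j in S],
        col_indices=S,
        dropped_columns=list(dropped or []),
        design=design,
        _std=dict(std or {}),
    )


class LinearMixedModel:
    """Model object: a random-intercept LMM on a prepared :class:`Dataset`.

    Parameters
    ----------
    dataset : Dataset
        Prepared sample table (log outcomes present, >= 2 farms).
    outcome : str
        ``"log_tbc"`` or ``"log_cc"``.
    terms : sequence of str
        Fixed-effect terms; categorical terms expand to indicator blocks.
    interactions : list of (str, str), optional
        Pairwise interaction blocks.
    on_collinear : {"drop", "raise"}
        Empty levels and linearly dependent columns are either dropped
        (first-in-order wins, recorded on the results) or raised.
    """

    def __init__(
        self,
        dataset: Dataset,
        outcome: str,
        terms,
        interactions=None,
        on_collinear: str = "drop",
    ):
        dataset.validate()
        if dataset.n_farms < 2:
            raise ValueError("need >= 2 farms")
        self.dataset = dataset
        self.outcome = outcome
        self.design = build_design(dataset, outcome, terms, interactions)
        self.cp = CrossProducts.from_design(self.design)
        self.on_collinear = on_collinear
        if self.design.n <= self.design.X.shape[1] + 2:
            raise ValueError("too few records for the number of coefficients")

    def fit(self) -> LMMResults:
        all_cols = list(range(self.design.X.shape[1]))
        kept, dropped = self.design.independent_subset(all_cols)
        if dropped and self.on_collinear == "raise":
            raise RankDeficientDesignError(
                [self.design.columns[j].name for j in dropped]
            )
        return fit_from_crossproducts(
            self.design,
            self.cp,
            kept,
            dropped=[self.design.columns[j].name for j in dropped],
            std=self.dataset.standardization,
        )


def fit_lmm(
    dataset: Dataset,
    outcome: str,
    terms,
    interactions=None,
    on_collinear: str = "drop",
) -> LMMResults:
    """Convenience wrapper: build the design and return the ML fit."""
    return LinearMixedModel(
        dataset, outcome, terms, interactions, on_collinear
    ).fit()


def fit_arrays(
    y, X, farm_codes, names=None, on_collinear: str = "drop"
) -> LMMResults:
    """Fit the random-intercept model directly from arrays.

    *X* must contain any intercept column explicitly; *farm_codes* are
    0-based group labels.  Mainly useful for simulation studies and
    cross-checks that bypass the sample-table schema.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    farm_codes = np.asarray(farm_codes, dtype=np.int64)
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    columns = [Column(str(nm), str(nm), None) for nm in names]
    farm_ids = [str(g) for g in range(int(farm_codes.max()) + 1)]
    design = DesignMatrix(
        y=y, X=X, columns=columns, terms=tuple(names),
        farm_codes=farm_codes, farm_ids=farm_ids, outcome="y",
    )
    cp = CrossProducts.from_design(design)
    kept, dropped = design.independent_subset(list(range(X.shape[1])))
    if dropped and on_collinear == "raise":
        raise RankDeficientDesignError([columns[j].name for j in dropped])
    return fit_from_crossproducts(
        design, cp, kept, dropped=[columns[j].name for j in dropped]
    )


def ols_profile(y, X, farm_codes):
    """Fixed-effect and residual-variance estimates with the farm variance
    profiled to exactly zero (the OLS limit); returns ``(beta, theta_eps,
    loglik)``."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    farm_codes = np.asarray(farm_codes, dtype=np.int64)
    G = int(farm_codes.max()) + 1
    M = np.zeros((G, X.shape[1]))
    np.add.at(M, farm_codes, X)
    s_y = np.bincount(farm_codes, weights=y, minlength=G)
    nj = np.bincount(farm_codes, minlength=G).astype(float)
    ev = _profile(0.0, X.T @ X, X.T @ y, float(y @ y), M, s_y, nj, len(y))
    return ev.beta, ev.theta_eps, -ev.nll


def aic_of(fit: LMMResults) -> float:
    """AIC = -2 loglik + 2 (n_fixed + 2); errors on a non-converged fit."""
    if not fit.converged:
        raise NotConvergedError("AIC requested for a non-converged fit")
    return fit.aic


def loglik_dense(y, X, beta, theta_U, theta_eps, farm_codes) -> float:
    """Brute-force marginal Gaussian log-density with the dense
    block-compound-symmetric covariance; independent oracle for ``llf``."""
    n = len(y)
    Z = np.zeros((n, int(farm_codes.max()) + 1))
    Z[np.arange(n), farm_codes] = 1.0
    V = theta_eps * np.eye(n) + theta_U * (Z @ Z.T)
    return float(
        stats.multivariate_normal.logpdf(y, mean=X @ beta, cov=V)
    )


def residual_normality(fit: LMMResults) -> dict:
    """Descriptive normality diagnostics of the conditional residuals.

    Advisory only: reports skewness, excess kurtosis and theoretical/sample
    quantile pairs for a normal Q-Q plot; flagged unreliable below n = 8.
    """
    r = np.sort(fit.resid)
    n = len(r)
    out = {
        "n": n,
        "skewness": float(stats.skew(r)) if n > 2 else np.nan,
        "kurtosis_excess": float(stats.kurtosis(r)) if n > 3 else np.nan,
        "unreliable": n < 8,
    }
    probs = (np.arange(1, n + 1) - 0.5) / n
    out["qq_theoretical"] = stats.norm.ppf(probs) * np.std(r, ddof=1) + np.mean(r)
    out["qq_sample"] = r
    return out
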