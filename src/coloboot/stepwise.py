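"""Backward elimination of whole fixed-effect terms by AIC.

Greedy loop: fit the current model; refit once per remaining candidate term
with that term's whole indicator block removed; commit the single deletion
that most lowers AIC (strict improvement required, no parsimony margin) and
repeat until no deletion helps.  The farm random intercept is never a
deletion candidate.  Ties within 1e-9 AIC are broken by dropping the term
appearing later in the declared candidate order, making the path
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .design import CrossProducts, DesignMatrix, build_design
from .lmm import LMMResults, NotConvergedError, fit_from_crossproducts
from .preprocess import Dataset

AIC_TIE_TOL = 1e-9


@dataclass
class StepResult:
    """Outcome of one backward-elimination run."""

    candidate_terms: tuple[str, ...]
    final_terms: tuple[str, ...]
    #: ordered (dropped term, AIC before, AIC after)
    path: list[tuple[str, float, float]]
    final_fit: LMMResults
    full_fit: LMMResults
    skipped: list[str] = field(default_factory=list)  # non-converged deletions

    @property
    def final_aic(self) -> float:
        return self.final_fit.aic


class _TermFitter:
    """Fits arbitrary term subsets of one full design, caching by subset."""

    def __init__(self, design: DesignMatrix, std: dict):
        self.design = design
        self.cp = CrossProducts.from_design(design)
        self.std = std
        self._cache: dict[frozenset, LMMResults] = {}

    def fit_terms(self, terms) -> LMMResults:
        key = frozenset(terms)
        if key not in self._cache:
            cols = self.design.columns_for_terms(terms)
            kept, dropped = self.design.independent_subset(cols)
            fit = fit_from_crossproducts(
                self.design,
                self.cp,
                kept,
                dropped=[self.design.columns[j].name for j in dropped],
                std=self.std,
            )
            self._cache[key] = fit
        return self._cache[key]


def backward_step(
    dataset: Dataset,
    outcome: str,
    candidate_terms,
    design: DesignMatrix | None = None,
) -> StepResult:
    """Run AIC backward elimination over *candidate_terms*.

    A pre-built full design may be supplied (the bootstrap loop reuses one per
    resample); otherwise it is built here.  Deletions whose refit fails to
    converge are unavailable at that step and recorded in ``skipped``.
    """
    candidate_terms = tuple(candidate_terms)
    if design is None:
        design = build_design(dataset, outcome, candidate_terms)
    fitter = _TermFitter(design, dataset.standardization)

    current = list(candidate_terms)
    full_fit = fitter.fit_terms(current)
    fit = full_fit
    path: list[tuple[str, float, float]] = []
    skipped: list[str] = []

    while current:
        current_aic = fit.aic
        best_term = None
        best_fit = None
        best_aic = None
        for term in current:  # declared order; later term wins AIC ties
            reduced = [t for t in current if t != term]
            try:
                cand = fitter.fit_terms(reduced)
            except NotConvergedError:
                skipped.append(term)
                continue
            if not cand.converged:
                skipped.append(term)
                continue
            if best_aic is None or cand.aic < best_aic - AIC_TIE_TOL or (
                abs(cand.aic - best_aic) <= AIC_TIE_TOL
            ):
                best_term, best_fit, best_aic = term, cand, cand.aic
        if best_term is None or best_aic >= current_aic:
            break
        path.append((best_term, current_aic, best_aic))
        current.remove(best_term)
        fit = best_fit

    return StepResult(
        candidate_terms=candidate_terms,
        final_terms=tuple(current),
        path=path,
        final_fit=fit,
        full_fit=full_fit,
        skipped=skipped,
    )


def record_selection(step: StepResult) -> tuple[dict[str, bool], dict[str, float]]:
    """Flatten a step result into per-term selection flags and per-level
    coefficients (reference levels and unselected terms carry no entry;
    levels dropped from a resample's design are absent, not zero)."""
    selected = {t: (t in step.final_terms) for t in step.candidate_terms}
    coefs: dict[str, float] = {}
    for col, est in zip(step.final_fit.columns, step.final_fit.params.to_numpy()):
        if col.term in step.final_terms:
            coefs[col.name] = float(est)
    return selected, coefs
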