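"""Design-matrix construction for the random-intercept model.

Categorical terms are expanded to indicator columns against their declared
reference level, in declared level order; the continuous covariate enters on
its frozen standardized scale.  Bootstrap resamples routinely empty factor
levels and the structural Not-applicable coding makes several columns exact
linear combinations of others, so the builder can drop empty and collinear
columns deterministically (first-in-order column wins), recording what was
dropped and why.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import Dataset
from .schema import VARIABLES_BY_NAME, term_label

INTERCEPT = "Intercept"


@dataclass(frozen=True)
class Column:
    name: str          # canonical label, e.g. "milking_system:Robot"
    term: str          # owning term ("milking_system", "a#b" for interactions)
    level: str | None  # non-reference level, None for continuous/intercept


@dataclass
class DesignMatrix:
    """Numeric design for one outcome: y, X and per-term column bookkeeping."""

    y: np.ndarray
    X: np.ndarray                     # (n, p); column 0 is the intercept
    columns: list[Column]             # parallel to X's columns
    terms: tuple[str, ...]            # candidate terms, declared order
    farm_codes: np.ndarray            # 0..G-1 per record
    farm_ids: list[str]
    outcome: str
    gram: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.gram = self.X.T @ self.X

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_farms(self) -> int:
        return len(self.farm_ids)

    def term_columns(self, term: str) -> list[int]:
        return [i for i, c in enumerate(self.columns) if c.term == term]

    def columns_for_terms(self, terms) -> list[int]:
        """Intercept plus the columns of *terms*, in design order."""
        wanted = set(terms)
        return [
            i
            for i, c in enumerate(self.columns)
            if c.term == INTERCEPT or c.term in wanted
        ]

    def empty_columns(self) -> list[int]:
        return [i for i in range(self.X.shape[1]) if self.gram[i, i] == 0.0]

    def independent_subset(self, cols, tol: float = 1e-8) -> tuple[list[int], list[int]]:
        """Greedy first-in-order maximal linearly independent subset of *cols*.

        Works on the Gram matrix via incremental Cholesky; returns
        ``(kept, dropped)``.  Empty (all-zero) columns are always dropped.
        """
        kept: list[int] = []
        dropped: list[int] = []
        L = np.zeros((len(cols), len(cols)))
        k = 0
        for j in cols:
            gjj = self.gram[j, j]
            if gjj <= 0.0:
                dropped.append(j)
                continue
            if k == 0:
                L[0, 0] = np.sqrt(gjj)
                kept.append(j)
                k = 1
                continue
            g = self.gram[np.ix_(kept, [j])].ravel()
            w = np.linalg.solve(L[:k, :k], g) if k else g
            d = gjj - w @ w
            if d > tol * gjj:
                L[k, :k] = w
                L[k, k] = np.sqrt(d)
                kept.append(j)
                k += 1
            else:
                dropped.append(j)
        return kept, dropped


def _encode_term(ds: Dataset, term: str) -> tuple[np.ndarray, list[Column]]:
    var = VARIABLES_BY_NAME.get(term)
    df = ds.frame
    if var is not None and var.kind == "continuous":
        x = ds.standardized(term) if term in ds.standardization else (
            df[term].to_numpy(dtype=float)
        )
        return x[:, None], [Column(term, term, None)]
    if var is None:
        raise KeyError(f"unknown model term: {term}")
    vals = df[term].to_numpy()
    cols, meta = [], []
    for level in var.nonref_levels:
        cols.append((vals == level).astype(float))
        meta.append(Column(term_label(term, level), term, level))
    return np.column_stack(cols), meta


def build_design(
    ds: Dataset,
    outcome: str,
    terms,
    interactions: list[tuple[str, str]] | None = None,
) -> DesignMatrix:
    """Assemble the full candidate design (no dropping) for *terms*.

    *interactions* adds product blocks named ``"a#b"`` built from the two
    terms' encoded columns.
    """
    terms = tuple(terms)
    if len(set(terms)) != len(terms):
        raise ValueError("duplicate model terms")
    df = ds.frame
    if outcome not in df.columns:
        raise KeyError(f"outcome not in dataset: {outcome}")

    blocks = [np.ones((len(df), 1))]
    columns = [Column(INTERCEPT, INTERCEPT, None)]
    encoded: dict[str, tuple[np.ndarray, list[Column]]] = {}
    for term in terms:
        X_t, meta = _encode_term(ds, term)
        encoded[term] = (X_t, meta)
        blocks.append(X_t)
        columns.extend(meta)
    for a, b in interactions or []:
        Xa, ma = encoded[a]
        Xb, mb = encoded[b]
        inter = a + "#" + b
        for ia, ca in enumerate(ma):
            for ib, cb in enumerate(mb):
                blocks.append((Xa[:, ia] * Xb[:, ib])[:, None])
                columns.append(Column(f"{ca.name} x {cb.name}", inter, None))

    X = np.column_stack(blocks)
    farms = df["farm_id"].to_numpy()
    farm_ids = sorted(set(farms))
    code = {f: i for i, f in enumerate(farm_ids)}
    farm_codes = np.array([code[f] for f in farms], dtype=np.int64)
    y = df[outcome].to_numpy(dtype=float)
    all_terms = terms + tuple(a + "#" + b for a, b in interactions or [])
    return DesignMatrix(
        y=y, X=X, columns=columns, terms=all_terms,
        farm_codes=farm_codes, farm_ids=list(farm_ids), outcome=outcome,
    )


@dataclass
class CrossProducts:
    """Per-farm sufficient statistics of a design, computed once so that every
    submodel fit reduces to slicing plus a 1-D profile optimisation."""

    XtX: np.ndarray    # (p, p)
    Xty: np.ndarray    # (p,)
    yty: float
    M: np.ndarray      # (G, p): per-farm column sums of X
    s_y: np.ndarray    # (G,): per-farm sums of y
    nj: np.ndarray     # (G,): farm sizes
    n: int

    @classmethod
    def from_design(cls, d: DesignMatrix) -> "CrossProducts":
        G = d.n_farms
        p = d.X.shape[1]
        M = np.zeros((G, p))
        np.add.at(M, d.farm_codes, d.X)
        s_y = np.bincount(d.farm_codes, weights=d.y, minlength=G)
        nj = np.bincount(d.farm_codes, minlength=G).astype(float)
        return cls(
            XtX=d.gram,
            Xty=d.X.T @ d.y,
            yty=float(d.y @ d.y),
            M=M,
            s_y=s_y,
            nj=nj,
            n=d.n,
        )
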