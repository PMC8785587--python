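"""Descriptive layer: crosstab odds ratios, univariate logistic fits,
and the multicollinearity screen.

The crosstab odds ratio works identically on cell counts and on column
percentages (the column totals cancel in the cross-product ratio), which is
what makes published two-way percentage tables directly reusable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import CovariateSchema

__all__ = [
    "UnadjustedOR",
    "LogisticFit",
    "crosstab_odds_ratio",
    "univariate_logistic_or",
    "multicollinearity_screen",
    "table_one",
]


@dataclass
class UnadjustedOR:
    """Per-category unadjusted odds ratios (reference category OR = 1)."""

    categories: list
    odds_ratio: np.ndarray        # aligned with categories; [0] == 1.0
    ci_low: Optional[np.ndarray]  # Wald 95% bounds, counts input only
    ci_high: Optional[np.ndarray]

    def rounded(self, ndigits: int = 2) -> list:
        return [round(float(v), ndigits) for v in self.odds_ratio]


def crosstab_odds_ratio(table, categories: Optional[Sequence] = None,
                        kind: str = "auto") -> UnadjustedOR:
    """Unadjusted ORs from a K x 2 table (columns: non-stunted, stunted).

    The first row is the reference category.  ``kind`` may be ``"counts"``,
    ``"percent"`` (column percentages summing to 100), or ``"auto"``.
    Wald 95% intervals are only available for counts (percentages lose n).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("table must be K x 2 (columns: non-stunted, stunted)")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 exposure rows")
    if np.any(arr < 0):
        raise ValueError("negative cell")
    if kind == "auto":
        colsum = arr.sum(axis=0)
        kind = "percent" if np.allclose(colsum, 100.0, atol=0.5) else "counts"
    if kind == "percent":
        colsum = arr.sum(axis=0)
        if not np.allclose(colsum, 100.0, atol=0.5):
            raise ValueError(f"percentage columns sum to {colsum}, not 100")
    zero = np.argwhere(arr[0] == 0)
    if zero.size:
        raise ValueError(f"zero cell in reference row, column {int(zero[0, 0])}")
    if categories is None:
        categories = list(range(arr.shape[0]))

    non, stu = arr[:, 0], arr[:, 1]
    with np.errstate(divide="ignore"):
        ors = (stu / stu[0]) / (non / non[0])
    ci_low = ci_high = None
    if kind == "counts":
        with np.errstate(divide="ignore"):
            se = np.sqrt(1.0 / stu + 1.0 / non + 1.0 / stu[0] + 1.0 / non[0])
        lo = ors * np.exp(-1.959963984540054 * se)
        hi = ors * np.exp(1.959963984540054 * se)
        lo[0] = hi[0] = 1.0
        ci_low, ci_high = lo, hi
    ors[0] = 1.0
    return UnadjustedOR(list(categories), ors, ci_low, ci_high)


@dataclass
class LogisticFit:
    """Univariate logistic-regression result (odds ratio per unit of x)."""

    intercept: float
    slope: float
    se_slope: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    converged: bool
    separated: bool
    n_iter: int


def univariate_logistic_or(x, y, max_iter: int = 100, tol: float = 1e-10) -> LogisticFit:
    """ML logistic fit of y on a single continuous x via IRLS.

    Complete cases only; convergence on relative log-likelihood change.
    Perfect separation is flagged and the interval reported as unbounded.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 10:
        raise ValueError("need at least 10 complete observations")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")

    b = np.zeros(2)
    X = np.column_stack([np.ones_like(x), x])
    ll_old = -len(x) * math.log(2.0)
    converged, separated = False, False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ b
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        w = np.clip(p * (1.0 - p), 1e-12, None)
        # one Newton step via weighted least squares
        XtW = X.T * w
        try:
            b = b + np.linalg.solve(XtW @ X, X.T @ (y - p))
        except np.linalg.LinAlgError:
            separated = True
            break
        eta = X @ b
        sign = 2.0 * y - 1.0
        ll = float(-np.logaddexp(0.0, -sign * eta).sum())
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1e-12):
            converged = True
            ll_old = ll
            break
        ll_old = ll
    eta = X @ b
    # separation: fitted probabilities collapse onto the outcomes
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    if np.all((p > 0.5) == (y > 0.5)) and np.min(np.abs(eta)) > 5.0:
        separated = True
    w = np.clip(p * (1.0 - p), 1e-12, None)
    info = (X.T * w) @ X
    try:
        se = math.sqrt(np.linalg.inv(info)[1, 1])
    except np.linalg.LinAlgError:
        se = math.inf
    if separated:
        se = math.inf
    or_ = math.exp(b[1])
    z = 1.959963984540054
    lo = or_ * math.exp(-z * se) if math.isfinite(se) else 0.0
    hi = or_ * math.exp(z * se) if math.isfinite(se) else math.inf
    return LogisticFit(intercept=float(b[0]), slope=float(b[1]), se_slope=float(se),
                       odds_ratio=float(or_), ci_low=float(lo), ci_high=float(hi),
                       converged=converged, separated=separated, n_iter=it)


def multicollinearity_screen(table: pd.DataFrame, threshold: float = 0.7,
                             schema: Optional[CovariateSchema] = None) -> list:
    """Flag covariate pairs with |Pearson r| > threshold.

    Categorical covariates are coded as integer category indices; missing
    values are handled pairwise-complete.  Constant columns are excluded
    with a warning.  Returns [(name_a, name_b, r), ...].
    """
    cols = {}
    names = schema.names if schema is not None else [
        c for c in table.columns if c not in ("child_id", "cluster_id", "y")]
    if len(names) < 2:
        raise ValueError("need at least 2 covariates to screen")
    for name in names:
        col = table[name]
        if col.dtype.kind in "fiu":
            vals = col.astype(float)
        else:
            if schema is not None and name in [c.name for c in schema.categorical]:
                order = schema[name].categories
                vals = col.map({cat: k for k, cat in enumerate(order)}).astype(float)
            else:
                codes, _ = pd.factorize(col, use_na_sentinel=True)
                vals = pd.Series(np.where(codes < 0, np.nan, codes), index=col.index, dtype=float)
        if vals.dropna().nunique() <= 1:
            warnings.warn(f"constant column {name!r} excluded from the screen")
            continue
        cols[name] = vals
    corr = pd.DataFrame(cols).corr(method="pearson", min_periods=2)
    flagged = []
    keys = list(corr.columns)
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) > threshold:
                flagged.append((a, b, float(r)))
    return flagged


def table_one(table: pd.DataFrame, schema: CovariateSchema,
              weights: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Descriptive summary in the two-column-percentage layout.

    Categorical covariates: column % among non-stunted and stunted children,
    observed N (%), and the unadjusted OR against the reference category.
    Continuous covariates: mean (SE) per outcome group and the univariate
    logistic OR per unit.  Optional per-child weights give weighted cell
    totals (defaults to unweighted).
    """
    y = table["y"].to_numpy()
    w = np.ones(len(table)) if weights is None else np.asarray(weights, dtype=float)
    rows = []
    for cov in schema.continuous:
        x = pd.to_numeric(table[cov.name], errors="coerce").to_numpy(dtype=float)
        obs = np.isfinite(x)
        fit = univariate_logistic_or(x[obs], y[obs]) if obs.sum() >= 10 else None
        for lab, grp in (("non-stunted", 0), ("stunted", 1)):
            sel = obs & (y == grp)
            rows.append({"covariate": cov.name, "category": lab,
                         "mean": float(np.average(x[sel], weights=w[sel])),
                         "se": float(np.std(x[sel], ddof=1) / math.sqrt(sel.sum())),
                         "n": int(sel.sum()),
                         "odds_ratio": fit.odds_ratio if fit else np.nan})
    for cov in schema.categorical:
        col = table[cov.name]
        obs = col.notna().to_numpy()
        counts = np.zeros((cov.n_categories, 2))
        for k, cat in enumerate(cov.categories):
            sel = obs & (col == cat).to_numpy()
            counts[k, 0] = w[sel & (y == 0)].sum()
            counts[k, 1] = w[sel & (y == 1)].sum()
        pct = 100.0 * counts / counts.sum(axis=0, keepdims=True)
        try:
            ors = crosstab_odds_ratio(counts, categories=cov.categories, kind="counts").odds_ratio
        except ValueError:
            ors = np.full(cov.n_categories, np.nan)
        tot = counts.sum()
        for k, cat in enumerate(cov.categories):
            rows.append({"covariate": cov.name, "category": cat,
                         "pct_non_stunted": float(pct[k, 0]), "pct_stunted": float(pct[k, 1]),
                         "n": int(round(counts[k].sum())),
                         "n_pct": float(100.0 * counts[k].sum() / tot),
                         "odds_ratio": float(ors[k])})
    return pd.DataFrame(rows)
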