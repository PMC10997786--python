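"""Per-gene quadratic regression over metareplicates with ANOVA gating.

Each gene's mean normalized expression across metareplicates is
regressed on day since symptom onset with ``y = A x^2 + B x + C``; the
overall ANOVA F-test (null: all fitted-curve coefficients zero) is
FDR-corrected per stratum and genes pass only with ``q < alpha`` and
``R^2 > r2_min``.  Constant genes and genes expressed in exactly one
metareplicate are excluded before testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .metacells import MetacellSet

__all__ = [
    "RegressionFit",
    "ConstantGeneError",
    "fit_quadratic",
    "fit_quadratic_many",
    "benjamini_hochberg",
    "single_nonzero_filter",
    "find_timecourse_degs",
    "baseline_contrast",
]

logger = logging.getLogger(__name__)

_EXACT_FIT_RTOL = 1e-12


class ConstantGeneError(ValueError):
    """Response is constant: no variance to model (handled upstream)."""


@dataclass
class RegressionFit:
    """OLS quadratic fit of expression on time.

    ``p_F`` comes from F(2, n-3) on the model F statistic; per-coefficient
    two-sided p-values use t(n-3) with standard errors from the unscaled
    design covariance.
    """

    n: int
    A: float
    B: float
    C: float
    r2: float
    F: float
    p_F: float
    p_A: float
    p_B: float
    p_C: float
    fitted: np.ndarray
    gene: str | None = None
    cell_type: str | None = None

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.A * t**2 + self.B * t + self.C


def _design(times: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(times), times, times**2])


def fit_quadratic_many(times: np.ndarray, values: np.ndarray) -> pd.DataFrame:
    """Vectorized OLS of many genes sharing one time design.

    Parameters
    ----------
    times : shape (n,)
    values : shape (n_genes, n)

    Returns a frame with columns A, B, C, r2, F, p_F, p_A, p_B, p_C.
    Rows with zero response variance get NaN statistics (callers exclude
    them before testing).
    """
    times = np.asarray(times, dtype=float)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = times.size
    if n < 4:
        raise ValueError(f"need n >= 4 observations, got {n}")
    if np.unique(times).size < 3:
        raise ValueError("need >= 3 distinct time values for a quadratic fit")
    if values.shape[1] != n:
        raise ValueError("values must be genes x observations matching times")

    X = _design(times)
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = np.linalg.lstsq(X, values.T, rcond=None)[0].T  # genes x 3, order (C, B, A)
    fitted = beta @ X.T
    resid = values - fitted
    sse = np.einsum("ij,ij->i", resid, resid)
    ybar = values.mean(axis=1)
    sst = np.einsum("ij,ij->i", values - ybar[:, None], values - ybar[:, None])
    df_resid = n - 3
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sst > 0, 1.0 - sse / sst, np.nan)
        ssr = sst - sse
        exact = sse <= _EXACT_FIT_RTOL * np.maximum(sst, 1.0)
        F = np.where(exact, np.inf, (ssr / 2.0) / (sse / df_resid))
        p_F = np.where(exact, 0.0, scipy.stats.f.sf(F, 2, df_resid))
        sigma2 = sse / df_resid
        se = np.sqrt(np.maximum(sigma2[:, None] * np.diag(XtX_inv)[None, :], 0.0))
        tstat = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf))
        p_coef = np.where(
            se > 0,
            2.0 * scipy.stats.t.sf(np.abs(tstat), df_resid),
            np.where(beta == 0, 1.0, 0.0),
        )
    r2 = np.clip(r2, 0.0, 1.0)
    return pd.DataFrame(
        {
            "A": beta[:, 2],
            "B": beta[:, 1],
            "C": beta[:, 0],
            "r2": r2,
            "F": F,
            "p_F": p_F,
            "p_A": p_coef[:, 2],
            "p_B": p_coef[:, 1],
            "p_C": p_coef[:, 0],
        }
    )


def fit_quadratic(times: np.ndarray, values: np.ndarray) -> RegressionFit:
    """Quadratic OLS for one gene; raises ``ConstantGeneError`` when flat."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float).ravel()
    if values.size != times.size:
        raise ValueError("times and values must have equal length")
    if np.all(values == values[0]):
        raise ConstantGeneError("response is constant")
    row = fit_quadratic_many(times, values[None, :]).iloc[0]
    X = _design(times)
    fitted = X @ np.array([row["C"], row["B"], row["A"]])
    return RegressionFit(
        n=times.size,
        A=row["A"],
        B=row["B"],
        C=row["C"],
        r2=row["r2"],
        F=row["F"],
        p_F=row["p_F"],
        p_A=row["p_A"],
        p_B=row["p_B"],
        p_C=row["p_C"],
        fitted=fitted,
    )


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Step-up BH q-values, order-preserving with monotonicity enforced."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def single_nonzero_filter(values: np.ndarray) -> bool:
    """Keep the gene unless exactly one value is > 0 and the rest are 0."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    return not (np.count_nonzero(v > 0) == 1 and np.count_nonzero(v) == 1)


def _strata(mcs: MetacellSet, grouping: str) -> dict[str, np.ndarray]:
    meta = mcs.meta_table()
    if grouping == "all-cells":
        return {"all": np.arange(len(mcs))}
    if grouping == "per-type":
        return {
            ct: np.flatnonzero((meta["cell_type"] == ct).to_numpy())
            for ct in sorted(meta["cell_type"].unique())
        }
    raise ValueError(f"unknown grouping {grouping!r} (use 'per-type' or 'all-cells')")


def find_timecourse_degs(
    mcs: MetacellSet,
    alpha: float = 0.05,
    r2_min: float = 0.5,
    grouping: str = "per-type",
    min_n: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every gene per stratum, correct within stratum, gate, and report.

    Returns ``(fits, degs)``: the full per-gene fit table (with a
    ``status`` column of tested/constant/single_nonzero) and the gated
    subset satisfying ``q < alpha`` and ``r2 > r2_min``.
    """
    expr = mcs.expression_matrix()
    meta = mcs.meta_table()
    days_all = meta["day"].to_numpy()
    frames = []
    for stratum, idx in _strata(mcs, grouping).items():
        times = days_all[idx].astype(float)
        n = idx.size
        if n < max(min_n, 4) or np.unique(times).size < 3:
            logger.warning(
                "stratum %s skipped: n=%d, %d distinct days",
                stratum, n, np.unique(times).size,
            )
            continue
        V = expr[idx].T  # genes x n
        constant = np.all(V == V[:, :1], axis=1)
        nonzero_counts = np.count_nonzero(V > 0, axis=1)
        single_nz = (nonzero_counts == 1) & (np.count_nonzero(V != 0, axis=1) == 1)
        testable = ~(constant | single_nz)

        frame = pd.DataFrame(
            {
                "gene": mcs.gene_ids,
                "cell_type": stratum,
                "n": n,
                "status": np.where(
                    constant, "constant", np.where(single_nz, "single_nonzero", "tested")
                ),
            }
        )
        stats_cols = ["A", "B", "C", "r2", "F", "p_F", "p_A", "p_B", "p_C"]
        for c in stats_cols + ["q"]:
            frame[c] = np.nan
        if testable.any():
            fit = fit_quadratic_many(times, V[testable])
            frame.loc[testable, stats_cols] = fit[stats_cols].to_numpy()
            frame.loc[testable, "q"] = benjamini_hochberg(
                frame.loc[testable, "p_F"].to_numpy()
            )
        frames.append(frame)
    if not frames:
        raise ValueError("no stratum satisfied the fitting preconditions")
    fits = pd.concat(frames, ignore_index=True)
    gated = (
        (fits["status"] == "tested")
        & (fits["q"] < alpha)
        & (fits["r2"] > r2_min)
    )
    degs = fits[gated].reset_index(drop=True)
    logger.info(
        "find_timecourse_degs: %d strata, %d fits, %d DEGs",
        fits["cell_type"].nunique(), int((fits["status"] == "tested").sum()), len(degs),
    )
    return fits, degs


def stratum_day_means(mcs: MetacellSet, stratum: str, grouping: str = "per-type") -> pd.DataFrame:
    """Observed per-day mean expression (days x genes) for one stratum."""
    idx = _strata(mcs, grouping)[stratum]
    expr = mcs.expression_matrix()[idx]
    days = mcs.meta_table()["day"].to_numpy()[idx]
    uniq = np.sort(np.unique(days))
    means = np.vstack([expr[days == d].mean(axis=0) for d in uniq])
    return pd.DataFrame(means, index=uniq, columns=mcs.gene_ids)


def baseline_contrast(values: np.ndarray, baseline: np.ndarray) -> tuple[float, float]:
    """Two-sided, unpaired, equal-variance t-test of group means.

    Degenerate case: zero pooled variance with equal means gives
    ``(0.0, 1.0)``; with unequal means it is an error.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(baseline, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two values")
    n1, n2 = x.size, y.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if sp2 == 0:
        if diff == 0:
            return 0.0, 1.0
        raise ValueError("degenerate contrast: zero pooled variance, unequal means")
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return float(t), float(p)
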