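"""Statistical layer: delay summaries, robust trend, ANOVA, pairwise t-tests.

The trend of reaction delay against time-in-session is fit with a robust
linear model estimated by iteratively reweighted least squares using Huber's T
criterion: residuals are scaled by MAD/0.6745 and observations with scaled
residual beyond the tuning constant c (default 1.345, ~95% Gaussian
efficiency) are downweighted proportionally. Algorithm comparisons pool the
absolute test errors of every repetition into one group per algorithm and
apply a one-way ANOVA followed by pairwise two-sided t-tests (Welch by
default; a paired mode exists for matched designs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import EventTable

__all__ = [
    "TrendFit",
    "DelaySummary",
    "huber_rlm",
    "summarize_delays",
    "anova_oneway",
    "pairwise_ttests",
]


@dataclass
class TrendFit:
    slope: float
    intercept: float
    slope_se: float
    slope_p: float
    weights: np.ndarray
    n_iterations: int
    converged: bool


def huber_rlm(
    x: np.ndarray,
    y: np.ndarray,
    tuning_c: float = 1.345,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> TrendFit:
    """Robust line fit y ~ a + b*x via IRLS with Huber's T weights.

    Each iteration: weighted least squares; residual scale = MAD/0.6745
    (about zero — the intercept centres the residuals); weights w_i = 1 for
    |r_i|/scale <= c, else c/(|r_i|/scale). Iteration stops when the largest
    coefficient change drops below ``tol`` or the Huber objective goes flat
    (relative change below ``tol``) — with very few points the coefficients
    can creep geometrically long after the objective has converged. The slope
    p-value comes from the asymptotic normal statistic slope/se with the
    usual weighted-LS covariance at the final weights.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("robust trend fit needs at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: slope is undefined")

    X = np.column_stack([np.ones(n), x])
    w = np.ones(n)
    beta = np.zeros(2)
    converged = False
    history = []
    for it in range(1, max_iter + 1):
        Xw = X * w[:, None]
        beta_new, *_ = np.linalg.lstsq(Xw.T @ X, Xw.T @ y, rcond=None)
        resid = y - X @ beta_new
        # MAD about zero (the intercept centres the residuals already);
        # this is the convention of the standard IRLS implementations
        scale = np.median(np.abs(resid)) / 0.6745
        if scale <= 0:
            # exact fit (or half the residuals identical): weights stay put
            beta, w = beta_new, np.ones(n)
            converged = True
            n_iter = it
            break
        z = np.abs(resid) / scale
        with np.errstate(divide="ignore"):
            w_new = np.where(z <= tuning_c, 1.0, tuning_c / np.maximum(z, 1e-300))
        objective = float(scale**2 * np.sum(
            np.where(z <= tuning_c, 0.5 * z**2, tuning_c * z - 0.5 * tuning_c**2)
        ))
        delta = np.max(np.abs(beta_new - beta))
        obj_flat = history and abs(objective - history[-1][1]) <= tol * max(1.0, abs(objective))
        history.append((delta, objective))
        beta, w = beta_new, w_new
        if it > 1 and (delta < tol or obj_flat):
            converged = True
            n_iter = it
            break
    else:
        n_iter = max_iter
    if not converged:
        raise RuntimeError(
            f"IRLS did not converge in {max_iter} iterations; "
            f"(coefficient-change, objective) trace: {history[-5:]}"
        )

    resid = y - X @ beta
    dof = max(n - 2, 1)
    sigma2 = float((w * resid ** 2).sum() / dof)
    cov = sigma2 * np.linalg.inv((X * w[:, None]).T @ X)
    se = float(np.sqrt(cov[1, 1]))
    z_stat = beta[1] / se if se > 0 else 0.0
    p = float(2 * sps.norm.sf(abs(z_stat)))
    return TrendFit(slope=float(beta[1]), intercept=float(beta[0]),
                    slope_se=se, slope_p=p, weights=w,
                    n_iterations=n_iter, converged=True)


@dataclass
class DelaySummary:
    """Per-subject reaction-delay statistics plus the robust time trend."""

    min_s: float
    median_s: float
    max_s: float
    sd_s: float
    slope_s_per_s: float
    slope_p: float
    n_epochs: int

    def to_row(self) -> dict:
        return {
            "min_s": self.min_s, "median_s": self.median_s, "max_s": self.max_s,
            "sd_s": self.sd_s, "slope_s_per_s": self.slope_s_per_s,
            "slope_p": self.slope_p, "n_epochs": self.n_epochs,
        }


def summarize_delays(events: EventTable) -> DelaySummary:
    """Min/median/max/sd of the delays and the robust delay-vs-time slope."""
    d = events.delay_s
    if np.ptp(d) == 0:
        slope, p = 0.0, 1.0
    else:
        fit = huber_rlm(events.cue_onset_s, d)
        slope, p = fit.slope, fit.slope_p
    return DelaySummary(
        min_s=float(d.min()),
        median_s=float(np.median(d)),
        max_s=float(d.max()),
        sd_s=float(d.std(ddof=1)) if len(d) > 1 else 0.0,
        slope_s_per_s=slope,
        slope_p=p,
        n_epochs=len(d),
    )


def anova_oneway(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA over k groups of observations.

    Returns (F, p) with F = MS_between / MS_within on (k-1, N-k) degrees of
    freedom. All-identical data yields (0, 1); nonzero between-group spread
    with zero within-group spread leaves F undefined and raises.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    all_obs = np.concatenate(groups)
    grand = all_obs.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = len(all_obs) - len(groups)
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, 1.0
        raise ValueError("zero within-group variance: F is undefined")
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f_stat, df_between, df_within))
    return float(f_stat), p


def pairwise_ttests(
    groups: dict[str, np.ndarray] | Sequence[np.ndarray],
    paired: bool = False,
    correction: str | None = None,
) -> pd.DataFrame:
    """Symmetric table of two-sided p-values for every unordered pair.

    Unpaired mode uses Welch's t-test (group sizes may differ); paired mode
    requires matched orderings of equal length. A pair whose differences are
    all zero (e.g. a group against itself, paired) is reported as p = 1 by
    convention. ``correction`` may be ``"bonferroni"`` or ``"holm"``; the
    default reports raw p-values.
    """
    if isinstance(groups, dict):
        names = list(groups)
        arrays = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        arrays = [np.asarray(g, dtype=float) for g in groups]
        names = [f"group{i}" for i in range(len(arrays))]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")

    pairs, raw = [], []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            a, b = arrays[i], arrays[j]
            if paired:
                if len(a) != len(b):
                    raise ValueError(
                        f"paired test needs equal lengths ({names[i]}: {len(a)}, "
                        f"{names[j]}: {len(b)})"
                    )
                diff = a - b
                p = 1.0 if np.all(diff == 0) else float(sps.ttest_rel(a, b).pvalue)
            else:
                p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
            pairs.append((i, j))
            raw.append(p)

    adjusted = _adjust(np.asarray(raw), correction)
    table = pd.DataFrame(np.nan, index=names, columns=names)
    for (i, j), p in zip(pairs, adjusted):
        table.iloc[i, j] = p
        table.iloc[j, i] = p
    return table


def _adjust(p: np.ndarray, method: str | None) -> np.ndarray:
    if method is None:
        return p
    m = len(p)
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "holm":
        order = np.argsort(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(running, 1.0)
        return adj
    raise ValueError(f"unknown correction {method!r}")
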