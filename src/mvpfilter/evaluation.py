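"""Association scans and false-discovery evaluation.

These routines quantify what probe filtering buys: fewer tests m, a lower
estimated proportion of null probes p0, and more discoveries at any given
q-value threshold.

*Association scan.* Each probe is tested one at a time as the sole
predictor in a simple linear regression of the outcome; the F statistic
for the slope is F = (n - 2) R^2 / (1 - R^2) on (1, n - 2) degrees of
freedom, with the p-value from the upper tail.

*Proportion of nulls.* The default estimator bounds the empirical CDF of
the p-values by what a uniform sample could plausibly do: with F_m the
empirical CDF,

    p0_hat = 1 - sup_t [ F_m(t) - t - beta_m(t) ] / (1 - t),

where the bounding function beta_m(t) = c(alpha, m) sqrt(t (1 - t)) is
calibrated by seeded Monte-Carlo simulation of the uniform empirical
process so that under a global null the bound is exceeded with
probability alpha. The supremum is taken over the observed p-values. The
estimate may exceed 1 and is deliberately not clipped; it is a
conservative (downward-biased-in-signal) estimate that behaves well when
p0 is close to 1. Storey's estimator #{p_i > lambda} / (m (1 - lambda))
is provided as a cross-check.

*q-values.* The positive false discovery rate at threshold t is estimated
as p0 * m * t / #{p_i <= t}; evaluating at each observed p-value and
enforcing monotonicity by a running minimum from the largest p-value down
yields per-probe q-values that increase in the same order as the
p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .iolayer import BetaMatrix, ValidationError
from .mixture import SelectionResult

__all__ = [
    "association_scan",
    "P0Estimate",
    "estimate_p0",
    "qvalues",
    "significance_curve",
    "bonferroni_threshold",
]

_MIN_SAMPLES = 4  # simple regression needs n - 2 >= 2 residual df


def association_scan(
    betas: BetaMatrix,
    outcome: pd.Series,
    selection: SelectionResult | None = None,
) -> pd.DataFrame:
    """Per-probe simple-regression F-test of a continuous outcome.

    Parameters
    ----------
    betas
        Probe × sample methylation fractions; samples absent from
        ``outcome`` (e.g. second-replicate columns) are ignored.
    outcome
        Continuous phenotype indexed by sample ID.
    selection
        When given, the scan is restricted to the selected probes, which
        is exactly how filtering changes the multiple-testing burden.

    Returns a DataFrame indexed by probe ID with columns ``F, p, n_used,
    zero_var`` and attrs ``outcome`` (name) and ``m`` (tests performed).
    Probes with zero variance among complete cases get F = 0, p = 1 and a
    flag; a perfect fit (R^2 = 1) gets the largest representable F and
    the smallest positive p, flagged via ``perfect_fit``.
    """
    data = betas.data
    if selection is not None:
        data = data.loc[selection.mask.index[selection.mask]]
    out = outcome.dropna()
    common = [s for s in data.columns if s in out.index]
    if len(common) < _MIN_SAMPLES:
        raise ValidationError(
            f"association scan needs >= {_MIN_SAMPLES} samples with outcome, "
            f"got {len(common)}"
        )
    x = data[common].to_numpy()
    y = out.loc[common].to_numpy(dtype=float)

    ok = np.isfinite(x)
    n = ok.sum(axis=1)
    xm = np.where(ok, x, 0.0)
    yb = np.broadcast_to(y, x.shape)
    ym = np.where(ok, yb, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nn = np.where(n > 0, n, 1)
        mx = xm.sum(axis=1) / nn
        my = ym.sum(axis=1) / nn
        dx = np.where(ok, x - mx[:, None], 0.0)
        dy = np.where(ok, yb - my[:, None], 0.0)
        sxx = (dx * dx).sum(axis=1)
        syy = (dy * dy).sum(axis=1)
        sxy = (dx * dy).sum(axis=1)
        # rounding guard: a numerically constant probe has sxx at the level
        # of accumulated eps**2 noise, not exactly zero
        sxx_floor = n * (np.finfo(float).eps * np.maximum(np.abs(mx), 1.0)) ** 2
        syy_floor = n * (np.finfo(float).eps * np.maximum(np.abs(my), 1.0)) ** 2
        zero_var = (sxx <= sxx_floor) | (syy <= syy_floor) | (n < _MIN_SAMPLES)
        r2 = np.where(~zero_var, sxy**2 / np.where(zero_var, 1.0, sxx * syy), 0.0)
    r2 = np.clip(r2, 0.0, 1.0)

    perfect = (~zero_var) & (r2 >= 1.0 - 1e-12)
    r2 = np.where(perfect, 1.0, r2)
    df_resid = np.maximum(n - 2, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = df_resid * r2 / (1.0 - r2)
    F = np.where(zero_var, 0.0, F)
    F = np.where(perfect, np.finfo(float).max, F)
    p = stats.f.sf(F, 1, df_resid)
    p = np.where(zero_var, 1.0, p)
    p = np.where(perfect, np.finfo(float).tiny, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    res = pd.DataFrame(
        {"F": F, "p": p, "n_used": n.astype(int), "zero_var": zero_var,
         "perfect_fit": perfect},
        index=data.index.copy(),
    )
    res.attrs["outcome"] = str(outcome.name)
    res.attrs["m"] = len(res)
    return res


@dataclass
class P0Estimate:
    """Estimated proportion of probes with no true association."""

    p0_hat: float  # may exceed 1; not clipped by default
    method: str
    settings: dict = field(default_factory=dict)

    def clipped(self) -> float:
        """p0 capped at 1, for downstream use where a proportion is needed."""
        return min(self.p0_hat, 1.0)


@lru_cache(maxsize=64)
def _bounding_constant(
    m: int, alpha: float, n_sim: int, calibration_seed: int
) -> float:
    """(1 - alpha)-quantile of sup_i (i/m - U_(i)) / sqrt(U_(i)(1 - U_(i)))
    over seeded uniform samples of size m."""
    rng = np.random.default_rng(calibration_seed)
    ecdf = np.arange(1, m + 1) / m
    sups = np.empty(n_sim)
    for b in range(n_sim):
        u = np.sort(rng.random(m))
        sups[b] = np.max((ecdf - u) / np.sqrt(u * (1.0 - u)))
    return float(np.quantile(sups, 1.0 - alpha))


def estimate_p0(
    p_values,
    method: str = "meinshausen-rice",
    *,
    alpha: float = 0.05,
    lam: float = 0.5,
    n_calibration: int = 500,
    calibration_seed: int = 20100505,
) -> P0Estimate:
    """Estimate the proportion of true-null tests from a p-value vector.

    ``method`` is ``"meinshausen-rice"`` (bounding-function estimator,
    default; suited to p0 near 1) or ``"storey"`` (tail-counting
    cross-check with tuning parameter ``lam``). The bounding constant
    c(alpha, m) is calibrated once per (m, alpha) by ``n_calibration``
    seeded uniform simulations and cached. Estimates may exceed 1 and are
    not clipped; use :meth:`P0Estimate.clipped` where a proportion is
    required.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    m = p.size
    if m < 10:
        raise ValidationError(f"p0 estimation needs >= 10 p-values, got {m}")
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")

    if method == "storey":
        if not 0.0 < lam < 1.0:
            raise ValidationError(f"lambda must be in (0, 1), got {lam}")
        p0 = float(np.sum(p > lam)) / (m * (1.0 - lam))
        return P0Estimate(p0, "storey", {"lambda": lam})

    if method != "meinshausen-rice":
        raise ValueError(f"unknown p0 method {method!r}")
    c = _bounding_constant(m, alpha, n_calibration, calibration_seed)
    t = np.sort(p)
    ecdf = np.searchsorted(t, t, side="right") / m
    valid = t < 1.0
    if not valid.any():
        # every p-value is 1: nothing rejects, nulls everywhere
        return P0Estimate(1.0, "meinshausen-rice", {"alpha": alpha, "c": c})
    tt = t[valid]
    num = ecdf[valid] - tt - c * np.sqrt(tt * (1.0 - tt))
    sup = float(np.max(num / (1.0 - tt)))
    return P0Estimate(
        1.0 - sup,
        "meinshausen-rice",
        {"alpha": alpha, "c": c, "n_calibration": n_calibration},
    )


def qvalues(p_values, p0: float = 1.0) -> pd.DataFrame:
    """Per-test q-values from the pFDR estimator p0·m·t / #{p <= t}.

    Evaluates the estimator at every observed p-value and enforces
    monotonicity with a running minimum from the largest p-value down, so
    ordering by p and by q agree; tied p-values receive equal q. Returns
    a DataFrame with columns ``p, q`` in the input order (index preserved
    for Series input) and attrs ``p0, m``.
    """
    if isinstance(p_values, pd.Series):
        index = p_values.index
        p = p_values.to_numpy(dtype=float)
    else:
        p = np.asarray(p_values, dtype=float).ravel()
        index = pd.RangeIndex(p.size)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    if p0 < 0:
        raise ValidationError(f"p0 must be >= 0, got {p0}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    ranks = np.searchsorted(ps, ps, side="right")  # ties share the larger count
    raw = p0 * m * ps / ranks
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q = np.empty(m)
    q[order] = q_sorted
    out = pd.DataFrame({"p": p, "q": q}, index=index)
    out.attrs["p0"] = float(p0)
    out.attrs["m"] = m
    return out


def significance_curve(qtable: pd.DataFrame, thresholds) -> pd.DataFrame:
    """Count discoveries at each q-value threshold.

    Returns a DataFrame with columns ``threshold, n_significant``; the
    count is monotone non-decreasing in the threshold.
    """
    thr = np.asarray(thresholds, dtype=float).ravel()
    if (thr <= 0).any() or (thr > 1).any():
        raise ValidationError("thresholds must lie in (0, 1]")
    q = qtable["q"].to_numpy()
    counts = [int(np.sum(q <= t)) for t in thr]
    return pd.DataFrame({"threshold": thr, "n_significant": counts})


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise-error p-value threshold alpha / m.

    Shrinking the test family from all probes to the selected subset
    directly relaxes this threshold, which is the power argument for
    filtering under family-wise error control as well as under FDR.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValidationError(f"alpha must be in (0, 1], got {alpha}")
    if m < 1:
        raise ValidationError(f"m must be >= 1, got {m}")
    return alpha / m
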