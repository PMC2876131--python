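"""Univariate Gaussian mixture modeling of probe correlations.

The distribution of replicate probe correlations across an array is
typically bimodal: a component near zero (probes with no inter-individual
methylation variation, whose apparent signal is measurement noise) and a
component at moderate-to-high correlation (probes carrying biological
variation). A K-component normal mixture

    f(r) = sum_k  pi_k  N(r; mu_k, sigma^2_k)

is fitted by Expectation-Maximization:

* E-step: posterior responsibilities
  gamma_jk = pi_k phi(r_j; mu_k, sigma^2_k) / sum_l pi_l phi(r_j; mu_l, sigma^2_l)
* M-step: pi_k = mean_j gamma_jk; mu_k the gamma-weighted mean; sigma^2_k
  the gamma-weighted variance, floored to keep the likelihood bounded.

Iteration stops when the relative log-likelihood change drops below
``tol``. Multiple restarts (means initialized at evenly spaced quantiles
plus seeded jitter, equal weights, pooled variance) guard against local
maxima; the best log-likelihood wins. Components are always stored in
ascending-mean order so that "class 1" is the non-variable class
regardless of initialization.

There is no statistical test for the number of classes; ``scan_class_counts``
reports AIC/BIC over a range of K as guidance, and in this application a
two-class solution — one class with mean correlation near zero — is
usually sufficient for the filtering purpose.

Probes whose replicate correlation is undefined (no variance across
samples, or too few complete pairs) never enter the likelihood; they are
deterministically assigned to the lowest-mean class, on the rationale
that a probe with no variance is non-variable by definition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "MixtureModel",
    "fit_mixture",
    "scan_class_counts",
    "posteriors",
    "SelectionResult",
    "select_probes",
]


@dataclass
class MixtureModel:
    """Fitted K-component univariate normal mixture.

    Components are sorted by ascending mean; weights lie on the simplex
    and each variance respects the fitting floor. ``aic``/``bic`` use
    3K - 1 free parameters (K weights on the simplex, K means, K
    variances).
    """

    k: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: float
    aic: float
    bic: float
    n_iterations: int
    converged: bool
    n_restarts_used: int
    seed: int
    ll_history: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-10):
            raise ValueError("mixture weights must sum to 1")
        if (self.weights < 0).any():
            raise ValueError("mixture weights must be non-negative")
        if not np.all(np.diff(self.means) >= 0):
            raise ValueError("components must be sorted by ascending mean")

    def log_density(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return logsumexp(self._component_logpdf(x), axis=1)

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        """Posterior class probabilities, rows summing to 1."""
        lp = self._component_logpdf(np.asarray(x, dtype=float))
        return np.exp(lp - logsumexp(lp, axis=1, keepdims=True))

    def _component_logpdf(self, x: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            logw = np.log(self.weights)
        return (
            logw
            - 0.5 * np.log(2.0 * np.pi * self.variances)
            - 0.5 * (x[:, None] - self.means) ** 2 / self.variances
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "MixtureModel":
        d = json.loads(Path(path).read_text())
        return cls(
            k=d["k"],
            weights=np.array(d["weights"]),
            means=np.array(d["means"]),
            variances=np.array(d["variances"]),
            log_likelihood=d["log_likelihood"],
            aic=d["aic"],
            bic=d["bic"],
            n_iterations=-1,
            converged=d["converged"],
            n_restarts_used=-1,
            seed=d["seed"],
        )


def _em_once(
    x: np.ndarray,
    k: int,
    mu0: np.ndarray,
    tol: float,
    max_iter: int,
    variance_floor: float,
):
    n = x.size
    w = np.full(k, 1.0 / k)
    mu = mu0.astype(float).copy()
    pooled = max(float(np.var(x)), variance_floor)
    var = np.full(k, pooled)
    history: list[float] = []
    prev_ll = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        with np.errstate(divide="ignore"):
            logw = np.log(w)
        lp = (
            logw
            - 0.5 * np.log(2.0 * np.pi * var)
            - 0.5 * (x[:, None] - mu) ** 2 / var
        )
        norm = logsumexp(lp, axis=1)
        ll = float(norm.sum())
        history.append(ll)
        gamma = np.exp(lp - norm[:, None])
        nk = gamma.sum(axis=0)
        # empty component: leave its parameters where they are
        safe = np.where(nk > 0, nk, 1.0)
        w = nk / n
        mu_new = (gamma * x[:, None]).sum(axis=0) / safe
        mu = np.where(nk > 0, mu_new, mu)
        var_new = (gamma * (x[:, None] - mu) ** 2).sum(axis=0) / safe
        var = np.where(nk > 0, np.maximum(var_new, variance_floor), var)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * abs(ll):
            converged = True
            break
        prev_ll = ll
    return w, mu, var, history[-1], len(history), converged, history


def fit_mixture(
    values: Sequence[float] | np.ndarray,
    k: int,
    *,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
    n_restarts: int = 10,
    variance_floor: float = 1e-6,
) -> MixtureModel:
    """Fit a K-component univariate normal mixture by EM.

    Parameters
    ----------
    values
        Defined probe correlations (NaN entries are rejected; filter
        undefined probes out first).
    k
        Number of components, >= 1; at least 2k values are required.
    seed
        Seeds the restart jitter only — the fit is deterministic given
        ``values``, ``k`` and ``seed``.
    tol, max_iter
        Convergence is a relative log-likelihood change below ``tol``.
    n_restarts
        Independent initializations; the best final log-likelihood wins.
    variance_floor
        Lower bound on component variances, keeping the likelihood
        bounded (an unconstrained normal mixture's likelihood is
        unbounded as any variance shrinks onto a data point).
    """
    x = np.asarray(values, dtype=float).ravel()
    if np.isnan(x).any():
        raise ValueError("values contain NaN; drop undefined correlations first")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if x.size < 2 * k:
        raise ValueError(f"need >= {2 * k} values for k={k}, got {x.size}")
    if k > 1 and np.ptp(x) == 0:
        raise ValueError("all values identical; a multi-component fit is degenerate")

    if k == 1:
        # EM fixed point in closed form
        mu = float(np.mean(x))
        var = max(float(np.var(x)), variance_floor)
        ll = float(
            np.sum(-0.5 * np.log(2.0 * np.pi * var) - 0.5 * (x - mu) ** 2 / var)
        )
        return _finalize(
            np.array([1.0]), np.array([mu]), np.array([var]), ll, x.size,
            n_iter=1, converged=True, n_restarts_used=1, seed=seed, history=[ll],
        )

    rng = np.random.default_rng(seed)
    q = np.quantile(x, (np.arange(k) + 0.5) / k)
    jitter_scale = 0.1 * (np.std(x) + 1e-12)
    best = None
    for _ in range(n_restarts):
        mu0 = q + rng.normal(0.0, jitter_scale, size=k)
        out = _em_once(x, k, mu0, tol, max_iter, variance_floor)
        if best is None or out[3] > best[3]:
            best = out
    w, mu, var, ll, n_iter, converged, history = best
    return _finalize(
        w, mu, var, ll, x.size,
        n_iter=n_iter, converged=converged, n_restarts_used=n_restarts,
        seed=seed, history=history,
    )


def _finalize(w, mu, var, ll, n, *, n_iter, converged, n_restarts_used, seed,
              history) -> MixtureModel:
    order = np.argsort(mu)
    n_params = 3 * len(mu) - 1
    return MixtureModel(
        k=len(mu),
        weights=w[order],
        means=mu[order],
        variances=var[order],
        log_likelihood=ll,
        aic=2.0 * n_params - 2.0 * ll,
        bic=n_params * np.log(n) - 2.0 * ll,
        n_iterations=n_iter,
        converged=converged,
        n_restarts_used=n_restarts_used,
        seed=seed,
        ll_history=list(history),
    )


def scan_class_counts(
    values: Sequence[float] | np.ndarray,
    k_range: Iterable[int] = range(1, 7),
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit one mixture per class count and tabulate fit indices.

    Returns a DataFrame with columns ``k, log_likelihood, aic, bic,
    converged``, sorted by K. All fits share the same seed policy, so the
    scan is deterministic.
    """
    rows = []
    for k in sorted(k_range):
        m = fit_mixture(values, k, **fit_kwargs)
        rows.append(
            {"k": k, "log_likelihood": m.log_likelihood, "aic": m.aic,
             "bic": m.bic, "converged": m.converged}
        )
    return pd.DataFrame(rows)


def posteriors(model: MixtureModel, pct: pd.DataFrame) -> pd.DataFrame:
    """Posterior class probabilities for every probe in a correlation table.

    Probes with a defined correlation get Bayes posteriors under
    ``model``; undefined probes get posterior 1 on the lowest-mean
    (non-variable) class. Columns ``post_1 .. post_K`` follow the model's
    ascending-mean class order; ``assigned`` is the argmax class (1-based)
    and ``defined`` carries the flag through.
    """
    out = pd.DataFrame(index=pct.index)
    defined = pct["defined"].to_numpy(dtype=bool)
    gamma = np.zeros((len(pct), model.k))
    gamma[:, 0] = 1.0  # convention for undefined probes
    if defined.any():
        gamma[defined] = model.responsibilities(pct.loc[defined, "r"].to_numpy())
    for j in range(model.k):
        out[f"post_{j + 1}"] = gamma[:, j]
    out["assigned"] = gamma.argmax(axis=1) + 1
    out["defined"] = defined
    return out


@dataclass
class SelectionResult:
    """Outcome of thresholding posteriors for the variable class(es)."""

    threshold: float
    mask: pd.Series  # bool per probe, index = probe IDs
    n_selected: int
    n_excluded: int

    @property
    def selected_ids(self) -> list[str]:
        return list(self.mask.index[self.mask])


def select_probes(post: pd.DataFrame, threshold: float = 0.5) -> SelectionResult:
    """Select probes whose posterior mass on the variable class(es) is
    at least ``threshold``.

    The non-variable class is the lowest-mean component; with K > 2 the
    "variable" posterior is the summed posterior of every other class.
    Ties at exactly ``threshold`` are selected. Undefined-correlation
    probes carry zero variable-class posterior and are never selected.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    post_cols = [c for c in post.columns if c.startswith("post_")]
    variable_mass = post[post_cols[1:]].sum(axis=1) if len(post_cols) > 1 \
        else pd.Series(0.0, index=post.index)
    mask = variable_mass >= threshold
    return SelectionResult(
        threshold=threshold,
        mask=mask,
        n_selected=int(mask.sum()),
        n_excluded=int((~mask).sum()),
    )
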