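"""Probe and sample correlations between technical replicates.

With each biosample assayed twice, the signal for biosample *i* on probe
*j*, replicate *k*, decomposes as

    y_ijk = m_j + a_ij + e_ijk,

where m_j is the probe's average level, a_ij the biosample-specific
deviation (the biological signal, variance VAR(A)_j), and e_ijk
independent measurement error (variance VAR(E)_j, assumed equal across
the two replicates). Under uncorrelated errors the Pearson correlation of
a probe's two replicate vectors across biosamples — the *probe
correlation* — estimates the signal-to-total-variance ratio

    rho_j = VAR(A)_j / (VAR(A)_j + VAR(E)_j),

so a probe correlation near zero means the probe carries essentially no
inter-individual methylation variation. The *sample correlation* — the
correlation of one biosample's two replicate profiles across probes —
estimates VAR(M)_i / (VAR(M)_i + VAR(E)_i), the between-probe methylation
spread against the error. Low probe correlations combined with high
sample correlations indicate that probes are non-variable, not that the
assay is noisy; the diagnostics summary quantifies this by correlating
probe correlations with total probe variances (positive when low
correlations come from low biological variance) and with mean methylation
levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .iolayer import BetaMatrix, ReplicateDesign, ValidationError

__all__ = [
    "expected_correlation",
    "probe_correlations",
    "sample_correlations",
    "diagnostics",
    "DiagnosticsSummary",
]

# below this many probes a probe-level diagnostic correlation is meaningless
_STABLE_MIN_PROBES = 10


def expected_correlation(lambda_ratio: float) -> float:
    """Probe correlation implied by a signal-to-error variance ratio.

    For lambda = VAR(A)/VAR(E) >= 0 the replicate correlation is
    lambda / (1 + lambda): 0 when the probe has no biological variance,
    0.5 at parity, approaching 1 as signal dominates.
    """
    if lambda_ratio < 0:
        raise ValueError(f"variance ratio must be >= 0, got {lambda_ratio}")
    return lambda_ratio / (1.0 + lambda_ratio)


def _pairwise_pearson(x: np.ndarray, y: np.ndarray, min_n: int):
    """Row-wise Pearson r over pairwise-complete columns.

    Returns (r, n, defined); r is NaN where fewer than ``min_n`` complete
    pairs remain or either vector is constant over the complete pairs.
    """
    ok = np.isfinite(x) & np.isfinite(y)
    n = ok.sum(axis=1)
    xm = np.where(ok, x, 0.0)
    ym = np.where(ok, y, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nn = np.where(n > 0, n, 1)
        mx = xm.sum(axis=1) / nn
        my = ym.sum(axis=1) / nn
        dx = np.where(ok, x - mx[:, None], 0.0)
        dy = np.where(ok, y - my[:, None], 0.0)
        sxx = (dx * dx).sum(axis=1)
        syy = (dy * dy).sum(axis=1)
        sxy = (dx * dy).sum(axis=1)
        r = sxy / np.sqrt(sxx * syy)
    defined = (n >= min_n) & (sxx > 0) & (syy > 0)
    r = np.where(defined, r, np.nan)
    # clamp tiny floating excursions beyond +/-1
    r = np.clip(r, -1.0, 1.0)
    return r, n.astype(int), defined


def probe_correlations(
    betas: BetaMatrix, design: ReplicateDesign, min_pairs: int = 10
) -> pd.DataFrame:
    """Per-probe replicate correlation with variance/mean diagnostics.

    Returns a DataFrame indexed by probe ID with columns:

    ``r``
        Pearson correlation between the probe's rep-1 and rep-2 vectors
        over pairwise-complete replicate pairs; NaN (``defined`` False)
        when fewer than ``min_pairs`` complete pairs remain or either
        vector is constant. Undefined probes are kept, not dropped: a
        probe with no variance across samples is non-variable by
        definition and is forced into the non-variable class downstream.
    ``n_pairs``
        Complete replicate pairs used.
    ``total_var``
        Variance across biosamples of the per-biosample replicate-mean
        beta (averaging replicates first halves the error contribution).
    ``mean_meth``
        Mean of all non-missing values for the probe.
    """
    if min_pairs < 3:
        raise ValidationError(f"min_pairs must be >= 3, got {min_pairs}")
    design.check_against(betas)
    rep1 = design.pairs["sample_rep1"].tolist()
    rep2 = design.pairs["sample_rep2"].tolist()
    x = betas.data[rep1].to_numpy()
    y = betas.data[rep2].to_numpy()
    r, n, defined = _pairwise_pearson(x, y, min_pairs)

    # per-biosample value: replicate mean for paired samples, raw otherwise
    paired = set(rep1) | set(rep2)
    singles = [s for s in betas.sample_ids if s not in paired]
    pair_mean = np.nanmean(np.stack([x, y]), axis=0)
    per_biosample = [pair_mean]
    if singles:
        per_biosample.append(betas.data[singles].to_numpy())
    biosample_vals = np.concatenate(per_biosample, axis=1)
    with np.errstate(invalid="ignore"):
        total_var = np.nanvar(biosample_vals, axis=1, ddof=1)
        mean_meth = np.nanmean(betas.values(), axis=1)

    return pd.DataFrame(
        {
            "r": r,
            "defined": defined,
            "n_pairs": n,
            "total_var": total_var,
            "mean_meth": mean_meth,
        },
        index=pd.Index(betas.probe_ids, name="probe_id"),
    )


def sample_correlations(
    betas: BetaMatrix, design: ReplicateDesign
) -> pd.DataFrame:
    """Per-pair correlation of the two replicate profiles across probes.

    Returns a DataFrame indexed by pair ID with columns ``r`` (NaN and
    ``defined`` False when degenerate), ``n_probes``.
    """
    design.check_against(betas)
    x = betas.data[design.pairs["sample_rep1"].tolist()].to_numpy().T
    y = betas.data[design.pairs["sample_rep2"].tolist()].to_numpy().T
    r, n, defined = _pairwise_pearson(x, y, min_n=3)
    return pd.DataFrame(
        {"r": r, "defined": defined, "n_probes": n},
        index=pd.Index(design.pairs["pair_id"], name="pair_id"),
    )


@dataclass
class DiagnosticsSummary:
    """Summary correlations attributing low probe correlations to low
    biological variance (positive ``corr_probecorr_totalvar``) versus
    high measurement error (negative)."""

    corr_probecorr_totalvar: float
    corr_probecorr_meanmeth: float
    mean_probe_correlation: float
    sd_probe_correlation: float
    mean_sample_correlation: float
    sd_sample_correlation: float
    n_probes_used: int
    stable: bool  # False below 10 defined probe correlations


def diagnostics(pct: pd.DataFrame, sct: pd.DataFrame) -> DiagnosticsSummary:
    """Correlate probe correlations with total variance and mean level.

    Computed over probes with a defined replicate correlation; raises if
    fewer than 3 remain, and flags the result unstable below 10.
    """
    ok = pct["defined"].to_numpy(dtype=bool)
    n_ok = int(ok.sum())
    if n_ok < 3:
        raise ValidationError(
            f"diagnostics need >=3 defined probe correlations, got {n_ok}"
        )
    r = pct.loc[ok, "r"].to_numpy()
    tv = pct.loc[ok, "total_var"].to_numpy()
    mm = pct.loc[ok, "mean_meth"].to_numpy()
    s_ok = sct["defined"].to_numpy(dtype=bool)
    rs = sct.loc[s_ok, "r"].to_numpy()

    def _corr(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])

    return DiagnosticsSummary(
        corr_probecorr_totalvar=_corr(r, tv),
        corr_probecorr_meanmeth=_corr(r, mm),
        mean_probe_correlation=float(np.mean(r)),
        sd_probe_correlation=float(np.std(r, ddof=1)) if n_ok > 1 else float("nan"),
        mean_sample_correlation=float(np.mean(rs)) if len(rs) else float("nan"),
        sd_sample_correlation=float(np.std(rs, ddof=1)) if len(rs) > 1 else float("nan"),
        n_probes_used=n_ok,
        stable=n_ok >= _STABLE_MIN_PROBES,
    )
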