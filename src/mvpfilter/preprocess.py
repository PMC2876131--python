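"""Two-channel signal correction and beta-value computation.

The methylation fraction at a probe is the ratio of the methylated-allele
intensity to the total intensity of both alleles,

    y_ij = Cy5_ij / (Cy5_ij + Cy3_ij),

which is dimensionless and bounded in [0, 1]. Before taking the ratio the
raw intensities can be corrected, independently per channel, for

1. *background signal* — per sample and channel, the mean of the
   negative-control intensities when a controls sidecar is supplied,
   otherwise the 5th percentile of that sample's intensities in the
   channel; corrected intensities are floored at ``alpha_floor`` so the
   ratio's denominator stays positive; and
2. *differential bisulfite conversion* — when per-sample conversion scores
   are available, an ordinary-least-squares fit of each sample's mean
   log-intensity on its conversion score (per channel, across samples);
   each sample's fitted deviation from the grand mean is subtracted from
   all its log intensities, removing the sample-level multiplicative bias
   that incomplete conversion induces.

The conversion correction here is a documented in-house design: it removes
a multiplicative per-sample bias that is linear in the conversion score on
the log scale. The :class:`CorrectionReport` records everything applied so
users who prefer their own pipeline can bypass this step and supply beta
values directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .iolayer import BetaMatrix, SignalTable, ValidationError

__all__ = ["CorrectionReport", "correct_signals", "compute_beta"]

_CHANNELS = ("cy3", "cy5")
_BG_PERCENTILE = 5.0  # fallback background when no negative controls given


@dataclass
class CorrectionReport:
    """What :func:`correct_signals` did, per sample and channel."""

    background: pd.DataFrame  # samples × channels, intensity units
    conversion_applied: bool
    conversion_coef: dict[str, float] = field(default_factory=dict)
    n_floored: dict[str, int] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


def correct_signals(
    signals: SignalTable, alpha_floor: float = 1.0
) -> tuple[SignalTable, CorrectionReport]:
    """Background-correct (and, when possible, conversion-correct) signals.

    Parameters
    ----------
    signals
        Raw two-channel records; ``signals.sample_info`` may carry
        ``background_cy3`` / ``background_cy5`` negative-control means and
        a ``conversion_score`` column.
    alpha_floor
        Lower bound (intensity units) applied after background
        subtraction; keeps every corrected intensity strictly positive.

    Returns the corrected table and a :class:`CorrectionReport`. The
    conversion step is skipped, with a note, when conversion scores are
    absent; it is refused outright when fewer than 3 samples carry a score
    (the regression would be degenerate).
    """
    if signals.records.empty:
        raise ValidationError("signal table is empty")
    if alpha_floor <= 0:
        raise ValidationError(f"alpha_floor must be > 0, got {alpha_floor}")

    rec = signals.records.copy()
    info = signals.sample_info
    sample_ids = signals.sample_ids

    bg = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"),
                      columns=list(_CHANNELS), dtype=float)
    report = CorrectionReport(background=bg, conversion_applied=False)

    by_sample = rec.groupby("sample_id", sort=False)
    for ch in _CHANNELS:
        ctrl_col = f"background_{ch}"
        floored = 0
        for sid, idx in by_sample.groups.items():
            raw = rec.loc[idx, ch].to_numpy(dtype=float)
            if info is not None and ctrl_col in info.columns and sid in info.index \
                    and np.isfinite(info.loc[sid, ctrl_col]):
                b = float(info.loc[sid, ctrl_col])
            else:
                b = float(np.percentile(raw, _BG_PERCENTILE))
            b = max(b, 0.0)
            bg.loc[sid, ch] = b
            corrected = np.maximum(raw - b, alpha_floor)
            floored += int(np.sum(raw - b < alpha_floor))
            rec.loc[idx, ch] = corrected
        report.n_floored[ch] = floored

    scores = None
    if info is not None and "conversion_score" in info.columns:
        scores = info["conversion_score"].dropna()
        scores = scores[scores.index.isin(sample_ids)]
    if scores is None or scores.empty:
        report.notes.append("conversion scores absent; conversion step skipped")
    elif len(scores) < 3:
        raise ValidationError(
            f"conversion correction needs >=3 scored samples, got {len(scores)}"
        )
    else:
        for ch in _CHANNELS:
            mean_log = np.log(
                rec[rec["sample_id"].isin(scores.index)]
                .groupby("sample_id", sort=False)[ch]
                .mean()
            )
            x = scores.loc[mean_log.index].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                report.conversion_coef[ch] = 0.0
                continue
            fit = stats.linregress(x, mean_log.to_numpy())
            report.conversion_coef[ch] = float(fit.slope)
            fitted = fit.intercept + fit.slope * scores
            deviation = fitted - fitted.mean()
            dev = rec["sample_id"].map(deviation).fillna(0.0).to_numpy()
            rec[ch] = np.exp(np.log(rec[ch].to_numpy(dtype=float)) - dev)
        report.conversion_applied = True

    return SignalTable(rec, info), report


def compute_beta(signals: SignalTable) -> BetaMatrix:
    """Methylated-fraction matrix from two-channel intensities.

    y = cy5 / (cy5 + cy3); records with zero total intensity become
    missing values rather than errors. The result is invariant to
    rescaling both channels of a record by any positive constant.
    """
    rec = signals.records
    total = rec["cy5"].to_numpy(dtype=float) + rec["cy3"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, rec["cy5"].to_numpy(dtype=float) / total, np.nan)
    long = pd.DataFrame(
        {"probe_id": rec["probe_id"], "sample_id": rec["sample_id"], "beta": beta}
    )
    wide = long.pivot(index="probe_id", columns="sample_id", values="beta")
    # preserve first-appearance order rather than pivot's lexicographic sort
    wide = wide.reindex(index=pd.unique(rec["probe_id"]),
                        columns=pd.unique(rec["sample_id"]))
    wide.index.name = "probe_id"
    wide.columns.name = None
    return BetaMatrix(wide)
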