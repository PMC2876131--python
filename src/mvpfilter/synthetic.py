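"""Synthetic replicate methylation datasets with known probe classes.

The generator realizes the variance-components signal model

    y_ijk = m_j + a_ij + e_ijk,

with per-probe baseline m_j drawn from a bimodal (mostly-unmethylated /
mostly-methylated) distribution, biosample deviations a_ij ~ N(0,
lambda_j sigma_e^2), and independent measurement error e_ijk ~ N(0,
sigma_e^2) per replicate. Probes fall into two latent classes that differ
only in the biological-to-error variance ratio lambda_j = VAR(A)_j /
VAR(E)_j: a *non-variable* class with lambda near zero and a *variable*
class with lambda near 1. The implied replicate probe correlation is
lambda_j / (1 + lambda_j), so the defaults

    lambda_null = 0.099  ->  expected r = 0.090
    lambda_var  = 1.041  ->  expected r = 0.510
    pi_null     = 0.58

put the two class-mean correlations at 0.09 and 0.51 with 58% of probes
non-variable, and the overall expected mean probe correlation at
0.58*0.090 + 0.42*0.510 = 0.267. lambda is constant within class; the
observed spread of probe correlations then comes entirely from Pearson
sampling error at the number of replicate pairs (SD roughly 0.07-0.09 at
126 pairs), which is what gives the fitted mixture components realistic
widths. Sample correlations are governed by the between-probe spread of
m_j against sigma_e; with the default bimodal baseline the analytic value
is about 0.995.

Default sizes (1505 probes, 311 biosamples, 126 replicate pairs) match a
cancer-panel methylation array study of peripheral-blood DNA; they are
the conditions under which the package's headline numbers are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy import stats

from .iolayer import BetaMatrix, OutcomeTable, ReplicateDesign, ValidationError

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "generate_dataset",
    "generate_outcomes",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic replicate-array generator.

    ``mean_weights``/``mean_locs``/``mean_scales`` define the bimodal
    baseline-methylation distribution (a two-component normal mixture
    truncated to ``mean_bounds``); ``sigma_e`` is the measurement-error
    SD in beta units; ``lambda_null``/``lambda_var`` are the
    VAR(A)/VAR(E) ratios of the two probe classes and ``pi_null`` the
    non-variable fraction.
    """

    n_probes: int = 1505
    n_samples: int = 311
    n_replicate_pairs: int = 126
    pi_null: float = 0.58
    sigma_e: float = 0.02
    lambda_null: float = 0.099
    lambda_var: float = 1.041
    mean_weights: tuple[float, float] = (0.6, 0.4)
    mean_locs: tuple[float, float] = (0.15, 0.75)
    mean_scales: tuple[float, float] = (0.05, 0.08)
    mean_bounds: tuple[float, float] = (0.02, 0.98)
    clip: bool = True
    shuffle_pairs: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_probes < 1 or self.n_samples < 1:
            raise ValidationError("n_probes and n_samples must be positive")
        if not 0 <= self.n_replicate_pairs <= self.n_samples:
            raise ValidationError(
                f"n_replicate_pairs must be in [0, n_samples], got "
                f"{self.n_replicate_pairs}"
            )
        if not 0.0 <= self.pi_null <= 1.0:
            raise ValidationError(f"pi_null must be in [0, 1], got {self.pi_null}")
        if self.sigma_e <= 0:
            raise ValidationError(f"sigma_e must be > 0, got {self.sigma_e}")
        if self.lambda_null < 0 or self.lambda_var < 0:
            raise ValidationError("lambda ratios must be >= 0")
        if not np.isclose(sum(self.mean_weights), 1.0):
            raise ValidationError("mean_weights must sum to 1")
        lo, hi = self.mean_bounds
        if not 0.0 <= lo < hi <= 1.0:
            raise ValidationError(f"mean_bounds must satisfy 0 <= lo < hi <= 1")

    def expected_sample_correlation(self) -> float:
        """Closed-form expected sample correlation VAR(M)/(VAR(M)+sigma_e^2).

        VAR(M) is the between-probe variance of m_j + a_ij by the law of
        total variance (truncation of the baseline mixture ignored, which
        is negligible at the default bounds).
        """
        w = np.asarray(self.mean_weights)
        mu = np.asarray(self.mean_locs)
        sd = np.asarray(self.mean_scales)
        var_m = float(np.sum(w * sd**2) + np.sum(w * mu**2) - np.sum(w * mu) ** 2)
        mean_lambda = self.pi_null * self.lambda_null + (1 - self.pi_null) * self.lambda_var
        var_m += mean_lambda * self.sigma_e**2
        return var_m / (var_m + self.sigma_e**2)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimulationConfig":
        """Build a config from flat key=value strings (CLI config files)."""
        kwargs = {}
        by_name = {f.name: f for f in fields(cls)}
        for key, val in mapping.items():
            if key not in by_name:
                raise ValidationError(f"unknown simulation parameter {key!r}")
            default = getattr(cls, key)
            if isinstance(default, bool):
                kwargs[key] = str(val).strip().lower() in ("1", "true", "yes", "on")
            elif isinstance(default, int):
                kwargs[key] = int(val)
            elif isinstance(default, float):
                kwargs[key] = float(val)
            elif isinstance(default, tuple):
                parts = [float(v) for v in str(val).replace(",", " ").split()]
                kwargs[key] = tuple(parts)
            else:  # pragma: no cover - no other field kinds
                kwargs[key] = val
        return cls(**kwargs)


@dataclass
class SimulationTruth:
    """Latent per-probe state of a generated dataset.

    ``probes`` is indexed by probe ID with columns ``label`` ("null" or
    "variable"), ``lambda``, ``var_a``, ``expected_r`` (= lambda/(1 +
    lambda)) and ``m`` (baseline). ``deviations`` holds the realized
    biosample deviations a_ij (probe × biosample) so that outcomes causally
    linked to true biology — not to measurement error — can be built.
    """

    probes: pd.DataFrame
    sigma_e: float
    seed: int
    deviations: np.ndarray = field(repr=False)
    biosample_ids: list[str] = field(default_factory=list)

    def class_ids(self, label: str) -> list[str]:
        return list(self.probes.index[self.probes["label"] == label])


def _draw_baselines(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    comp = rng.choice(len(cfg.mean_weights), size=cfg.n_probes, p=cfg.mean_weights)
    lo, hi = cfg.mean_bounds
    m = np.empty(cfg.n_probes)
    for c, (mu, sd) in enumerate(zip(cfg.mean_locs, cfg.mean_scales)):
        idx = comp == c
        a, b = (lo - mu) / sd, (hi - mu) / sd
        m[idx] = stats.truncnorm.rvs(
            a, b, loc=mu, scale=sd, size=int(idx.sum()), random_state=rng
        )
    return m


def generate_dataset(
    config: SimulationConfig | None = None,
) -> tuple[BetaMatrix, ReplicateDesign, SimulationTruth]:
    """Generate a replicate beta matrix with known probe classes.

    The first ``n_replicate_pairs`` biosamples are assayed twice; the
    second replicate appears as an extra column suffixed ``_r2`` and the
    pairing is returned as a :class:`ReplicateDesign` (set
    ``shuffle_pairs`` to randomize which biosamples are replicated).
    Outputs are clipped to [0, 1] when ``clip`` is on; under the default
    parameters clipping touches roughly 0.1% of values (mostly baselines
    near the lower truncation bound), too few to distort the calibration.
    Fully deterministic given ``config.seed``.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    probe_ids = [f"cg{j:05d}" for j in range(cfg.n_probes)]
    biosample_ids = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]

    m = _draw_baselines(cfg, rng)
    is_null = rng.random(cfg.n_probes) < cfg.pi_null
    lam = np.where(is_null, cfg.lambda_null, cfg.lambda_var)
    var_a = lam * cfg.sigma_e**2

    a = rng.normal(0.0, 1.0, size=(cfg.n_probes, cfg.n_samples)) * np.sqrt(var_a)[:, None]
    signal = m[:, None] + a

    if cfg.shuffle_pairs:
        paired_idx = rng.choice(cfg.n_samples, cfg.n_replicate_pairs, replace=False)
        paired_idx.sort()
    else:
        paired_idx = np.arange(cfg.n_replicate_pairs)

    e1 = rng.normal(0.0, cfg.sigma_e, size=(cfg.n_probes, cfg.n_samples))
    e2 = rng.normal(0.0, cfg.sigma_e, size=(cfg.n_probes, len(paired_idx)))
    y1 = signal + e1
    y2 = signal[:, paired_idx] + e2
    if cfg.clip:
        y1 = np.clip(y1, 0.0, 1.0)
        y2 = np.clip(y2, 0.0, 1.0)

    rep1_ids = [biosample_ids[i] for i in paired_idx]
    rep2_ids = [f"{sid}_r2" for sid in rep1_ids]
    data = pd.DataFrame(
        np.concatenate([y1, y2], axis=1),
        index=pd.Index(probe_ids, name="probe_id"),
        columns=biosample_ids + rep2_ids,
    )
    betas = BetaMatrix(data)
    design = ReplicateDesign(
        pd.DataFrame(
            {
                "pair_id": [f"P{i + 1:03d}" for i in range(len(rep1_ids))],
                "sample_rep1": rep1_ids,
                "sample_rep2": rep2_ids,
            }
        )
    )
    truth = SimulationTruth(
        probes=pd.DataFrame(
            {
                "label": np.where(is_null, "null", "variable"),
                "lambda": lam,
                "var_a": var_a,
                "expected_r": lam / (1.0 + lam),
                "m": m,
            },
            index=pd.Index(probe_ids, name="probe_id"),
        ),
        sigma_e=cfg.sigma_e,
        seed=cfg.seed,
        deviations=a,
        biosample_ids=biosample_ids,
    )
    return betas, design, truth


def generate_outcomes(
    truth: SimulationTruth,
    betas: BetaMatrix,
    n_causal: int = 10,
    effect_size: float = 0.4,
    restrict_to_variable: bool = True,
    seed: int = 0,
    name: str = "outcome",
) -> OutcomeTable:
    """Continuous outcome driven by the true biology of a few probes.

    The outcome for biosample i is

        sum_c effect_size * standardized(a_ic) + N(0, 1),

    with the causal probes drawn from the variable class when
    ``restrict_to_variable`` (the scientifically interesting case: real
    effects live where there is real variation). Building the outcome
    from the latent deviations a_ic rather than the measured betas keeps
    measurement error out of the causal path. Causal probe IDs are
    recorded on the returned table.
    """
    rng = np.random.default_rng(seed)
    if restrict_to_variable:
        eligible = truth.class_ids("variable")
        if not eligible:
            raise ValidationError("no variable-class probes to draw causal set from")
    else:
        eligible = list(truth.probes.index)
    if n_causal > len(eligible):
        raise ValidationError(
            f"n_causal={n_causal} exceeds {len(eligible)} eligible probes"
        )
    causal = sorted(rng.choice(eligible, size=n_causal, replace=False).tolist())

    n = len(truth.biosample_ids)
    y = rng.normal(0.0, 1.0, size=n)
    if n_causal:
        pos = truth.probes.index.get_indexer(causal)
        dev = truth.deviations[pos]
        sd = dev.std(axis=1, ddof=0)
        sd[sd == 0] = 1.0
        z = (dev - dev.mean(axis=1, keepdims=True)) / sd[:, None]
        y = y + effect_size * z.sum(axis=0)

    table = OutcomeTable(
        pd.DataFrame({name: y}, index=pd.Index(truth.biosample_ids, name="sample_id"))
    )
    table.causal_probes[name] = causal
    return table
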