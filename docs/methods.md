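# Methods

## The probe-selection problem

High-throughput methylation arrays report a beta value — the methylated
fraction, in [0, 1] — for each CpG probe in each biosample. In any given
study population, many probes show essentially no inter-individual
variation in methylation. Whatever signal such a probe shows across
samples is measurement noise (sample preparation, hybridization, image
processing), so any association it exhibits with a phenotype is a false
positive; worse, carrying thousands of such probes into an association
scan inflates the multiple-testing burden and erodes power at the probes
that do vary. `mvpfilter` identifies these non-variable probes from
technical replicates and removes them before association testing.

## Signal model and replicate correlations

With each biosample assayed twice, the measurement for biosample *i* on
probe *j*, replicate *k*, is modelled as

    y_ijk = m_j + a_ij + e_ijk,

where m_j is the probe's mean level, a_ij ~ (0, VAR(A)_j) the
biosample-specific deviation (biological signal), and e_ijk ~ (0,
VAR(E)_j) independent measurement error, with equal error variance in
the two replicates. Under uncorrelated errors,

* the **probe correlation** — Pearson correlation of a probe's rep-1 and
  rep-2 vectors across biosamples — estimates
  VAR(A)_j / (VAR(A)_j + VAR(E)_j), a signal-to-total-variance ratio;
* the **sample correlation** — correlation of one biosample's two
  replicate profiles across probes — estimates
  VAR(M)_i / (VAR(M)_i + VAR(E)_i), where VAR(M)_i is the between-probe
  methylation spread.

Low probe correlations together with high sample correlations indicate
that probes lack biological variance, not that the assay is noisy. The
`diagnostics` summary adds the correlation between probe correlations
and total probe variances (positive when low correlations reflect low
biological variance) and between probe correlations and mean methylation
levels. Only Pearson correlation is offered: the estimand above is
defined through linear covariance decomposition, and a rank correlation
would estimate something else. Total probe variance averages the two
replicates per biosample before taking the variance across biosamples,
which halves the error contribution; this choice is deliberate and
documented here because the alternative (pooling replicates as extra
observations) changes the diagnostic's scale, though not its sign.

Probes whose correlation is undefined — fewer than `min_pairs`
(default 10) complete replicate pairs, or zero variance in either
replicate vector — are retained with a flag rather than dropped, and are
deterministically treated as non-variable downstream: a probe with no
variance across samples is non-variable by definition.

## Mixture model and selection rule

The probe correlations r_1..r_n (defined ones only) are fitted with a
K-component univariate normal mixture by EM (module `mixture`; the EM is
implemented in this package, not delegated). Numerical choices:

* convergence when the relative log-likelihood change is below
  `tol = 1e-8`, capped at `max_iter = 1000`;
* `n_restarts = 10` initializations — means at evenly spaced quantiles
  of the data plus seeded jitter (scale 0.1 SD), equal weights, pooled
  variance — keeping the best final log-likelihood;
* component variances floored at `variance_floor = 1e-6` (squared
  correlation units), since the unconstrained mixture likelihood is
  unbounded as a variance collapses onto a data point;
* components reported in ascending-mean order, so class 1 is always the
  non-variable class; an empty component keeps its parameters rather
  than producing NaNs;
* K = 1 is returned in closed form (sample mean, biased /n variance),
  which is the EM fixed point.

K is chosen by the user; `scan_class_counts` tabulates AIC/BIC over
K = 1..6 as guidance (AIC = 2(3K−1) − 2LL, BIC = (3K−1)ln n − 2LL). No
automatic selection is attempted — there is no valid likelihood-ratio
test between mixture class counts — and for the filtering purpose a
model with one class centred near zero correlation is sufficient. On
bimodal correlation distributions like the default synthetic data, BIC
drops dramatically from K = 1 to K = 2 and negligibly thereafter.

Selection: each probe's posterior mass on the non-lowest-mean class(es)
is compared to a threshold τ (default 0.5); ties at exactly τ are
selected. Undefined-correlation probes carry zero variable-class
posterior and are never selected. The selected count is monotone
non-increasing in τ.

## Association evaluation

`association_scan` regresses the outcome on each probe separately
(complete cases; F = (n−2)R²/(1−R²) on (1, n−2) df). No covariates are
included by default — probes are the sole predictors. Degenerate cases
are flagged, not raised: a zero-variance probe gets F = 0, p = 1; a
perfect fit gets the largest representable F and smallest positive p.

The proportion of null probes p0 is estimated by a bounding-function
estimator: with F̂_m the empirical CDF of the p-values,

    p0_hat = 1 − sup_t [ F̂_m(t) − t − c(α, m)·sqrt(t(1−t)) ] / (1 − t),

the sup taken over the observed p-values and c(α, m) the (1−α) quantile
(default α = 0.05) of sup_i (i/m − U_(i))/sqrt(U_(i)(1−U_(i))) over 500
seeded uniform samples of size m (cached per (m, α); internal
calibration seed fixed so results are reproducible). The estimate may
exceed 1 and is deliberately reported unclipped — values slightly above
1 are informative about how null the p-value set looks — with
`P0Estimate.clipped()` available where a proportion is required. Storey's
estimator #{p > λ}/(m(1−λ)), λ = 0.5, is provided as a cross-check.

q-values follow the pFDR estimator q̂(t) = p0·m·t / #{p_i ≤ t} evaluated
at each observed p-value, with monotonicity enforced by a running
minimum from the largest p-value down; tied p-values receive equal q,
and p0 is used exactly as supplied (clipping is the caller's opt-in).
`bonferroni_threshold(α, m) = α/m` expresses the same power argument
under family-wise error control: shrinking m relaxes the threshold.

## Signal correction (preprocess)

Beta values are cy5/(cy5 + cy3) (methylated over total), with zero-total
records becoming missing values. The optional correction is an in-house
design, flagged in its report so users can bypass it: per sample and
channel, background is the mean negative-control intensity when
supplied, else the 5th percentile of the sample's intensities, with
corrected intensities floored at `alpha_floor` (default 1.0 intensity
unit, keeping denominators positive); bisulfite-conversion differences
are removed by OLS of per-sample mean log intensity on conversion score
(per channel), subtracting each sample's fitted deviation from the grand
mean — i.e. a multiplicative per-sample bias log-linear in the score.
The regression is refused below 3 scored samples. No dye-bias, plate, or
probe-type normalization is attempted.

## Synthetic data generator

`generate_dataset` realizes the signal model directly, with two probe
classes differing only in λ_j = VAR(A)_j/VAR(E)_j. Defaults:

| parameter | default | meaning |
|---|---|---|
| n_probes | 1505 | probes on the emulated panel |
| n_samples | 311 | biosamples |
| n_replicate_pairs | 126 | biosamples assayed twice |
| pi_null | 0.58 | non-variable probe fraction |
| sigma_e | 0.02 | measurement-error SD (beta units) |
| lambda_null | 0.099 | λ of non-variable probes → expected r = 0.090 |
| lambda_var | 1.041 | λ of variable probes → expected r = 0.510 |
| baseline m_j | 0.6·N(0.15, 0.05²) + 0.4·N(0.75, 0.08²), truncated to [0.02, 0.98] | bimodal mostly-unmethylated / mostly-methylated panel |

The λ values were chosen by inverting r = λ/(1+λ) at the target class
means, and σ_e = 0.02 puts the analytic expected sample correlation
VAR(M)/(VAR(M)+σ_e²) at ≈ 0.9956 (law of total variance over the
baseline mixture; `SimulationConfig.expected_sample_correlation()`
computes it). λ is constant within class: the observed spread of probe
correlations then comes entirely from Pearson sampling error at 126
pairs (SD ≈ 0.07–0.09), which is what gives the fitted mixture
components realistic widths. A per-probe λ distribution would be a
config extension, deliberately off by default. Replicated biosamples are
the first `n_replicate_pairs` by default (reproducibility); a
`shuffle_pairs` option randomizes them.

Values are clipped to [0, 1]; under the defaults clipping touches
roughly 0.1% of values (0.07–0.16% per seed, concentrated at baselines
near the lower truncation bound) and demonstrably does not move the
calibration targets. What the generator does **not** emulate: probe
annotations (CpG-island status), batch/plate structure, heteroscedastic
error across probes ("similar precision in the two replicates" is taken
across probes too), non-normal error, and cross-tissue structure.
Passing tests therefore show the machinery recovers the calibrated
composition under the model's own assumptions; they do not certify
behavior under batch effects or heavy-tailed noise.

`generate_outcomes` builds a continuous phenotype from the latent
deviations a_ic of a few causal probes (default 10 causal, effect 0.4 SD
per standardized deviation, causal set drawn from the variable class),
plus unit normal noise — so the causal path runs through true biology,
never through measurement error.

## Problem sizes used in the shipped analyses

The headline summaries average 10 generator seeds at the default sizes
(1505 × 311, 126 pairs); the paired power experiment uses 50 seeds with
10 causal variable-class probes at effect 0.4; null-calibration checks
use 100 uniform p-value vectors of length 1505. These sizes give
Monte-Carlo standard errors comfortably inside the tolerances quoted in
the tests.

## Known limitations

* The power comparison counts discoveries; before filtering some
  "discoveries" are chance hits on non-variable probes, so on any single
  dataset the before/after significance curves can cross at loose
  q-thresholds even though the after-curve dominates in expectation and
  the estimated p0 essentially always drops.
* The bounding-function p0 estimator is conservative by construction;
  with few, weak signals it frequently returns values at or slightly
  above 1, and differences between analyses can be small relative to its
  Monte-Carlo calibration noise.
* Exactly two replicates are supported; an intraclass-correlation /
  mixed-model path for more replicates is out of scope.
* The conversion correction is a declared stand-in for a vendor-specific
  procedure whose details are not public; users with their own
  preprocessing should supply beta values directly.
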