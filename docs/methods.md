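# Methods

## The analysis model

The pipeline treats a zona glomerulosa recording as a set of uniformly
sampled fluorescence traces (one per cell ROI, default 10 Hz) observed
under a stepped perfusion protocol of ([K⁺], [AT-II]) epochs, with a
nested animal → slice → cell hierarchy.  Frame *i* maps to time
`i · frame_interval_s` (no offset); epoch membership is half-open
`[start, end)`, so an event exactly at a solution switch belongs to the
later epoch.

### Detrending and spike registration

Bleaching decay and slow drift are removed by subtracting the minimum
within a **trailing** window of `window_frames` (default 50 = 5 s)
ending at the current frame.  The window alignment is a design choice:
a trailing window is causal (no future data leaks into the baseline) and
shrinks at the recording start, which suits a monotone bleaching
correction; a centered window would shift spike onsets.  The detrended
trace is everywhere ≥ 0 and invariant to constant offsets.

Spikes are registered where the frame-to-frame difference of the
detrended trace exceeds a threshold.  Runs of consecutive
supra-threshold frames collapse to the run's first frame (the rule is a
rise detector, so the onset is the defensible timestamp), and spikes
closer than `min_separation_s` (default 0.3 s = 3 frames) to the
previously accepted spike merge into it, preventing multi-frame rises
from double-counting.  This refractory rule means intra-burst intervals
shorter than 0.3 s are not resolvable: on bursty synthetic data with
exponential intra-burst intervals of mean 0.5 s, roughly the shortest
half of those intervals merge and detected spike rates sit 20–30 % below
the generative rates.  Burst *counts* and all rate *comparisons* are
unaffected in kind, but absolute detected spike rates should be read
with this resolution floor in mind.

Two threshold modes exist.  The numeric mode reproduces the manual
workflow: the analyst sets a value above the background difference level
seen in quiet stretches of the recording (at noise SD σ, background
differences span roughly ±3·√2·σ, so ~5σ is a practical choice).  The
automatic mode sets `auto_k × 1.4826 × MAD` of the difference signal
(default `auto_k = 5`), a robust plug-in for "k standard deviations of
background" that is insensitive to sparse spikes.  Because the
difference signal carries √2 times the trace noise SD, the auto
threshold at k = 5 is ≈ 7.1 trace-noise SDs; reliable (≥ 95 %) recall of
single-frame rises under the auto mode therefore needs an
amplitude-to-noise ratio of roughly 10 or more, and sub-frame spike
timing attenuates the observed rise by up to `e^(−Δt/τ_decay)`.  The
numeric mode, set as above, detects reliably from lower ratios.

Artifact handling replaces manual inspection with a stated rule: a frame
whose spike registers simultaneously in more than a configurable
fraction (default 0.5) of all cells is treated as a global motion or
perfusion signature and its spikes are removed everywhere, with per-cell
logging.  The policy is off by default and is an automated proxy — it
catches global transients, not local tissue deformation.

Cell selection mirrors the recording workflow: cells with no spike
during the high-AT-II reference condition (default 1 nM = 1000 pM) can
be excluded before summarization.

### Bursts and activity metrics

A burst is a cluster of ≥ `min_spikes` (default 3) spikes whose internal
gaps are all strictly < `max_gap_s` (default 4 s); the strictness
matches the quiescence definition (a gap of exactly 4 s splits).
Segmentation is a greedy linear scan; the decomposition conserves spikes
(isolated + in-burst = total).  Burst duration is last-spike minus
first-spike time — the only definition available from spike times alone
— and intra-burst frequency is `(n_spikes − 1)/duration`, the rate of
intervals, which avoids the +1 bias of counting spikes.  Per cell and
epoch the pipeline reports spikes/s and bursts/s over the effective
epoch duration (optionally discarding `equilibration_discard_s` after
each solution switch, default 0), with a burst assigned to the epoch of
its first spike.  Cells with zero spikes keep rate 0 and are retained in
group averages; their burst-shape metrics are flagged undefined rather
than zero.  When a condition recurs in a protocol, each epoch is
summarized separately (pooling is left to the caller).

### Inference

Cells from one animal are correlated (pseudoreplication), so genotype
comparisons use a Gaussian linear mixed model with a random intercept
per animal, `metric ~ genotype + (1 | animal)`, fitted by **maximum
likelihood** — not REML, because the likelihood-ratio test compares
models with different fixed effects and REML log-likelihoods are not
comparable across such pairs.  The LRT statistic `2Δℓ` (clipped at 0) is
referred to χ² with df = fixed-parameter difference, upper tail.  The
fit is delegated to statsmodels MixedLM; on a fixed simulated dataset
the resulting χ² and p agree with lme4's `anova(lmer(REML=FALSE))` to
six decimals.  Several random factors (the telemetry blood-pressure
design uses animal and time-of-day) are fitted as independent variance
components on a single group, i.e. crossed random intercepts.

Two caveats are measured rather than hidden.  First, with 16 animals the
asymptotic χ²(1) reference is anticonservative for a between-animal
fixed effect: over 1000 null simulations from the generator the LRT
rejects at ≈ 0.08 instead of 0.05 (the effective degrees of freedom are
≈ 14, and `P(|t₁₄| > 1.96) ≈ 0.07`).  This is a property of the
procedure itself — lme4 produces identical statistics — and is far
smaller than the error of ignoring the hierarchy: pooled OLS rejects at
≈ 0.42 on the same nulls.  Second, boundary-corrected p-values for
comparing random-effect structures (e.g. adding a slice intercept) are
not implemented; such comparisons are exploratory.

Conditions in which the response is identically zero in both genotypes
(e.g. no-AT-II epochs with essentially no spikes) are flagged "not
tested" instead of fitted.

The phenotype formulas: relative expression per animal is
`ΔCt = Ct_target − Ct_housekeeping`, `ΔΔCt = ΔCt − mean(ΔCt_reference)`,
fold change `2^(−ΔΔCt)` — the sign convention makes higher expression
give fold change > 1 and forces the reference group's geometric mean to
exactly 1.  ARR is the per-animal `aldosterone / PRC` ratio
(pg ml⁻¹ per ng ml⁻¹ h⁻¹); group ARR is the mean of per-animal ratios,
never the ratio of group means.

## The synthetic generator

The generator emulates the study design: 2 genotypes × 8 animals ×
1 slice × 15 cells by default, 10 Hz sampling, and a stepped protocol at
3 mM [K⁺] with 300 s epochs of 0 / 20 / 1000 pM AT-II.  Per cell, burst
onsets and isolated spikes are independent Poisson processes whose rates
depend on the epoch condition and are multiplied by the genotype factor
(default 2 for the mutant) and a per-animal lognormal random effect
(log-rate SD 0.3) — both processes share the modifiers, since the
phenotype being modelled is an overall gain in excitability and the
downstream model fits a single animal intercept.  Default condition
rates were chosen so that wild-type mean spike rates land in the
experimentally observed range (~0.004 s⁻¹ at 20 pM, ~0.13 s⁻¹ at 1 nM
AT-II for 3 mM [K⁺]) given the default burst size law
(3 + Poisson(3), mean 6 spikes) and intra-burst exponential intervals of
mean 0.5 s, censored into `[frame_interval, 0.99 × 4 s]` so every
generated burst satisfies the burst rule by construction.

Events are placed with a 4 s refractory margin after the last emitted
spike (candidates closer than that are dropped, and a burst truncated by
the recording end below 3 spikes is dropped entirely).  This guarantees
that segmenting the *true* spike train recovers the *true* burst
decomposition exactly — the property that makes the generator usable as
an oracle — at the cost of a dead-time bias: realized event rates fall
below nominal by roughly a factor `1/(1 + λ_events · D)` with D ≈ burst
length + 4 s.  At the default rates this is a few percent; calibration
checks are run in the sparse regime (≤ 0.01 events/s) where the bias is
well inside 3 Monte-Carlo SEs.  Rate-recovery "truths" for the mixed
model are therefore taken from a large Monte-Carlo cohort at the same
configuration rather than from the nominal rates.

Traces are rendered as
`F(t) = F₀·e^(−t/τ_bleach) + Σ A·e^(−(t−t_s)/τ_decay)·1[t ≥ t_s] + ε`,
with i.i.d. Gaussian noise ε — an instantaneous one-frame rise with
single-exponential decay (defaults: F₀ = 500, τ_bleach = 600 s, A = 50,
τ_decay = 1 s, noise SD 5).  What the generator does **not** model:
photon-shot (intensity-dependent) noise, optical blur, slice motion,
perfusion transients, cell-to-cell kinetic differences, or baseline
drift beyond single-exponential bleaching.  Passing tests on synthetic
data therefore demonstrate the correctness of the algorithms under the
stated signal model, not robustness to every artifact of real
recordings; the artifact-suppression and equilibration-discard options
exist precisely because real data deviate from this model.

Image stacks paint each cell's noiseless trace onto a disk over a
constant background with an integer label mask, exercising ROI
mean-intensity extraction end to end (the round trip is exact to machine
precision by construction).

Phenotype tables draw per-animal Ct values from normal distributions and
hormone concentrations from lognormals (concentration data are positive
and right-skewed); the default mutant group shifts target Ct by −1
(≈ 2-fold expression) and aldosterone by +50 % at unchanged renin.

All randomness flows from a single integer seed through independent
numpy Generator streams for spike trains, trace noise and phenotypes;
identical configurations and seeds reproduce outputs bit-exactly.

## Problem sizes used in validation

The test suite exercises detrending against a windowed-minimum reference
on 1000 × 2000-frame traces, burst segmentation against a brute-force
grouper on 10,000 fuzzed trains, detection on ~2500 planted spikes,
calibration on 10⁴ s single-cell runs, the null LRT on 1000 simulated
cohorts and power/recovery on 100 cohorts of 8 vs 8 animals — sizes at
which Monte-Carlo error is small relative to the tested tolerances while
the whole suite completes in a few minutes.
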