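# zgcalcium

Analysis pipeline for calcium-imaging recordings of adrenal **zona
glomerulosa (ZG)** cells in acute slice preparations, and a matched
synthetic-data generator for validating every stage of it.

ZG cells control aldosterone synthesis through intracellular calcium
signalling: under angiotensin II (AT-II) and elevated extracellular
potassium they fire calcium spikes, singly or in temporally clustered
bursts.  Comparing this activity between genotypes (e.g. a
gain-of-function chloride-channel mutant versus wild type) requires
(1) robust spike detection on bleaching, noisy fluorescence traces,
(2) a reproducible burst definition, and (3) statistics that respect the
nested animal → slice → cell design — cells from one animal are not
independent replicates.

## What the pipeline computes

1. **Detrending** — the baseline (photobleaching decay plus slow drift)
   is removed by subtracting the minimum within a trailing rolling window
   of 50 frames (5 s at the 10 Hz frame rate):
   `F̃ᵢ = Fᵢ − min(F over the 50 frames ending at i)`.
2. **Spike detection** — the frame-to-frame difference `ΔF̃ᵢ = F̃ᵢ₊₁ − F̃ᵢ`
   registers a spike wherever it exceeds a threshold; runs of
   supra-threshold frames collapse to the onset frame.  The threshold is
   either set manually or estimated as `k · 1.4826 · MAD(ΔF̃)` (default
   `k = 5`), a robust estimate of k standard deviations of the background
   noise.
3. **Burst segmentation** — a burst is a cluster of **≥ 3 spikes** whose
   internal quiescent gaps are all **< 4 s**; smaller clusters count as
   isolated spikes.  Per cell and perfusion epoch the pipeline reports
   spikes/s, bursts/s, mean burst duration and mean intra-burst
   frequency.
4. **Inference** — per condition ([K⁺], [AT-II]), a Gaussian linear mixed
   model `metric ~ genotype + (1 | animal)` is fitted by maximum
   likelihood and the genotype effect is tested with a likelihood-ratio
   test: `χ² = 2(ℓ_full − ℓ_reduced)` against `χ²₁`.  Also included:
   relative gene expression as `2^(−ΔΔCt)` fold change and per-animal
   aldosterone:renin ratios (ARR).

The synthetic generator simulates the whole study — burst-structured
Poisson spike trains whose rates depend on condition and genotype, a
lognormal per-animal random effect, fluorescence rendering with
exponential bleaching and spike decay kernels, optional TIFF image
stacks with ROI label masks, and per-animal phenotype tables — so every
stage can be checked against known ground truth.

## Worked example

```python
from zgcalcium import (SimConfig, simulate_spike_trains, render_traces,
                       detect_spikes, summarize_cells, compare_conditions)

config = SimConfig(seed=7)           # 8 animals/genotype, 15 cells each
trains, truth = simulate_spike_trains(config)
traces = render_traces(truth, config)
detected = detect_spikes(traces)
summary = summarize_cells(detected, config.protocol)
report = compare_conditions(summary, metric="spikes_per_s")
print(report[["condition", "mean_WT", "mean_MUT", "chi2", "p_value"]].round(4))
```

prints

```
     condition  mean_WT  mean_MUT    chi2  p_value
0     K3_ATII0   0.0004    0.0007  0.8951   0.3441
1    K3_ATII20   0.0034    0.0048  3.8134   0.0508
2  K3_ATII1000   0.0739    0.1158  8.1710   0.0043
```

Reading: under 1 nM AT-II the mutant cells fire ~0.12 spikes s⁻¹ cell⁻¹
versus ~0.07 in wild type, and the mixed-model LRT puts χ²(1) ≈ 8.2,
p ≈ 0.004 on the genotype effect, while the near-silent no-AT-II epoch
shows none.  (Detected rates sit below the generator's configured rates
because spikes inside bursts closer than the 0.3 s refractory period
merge — see `docs/methods.md`.)

A CLI covers the same flow:
`zgcalcium run-all --seed 1 --out runs/demo` writes traces, spike,
burst, summary and statistics tables.

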