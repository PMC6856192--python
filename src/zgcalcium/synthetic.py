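"""Synthetic zona glomerulosa recordings with known ground truth.

The generator emulates calcium-imaging recordings of acute adrenal slice
preparations: cells fire calcium spikes either in isolation or in bursts,
at rates that depend on the bath condition ([K+] in mM, [AT-II] in pM)
and on genotype, with a nested animal -> slice -> cell hierarchy and a
per-animal lognormal random effect on rates.  Spike trains are rendered
into fluorescence traces as instantaneous rises with single-exponential
decay, superposed on an exponentially bleaching baseline plus i.i.d.
Gaussian noise — the signal model the detector is built for.

Event model, per cell:

* burst onsets: Poisson process with rate
  ``burst_initiation_rate_per_s[condition] * genotype_multiplier * exp(u_animal)``;
* isolated spikes: independent Poisson process with the corresponding
  isolated rate under the same multiplicative modifiers;
* each burst carries ``spikes_per_burst_law`` spikes (support >= 3)
  separated by exponential intra-burst intervals whose mean is well
  below the 4 s burst-quiescence gap, censored into
  ``[frame_interval_s, 0.99 * burst_gap_s]`` so every generated burst
  satisfies the burst rule by construction;
* events are placed with a ``burst_gap_s`` refractory margin so that
  ground-truth bursts are exactly recoverable by segmentation.  This
  thinning biases realized rates slightly below nominal when activity is
  high (dead time per burst approx. burst length + 4 s).

All randomness flows from ``SimConfig.seed`` (numpy Generator); the same
config and seed reproduce every output bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bursts import BurstParams, segment_bursts
from .detection import SpikeTrain
from .io import HIERARCHY_COLUMNS, PerfusionProtocol, TraceMatrix

__all__ = [
    "SpikesPerBurstLaw",
    "SimConfig",
    "GroundTruth",
    "default_protocol",
    "simulate_spike_trains",
    "render_traces",
    "render_image_stack",
    "simulate_phenotypes",
    "default_phenotype_effects",
]

Condition = tuple[float, float]  # (potassium_mM, atii_pM)


@dataclass(frozen=True)
class SpikesPerBurstLaw:
    """Shifted-Poisson burst size: ``minimum + Poisson(mean_extra)``.

    The minimum (default 3) keeps every generated burst a burst under the
    ">= 3 spikes" rule; mean_extra tunes the mean burst size
    (default mean 3 + 3 = 6 spikes).
    """

    minimum: int = 3
    mean_extra: float = 3.0

    def __post_init__(self):
        if self.minimum < 3:
            raise ValueError("burst size support must be >= 3")
        if self.mean_extra < 0:
            raise ValueError("mean_extra must be >= 0")

    @property
    def mean(self) -> float:
        return self.minimum + self.mean_extra

    def sample(self, rng: np.random.Generator, size=None):
        return self.minimum + rng.poisson(self.mean_extra, size=size)


def default_protocol() -> PerfusionProtocol:
    """Three-step AT-II protocol at 3 mM [K+]: none / 20 pM / 1 nM.

    Mirrors the stepped-perfusion design of the slice recordings: a
    baseline epoch without AT-II, a near-physiological 20 pM step and a
    supraphysiological 1 nM step, 300 s each.
    """
    return PerfusionProtocol(
        pd.DataFrame(
            {
                "start_s": [0.0, 300.0, 600.0],
                "end_s": [300.0, 600.0, 900.0],
                "potassium_mM": [3.0, 3.0, 3.0],
                "atii_pM": [0.0, 20.0, 1000.0],
            }
        )
    )


def _default_isolated_rates() -> dict[Condition, float]:
    # chosen so wild-type mean spike rates land near the observed
    # per-condition means (~0.004 /s at 3K/20pM, ~0.125 /s at 3K/1nM,
    # ~0.18 /s at 5K/1nM) given a mean burst size of 6
    return {
        (3.0, 0.0): 0.0002,
        (3.0, 20.0): 0.001,
        (3.0, 1000.0): 0.02,
        (5.0, 0.0): 0.0005,
        (5.0, 20.0): 0.002,
        (5.0, 1000.0): 0.03,
    }


def _default_burst_rates() -> dict[Condition, float]:
    return {
        (3.0, 0.0): 0.00005,
        (3.0, 20.0): 0.0005,
        (3.0, 1000.0): 0.018,
        (5.0, 0.0): 0.0001,
        (5.0, 20.0): 0.001,
        (5.0, 1000.0): 0.025,
    }


@dataclass
class SimConfig:
    """Study-design and signal parameters of the simulator.

    Defaults follow the slice-imaging design: 8 animals per genotype,
    10 Hz sampling, a stepped AT-II protocol, and condition-dependent
    rates tuned to the observed wild-type activity range; the mutant
    genotype doubles event-initiation rates.
    """

    n_animals_per_genotype: int = 8
    slices_per_animal: int = 1
    cells_per_slice: int = 15
    frame_interval_s: float = 0.1
    protocol: PerfusionProtocol = field(default_factory=default_protocol)
    baseline_f0: float = 500.0
    bleach_tau_s: float = 600.0          # np.inf disables bleaching
    spike_amplitude: float = 50.0
    spike_decay_tau_s: float = 1.0
    noise_sd: float = 5.0
    isolated_spike_rate_per_s: dict[Condition, float] = field(
        default_factory=_default_isolated_rates
    )
    burst_initiation_rate_per_s: dict[Condition, float] = field(
        default_factory=_default_burst_rates
    )
    genotype_rate_multiplier: float = 2.0
    intra_burst_isi_s: float = 0.5
    spikes_per_burst_law: SpikesPerBurstLaw = field(default_factory=SpikesPerBurstLaw)
    animal_random_effect_sd: float = 0.3  # SD of per-animal log-rate offsets
    burst_gap_s: float = 4.0              # quiescence gap defining bursts downstream
    genotypes: tuple[str, str] = ("WT", "MUT")
    seed: int = 0

    def __post_init__(self):
        if self.n_animals_per_genotype < 1 or self.slices_per_animal < 1 or self.cells_per_slice < 1:
            raise ValueError("hierarchy counts must be >= 1")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.baseline_f0 <= 0 or self.spike_amplitude <= 0 or self.spike_decay_tau_s <= 0:
            raise ValueError("signal parameters must be > 0")
        if self.bleach_tau_s <= 0:
            raise ValueError("bleach_tau_s must be > 0 (use np.inf for no bleaching)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.genotype_rate_multiplier <= 0:
            raise ValueError("genotype_rate_multiplier must be > 0")
        if self.animal_random_effect_sd < 0:
            raise ValueError("animal_random_effect_sd must be >= 0")
        for name, rates in (
            ("isolated_spike_rate_per_s", self.isolated_spike_rate_per_s),
            ("burst_initiation_rate_per_s", self.burst_initiation_rate_per_s),
        ):
            if any(r < 0 for r in rates.values()):
                raise ValueError(f"{name} has a negative rate")
        if not self.intra_burst_isi_s > 0:
            raise ValueError("intra_burst_isi_s must be > 0")
        if not self.intra_burst_isi_s < self.burst_gap_s:
            raise ValueError(
                "mean intra-burst ISI must be below the burst quiescence gap, "
                f"got {self.intra_burst_isi_s} >= {self.burst_gap_s}"
            )
        for i in range(self.protocol.n_epochs):
            cond = self.protocol.condition(i)
            for name, rates in (
                ("isolated_spike_rate_per_s", self.isolated_spike_rate_per_s),
                ("burst_initiation_rate_per_s", self.burst_initiation_rate_per_s),
            ):
                if cond not in rates:
                    raise ValueError(f"{name} has no entry for protocol condition {cond}")

    @property
    def duration_s(self) -> float:
        return self.protocol.end_s

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s / self.frame_interval_s))


@dataclass
class GroundTruth:
    """True event structure behind a simulated cohort (the oracle)."""

    spike_times: dict[str, np.ndarray]              # cell_id -> sorted times (s)
    bursts: dict[str, list[tuple[float, float, int]]]  # cell_id -> (start, end, n)
    animal_effects: dict[str, float]                # animal_id -> log-rate offset
    hierarchy: pd.DataFrame                         # indexed by cell_id

    def n_spikes(self, cell_id: str) -> int:
        return len(self.spike_times[cell_id])

    def total_spikes(self) -> int:
        return sum(len(v) for v in self.spike_times.values())

    def total_bursts(self) -> int:
        return sum(len(v) for v in self.bursts.values())


# ---------------------------------------------------------------------------
# spike-train simulation
# ---------------------------------------------------------------------------

def _poisson_times(rng, rate, start, end):
    if rate <= 0:
        return np.empty(0)
    n = rng.poisson(rate * (end - start))
    return np.sort(rng.uniform(start, end, size=n))


def _simulate_cell(rng, config: SimConfig, rate_factor: float):
    """One cell's spike times and bursts.

    Candidate burst onsets and isolated spikes are drawn per epoch as
    Poisson processes, then swept in time order with a ``burst_gap_s``
    refractory margin after the last emitted spike, so that the emitted
    event decomposition is exactly what burst segmentation recovers.
    """
    proto = config.protocol
    events = []  # (time, kind)
    for i in range(proto.n_epochs):
        row = proto.epochs.iloc[i]
        start, end = float(row["start_s"]), float(row["end_s"])
        cond = proto.condition(i)
        rb = config.burst_initiation_rate_per_s[cond] * rate_factor
        ri = config.isolated_spike_rate_per_s[cond] * rate_factor
        events.extend((t, "burst") for t in _poisson_times(rng, rb, start, end))
        events.extend((t, "iso") for t in _poisson_times(rng, ri, start, end))
    events.sort()

    duration = config.duration_s
    gap = config.burst_gap_s
    max_isi = 0.99 * gap
    spikes: list[float] = []
    bursts: list[tuple[float, float, int]] = []
    last = -np.inf
    for t0, kind in events:
        if t0 < last + gap:
            continue  # refractory margin keeps events separable
        if kind == "iso":
            if t0 < duration:
                spikes.append(t0)
                last = t0
        else:
            n = int(config.spikes_per_burst_law.sample(rng))
            isis = rng.exponential(config.intra_burst_isi_s, size=n - 1)
            isis = np.clip(isis, config.frame_interval_s, max_isi)
            times = t0 + np.concatenate(([0.0], np.cumsum(isis)))
            times = times[times < duration]
            if times.size < config.spikes_per_burst_law.minimum:
                continue  # burst truncated by recording end; drop entirely
            spikes.extend(times)
            bursts.append((float(times[0]), float(times[-1]), int(times.size)))
            last = float(times[-1])
    return np.asarray(spikes), bursts


def simulate_spike_trains(config: SimConfig) -> tuple[list[SpikeTrain], GroundTruth]:
    """Simulate the full cohort's spike trains and their ground truth."""
    rng = np.random.default_rng([int(config.seed), 0])
    mult = {config.genotypes[0]: 1.0, config.genotypes[1]: config.genotype_rate_multiplier}
    trains: list[SpikeTrain] = []
    spike_times: dict[str, np.ndarray] = {}
    burst_map: dict[str, list[tuple[float, float, int]]] = {}
    animal_effects: dict[str, float] = {}
    hier_rows = []
    for genotype in config.genotypes:
        for a in range(config.n_animals_per_genotype):
            animal_id = f"{genotype}_A{a:02d}"
            u = float(rng.normal(0.0, config.animal_random_effect_sd))
            animal_effects[animal_id] = u
            sex = "M" if a % 2 == 0 else "F"
            for s in range(config.slices_per_animal):
                slice_id = f"{animal_id}_S{s:02d}"
                for c in range(config.cells_per_slice):
                    cell_id = f"{slice_id}_C{c:03d}"
                    factor = mult[genotype] * np.exp(u)
                    times, bursts = _simulate_cell(rng, config, factor)
                    spike_times[cell_id] = times
                    burst_map[cell_id] = bursts
                    hier_rows.append(
                        {
                            "cell_id": cell_id,
                            "animal_id": animal_id,
                            "slice_id": slice_id,
                            "genotype": genotype,
                            "sex": sex,
                        }
                    )
                    trains.append(
                        SpikeTrain(cell_id, times, animal_id, slice_id, genotype, sex)
                    )
    hierarchy = pd.DataFrame(hier_rows).set_index("cell_id")
    truth = GroundTruth(spike_times, burst_map, animal_effects, hierarchy)
    return trains, truth


# ---------------------------------------------------------------------------
# trace and image rendering
# ---------------------------------------------------------------------------

def _noiseless_trace(times_grid, spike_times, config: SimConfig):
    if np.isfinite(config.bleach_tau_s):
        f = config.baseline_f0 * np.exp(-times_grid / config.bleach_tau_s)
    else:
        f = np.full_like(times_grid, config.baseline_f0)
    for ts in spike_times:
        i0 = int(np.ceil(ts / config.frame_interval_s - 1e-9))
        if i0 >= times_grid.size:
            continue
        f[i0:] += config.spike_amplitude * np.exp(
            -(times_grid[i0:] - ts) / config.spike_decay_tau_s
        )
    return f


def render_traces(truth: GroundTruth, config: SimConfig) -> TraceMatrix:
    """Render ground-truth spike trains into noisy fluorescence traces.

    F(t) = baseline_f0 * exp(-t / bleach_tau_s)
           + sum over spikes of spike_amplitude * exp(-(t - t_spike)/spike_decay_tau_s)
             for t >= t_spike,
    sampled every ``frame_interval_s``, plus i.i.d. N(0, noise_sd^2).
    """
    if config.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng([int(config.seed), 1])
    grid = np.arange(config.n_frames) * config.frame_interval_s
    cell_ids = list(truth.hierarchy.index)
    values = np.empty((len(cell_ids), grid.size))
    for i, cid in enumerate(cell_ids):
        ts = truth.spike_times[cid]
        if ts.size and (ts.min() < 0 or ts.max() >= config.duration_s):
            raise ValueError(f"spike times outside [0, duration) for cell {cid}")
        f = _noiseless_trace(grid, ts, config)
        if config.noise_sd > 0:
            f = f + rng.normal(0.0, config.noise_sd, size=f.size)
        values[i] = f
    return TraceMatrix(cell_ids, values, config.frame_interval_s, truth.hierarchy)


def render_image_stack(
    truth: GroundTruth,
    config: SimConfig,
    geometry: list[tuple[float, float, float]],
    frame_shape: tuple[int, int] = (64, 64),
    background: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paint noiseless traces onto disks, returning (stack, label mask).

    ``geometry`` lists one ``(row, col, radius)`` disk per cell, in the
    cell order of ``truth.hierarchy``; disks must lie inside the frame
    and not overlap.  Label ``i+1`` marks cell ``i``; 0 is background.
    """
    cell_ids = list(truth.hierarchy.index)
    if len(geometry) != len(cell_ids):
        raise ValueError(f"{len(geometry)} disks for {len(cell_ids)} cells")
    h, w = frame_shape
    mask = np.zeros((h, w), dtype=np.int32)
    rr, cc = np.mgrid[0:h, 0:w]
    for i, (r, c, rad) in enumerate(geometry):
        if r - rad < -0.5 or c - rad < -0.5 or r + rad > h - 0.5 or c + rad > w - 0.5:
            raise ValueError(f"disk {i} exceeds the frame bounds")
        disk = (rr - r) ** 2 + (cc - c) ** 2 <= rad**2
        if not disk.any():
            raise ValueError(f"disk {i} covers no pixels")
        if (mask[disk] != 0).any():
            raise ValueError(f"disk {i} overlaps another cell")
        mask[disk] = i + 1
    grid = np.arange(config.n_frames) * config.frame_interval_s
    stack = np.full((config.n_frames, h, w), float(background))
    for i, cid in enumerate(cell_ids):
        f = _noiseless_trace(grid, truth.spike_times[cid], config)
        stack[:, mask == i + 1] = f[:, None]
    return stack, mask


# ---------------------------------------------------------------------------
# phenotype tables
# ---------------------------------------------------------------------------

def default_phenotype_effects() -> dict[str, dict[str, float]]:
    """Group-level generative parameters for the phenotype table.

    Ct values are normal per gene; hormone concentrations are lognormal
    (concentration data are right-skewed and positive).  The mutant group
    shifts target Ct down by 1 cycle (about 2-fold higher expression of
    the aldosterone-synthase target) and raises aldosterone by about
    50% at unchanged renin, the direction of a primary-aldosteronism
    phenotype.
    """
    wt = {
        "ct_target_mean": 24.0, "ct_target_sd": 0.5,
        "ct_housekeeping_mean": 18.0, "ct_housekeeping_sd": 0.3,
        "aldo_log_mean": np.log(300.0), "aldo_log_sd": 0.3,   # pg/ml
        "prc_log_mean": np.log(1500.0), "prc_log_sd": 0.3,    # ng/ml/h
    }
    mut = dict(wt)
    mut["ct_target_mean"] = 23.0
    mut["aldo_log_mean"] = np.log(450.0)
    return {"WT": wt, "MUT": mut}


def simulate_phenotypes(
    n_per_group: int,
    effects: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-animal phenotype table: Ct pairs, aldosterone, PRC.

    Columns: animal_id, genotype, sex, ct_target, ct_housekeeping,
    aldosterone (pg/ml), prc (ng/ml/h).
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    effects = effects or default_phenotype_effects()
    for g, e in effects.items():
        for k, v in e.items():
            if k.endswith("_sd") and v < 0:
                raise ValueError(f"{g}.{k} must be >= 0")
    rng = np.random.default_rng([int(seed), 2])
    rows = []
    for genotype, e in effects.items():
        for i in range(n_per_group):
            rows.append(
                {
                    "animal_id": f"{genotype}_P{i:02d}",
                    "genotype": genotype,
                    "sex": "M" if i % 2 == 0 else "F",
                    "ct_target": rng.normal(e["ct_target_mean"], e["ct_target_sd"]),
                    "ct_housekeeping": rng.normal(
                        e["ct_housekeeping_mean"], e["ct_housekeeping_sd"]
                    ),
                    "aldosterone": float(
                        np.exp(rng.normal(e["aldo_log_mean"], e["aldo_log_sd"]))
                    ),
                    "prc": float(np.exp(rng.normal(e["prc_log_mean"], e["prc_log_sd"]))),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ground-truth export
# ---------------------------------------------------------------------------

def ground_truth_tables(truth: GroundTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ground truth as (spike table, burst table) DataFrames for export."""
    spike_rows = [
        {"cell_id": cid, "spike_time_s": t}
        for cid, times in truth.spike_times.items()
        for t in times
    ]
    burst_rows = [
        {"cell_id": cid, "start_s": s, "end_s": e, "n_spikes": n}
        for cid, bursts in truth.bursts.items()
        for (s, e, n) in bursts
    ]
    return (
        pd.DataFrame(spike_rows, columns=["cell_id", "spike_time_s"]),
        pd.DataFrame(burst_rows, columns=["cell_id", "start_s", "end_s", "n_spikes"]),
    )
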