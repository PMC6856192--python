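"""Interspike intervals, burst segmentation and per-cell activity summaries.

A burst is a cluster of at least ``min_spikes`` (default 3) spikes in
which every internal quiescent gap is strictly shorter than ``max_gap_s``
(default 4 s).  Spikes in clusters smaller than ``min_spikes`` count as
isolated.  Segmentation is a greedy scan over the sorted train: a gap
>= ``max_gap_s`` closes the current cluster.  The decomposition conserves
spikes: isolated + in-burst = total.

Per-cell activity is summarized per perfusion epoch: spikes/s, bursts/s
(counts over the effective epoch duration), mean burst duration
(last-spike minus first-spike time) and mean intra-burst frequency
((n_spikes - 1) / duration, the rate of intervals).  Spikes belong to the
epoch containing them (half-open membership); a burst belongs to the
epoch containing its first spike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import SpikeTrain
from .io import PerfusionProtocol

__all__ = [
    "BurstParams",
    "Burst",
    "BurstSet",
    "interspike_intervals",
    "isi_distribution",
    "segment_bursts",
    "summarize_cell_epoch",
    "summarize_cells",
    "burst_table",
]


@dataclass(frozen=True)
class BurstParams:
    min_spikes: int = 3
    max_gap_s: float = 4.0

    def __post_init__(self):
        if self.min_spikes < 2:
            raise ValueError(f"min_spikes must be >= 2, got {self.min_spikes}")
        if self.max_gap_s <= 0:
            raise ValueError(f"max_gap_s must be > 0, got {self.max_gap_s}")


@dataclass(frozen=True)
class Burst:
    start_s: float
    end_s: float
    n_spikes: int

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def intra_burst_freq(self) -> float:
        """Interval rate inside the burst: (n_spikes - 1) / duration."""
        return (self.n_spikes - 1) / self.duration_s


@dataclass
class BurstSet:
    """Burst decomposition of one cell's spike train."""

    cell_id: str
    bursts: list[Burst]
    isolated_spike_times_s: np.ndarray

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    @property
    def total_spikes(self) -> int:
        return len(self.isolated_spike_times_s) + sum(b.n_spikes for b in self.bursts)


def interspike_intervals(train: SpikeTrain) -> np.ndarray:
    """Intervals between successive spikes (n-1 values; empty for n <= 1)."""
    t = np.asarray(train.spike_times_s, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"spike train {train.cell_id} is not strictly increasing")
    return np.diff(t)


def isi_distribution(trains: list[SpikeTrain], bin_width_s: float) -> pd.DataFrame:
    """Pooled ISI histogram over all supplied trains.

    Half-open bins ``[k*w, (k+1)*w)``; total count equals the number of
    intervals, sum over trains of max(n_i - 1, 0).
    """
    if bin_width_s <= 0:
        raise ValueError(f"bin_width_s must be > 0, got {bin_width_s}")
    isis = [interspike_intervals(t) for t in trains]
    pooled = np.concatenate(isis) if isis else np.empty(0)
    if pooled.size == 0:
        return pd.DataFrame(columns=["bin_left_s", "bin_right_s", "count"])
    n_bins = int(np.floor(pooled.max() / bin_width_s)) + 1
    idx = np.floor(pooled / bin_width_s).astype(int)
    counts = np.bincount(idx, minlength=n_bins)
    return pd.DataFrame(
        {
            "bin_left_s": np.arange(n_bins) * bin_width_s,
            "bin_right_s": (np.arange(n_bins) + 1) * bin_width_s,
            "count": counts,
        }
    )


def segment_bursts(train: SpikeTrain, params: BurstParams | None = None) -> BurstSet:
    """Split a spike train into bursts and isolated spikes.

    Consecutive spikes with gaps strictly below ``max_gap_s`` form a
    cluster; clusters of >= ``min_spikes`` spikes become bursts (start at
    the first spike, end at the last), smaller clusters contribute
    isolated spikes.
    """
    params = params or BurstParams()
    t = np.asarray(train.spike_times_s, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"spike train {train.cell_id} is not strictly increasing")
    bursts: list[Burst] = []
    isolated: list[float] = []
    if t.size:
        # indices where a new cluster starts (gap >= max_gap_s splits)
        splits = np.flatnonzero(np.diff(t) >= params.max_gap_s) + 1
        for cluster in np.split(t, splits):
            if cluster.size >= params.min_spikes:
                bursts.append(Burst(float(cluster[0]), float(cluster[-1]), int(cluster.size)))
            else:
                isolated.extend(float(x) for x in cluster)
    return BurstSet(train.cell_id, bursts, np.asarray(isolated))


def summarize_cell_epoch(
    train: SpikeTrain,
    burst_set: BurstSet,
    protocol: PerfusionProtocol,
    epoch_index: int,
) -> dict:
    """Activity metrics for one cell in one perfusion epoch.

    Rates are counts divided by the effective epoch duration (after any
    equilibration discard).  Cells with no spikes in the epoch get rate 0
    and NaN burst-shape metrics with ``burst_metrics_defined = False``.
    """
    start, end = protocol.effective_window(epoch_index)
    duration = end - start
    if duration <= 0:
        raise ValueError(f"epoch {epoch_index} has zero effective duration")
    t = train.spike_times_s
    in_epoch = (t >= start) & (t < end)
    n_spikes = int(in_epoch.sum())
    epoch_bursts = [b for b in burst_set.bursts if start <= b.start_s < end]
    n_bursts = len(epoch_bursts)
    k, a = protocol.condition(epoch_index)
    out = {
        "cell_id": train.cell_id,
        "animal_id": train.animal_id,
        "slice_id": train.slice_id,
        "genotype": train.genotype,
        "sex": train.sex,
        "epoch_index": epoch_index,
        "potassium_mM": k,
        "atii_pM": a,
        "condition": protocol.condition_label(epoch_index),
        "epoch_duration_s": duration,
        "n_spikes": n_spikes,
        "n_bursts": n_bursts,
        "spikes_per_s": n_spikes / duration,
        "bursts_per_s": n_bursts / duration,
    }
    if n_bursts:
        out["mean_burst_duration_s"] = float(np.mean([b.duration_s for b in epoch_bursts]))
        out["mean_intra_burst_freq"] = float(np.mean([b.intra_burst_freq for b in epoch_bursts]))
        out["burst_metrics_defined"] = True
    else:
        out["mean_burst_duration_s"] = np.nan
        out["mean_intra_burst_freq"] = np.nan
        out["burst_metrics_defined"] = False
    return out


def summarize_cells(
    trains: list[SpikeTrain],
    protocol: PerfusionProtocol,
    params: BurstParams | None = None,
) -> pd.DataFrame:
    """One row per cell x epoch with all activity metrics."""
    params = params or BurstParams()
    rows = []
    for train in trains:
        bs = segment_bursts(train, params)
        for e in range(protocol.n_epochs):
            rows.append(summarize_cell_epoch(train, bs, protocol, e))
    return pd.DataFrame(rows)


def burst_table(
    burst_sets: list[BurstSet], protocol: PerfusionProtocol | None = None
) -> pd.DataFrame:
    """Long burst table: one row per burst, with epoch labels if given."""
    rows = []
    for bs in burst_sets:
        for i, b in enumerate(bs.bursts):
            row = {
                "cell_id": bs.cell_id,
                "burst_index": i,
                "start_s": b.start_s,
                "end_s": b.end_s,
                "n_spikes": b.n_spikes,
            }
            if protocol is not None:
                idx = protocol.epoch_of(b.start_s)
                row["epoch_index"] = idx
                row["condition"] = protocol.condition_label(idx) if idx is not None else ""
            rows.append(row)
    cols = ["cell_id", "burst_index", "start_s", "end_s", "n_spikes"]
    if protocol is not None:
        cols += ["epoch_index", "condition"]
    return pd.DataFrame(rows, columns=cols)
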