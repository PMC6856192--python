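"""Spike detection on detrended fluorescence traces.

The detector mirrors the slice-imaging workflow: photobleaching decay and
slow baseline drift are removed by subtracting the minimum within a
trailing rolling window (50 frames = 5 s at 10 Hz by default), the
frame-to-frame difference of the detrended trace is computed, and frames
where that difference exceeds a threshold register a spike.  Runs of
consecutive supra-threshold frames collapse to the first frame of the run
(spike onset), and spikes closer than ``min_separation_s`` to the
previously accepted spike are merged into it.

The threshold is either a number (the manual-threshold workflow) or
``"auto"``: ``auto_k`` times a robust noise scale (1.4826 x the median
absolute deviation of the difference signal), which estimates the
standard deviation of the background fluctuations when spikes are sparse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io import TraceMatrix, PerfusionProtocol

logger = logging.getLogger("zgcalcium")

__all__ = [
    "DetectionParams",
    "SpikeTrain",
    "detrend",
    "frame_difference",
    "auto_threshold",
    "detect_spikes",
    "detect_spikes_trace",
    "suppress_artifacts",
    "filter_active_cells",
    "spike_table",
    "raster_table",
]


@dataclass(frozen=True)
class DetectionParams:
    """Tunable parameters of the spike detector.

    window_frames
        Length of the trailing rolling-minimum window (frames).
    threshold
        Spike-registration threshold on the frame difference of the
        detrended trace (a.u. per frame), or ``"auto"``.
    auto_k
        Multiplier on the robust noise SD for the automatic threshold.
    min_separation_s
        Minimum time between reported spikes; closer detections are
        merged into the earlier spike (guards against multi-frame rises
        double-counting).
    """

    window_frames: int = 50
    threshold: float | str = "auto"
    auto_k: float = 5.0
    min_separation_s: float = 0.3

    def __post_init__(self):
        if self.window_frames < 1:
            raise ValueError(f"window_frames must be >= 1, got {self.window_frames}")
        if isinstance(self.threshold, str):
            if self.threshold != "auto":
                raise ValueError(f"threshold must be numeric or 'auto', got {self.threshold!r}")
        elif self.threshold <= 0:
            raise ValueError(f"numeric threshold must be > 0, got {self.threshold}")
        if self.auto_k <= 0:
            raise ValueError("auto_k must be > 0")
        if self.min_separation_s < 0:
            raise ValueError("min_separation_s must be >= 0")


@dataclass
class SpikeTrain:
    """Ordered spike times for one cell, with its hierarchy labels."""

    cell_id: str
    spike_times_s: np.ndarray
    animal_id: str = "unassigned"
    slice_id: str = "unassigned"
    genotype: str = "unassigned"
    sex: str = "unassigned"

    def __post_init__(self):
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if self.spike_times_s.ndim != 1:
            raise ValueError("spike_times_s must be 1-D")
        if np.any(np.diff(self.spike_times_s) <= 0):
            raise ValueError(f"spike times not strictly increasing for cell {self.cell_id}")

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times_s)


# ---------------------------------------------------------------------------
# detrending and differencing
# ---------------------------------------------------------------------------

def detrend(trace: np.ndarray, window_frames: int = 50) -> np.ndarray:
    """Subtract the trailing rolling-window minimum from a trace.

    ``out[i] = trace[i] - min(trace[max(0, i-window_frames+1) : i+1])``.
    The window is causal (ends at the current frame) and shrinks at the
    start of the recording, so no future data leaks into the baseline
    estimate.  Output is everywhere >= 0 and invariant to adding a
    constant to the trace.
    """
    if window_frames < 1:
        raise ValueError(f"window_frames must be >= 1, got {window_frames}")
    trace = np.asarray(trace, dtype=float)
    if trace.size < 1:
        raise ValueError("trace must have at least one frame")
    rolling_min = (
        pd.Series(trace).rolling(window=window_frames, min_periods=1).min().to_numpy()
    )
    return trace - rolling_min


def frame_difference(trace: np.ndarray) -> np.ndarray:
    """Frame-to-frame change ``trace[i+1] - trace[i]`` (length n-1)."""
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2:
        raise ValueError("need at least two frames to difference")
    return np.diff(trace)


def auto_threshold(difference_signal: np.ndarray, auto_k: float = 5.0) -> float:
    """Automatic spike threshold: ``auto_k`` x robust SD of the differences.

    The robust SD is 1.4826 x the median absolute deviation, a consistent
    estimator of the Gaussian background sigma that is insensitive to the
    sparse large excursions caused by actual spikes.
    """
    d = np.asarray(difference_signal, dtype=float)
    if d.size == 0:
        raise ValueError("empty difference signal")
    sigma = stats.median_abs_deviation(d, scale="normal")
    if sigma == 0:
        raise ValueError(
            "zero-variance difference signal: no background noise level to estimate; "
            "set a numeric threshold instead"
        )
    return float(auto_k * sigma)


# ---------------------------------------------------------------------------
# spike registration
# ---------------------------------------------------------------------------

def _supra_frames(trace, params: DetectionParams) -> tuple[np.ndarray, float]:
    det = detrend(trace, params.window_frames)
    d = frame_difference(det)
    thr = params.threshold
    if thr == "auto":
        thr = auto_threshold(d, params.auto_k)
    supra = d > thr
    # difference index i refers to the rise into frame i+1
    return np.flatnonzero(supra) + 1, float(thr)


def _collapse(frames: np.ndarray, frame_interval_s: float, min_separation_s: float) -> np.ndarray:
    if frames.size == 0:
        return frames
    # runs of consecutive supra-threshold frames -> onset frame
    onsets = frames[np.concatenate(([True], np.diff(frames) > 1))]
    if min_separation_s <= 0:
        return onsets
    min_gap_frames = min_separation_s / frame_interval_s
    kept = [onsets[0]]
    for f in onsets[1:]:
        if f - kept[-1] >= min_gap_frames:
            kept.append(f)
    return np.asarray(kept)


def detect_spikes_trace(
    trace: np.ndarray, frame_interval_s: float, params: DetectionParams | None = None,
    cell_id: str = "cell",
) -> SpikeTrain:
    """Run the detector on a single trace and return its spike train."""
    params = params or DetectionParams()
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2:
        raise ValueError("trace too short for spike detection")
    frames, _ = _supra_frames(trace, params)
    frames = _collapse(frames, frame_interval_s, params.min_separation_s)
    return SpikeTrain(cell_id, frames * frame_interval_s)


def detect_spikes(tm: TraceMatrix, params: DetectionParams | None = None) -> list[SpikeTrain]:
    """Detect spikes in every cell of a trace matrix.

    With ``threshold="auto"`` the threshold is estimated per cell from
    that cell's own difference signal.
    """
    params = params or DetectionParams()
    trains = []
    for i, cid in enumerate(tm.cell_ids):
        frames, thr = _supra_frames(tm.values[i], params)
        frames = _collapse(frames, tm.frame_interval_s, params.min_separation_s)
        hier = tm.hierarchy.loc[str(cid)]
        trains.append(
            SpikeTrain(
                str(cid),
                frames * tm.frame_interval_s,
                animal_id=str(hier["animal_id"]),
                slice_id=str(hier["slice_id"]),
                genotype=str(hier["genotype"]),
                sex=str(hier["sex"]),
            )
        )
    total = sum(t.n_spikes for t in trains)
    logger.info("detected %d spikes in %d cells", total, len(trains))
    return trains


# ---------------------------------------------------------------------------
# artifact suppression and cell selection
# ---------------------------------------------------------------------------

def suppress_artifacts(
    trains: list[SpikeTrain],
    tm: TraceMatrix,
    fraction: float = 0.5,
) -> list[SpikeTrain]:
    """Remove globally coincident spikes (slice-motion / perfusion proxy).

    A frame whose spike is registered simultaneously in more than
    ``fraction`` of all cells carries a global motion signature rather
    than cellular activity; spikes at such frames are removed from every
    cell.  Removals are logged per cell.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if not trains:
        return []
    n_cells = len(trains)
    dt = tm.frame_interval_s
    frame_counts: dict[int, int] = {}
    for t in trains:
        for f in np.rint(t.spike_times_s / dt).astype(int):
            frame_counts[f] = frame_counts.get(f, 0) + 1
    bad_frames = {f for f, c in frame_counts.items() if c / n_cells > fraction}
    if not bad_frames:
        return trains
    logger.info("artifact suppression: flagged frames %s", sorted(bad_frames))
    out = []
    for t in trains:
        frames = np.rint(t.spike_times_s / dt).astype(int)
        keep = np.array([f not in bad_frames for f in frames], dtype=bool)
        removed = int((~keep).sum())
        if removed:
            logger.info("cell %s: removed %d artifact spike(s)", t.cell_id, removed)
        out.append(replace(t, spike_times_s=t.spike_times_s[keep]))
    return out


def filter_active_cells(
    trains: list[SpikeTrain],
    protocol: PerfusionProtocol,
    reference_atii_pM: float = 1000.0,
) -> tuple[list[SpikeTrain], list[str]]:
    """Keep cells with visible activity in the reference condition.

    Mirrors the selection rule that a cell must show at least one spike
    during high-[AT-II] perfusion (default 1 nM = 1000 pM).  Returns the
    retained trains and the list of excluded cell ids.
    """
    ref_epochs = protocol.epochs_matching(atii_pM=reference_atii_pM)
    if not ref_epochs:
        raise ValueError(
            f"no protocol epoch with atii_pM={reference_atii_pM} to use as reference"
        )
    windows = [
        (float(protocol.epochs["start_s"].iloc[i]), float(protocol.epochs["end_s"].iloc[i]))
        for i in ref_epochs
    ]
    kept, excluded = [], []
    for t in trains:
        active = any(
            np.any((t.spike_times_s >= s) & (t.spike_times_s < e)) for s, e in windows
        )
        if active:
            kept.append(t)
        else:
            excluded.append(t.cell_id)
    if excluded:
        logger.info("excluded %d inactive cell(s): %s", len(excluded), excluded)
    return kept, excluded


# ---------------------------------------------------------------------------
# export tables
# ---------------------------------------------------------------------------

def spike_table(trains: list[SpikeTrain], protocol: PerfusionProtocol | None = None) -> pd.DataFrame:
    """Long spike table (one row per spike) with hierarchy and epoch labels."""
    rows = []
    for t in trains:
        for ts in t.spike_times_s:
            row = {
                "cell_id": t.cell_id,
                "animal_id": t.animal_id,
                "slice_id": t.slice_id,
                "genotype": t.genotype,
                "sex": t.sex,
                "spike_time_s": ts,
            }
            if protocol is not None:
                idx = protocol.epoch_of(ts)
                row["epoch_index"] = idx
                row["condition"] = protocol.condition_label(idx) if idx is not None else ""
            rows.append(row)
    cols = ["cell_id", "animal_id", "slice_id", "genotype", "sex", "spike_time_s"]
    if protocol is not None:
        cols += ["epoch_index", "condition"]
    return pd.DataFrame(rows, columns=cols)


def raster_table(trains: list[SpikeTrain]) -> pd.DataFrame:
    """Burst-plot export: (cell row index, spike time) pairs."""
    rows = [
        {"cell_row": i, "cell_id": t.cell_id, "spike_time_s": ts}
        for i, t in enumerate(trains)
        for ts in t.spike_times_s
    ]
    return pd.DataFrame(rows, columns=["cell_row", "cell_id", "spike_time_s"])
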