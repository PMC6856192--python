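"""Readers, writers and containers for the formats the pipeline touches.

The pipeline's raw material is a set of uniformly sampled per-cell
fluorescence traces with a nested animal -> slice -> cell hierarchy
(:class:`TraceMatrix`), analysed relative to a timed sequence of bath
conditions (:class:`PerfusionProtocol`, [K+] in mM and [AT-II] in pM).
Traces can be read from delimited text tables (long or wide layout) or
extracted from a multi-page grayscale TIFF stack plus an integer ROI
label mask.

Time convention: frame ``i`` maps to time ``i * frame_interval_s``
(0-based frames, time 0 at the first frame).  Epoch membership is
half-open ``[start_s, end_s)``: an event exactly at a solution switch
belongs to the later epoch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("zgcalcium")

HIERARCHY_COLUMNS = ("animal_id", "slice_id", "genotype", "sex")

__all__ = [
    "TraceMatrix",
    "PerfusionProtocol",
    "read_traces",
    "write_traces",
    "read_protocol",
    "write_protocol",
    "extract_roi_traces",
    "read_stack",
    "write_stack",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TraceMatrix:
    """Uniformly sampled fluorescence for a set of cells.

    Parameters
    ----------
    cell_ids
        One identifier per row of ``values``.
    values
        Array of shape ``(n_cells, n_frames)``, fluorescence in arbitrary
        units.  All cells share the same frame grid (uniform sampling).
    frame_interval_s
        Seconds between consecutive frames (must be positive).
    hierarchy
        Per-cell labels (``animal_id``, ``slice_id``, ``genotype``,
        ``sex``) indexed by cell id.  Missing labels default to a single
        group with a warning, so single-recording files still parse.
    """

    cell_ids: list[str]
    values: np.ndarray
    frame_interval_s: float
    hierarchy: pd.DataFrame = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (cells x frames) array")
        if len(self.cell_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {self.values.shape[0]} trace rows"
            )
        if self.frame_interval_s <= 0:
            raise ValueError(f"frame_interval_s must be > 0, got {self.frame_interval_s}")
        if not np.all(np.isfinite(self.values)):
            cell_idx, frame_idx = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite fluorescence for cell {self.cell_ids[cell_idx]!r} "
                f"at frame {frame_idx}"
            )
        if self.hierarchy is None:
            logger.warning("no hierarchy labels supplied; defaulting to a single group")
            self.hierarchy = pd.DataFrame(
                {c: ["unassigned"] * len(self.cell_ids) for c in HIERARCHY_COLUMNS},
                index=pd.Index(self.cell_ids, name="cell_id"),
            )
        else:
            self.hierarchy = self.hierarchy.copy()
            self.hierarchy.index = pd.Index(
                [str(c) for c in self.hierarchy.index], name="cell_id"
            )
            missing = [c for c in HIERARCHY_COLUMNS if c not in self.hierarchy.columns]
            if missing:
                logger.warning(
                    "hierarchy columns %s missing; defaulting to a single group", missing
                )
                for c in missing:
                    self.hierarchy[c] = "unassigned"
            if list(self.hierarchy.index) != [str(c) for c in self.cell_ids]:
                self.hierarchy = self.hierarchy.loc[[str(c) for c in self.cell_ids]]

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        """Total recorded time: n_frames * frame_interval_s."""
        return self.n_frames * self.frame_interval_s

    def times(self) -> np.ndarray:
        """Frame times in seconds (frame i at i * frame_interval_s)."""
        return np.arange(self.n_frames) * self.frame_interval_s

    def trace(self, cell_id: str) -> np.ndarray:
        return self.values[self.cell_ids.index(cell_id)]

    def to_long(self) -> pd.DataFrame:
        """Long-format table: one row per (cell, frame)."""
        n = self.n_frames
        frames = np.tile(np.arange(n), self.n_cells)
        rows = {
            "cell_id": np.repeat(self.cell_ids, n),
            "frame_index": frames,
            "time_s": frames * self.frame_interval_s,
            "fluorescence": self.values.ravel(),
        }
        df = pd.DataFrame(rows)
        hier = self.hierarchy.loc[df["cell_id"]].reset_index(drop=True)
        for c in HIERARCHY_COLUMNS:
            df[c] = hier[c].to_numpy()
        return df


@dataclass
class PerfusionProtocol:
    """Ordered bath-condition epochs for one recording.

    ``epochs`` is a table with columns ``start_s``, ``end_s``,
    ``potassium_mM``, ``atii_pM``; epochs must be sorted, non-overlapping
    and non-empty.  ``equilibration_discard_s`` optionally drops the first
    seconds after each solution switch from rate numerators and
    denominators (solution-exchange transients; default 0).
    """

    epochs: pd.DataFrame
    equilibration_discard_s: float = 0.0

    def __post_init__(self):
        df = pd.DataFrame(self.epochs).copy()
        required = ["start_s", "end_s", "potassium_mM", "atii_pM"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"protocol table missing columns {missing}")
        df = df[required].astype(float).reset_index(drop=True)
        if len(df) == 0:
            raise ValueError("protocol has no epochs")
        if (df["end_s"] <= df["start_s"]).any():
            bad = df.index[df["end_s"] <= df["start_s"]][0]
            raise ValueError(f"epoch {bad} has nonpositive duration")
        if not df["start_s"].is_monotonic_increasing:
            raise ValueError("epochs must be sorted by start_s")
        if (df["start_s"].to_numpy()[1:] < df["end_s"].to_numpy()[:-1]).any():
            raise ValueError("epochs overlap")
        if self.equilibration_discard_s < 0:
            raise ValueError("equilibration_discard_s must be >= 0")
        self.epochs = df

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    @property
    def end_s(self) -> float:
        return float(self.epochs["end_s"].iloc[-1])

    def condition(self, epoch_index: int) -> tuple[float, float]:
        row = self.epochs.iloc[epoch_index]
        return (float(row["potassium_mM"]), float(row["atii_pM"]))

    def condition_label(self, epoch_index: int) -> str:
        k, a = self.condition(epoch_index)
        return f"K{k:g}_ATII{a:g}"

    def epoch_of(self, time_s: float) -> int | None:
        """Index of the epoch containing ``time_s`` (half-open membership)."""
        df = self.epochs
        hit = (df["start_s"] <= time_s) & (time_s < df["end_s"])
        idx = np.flatnonzero(hit.to_numpy())
        return int(idx[0]) if idx.size else None

    def effective_window(self, epoch_index: int) -> tuple[float, float]:
        """Epoch window with the post-switch equilibration discard applied."""
        row = self.epochs.iloc[epoch_index]
        start = float(row["start_s"]) + self.equilibration_discard_s
        end = float(row["end_s"])
        if start >= end:
            raise ValueError(
                f"equilibration_discard_s={self.equilibration_discard_s} consumes "
                f"epoch {epoch_index} entirely"
            )
        return start, end

    def epochs_matching(self, potassium_mM=None, atii_pM=None) -> list[int]:
        """Indices of epochs whose condition matches the given values."""
        out = []
        for i in range(self.n_epochs):
            k, a = self.condition(i)
            if potassium_mM is not None and k != float(potassium_mM):
                continue
            if atii_pM is not None and a != float(atii_pM):
                continue
            out.append(i)
        return out


# ---------------------------------------------------------------------------
# delimited-text tables
# ---------------------------------------------------------------------------

def _read_table(path, sep=None) -> pd.DataFrame:
    # comma default, tab accepted; sniff when not told
    if sep is None:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") > header.count(",") else ","
    # round_trip parsing keeps write -> read bit-exact for float64 values
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_traces(path, frame_interval_s: float | None = None) -> TraceMatrix:
    """Read a trace table (long or wide layout) into a :class:`TraceMatrix`.

    Long layout needs columns ``cell_id``, ``frame_index`` (or ``time_s``)
    and ``fluorescence``, optionally hierarchy columns.  Wide layout has
    one column per cell (plus an optional ``time_s``/``frame_index``
    column) and requires ``frame_interval_s`` unless a ``time_s`` column
    fixes it.
    """
    df = _read_table(path)
    if "fluorescence" in df.columns:
        return _traces_from_long(df, frame_interval_s, path)
    return _traces_from_wide(df, frame_interval_s, path)


def _traces_from_long(df, frame_interval_s, path) -> TraceMatrix:
    for col in ("cell_id", "fluorescence"):
        if col not in df.columns:
            raise ValueError(f"{path}: long-format trace table missing column {col!r}")
    if "frame_index" not in df.columns:
        if "time_s" not in df.columns:
            raise ValueError(f"{path}: need a frame_index or time_s column")
        if frame_interval_s is None:
            t = np.sort(df["time_s"].unique())
            if len(t) < 2:
                raise ValueError(f"{path}: cannot infer frame interval from one frame")
            frame_interval_s = float(np.median(np.diff(t)))
        df = df.assign(frame_index=np.rint(df["time_s"] / frame_interval_s).astype(int))
    if frame_interval_s is None:
        if "time_s" not in df.columns:
            raise ValueError(f"{path}: frame_interval_s required (no time_s column)")
        sub = df[df["frame_index"] == 1]
        if len(sub) == 0:
            raise ValueError(f"{path}: cannot infer frame interval")
        frame_interval_s = float(sub["time_s"].iloc[0])
    if frame_interval_s <= 0:
        raise ValueError(f"frame_interval_s must be > 0, got {frame_interval_s}")

    if not pd.api.types.is_numeric_dtype(df["fluorescence"]):
        raise ValueError(f"{path}: non-numeric fluorescence values")
    cell_ids = [str(c) for c in pd.unique(df["cell_id"])]
    counts = df.groupby("cell_id", sort=False).size()
    if counts.nunique() > 1:
        raise ValueError(
            f"{path}: non-uniform frame count per cell "
            f"(min {counts.min()}, max {counts.max()})"
        )
    n_frames = int(counts.iloc[0])
    wide = df.pivot(index="cell_id", columns="frame_index", values="fluorescence")
    wide = wide.reindex(index=cell_ids, columns=range(n_frames))
    if wide.isna().any().any():
        cell = wide.index[wide.isna().any(axis=1)][0]
        frame = wide.columns[wide.loc[cell].isna()][0]
        raise ValueError(
            f"{path}: missing/NaN fluorescence for cell {cell!r} at frame {frame}"
        )
    hier_cols = [c for c in HIERARCHY_COLUMNS if c in df.columns]
    hierarchy = None
    if hier_cols:
        hierarchy = (
            df.drop_duplicates("cell_id").set_index("cell_id")[hier_cols].astype(str)
        )
    return TraceMatrix(cell_ids, wide.to_numpy(), frame_interval_s, hierarchy)


def _traces_from_wide(df, frame_interval_s, path) -> TraceMatrix:
    time_col = None
    for cand in ("time_s", "frame_index"):
        if cand in df.columns:
            time_col = cand
    if time_col == "time_s" and frame_interval_s is None:
        t = df["time_s"].to_numpy(float)
        if len(t) < 2:
            raise ValueError(f"{path}: cannot infer frame interval from one frame")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0]):
            raise ValueError(f"{path}: time_s column is not uniformly sampled")
        frame_interval_s = float(dt[0])
    if frame_interval_s is None:
        raise ValueError(f"{path}: frame_interval_s required for wide-format tables")
    value_cols = [c for c in df.columns if c not in ("time_s", "frame_index")]
    if not value_cols:
        raise ValueError(f"{path}: wide-format table has no trace columns")
    vals = df[value_cols].to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise ValueError(f"{path}: non-numeric fluorescence values")
    return TraceMatrix([str(c) for c in value_cols], vals.T, frame_interval_s, None)


def write_traces(tm: TraceMatrix, path, sep=",") -> None:
    """Write a :class:`TraceMatrix` as a long-format delimited table."""
    tm.to_long().to_csv(path, sep=sep, index=False)


def read_protocol(path, equilibration_discard_s: float = 0.0) -> PerfusionProtocol:
    return PerfusionProtocol(_read_table(path), equilibration_discard_s)


def write_protocol(protocol: PerfusionProtocol, path, sep=",") -> None:
    protocol.epochs.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

def extract_roi_traces(
    stack: np.ndarray,
    mask: np.ndarray,
    frame_interval_s: float,
    hierarchy: pd.DataFrame | None = None,
) -> TraceMatrix:
    """Mean ROI intensity per frame from a stack and an integer label mask.

    ``stack`` is ``(n_frames, h, w)`` grayscale; ``mask`` is ``(h, w)``
    with nonnegative integer labels, 0 = background.  Returns one trace
    per label in ascending label order, each the arithmetic mean of the
    pixel values under that label.
    """
    stack = np.asarray(stack, dtype=float)
    mask = np.asarray(mask)
    if stack.ndim != 3:
        raise ValueError(f"stack must be (frames, h, w), got shape {stack.shape}")
    if mask.shape != stack.shape[1:]:
        raise ValueError(
            f"mask shape {mask.shape} does not match frame shape {stack.shape[1:]}"
        )
    if not np.issubdtype(mask.dtype, np.integer) or mask.min() < 0:
        raise ValueError("mask must contain nonnegative integer labels")
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        return TraceMatrix([], np.empty((0, stack.shape[0])), frame_interval_s,
                           pd.DataFrame(columns=list(HIERARCHY_COLUMNS)))
    flat_mask = mask.ravel()
    counts = np.bincount(flat_mask, minlength=labels.max() + 1)
    n_frames = stack.shape[0]
    values = np.empty((labels.size, n_frames))
    flat = stack.reshape(n_frames, -1)
    for f in range(n_frames):
        sums = np.bincount(flat_mask, weights=flat[f], minlength=labels.max() + 1)
        values[:, f] = sums[labels] / counts[labels]
    return TraceMatrix([str(l) for l in labels], values, frame_interval_s, hierarchy)


def read_stack(path) -> np.ndarray:
    """Read a multi-page grayscale TIFF as a (frames, h, w) array."""
    import tifffile

    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_stack(stack: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(stack), photometric="minisblack")
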