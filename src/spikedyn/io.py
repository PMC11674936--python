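"""Spike-time tables, binary rasters, and the study's inclusion filters.

Spike times live in simple two-column CSV files ``(neuron_id, time_ms)``,
one file per recording condition (control / drug / washout). Rasters are
dense binary ``neurons x bins`` matrices at a stated bin width (1 ms by
default), with the half-open binning convention ``[k*w, (k+1)*w)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("control", "drug", "washout")

__all__ = [
    "CONDITIONS",
    "SpikeTable",
    "Raster",
    "read_spike_csv",
    "write_spike_csv",
    "rasterize",
    "filter_common_active",
    "filter_min_neurons",
]


@dataclass
class SpikeTable:
    """Spike times for one culture in one condition.

    ``spikes`` has columns ``neuron_id`` (string label) and ``time_ms``
    (nonnegative milliseconds from condition start), sorted by neuron then
    time with exact duplicates collapsed.
    """

    spikes: pd.DataFrame
    condition: str = "control"
    culture_id: str = "culture0"
    duration_ms: float | None = None

    def __post_init__(self):
        df = self.spikes
        if list(df.columns) != ["neuron_id", "time_ms"]:
            df = df.rename(columns=dict(zip(df.columns, ["neuron_id", "time_ms"])))
        df = df.astype({"neuron_id": str, "time_ms": float})
        if (df["time_ms"] < 0).any():
            raise ValueError("negative spike times")
        df = (
            df.drop_duplicates()
            .sort_values(["neuron_id", "time_ms"], kind="mergesort")
            .reset_index(drop=True)
        )
        self.spikes = df

    @property
    def neuron_ids(self) -> list[str]:
        return sorted(self.spikes["neuron_id"].unique())

    @property
    def n_spikes(self) -> int:
        return len(self.spikes)

    def times_for(self, neuron_id: str) -> np.ndarray:
        sel = self.spikes.loc[self.spikes["neuron_id"] == str(neuron_id), "time_ms"]
        return sel.to_numpy()


@dataclass
class Raster:
    """Binary neuron x time-bin matrix; 1 = at least one spike in the bin."""

    matrix: np.ndarray
    bin_width_ms: float = 1.0
    neuron_ids: list[str] = field(default_factory=list)
    condition: str = "control"
    culture_id: str = "culture0"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise ValueError("raster matrix must be 2-D")
        if not self.neuron_ids:
            self.neuron_ids = [f"n{i}" for i in range(self.matrix.shape[0])]
        if len(self.neuron_ids) != self.matrix.shape[0]:
            raise ValueError("neuron_ids length must match the row count")
        self.neuron_ids = [str(i) for i in self.neuron_ids]
        if self.matrix.size and self.matrix.max() > 1:
            raise ValueError("raster entries must be binary")

    @property
    def n_neurons(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_bins * self.bin_width_ms

    def row(self, neuron_id: str) -> np.ndarray:
        return self.matrix[self.neuron_ids.index(str(neuron_id))]

    def active_mask(self, min_spikes: int = 1) -> np.ndarray:
        return self.matrix.sum(axis=1) >= min_spikes

    def subset(self, neuron_ids) -> "Raster":
        idx = [self.neuron_ids.index(str(i)) for i in neuron_ids]
        return Raster(
            self.matrix[idx],
            self.bin_width_ms,
            [self.neuron_ids[i] for i in idx],
            self.condition,
            self.culture_id,
        )

    def to_dense_csv(self, path) -> None:
        """Write the full binary matrix, one row per neuron, bins as columns."""
        pd.DataFrame(self.matrix, index=pd.Index(self.neuron_ids, name="neuron_id")).to_csv(path)

    def to_sparse_pairs(self) -> pd.DataFrame:
        """(neuron_id, bin) rows for every 1-entry."""
        rows, cols = np.nonzero(self.matrix)
        return pd.DataFrame(
            {"neuron_id": [self.neuron_ids[r] for r in rows], "bin": cols}
        )

    def to_spike_table(self) -> SpikeTable:
        """Place one spike at the centre of every occupied bin."""
        pairs = self.to_sparse_pairs()
        df = pd.DataFrame(
            {
                "neuron_id": pairs["neuron_id"],
                "time_ms": (pairs["bin"] + 0.5) * self.bin_width_ms,
            }
        )
        return SpikeTable(df, self.condition, self.culture_id, self.duration_ms)


def read_spike_csv(
    path, condition: str = "control", culture_id: str = "culture0"
) -> SpikeTable:
    """Read a two-column ``(neuron_id, time_ms)`` spike CSV.

    A header row is auto-detected (non-numeric second column). Duplicate
    rows collapse to a single spike; an unparseable time raises with the
    offending row number; an empty file yields an empty table with a warning.
    """
    try:
        raw = pd.read_csv(path, header=None, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        warnings.warn(f"empty spike file: {path}")
        return SpikeTable(
            pd.DataFrame({"neuron_id": [], "time_ms": []}), condition, culture_id
        )
    if raw.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (neuron_id, time_ms)")
    raw = raw.iloc[:, :2]
    raw.columns = ["neuron_id", "time_ms"]
    start = 0
    try:
        float(raw.iloc[0, 1])
    except (TypeError, ValueError):
        start = 1  # header row
    body = raw.iloc[start:]
    if body.empty:
        warnings.warn(f"spike file has a header but no rows: {path}")
        return SpikeTable(
            pd.DataFrame({"neuron_id": [], "time_ms": []}), condition, culture_id
        )
    times = pd.to_numeric(body["time_ms"], errors="coerce")
    bad = times.isna()
    if bad.any():
        rownum = int(body.index[bad][0]) + 1  # 1-based line number in the file
        raise ValueError(f"{path}: unparseable spike time at row {rownum}")
    df = pd.DataFrame({"neuron_id": body["neuron_id"].to_numpy(), "time_ms": times.to_numpy()})
    return SpikeTable(df, condition, culture_id)


def write_spike_csv(table: SpikeTable, path, header: bool = True) -> None:
    table.spikes.to_csv(path, index=False, header=header)


def rasterize(
    table: SpikeTable, bin_width_ms: float = 1.0, duration_ms: float | None = None
) -> Raster:
    """Bin spike times into a binary raster with half-open bins.

    A spike at time t lands in bin ``floor(t / w)``; multiple spikes in one
    bin map to a single 1. ``duration_ms`` defaults to the table's stated
    duration, else to the smallest whole number of bins covering the last
    spike. Spikes at or beyond the duration are a hard error.
    """
    if bin_width_ms <= 0:
        raise ValueError("bin width must be positive")
    times = table.spikes["time_ms"].to_numpy()
    if duration_ms is None:
        duration_ms = table.duration_ms
    if duration_ms is None:
        last = times.max() if times.size else 0.0
        duration_ms = (np.floor(last / bin_width_ms) + 1) * bin_width_ms
    if times.size and times.max() >= duration_ms:
        raise ValueError("spike time at or beyond the stated duration")
    n_bins = int(np.ceil(duration_ms / bin_width_ms))
    ids = table.neuron_ids
    mat = np.zeros((len(ids), n_bins), dtype=np.uint8)
    row_of = {nid: i for i, nid in enumerate(ids)}
    rows = table.spikes["neuron_id"].map(row_of).to_numpy(dtype=np.int64)
    cols = np.floor(times / bin_width_ms).astype(np.int64)
    mat[rows, cols] = 1
    return Raster(mat, bin_width_ms, ids, table.condition, table.culture_id)


def filter_common_active(
    rasters: dict[str, Raster], min_spikes: int = 1
) -> dict[str, Raster]:
    """Keep only neurons active (>= min_spikes) in every condition.

    This is the inclusion rule that makes the three-condition repeated-measures
    design valid: each retained neuron contributes a value in all conditions.
    Row order of the first condition is preserved.
    """
    if not rasters:
        raise ValueError("no rasters given")
    universes = [tuple(sorted(r.neuron_ids)) for r in rasters.values()]
    if len(set(universes)) != 1:
        raise ValueError("conditions must share the same neuron universe")
    active = None
    for r in rasters.values():
        ids = {nid for nid, a in zip(r.neuron_ids, r.active_mask(min_spikes)) if a}
        active = ids if active is None else active & ids
    if not active:
        warnings.warn("no neuron is active in all conditions")
        active = set()
    first = next(iter(rasters.values()))
    keep = [nid for nid in first.neuron_ids if nid in active]
    return {cond: r.subset(keep) for cond, r in rasters.items()}


def filter_min_neurons(raster: Raster, min_n: int = 30, min_spikes: int = 1) -> bool:
    """True (keep) iff the raster has at least ``min_n`` active neurons."""
    return int(raster.active_mask(min_spikes).sum()) >= min_n
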