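"""Drink-aligned peri-event extraction and per-event transient metrics.

Each retained drink yields one row of z-scored ΔF/F sampled by linear
interpolation on a fixed bin grid spanning the 5 s before to the 5 s after
the drink start.  The default grid has 150 bins at 1/15 s spacing,
``t_k = -5 + k/15``: it matches the 15 Hz effective per-channel frame rate
and contains t = 0 exactly.

Per-event metrics follow the drinking event itself: the peak amplitude is
the maximum z-scored ΔF/F between drink start and drink end (capped at
+5 s), time-to-peak its first-occurrence argmax, and the AUC the
trapezoidal integral from the peak time to the end of the drink.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lickometer import Drink
from .photometry import DffTrace

__all__ = [
    "PeriEventMatrix",
    "TransientMetrics",
    "bin_grid",
    "align_to_drinks",
    "transient_metrics",
    "metrics_table",
    "group_mean_trace",
]

logger = logging.getLogger(__name__)


def bin_grid(window: tuple[float, float] = (-5.0, 5.0), n_bins: int = 150) -> np.ndarray:
    """Time offsets of the peri-event bins relative to drink start."""
    lo, hi = window
    if not (lo < 0 < hi):
        raise ValueError("window must straddle the drink start")
    step = (hi - lo) / n_bins
    return lo + step * np.arange(n_bins)


@dataclass
class PeriEventMatrix:
    """Rows of drink-aligned z-scored ΔF/F on a common bin grid, with
    per-row metadata.  Drinks whose window would run off the recording are
    dropped and listed in ``dropped`` (and logged), never padded."""

    offsets: np.ndarray
    values: np.ndarray
    meta: pd.DataFrame
    dropped: list[int] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]


@dataclass
class TransientMetrics:
    peak_amplitude: float
    time_to_peak: float
    auc: float
    drink_end: float


def align_to_drinks(
    trace: DffTrace,
    drinks: list[Drink],
    window: tuple[float, float] = (-5.0, 5.0),
    n_bins: int = 150,
    meta: dict | None = None,
) -> PeriEventMatrix:
    """Align a z-scored trace to drink starts.

    Drink timestamps are on the acquisition clock; the trace's
    ``clock_offset`` (frames trimmed at the start) is subtracted before
    interpolation.  Drinks whose full window is not covered by the trace
    are dropped with a log entry.
    """
    if trace.zdff is None:
        raise ValueError("trace has no z-scored ΔF/F (failed QC?)")
    offsets = bin_grid(window, n_bins)
    rows = []
    meta_rows = []
    dropped: list[int] = []
    t0, t1 = float(trace.time[0]), float(trace.time[-1])
    for i, drink in enumerate(drinks):
        start = drink.start - trace.clock_offset
        if start + offsets[0] < t0 or start + offsets[-1] > t1:
            dropped.append(i)
            logger.info("drink %d at %.1f s dropped: window exceeds recording", i, drink.start)
            continue
        row = np.interp(start + offsets, trace.time, trace.zdff)
        rows.append(row)
        entry = {"drink_index": i, "drink_start": drink.start, "drink_length": drink.length}
        if meta:
            entry.update(meta)
        meta_rows.append(entry)
    values = np.vstack(rows) if rows else np.empty((0, n_bins))
    return PeriEventMatrix(offsets, values, pd.DataFrame(meta_rows), dropped)


def transient_metrics(row: np.ndarray, offsets: np.ndarray, drink_length: float
                      ) -> TransientMetrics:
    """Peak amplitude, time-to-peak and AUC for one drink-aligned row.

    The peak is searched during the drinking event only, i.e. offsets in
    [0, min(drink length, window end)]; ties take the earliest bin.  The
    AUC is the trapezoidal integral of the row from the peak time to the
    drink end (capped at the window edge), in z·s.
    """
    row = np.asarray(row, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    if drink_length <= 0:
        raise ValueError("drink length must be positive")
    end = min(float(drink_length), float(offsets[-1]))
    search = (offsets >= 0) & (offsets <= end)
    if not search.any():
        raise ValueError("empty peak search window")
    seg = row[search]
    seg_t = offsets[search]
    k = int(np.argmax(seg))  # first occurrence on ties
    peak = float(seg[k])
    t_peak = float(seg_t[k])
    auc_mask = (offsets >= t_peak) & (offsets <= end)
    auc = float(np.trapezoid(row[auc_mask], offsets[auc_mask]))
    return TransientMetrics(peak, t_peak, auc, end)


def metrics_table(matrix: PeriEventMatrix) -> pd.DataFrame:
    """Per-event metrics for every row of a peri-event matrix, joined to
    the row metadata."""
    rows = []
    for i in range(matrix.n_rows):
        m = transient_metrics(
            matrix.values[i], matrix.offsets, float(matrix.meta.iloc[i]["drink_length"])
        )
        entry = matrix.meta.iloc[i].to_dict()
        entry.update(
            peak_amplitude=m.peak_amplitude,
            time_to_peak=m.time_to_peak,
            auc=m.auc,
            drink_end=m.drink_end,
        )
        rows.append(entry)
    return pd.DataFrame(rows)


def group_mean_trace(
    matrix: PeriEventMatrix, by: tuple[str, ...] = ("sex", "fluid", "side")
) -> pd.DataFrame:
    """Per-bin mean ± SEM of the aligned rows within each metadata group.

    Groups with fewer than 2 rows report the mean with SEM marked missing
    (NaN).  Returns a tidy frame: one row per group per bin with columns
    ``offset_s``, ``mean``, ``sem``, ``n``.
    """
    if matrix.n_rows == 0:
        raise ValueError("empty peri-event matrix")
    missing = [c for c in by if c not in matrix.meta.columns]
    if missing:
        raise ValueError(f"grouping columns absent from metadata: {missing}")
    out = []
    for key, idx in matrix.meta.groupby(list(by), sort=True).groups.items():
        key = key if isinstance(key, tuple) else (key,)
        block = matrix.values[matrix.meta.index.get_indexer(idx)]
        n = block.shape[0]
        mean = block.mean(axis=0)
        sem = block.std(axis=0, ddof=1) / np.sqrt(n) if n >= 2 else np.full(block.shape[1], np.nan)
        frame = pd.DataFrame({"offset_s": matrix.offsets, "mean": mean, "sem": sem, "n": n})
        for col, val in zip(by, key):
            frame[col] = val
        out.append(frame)
    return pd.concat(out, ignore_index=True)[list(by) + ["offset_s", "mean", "sem", "n"]]
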