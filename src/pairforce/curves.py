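"""From inferred per-pair forces to distance-force curves.

The raw output of the inference is a scatter of (distance, force) points,
one per cell pair per frame transition.  Individual points are dominated by
the cells' intrinsic force fluctuations; the systematic distance dependence
emerges in the binned average, optionally restricted to a time window or
partitioned by cell-type label pairs (e.g. inner/outer blastomeres), and the
point density is visualized as an n x n frequency map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .potentials import DFCurve

__all__ = ["FrequencyMap", "bin_average", "frequency_map", "grouped_curves"]


def _scatter_arrays(scatter) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(scatter, pd.DataFrame):
        return (scatter["distance_um"].to_numpy(),
                scatter["force_au"].to_numpy())
    d, f = scatter
    return np.asarray(d, dtype=float), np.asarray(f, dtype=float)


def bin_average(scatter, bin_width: float, min_count: int = 10) -> DFCurve:
    """Binned-average DF curve from a (distance, force) scatter.

    Distances are binned at ``bin_width``; each kept bin contributes its
    unweighted mean force, plotted at the mean distance of the points in the
    bin (using the in-bin mean rather than the geometric bin center avoids
    misplacing the curve where the occupancy is strongly nonuniform, e.g. on
    the steep inner edge of the attractive well).  Bins with fewer than
    ``min_count`` points are omitted; per-bin counts are carried in the
    curve metadata.

    ``scatter`` is either a DataFrame with ``distance_um``/``force_au``
    columns (e.g. from :class:`~pairforce.inference.InferredForceTable`) or a
    ``(distances, forces)`` pair.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    d, f = _scatter_arrays(scatter)
    if d.size == 0:
        raise ValueError("empty scatter")
    first = np.floor(d.min() / bin_width)
    idx = (np.floor(d / bin_width) - first).astype(int)
    n_bins = idx.max() + 1
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=f, minlength=n_bins)
    d_sums = np.bincount(idx, weights=d, minlength=n_bins)
    keep = counts >= max(1, min_count)
    if not np.any(keep):
        raise ValueError(
            f"no bin reaches min_count={min_count} (max bin count {counts.max()})")
    centers = d_sums[keep] / counts[keep]
    means = sums[keep] / counts[keep]
    return DFCurve(centers, means,
                   metadata={"counts": counts[keep], "bin_width": bin_width,
                             "source": "binned_average"})


@dataclass
class FrequencyMap:
    """2D histogram of (distance, force) scatter points."""

    counts: np.ndarray
    d_edges: np.ndarray
    f_edges: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_text(self, path) -> None:
        """Dense matrix text dump with axis metadata in header comments."""
        header = (f"frequency map {self.counts.shape[0]}x{self.counts.shape[1]}\n"
                  f"distance_um range [{self.d_edges[0]}, {self.d_edges[-1]}]\n"
                  f"force_au range [{self.f_edges[0]}, {self.f_edges[-1]}]\n"
                  "rows: distance bins, columns: force bins")
        np.savetxt(path, self.counts, fmt="%d", header=header)


def frequency_map(scatter, n: int = 128,
                  d_range: Optional[tuple] = None,
                  f_range: Optional[tuple] = None) -> FrequencyMap:
    """Count scatter points on an ``n`` x ``n`` (distance, force) grid.

    Ranges default to the data extents; points outside explicit ranges are
    not counted.
    """
    d, f = _scatter_arrays(scatter)
    if d.size == 0:
        raise ValueError("empty scatter")
    counts, d_edges, f_edges = np.histogram2d(
        d, f, bins=n,
        range=None if d_range is None and f_range is None else
        [d_range or (d.min(), d.max()), f_range or (f.min(), f.max())])
    return FrequencyMap(counts.astype(int), d_edges, f_edges)


def grouped_curves(scatter: pd.DataFrame, labels: dict,
                   bin_width: float, min_count: int = 10) -> dict:
    """Binned DF curves per unordered label pair.

    With two cell labels (e.g. inner/outer) there are exactly three
    interaction categories: inner-inner, outer-outer and inner-outer.  Every
    cell appearing in the scatter must be labeled.
    """
    cells = set(scatter["cell_a"]) | set(scatter["cell_b"])
    missing = sorted(c for c in cells if c not in labels)
    if missing:
        raise ValueError(f"missing labels for cells: {missing}")
    key = [tuple(sorted((labels[a], labels[b])))
           for a, b in zip(scatter["cell_a"], scatter["cell_b"])]
    out = {}
    frame = scatter.assign(_pairkey=key)
    for pairkey, sub in frame.groupby("_pairkey"):
        out[pairkey] = bin_average(sub, bin_width, min_count)
    return out
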