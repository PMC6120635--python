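"""Cell calling from the reads-per-barcode rank curve.

Cell-containing barcodes sit on a high plateau of the log-log rank curve;
ambient/background barcodes form the long low tail.  The knee separating
them is located as the point of maximum perpendicular distance from the
chord joining the first and last points of the (log10 rank, log10 count)
curve — deterministic and parameter-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .barcodes import CellCountMatrix
from .genotype import AlleleCounts

DEFAULT_MIN_READS_FLOOR = 100


@dataclass
class RankCurve:
    """Barcodes ranked by descending read total, with log10 transforms."""

    barcodes: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if (np.diff(self.counts) > 0).any():
            raise ValueError("rank-curve counts must be non-increasing")
        if (self.counts <= 0).any():
            raise ValueError("rank-curve counts must be positive")

    @property
    def log_rank(self) -> np.ndarray:
        return np.log10(np.arange(1, len(self.counts) + 1))

    @property
    def log_count(self) -> np.ndarray:
        return np.log10(self.counts)

    @classmethod
    def from_matrix(cls, matrix: CellCountMatrix) -> "RankCurve":
        totals = matrix.totals
        totals = totals[totals > 0]
        return cls(totals.index.to_numpy(), totals.to_numpy())


@dataclass
class CellCalls:
    """Result of knee-point cell calling."""

    cells: list[str]
    knee_rank: int | None
    curve: RankCurve
    flat_curve: bool = False
    distances: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def chord_distances(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Perpendicular distance of each point from the first-to-last chord."""
    x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
    dx, dy = x1 - x0, y1 - y0
    norm = np.hypot(dx, dy)
    return np.abs(dy * (x - x0) - dx * (y - y0)) / norm


def call_cells(
    matrix: CellCountMatrix,
    min_reads_floor: int = DEFAULT_MIN_READS_FLOOR,
) -> CellCalls:
    """Call cell-containing barcodes from the rank curve knee.

    Barcodes ranked strictly above the knee point and with at least
    ``min_reads_floor`` reads are cells (the knee itself marks the first
    background barcode; the chord's own endpoints have distance zero, so
    the maximum falls just past the cell plateau).  Ties at the maximum
    distance break toward the larger rank (more cells); a flat curve (all
    counts equal) has no knee and returns every barcode above the floor
    with ``flat_curve`` set.
    """
    curve = RankCurve.from_matrix(matrix)
    if len(curve.counts) < 10:
        raise ValueError("cell calling requires at least 10 barcodes with reads")
    if curve.counts[0] == curve.counts[-1]:
        cells = [b for b, c in zip(curve.barcodes, curve.counts) if c >= min_reads_floor]
        return CellCalls(cells, None, curve, flat_curve=True)
    d = chord_distances(curve.log_rank, curve.log_count)
    knee_rank = int(np.flatnonzero(d == d.max()).max()) + 1  # 1-based rank
    n_above = knee_rank - 1
    mask = curve.counts[:n_above] >= min_reads_floor
    cells = list(curve.barcodes[:n_above][mask])
    return CellCalls(cells, knee_rank, curve, distances=d)


def genotypeable_subset(
    cells: Sequence[str],
    allele_counts: AlleleCounts,
    site_ids: Sequence[str],
    min_depth: int = 10,
) -> list[str]:
    """Cells with depth >= ``min_depth`` at every listed variant site."""
    present = [c for c in cells if c in allele_counts.ref.index]
    if not present:
        return []
    depth = allele_counts.depth.loc[present, list(site_ids)]
    keep = (depth >= min_depth).all(axis=1)
    return list(depth.index[keep])


def plot_rank_curve(calls: CellCalls, ax=None):  # pragma: no cover - plotting helper
    """Log-log rank plot with the knee marked (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    curve = calls.curve
    ax.plot(10 ** curve.log_rank, curve.counts, lw=1)
    if calls.knee_rank is not None:
        ax.axvline(calls.knee_rank, color="red", ls="--", label=f"knee @ {calls.knee_rank}")
        ax.legend()
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("barcode rank")
    ax.set_ylabel("reads per barcode")
    return ax
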