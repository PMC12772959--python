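"""Binning of spot-level in situ sequencing (ISS) reads into a binary
landmark-signature grid.

An ISS experiment reports one record per detected transcript: a gene symbol
from a curated landmark panel and a fractional (x, y) pixel coordinate inside
a fixed-size reference space.  The reference space is tiled with square bins
(``tile`` pixels on edge, half-open intervals, origin at the top-left,
x = column axis, y = row axis); each bin's *signature* is the bit vector of
landmark presence within it.  Many bins share a signature, so the grid also
carries a table of unique signatures with occupancy counts and a per-bin
index into that table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "SignatureGrid",
    "read_spot_table",
    "read_panel",
    "aggregate_reads",
    "unique_signatures",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the reference space and its square aggregation tiles.

    Parameters
    ----------
    width_px, height_px
        Extent of the reference space in pixels; x coordinates live in
        ``[0, width_px)`` and y in ``[0, height_px)``.
    tile
        Edge length of the square aggregation tiles, in pixels.  Partial
        tiles at the right/bottom edges are retained, so the bin counts are
        ceilings of the pixel extents.
    """

    width_px: int
    height_px: int
    tile: int = 16

    def __post_init__(self) -> None:
        if self.tile < 1:
            raise ValueError(f"tile must be >= 1, got {self.tile}")
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("reference space must have positive extent")

    @property
    def bins_w(self) -> int:
        return math.ceil(self.width_px / self.tile)

    @property
    def bins_h(self) -> int:
        return math.ceil(self.height_px / self.tile)

    @property
    def n_bins(self) -> int:
        return self.bins_h * self.bins_w


@dataclass
class SignatureGrid:
    """Binary landmark-presence tensor over spatial bins.

    Attributes
    ----------
    bits
        Boolean tensor of shape ``(bins_h, bins_w, L)``; ``bits[h, w, l]`` is
        True iff at least one read of landmark ``l`` fell in tile ``(h, w)``.
    sig_index
        Integer array ``(bins_h, bins_w)`` giving each bin's row in
        ``sig_table``.
    sig_table
        Unique L-bit signatures, shape ``(S, L)`` boolean.
    sig_counts
        Occupancy count per unique signature; sums to the number of bins.
    panel
        Landmark symbols in bit order.
    counts
        Optional integer read-count tensor (same shape as ``bits``); only
        populated when aggregation ran in count mode.  The core model uses
        presence/absence.
    """

    bits: np.ndarray
    sig_index: np.ndarray
    sig_table: np.ndarray
    sig_counts: np.ndarray
    panel: list[str]
    grid: GridSpec
    counts: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_landmarks(self) -> int:
        return self.bits.shape[2]

    @property
    def n_signatures(self) -> int:
        return self.sig_table.shape[0]

    def landmark_bins(self, landmark: str) -> np.ndarray:
        """(row, col) coordinates of bins where ``landmark`` was detected."""
        try:
            l = self.panel.index(landmark)
        except ValueError:
            raise KeyError(f"landmark {landmark!r} not in panel") from None
        return np.argwhere(self.bits[:, :, l])

    def subset_panel(self, panel: list[str]) -> "SignatureGrid":
        """Restrict the grid to a sub-panel (re-deduplicating signatures)."""
        idx = [self.panel.index(g) for g in panel]
        bits = self.bits[:, :, idx]
        sig_index, sig_table, sig_counts = _dedupe(bits)
        return SignatureGrid(
            bits=bits,
            sig_index=sig_index,
            sig_table=sig_table,
            sig_counts=sig_counts,
            panel=list(panel),
            grid=self.grid,
            counts=None if self.counts is None else self.counts[:, :, idx],
        )

    def drop_landmark(self, landmark: str) -> "SignatureGrid":
        """Return a grid with one landmark's bit removed (e.g. for LOOCV).

        Signatures that become identical after dropping the bit are merged.
        """
        l = self.panel.index(landmark)
        keep = [i for i in range(self.n_landmarks) if i != l]
        bits = self.bits[:, :, keep]
        reduced_table = self.sig_table[:, keep]
        # Re-deduplicate: old signature ids map onto merged ids.
        merged, remap = np.unique(reduced_table, axis=0, return_inverse=True)
        sig_index = remap[self.sig_index]
        counts = np.bincount(remap, weights=self.sig_counts.astype(float),
                             minlength=merged.shape[0]).astype(np.int64)
        return SignatureGrid(
            bits=bits,
            sig_index=sig_index,
            sig_table=merged,
            sig_counts=counts,
            panel=[self.panel[i] for i in keep],
            grid=self.grid,
        )


def read_spot_table(path) -> pd.DataFrame:
    """Read a ``gene,x,y`` spot table (CSV, or TSV if so delimited)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"gene", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"spot table {path} lacks columns {sorted(missing)}")
    return df[["gene", "x", "y"]]


def read_panel(path) -> list[str]:
    """Read a landmark panel file: one gene symbol per line."""
    with open(path) as fh:
        panel = [line.strip() for line in fh if line.strip()]
    if not panel:
        raise ValueError(f"panel file {path} is empty")
    return panel


def aggregate_reads(
    reads: pd.DataFrame,
    grid: GridSpec,
    panel: list[str],
    count_mode: bool = False,
) -> SignatureGrid:
    """Aggregate spot-level reads into the binary signature grid.

    A read at fractional coordinate ``(x, y)`` maps to tile
    ``(floor(y / tile), floor(x / tile))``.  Coordinates on or beyond the
    maximum boundary are rejected (half-open tiles), as are reads whose gene
    is not in the panel.

    Parameters
    ----------
    reads
        DataFrame with columns ``gene``, ``x``, ``y``.
    grid
        Reference-space geometry.
    panel
        Landmark symbols defining bit order.  Duplicates are rejected.
    count_mode
        Also accumulate integer read counts per (bin, landmark).  Presence/
        absence bits are produced either way.
    """
    if not panel:
        raise ValueError("landmark panel is empty")
    if len(set(panel)) != len(panel):
        raise ValueError("landmark panel contains duplicates")
    gene_to_bit = {g: i for i, g in enumerate(panel)}

    genes = reads["gene"].to_numpy()
    unknown = [g for g in pd.unique(genes) if g not in gene_to_bit]
    if unknown:
        raise ValueError(
            f"reads reference genes outside the landmark panel: {unknown[:5]}"
        )

    x = np.asarray(reads["x"], dtype=float)
    y = np.asarray(reads["y"], dtype=float)
    bad = ~(np.isfinite(x) & np.isfinite(y))
    if bad.any():
        raise ValueError(f"{int(bad.sum())} reads have non-finite coordinates")
    oob = (x < 0) | (x >= grid.width_px) | (y < 0) | (y >= grid.height_px)
    if oob.any():
        i = int(np.argmax(oob))
        raise ValueError(
            f"read at ({x[i]}, {y[i]}) lies outside the "
            f"{grid.width_px}x{grid.height_px} reference space"
        )

    rows = np.floor(y / grid.tile).astype(np.int64)
    cols = np.floor(x / grid.tile).astype(np.int64)
    lidx = np.array([gene_to_bit[g] for g in genes], dtype=np.int64)

    H, W, L = grid.bins_h, grid.bins_w, len(panel)
    bits = np.zeros((H, W, L), dtype=bool)
    bits[rows, cols, lidx] = True
    counts = None
    if count_mode:
        counts = np.zeros((H, W, L), dtype=np.int64)
        np.add.at(counts, (rows, cols, lidx), 1)

    sig_index, sig_table, sig_counts = _dedupe(bits)
    return SignatureGrid(
        bits=bits,
        sig_index=sig_index,
        sig_table=sig_table,
        sig_counts=sig_counts,
        panel=list(panel),
        grid=grid,
        counts=counts,
    )


def _dedupe(bits: np.ndarray):
    H, W, L = bits.shape
    flat = bits.reshape(H * W, L)
    table, inverse, counts = np.unique(
        flat, axis=0, return_inverse=True, return_counts=True
    )
    return inverse.reshape(H, W), table, counts.astype(np.int64)


def unique_signatures(sg: SignatureGrid) -> pd.DataFrame:
    """Tabulate the unique landmark signatures with occupancy counts.

    The table is deterministic and order-stable (lexicographic in the bit
    vector, as produced by ``np.unique``); the all-zero signature is a
    legitimate entry.
    """
    return pd.DataFrame(
        {
            "signature_id": np.arange(sg.n_signatures),
            "bits": ["".join("1" if b else "0" for b in row) for row in sg.sig_table],
            "count": sg.sig_counts,
        }
    )
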