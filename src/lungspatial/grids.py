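"""Hexagonal Visium capture-lattice construction and adjacency.

The Visium array places 55 µm capture spots on a hexagonally packed grid
with 100 µm center-to-center spacing.  Position tables index spots by
(array_row, array_col) where column steps count *half* columns, so a spot
exists only where array_row + array_col is even and the six lattice
neighbors of (r, c) are (r, c±2) and (r±1, c±1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: sqrt(3)/2 — vertical row pitch of a unit hexagonal lattice.
_ROW_PITCH = math.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class GridGeometry:
    """Physical geometry of a Visium capture array.

    Parameters
    ----------
    spot_diameter_um
        Diameter of one capture spot (55 µm for Visium).
    center_spacing_um
        Center-to-center distance between adjacent spots (100 µm).
    microns_per_pixel
        Full-resolution image scale.  The default 10/3 µm/px makes the
        500 µm peripheral threshold equal exactly 150 px.
    n_rows, n_cols
        Array extent; ``n_cols`` counts half-columns, so each row holds
        ``ceil(n_cols / 2)`` spots.
    """

    spot_diameter_um: float = 55.0
    center_spacing_um: float = 100.0
    microns_per_pixel: float = 10.0 / 3.0
    n_rows: int = 40
    n_cols: int = 60

    def __post_init__(self) -> None:
        if self.spot_diameter_um <= 0 or self.center_spacing_um <= 0:
            raise ValueError("spot diameter and center spacing must be positive")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.spot_diameter_um >= self.center_spacing_um:
            raise ValueError("spot diameter must be smaller than center spacing")

    @property
    def interstitial_gap_um(self) -> float:
        """Gap between adjacent capture-area rims (45 µm for Visium)."""
        return self.center_spacing_um - self.spot_diameter_um

    @property
    def spacing_px(self) -> float:
        return self.center_spacing_um / self.microns_per_pixel


def spot_barcode(array_row: int, array_col: int) -> str:
    """Deterministic synthetic barcode for an array position."""
    return f"s{array_row:03d}x{array_col:03d}-1"


def make_hex_grid(
    geometry: GridGeometry,
    *,
    margin_spacings: float = 1.0,
    round_pixels: bool = True,
) -> pd.DataFrame:
    """Construct the parity hex lattice of a capture array.

    Returns a DataFrame with one row per spot and columns
    ``spot_id, array_row, array_col, px_row, px_col, in_tissue``.
    Pixel coordinates are spot centers in full-resolution pixels; with
    ``round_pixels`` they are rounded to the nearest integer pixel, the
    convention of Space Ranger position tables.  ``margin_spacings``
    shifts the lattice away from the image origin by that many
    center-spacings so rendered images keep a background border.
    """
    g = geometry
    rows = np.arange(g.n_rows)
    cols = np.arange(g.n_cols)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    keep = (rr + cc) % 2 == 0
    rr, cc = rr[keep], cc[keep]

    spacing_px = g.spacing_px
    margin = margin_spacings * spacing_px
    px_col = margin + cc * (spacing_px / 2.0)
    px_row = margin + rr * (spacing_px * _ROW_PITCH)
    if round_pixels:
        px_col = np.rint(px_col).astype(np.int64)
        px_row = np.rint(px_row).astype(np.int64)

    return pd.DataFrame(
        {
            "spot_id": [spot_barcode(r, c) for r, c in zip(rr, cc)],
            "array_row": rr.astype(np.int64),
            "array_col": cc.astype(np.int64),
            "px_row": px_row,
            "px_col": px_col,
            "in_tissue": np.ones(rr.size, dtype=np.int64),
        }
    )


def hex_neighbors(
    array_row: int,
    array_col: int,
    *,
    n_rows: int | None = None,
    n_cols: int | None = None,
) -> list[tuple[int, int]]:
    """The up-to-six lattice neighbors of a parity-grid position.

    Off-array positions (negative, or beyond ``n_rows``/``n_cols`` when
    given) are excluded.  Raises ``ValueError`` if (row + col) is odd.
    """
    if (array_row + array_col) % 2 != 0:
        raise ValueError(
            f"position ({array_row}, {array_col}) violates the parity "
            "convention (array_row + array_col must be even)"
        )
    candidates = [
        (array_row, array_col - 2),
        (array_row, array_col + 2),
        (array_row - 1, array_col - 1),
        (array_row - 1, array_col + 1),
        (array_row + 1, array_col - 1),
        (array_row + 1, array_col + 1),
    ]
    out = []
    for r, c in candidates:
        if r < 0 or c < 0:
            continue
        if n_rows is not None and r >= n_rows:
            continue
        if n_cols is not None and c >= n_cols:
            continue
        out.append((r, c))
    return out
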