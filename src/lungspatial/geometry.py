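"""Tissue-border selection, radial border distance and peripheral region.

The tissue border is the subset of edge spots facing the section
exterior (in real studies, spots resembling the pleural surface, chosen
manually).  Each tissue spot's radial distance to the nearest border
spot, measured center-to-center in full-resolution pixels, defines the
peripheral region: spots not farther than 500 µm (150 px at the study's
10/3 µm/px scale) from the border.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grids import hex_neighbors  # noqa: F401  (re-exported lattice adjacency)

logger = logging.getLogger(__name__)

_OFFSETS = ((0, -2), (0, 2), (-1, -1), (-1, 1), (1, -1), (1, 1))


@dataclass(frozen=True)
class PeripheryParams:
    """Thresholds of the peripheral-region definition.

    ``threshold_um`` is the radial cutoff (inclusive); ``fallback_threshold_px``
    is the fixed-pixel alternative used when no micron scale is available.
    The fiducial physical diameter is a vendor constant (85 µm) used with
    the spot diameter to derive the micron-per-pixel scale.
    """

    threshold_um: float = 500.0
    fallback_threshold_px: float = 150.0
    spot_diameter_um: float = 55.0
    fiducial_diameter_um: float = 85.0

    def __post_init__(self) -> None:
        if min(self.threshold_um, self.fallback_threshold_px,
               self.spot_diameter_um, self.fiducial_diameter_um) <= 0:
            raise ValueError("all periphery parameters must be positive")


def microns_per_pixel(
    scalefactors: dict,
    spot_diameter_um: float = 55.0,
    fiducial_diameter_um: float = 85.0,
    *,
    warn_rel_tol: float = 0.05,
) -> float:
    """Image scale from the mean of the spot- and fiducial-diameter ratios.

    Each channel contributes physical-diameter / full-resolution-pixel
    diameter; discordant channels (relative spread above ``warn_rel_tol``)
    are averaged with a warning.
    """
    spot_px = scalefactors["spot_diameter_fullres"]
    fid_px = scalefactors["fiducial_diameter_fullres"]
    if spot_px <= 0 or fid_px <= 0:
        raise ValueError("scale-factor diameters must be positive")
    s1 = spot_diameter_um / spot_px
    s2 = fiducial_diameter_um / fid_px
    mean = (s1 + s2) / 2.0
    if abs(s1 - s2) / mean > warn_rel_tol:
        logger.warning(
            "discordant µm/px estimates from spot (%.4f) and fiducial (%.4f) "
            "diameters; using their mean %.4f", s1, s2, mean,
        )
    return mean


def select_border_spots(
    grid: pd.DataFrame,
    edge_flags: pd.Series | np.ndarray,
    manual_file: str | Path | None = None,
    *,
    retained_flags: pd.Series | np.ndarray | None = None,
) -> pd.Index:
    """Designate the tissue-border spots among the edge spots.

    With ``manual_file`` (one barcode per line, ``#`` comments allowed)
    the listed spots are validated to be edge spots and returned — the
    faithful mode for pleural-surface selection.  Otherwise the automated
    default returns the edge spots of the largest connected tissue
    component that touch the exterior background (background reachable
    from off-array space), i.e. the outer tissue boundary, excluding the
    rims of interior holes.  ``retained_flags`` marks the tissue spots
    for the automated mode; it defaults to the edge-flag universe being
    treated as the whole of ``grid``.
    """
    edge = np.asarray(edge_flags, dtype=bool)
    if edge.size != len(grid):
        raise ValueError("edge_flags must align with grid rows")
    edge_ids = set(grid.loc[edge, "spot_id"])

    if manual_file is not None:
        ids = []
        for line in Path(manual_file).read_text().splitlines():
            token = line.split("#", 1)[0].strip()
            if token:
                ids.append(token)
        bad = [i for i in ids if i not in edge_ids]
        if bad:
            raise ValueError(
                f"manual border spots are not tissue-edge spots: {', '.join(bad)}"
            )
        return pd.Index(ids, name="spot_id")

    if retained_flags is None:
        retained = np.ones(len(grid), dtype=bool)
    else:
        retained = np.asarray(retained_flags, dtype=bool)
    tissue_pos = {
        (int(r), int(c))
        for r, c, keep in zip(grid["array_row"], grid["array_col"], retained)
        if keep
    }
    if not tissue_pos:
        raise ValueError("no retained tissue spots to trace a border from")
    largest = max(_connected_components(tissue_pos), key=len)
    exterior = _exterior_background(tissue_pos)
    border_pos = {
        p for p in largest
        if any((p[0] + dr, p[1] + dc) in exterior for dr, dc in _OFFSETS)
    }
    mask = np.array(
        [
            (int(r), int(c)) in border_pos
            for r, c in zip(grid["array_row"], grid["array_col"])
        ]
    )
    return pd.Index(grid.loc[mask & edge, "spot_id"], name="spot_id")


def _connected_components(positions: set[tuple[int, int]]) -> list[set]:
    seen: set[tuple[int, int]] = set()
    comps = []
    for start in positions:
        if start in seen:
            continue
        comp = {start}
        queue = deque([start])
        seen.add(start)
        while queue:
            r, c = queue.popleft()
            for dr, dc in _OFFSETS:
                nb = (r + dr, c + dc)
                if nb in positions and nb not in seen:
                    seen.add(nb)
                    comp.add(nb)
                    queue.append(nb)
        comps.append(comp)
    return comps


def _exterior_background(tissue_pos: set[tuple[int, int]]) -> set[tuple[int, int]]:
    """Background lattice positions reachable from outside the bounding box."""
    rs = [p[0] for p in tissue_pos]
    cs = [p[1] for p in tissue_pos]
    r_lo, r_hi = min(rs) - 1, max(rs) + 1
    c_lo, c_hi = min(cs) - 2, max(cs) + 2
    exterior: set[tuple[int, int]] = set()
    queue: deque[tuple[int, int]] = deque()
    for r in range(r_lo, r_hi + 1):
        for c in range(c_lo, c_hi + 1):
            if (r + c) % 2 != 0:
                continue
            on_rim = r in (r_lo, r_hi) or c in (c_lo, c_lo + 1, c_hi - 1, c_hi)
            if on_rim and (r, c) not in tissue_pos:
                exterior.add((r, c))
                queue.append((r, c))
    while queue:
        r, c = queue.popleft()
        for dr, dc in _OFFSETS:
            nb = (r + dr, c + dc)
            if (r_lo <= nb[0] <= r_hi and c_lo <= nb[1] <= c_hi
                    and nb not in tissue_pos and nb not in exterior):
                exterior.add(nb)
                queue.append(nb)
    return exterior


def distance_to_border(
    spots: pd.DataFrame,
    border_ids: pd.Index | list,
) -> pd.Series:
    """Radial (Euclidean) pixel distance to the nearest border-spot center.

    Border spots get exactly 0.  Distances are center-to-center in
    full-resolution pixels.
    """
    border_ids = pd.Index(border_ids)
    if len(border_ids) == 0:
        raise ValueError("border set is empty")
    border = spots[spots["spot_id"].isin(border_ids)]
    if len(border) == 0:
        raise ValueError("no border spot found in the spot table")
    tree = cKDTree(border[["px_row", "px_col"]].to_numpy(dtype=float))
    dist, _ = tree.query(spots[["px_row", "px_col"]].to_numpy(dtype=float))
    return pd.Series(dist, index=pd.Index(spots["spot_id"], name="spot_id"),
                     name="dist_px")


def flag_peripheral(
    distances_px: pd.Series,
    scale_um_per_px: float,
    params: PeripheryParams = PeripheryParams(),
    *,
    mode: str = "um",
) -> pd.Series:
    """Peripheral ⟺ border distance not greater than the threshold.

    ``mode="um"`` applies ``threshold_um`` to distance · scale;
    ``mode="px"`` applies the fixed ``fallback_threshold_px`` cutoff.
    The boundary is inclusive in both modes.
    """
    if scale_um_per_px <= 0:
        raise ValueError("scale must be positive")
    if mode == "um":
        flags = distances_px * scale_um_per_px <= params.threshold_um
    elif mode == "px":
        flags = distances_px <= params.fallback_threshold_px
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return flags.rename("peripheral_flag")


def border_distance_table(
    spots: pd.DataFrame,
    border_ids: pd.Index | list,
    scale_um_per_px: float,
    params: PeripheryParams = PeripheryParams(),
) -> pd.DataFrame:
    """Per-spot TSV payload: distances, µm conversion, peripheral/border flags."""
    dist = distance_to_border(spots, border_ids)
    table = pd.DataFrame(
        {
            "spot_id": spots["spot_id"].to_numpy(),
            "dist_px": dist.to_numpy(),
            "dist_um": dist.to_numpy() * scale_um_per_px,
        }
    )
    table["peripheral_flag"] = flag_peripheral(dist, scale_um_per_px, params
                                               ).to_numpy()
    table["border_flag"] = table["spot_id"].isin(pd.Index(border_ids)).to_numpy()
    return table
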