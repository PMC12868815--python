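"""Image-based Visium spot quality control.

The QC chain for an eosin-stained section: convert the RGB image to
optical density (Beer–Lambert), discard transparent pixels, take the
largest covariance eigenvector as the eosin stain direction, project and
normalize against a reference pixel value, then summarize each capture
spot by the 90th-percentile OD of its pixels.  Spots whose summary falls
below a threshold are tissue-sparse and reclassified as background; a
retained spot adjacent to any background position is a tissue-edge spot.
A final filter removes spots with fewer than 200 RNA molecules.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse as sp
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

#: default all-channel OD threshold below which a pixel is transparent
DEFAULT_TRANSPARENCY_OD = 0.15


class StainEstimationError(ValueError):
    """Raised when the stain direction cannot be estimated."""


@dataclass
class StainBasis:
    """Stain absorbance direction(s) in OD space.

    ``eosin`` is the unit 3-vector of the dominant (eosin) stain;
    ``second`` optionally holds a counter-stain (hematoxylin).
    ``transparency_od`` is the all-channel OD threshold β below which a
    pixel counts as transparent background.
    """

    eosin: np.ndarray
    second: np.ndarray | None = None
    transparency_od: float = DEFAULT_TRANSPARENCY_OD

    def __post_init__(self) -> None:
        self.eosin = np.asarray(self.eosin, dtype=float)
        if self.eosin.shape != (3,) or not np.isclose(np.linalg.norm(self.eosin), 1.0):
            raise ValueError("eosin vector must be a unit 3-vector")
        if self.second is not None:
            self.second = np.asarray(self.second, dtype=float)
            if self.second.shape != (3,) or not np.isclose(
                np.linalg.norm(self.second), 1.0
            ):
                raise ValueError("second stain vector must be a unit 3-vector")

    @property
    def matrix(self) -> np.ndarray:
        """Stacked (n_stains, 3) stain matrix."""
        if self.second is None:
            return self.eosin[None, :]
        return np.stack([self.eosin, self.second])


def rgb_to_od(image: np.ndarray, background_intensity: float = 255.0,
              eps: float = 1.0) -> np.ndarray:
    """Convert RGB intensities to optical density.

    OD_c = −log10((I_c + ε) / I0), clipped at zero, so OD is 0 exactly at
    (and just below) the background intensity.  ε guards log(0) and is
    below the 8-bit quantization step.
    """
    if background_intensity <= 0:
        raise ValueError("background intensity must be positive")
    img = np.asarray(image, dtype=float)
    od = -np.log10((img + eps) / background_intensity)
    return np.clip(od, 0.0, None)


def transparency_mask(od: np.ndarray, beta: float = DEFAULT_TRANSPARENCY_OD) -> np.ndarray:
    """True where a pixel is NON-transparent: every OD channel above β."""
    return (np.asarray(od) > beta).all(axis=-1)


def estimate_eosin_vector(od: np.ndarray,
                          beta: float = DEFAULT_TRANSPARENCY_OD) -> StainBasis:
    """Largest covariance eigenvector of non-transparent OD pixels.

    The sign is fixed so the mean projection of the retained pixels onto
    the vector is positive (absorbances are non-negative).
    """
    od = np.asarray(od, dtype=float)
    pixels = od.reshape(-1, od.shape[-1])[transparency_mask(od, beta).ravel()]
    if len(pixels) < 3:
        raise StainEstimationError(
            f"only {len(pixels)} non-transparent pixels (need >= 3)"
        )
    cov = np.cov(pixels.T)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[-1] <= 1e-12:
        raise StainEstimationError("degenerate OD covariance (no stain variation)")
    vec = eigvecs[:, -1]
    if np.mean(pixels @ vec) < 0:
        vec = -vec
    return StainBasis(eosin=vec, transparency_od=beta)


def normalize_eosin(
    od: np.ndarray,
    basis: StainBasis,
    reference_value: float = 1.0,
    reference_quantile: float = 0.99,
) -> np.ndarray:
    """Project OD onto the eosin direction and normalize to a reference.

    The projection image is rescaled so that its ``reference_quantile``
    over non-transparent pixels equals ``reference_value``; the result is
    a single-channel grayscale eosin-OD image, invariant to global OD
    scaling (and hence to exposure).
    """
    if reference_value <= 0:
        raise ValueError("reference value must be positive")
    od = np.asarray(od, dtype=float)
    proj = od @ basis.eosin
    keep = transparency_mask(od, basis.transparency_od)
    if not keep.any():
        raise StainEstimationError("no non-transparent pixels to normalize against")
    ref = np.quantile(proj[keep], reference_quantile)
    if ref <= 0:
        raise StainEstimationError("zero projection spread; cannot normalize")
    return proj * (reference_value / ref)


def spot_od_quantile(
    gray: np.ndarray,
    grid: pd.DataFrame,
    radius_px: float,
    q: float = 0.90,
) -> pd.Series:
    """Per-spot q-quantile of grayscale values within each capture disk.

    Uses the linear-interpolation quantile definition.  A spot whose disk
    covers no pixel gets NaN (logged).  Returns a Series indexed by
    ``spot_id``.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError("q must lie in (0, 1]")
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    gray = np.asarray(gray, dtype=float)
    h, w = gray.shape

    r = int(np.ceil(radius_px))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    inside = dy**2 + dx**2 <= radius_px**2
    dy, dx = dy[inside], dx[inside]

    out = np.full(len(grid), np.nan)
    rows = np.rint(grid["px_row"].to_numpy(dtype=float)).astype(int)
    cols = np.rint(grid["px_col"].to_numpy(dtype=float)).astype(int)
    for i, (cy, cx) in enumerate(zip(rows, cols)):
        yy, xx = cy + dy, cx + dx
        ok = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
        if not ok.any():
            logger.warning("spot %s: capture disk covers no pixels",
                           grid["spot_id"].iloc[i])
            continue
        out[i] = np.quantile(gray[yy[ok], xx[ok]], q)
    return pd.Series(out, index=pd.Index(grid["spot_id"], name="spot_id"),
                     name=f"q{int(round(q * 100))}_od")


def otsu_sparse_threshold(qvals: pd.Series | np.ndarray, nbins: int = 256) -> float:
    """Otsu split of the per-spot quantile distribution (default sparse cut).

    The histogram Otsu value is the center of the last low-class bin,
    which can sit below values inside that same bin; the returned
    threshold is therefore snapped to the midpoint of the data gap at the
    Otsu cut, so the induced two-class partition is reproduced exactly by
    a ``value < threshold`` rule.
    """
    vals = np.asarray(qvals, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2 or np.ptp(vals) == 0:
        raise ValueError("need at least two distinct quantile values for Otsu")
    t0 = float(threshold_otsu(vals, nbins=nbins))
    upper_edge = t0 + np.ptp(vals) / nbins / 2.0
    low = vals[vals <= upper_edge]
    high = vals[vals > upper_edge]
    if low.size == 0 or high.size == 0:
        return t0
    return float((low.max() + high.min()) / 2.0)


def flag_sparse_spots(qvals: pd.Series, threshold: float) -> pd.Series:
    """Tissue-sparse ⟺ per-spot quantile OD strictly below ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return (qvals < threshold).rename("sparse_flag")


def label_edge_spots(grid: pd.DataFrame, background_flags: pd.Series | np.ndarray
                     ) -> pd.Series:
    """Edge flags: a retained spot with ≥1 background/off-array hex neighbor.

    ``background_flags`` aligns with ``grid`` rows; positions not present
    in ``grid`` (off the array) count as background.  Background spots
    themselves get False (edge status is defined only for tissue spots).
    """
    background = np.asarray(background_flags, dtype=bool)
    if background.size != len(grid):
        raise ValueError("background_flags must align with grid rows")
    tissue_pos = {
        (r, c)
        for r, c, bg in zip(grid["array_row"], grid["array_col"], background)
        if not bg
    }
    offsets = ((0, -2), (0, 2), (-1, -1), (-1, 1), (1, -1), (1, 1))
    flags = np.zeros(len(grid), dtype=bool)
    for i, (r, c, bg) in enumerate(
        zip(grid["array_row"], grid["array_col"], background)
    ):
        if bg:
            continue
        # all six lattice positions count: off-array neighbors are background
        flags[i] = any((r + dr, c + dc) not in tissue_pos for dr, dc in offsets)
    return pd.Series(flags, index=pd.Index(grid["spot_id"], name="spot_id"),
                     name="edge_flag")


def filter_min_counts(counts, min_total: int = 200) -> np.ndarray:
    """Boolean mask of spots (columns) whose total count is ≥ ``min_total``.

    Order-preserving; the retained set of a retained set is itself
    (idempotence).
    """
    if min_total < 0:
        raise ValueError("min_total must be non-negative")
    if sp.issparse(counts):
        totals = np.asarray(counts.sum(axis=0)).ravel()
    else:
        totals = np.asarray(counts).sum(axis=0)
    return totals >= min_total


def spot_qc_table(
    grid: pd.DataFrame,
    qvals: pd.Series,
    counts,
    *,
    sparse_threshold: float | None = None,
    min_total: int = 200,
) -> pd.DataFrame:
    """Assemble the per-spot QC table and apply the full filter chain.

    Filter order: 10x in-tissue flag → 90th-quantile sparse filter →
    minimum-count filter; edge labels are computed on the final retained
    set.  ``counts`` columns must align with the in-tissue spots of
    ``grid`` in order.  With ``sparse_threshold=None`` the cut is the
    Otsu split of the in-tissue quantile distribution.
    """
    in_tissue = grid["in_tissue"].to_numpy(dtype=bool)
    q_tissue = qvals.loc[grid.loc[in_tissue, "spot_id"]]
    if sparse_threshold is None:
        sparse_threshold = otsu_sparse_threshold(q_tissue)
    sparse_t = flag_sparse_spots(q_tissue, sparse_threshold)

    if sp.issparse(counts):
        totals = np.asarray(counts.sum(axis=0)).ravel()
    else:
        totals = np.asarray(counts).sum(axis=0)
    if totals.size != int(in_tissue.sum()):
        raise ValueError("counts columns must align with in-tissue spots")
    count_pass = totals >= min_total

    table = grid[["spot_id", "array_row", "array_col", "px_row", "px_col",
                  "in_tissue"]].copy()
    table["q90_od"] = qvals.reindex(table["spot_id"]).to_numpy()
    table["sparse_flag"] = False
    table.loc[in_tissue, "sparse_flag"] = sparse_t.to_numpy()
    table["total_counts"] = 0
    table.loc[in_tissue, "total_counts"] = totals
    table["min_count_pass"] = False
    table.loc[in_tissue, "min_count_pass"] = count_pass
    table["retained"] = (
        table["in_tissue"].astype(bool)
        & ~table["sparse_flag"]
        & table["min_count_pass"]
    )
    table["edge_flag"] = label_edge_spots(grid, ~table["retained"].to_numpy()
                                          ).to_numpy()
    if table["sparse_flag"].any():
        logger.info(
            "QC: %d in-tissue, %d tissue-sparse, %d below %d counts, %d retained",
            in_tissue.sum(), int(table["sparse_flag"].sum()),
            int((~count_pass).sum()), min_total, int(table["retained"].sum()),
        )
    return table
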