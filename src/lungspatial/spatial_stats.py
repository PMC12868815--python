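"""Ripley's K/L spatial-organization statistics for categorical spots.

For each sample and spot type, the variance-stabilized Ripley's L
function L(r) = sqrt(K(r)/π) is computed over a radius grid from the
uncorrected estimator

    K̂(r) = |A| / (n (n−1)) · Σ_{i≠j} 1(d_ij ≤ r).

L(r) > r indicates clustering of that type at scale r.  Because Visium
spots sit on a fixed 55/100 µm lattice, the natural null is random
labeling — permuting type labels over the retained spot positions —
rather than a homogeneous Poisson process; pointwise percentile
envelopes under that null are provided.  Sample-level curves are pooled
by developmental stage and smoothed with tricube-weighted local linear
regression (loess).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)


class UndefinedCurveError(ValueError):
    """Ripley curve requested for fewer than two points."""


@dataclass
class Window:
    """Observation window: area and the radius grid.

    ``area`` is in squared coordinate units (pixels² for pixel input);
    ``radii`` must be non-negative and strictly increasing.
    """

    area: float
    radii: np.ndarray
    mode: str = "bbox"
    #: bounding-box side lengths, kept for the translation edge correction
    sides: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        if self.area <= 0:
            raise ValueError("window area must be positive")
        if self.radii.size == 0 or self.radii[0] < 0 or np.any(
            np.diff(self.radii) <= 0
        ):
            raise ValueError("radii must be non-negative and strictly increasing")

    @classmethod
    def from_points(
        cls,
        points: np.ndarray,
        n_radii: int = 50,
        mode: str = "bbox",
        max_radius: float | None = None,
    ) -> "Window":
        """Window over the bounding box (default) or convex hull of points.

        The default radius grid is ``n_radii`` equally spaced radii from 0
        to half the bounding box's shorter side.
        """
        pts = np.asarray(points, dtype=float)
        spans = pts.max(axis=0) - pts.min(axis=0)
        if np.any(spans <= 0):
            raise ValueError("points are degenerate (zero-extent window)")
        if mode == "bbox":
            area = float(spans.prod())
        elif mode == "hull":
            area = float(ConvexHull(pts).volume)
        else:
            raise ValueError(f"unknown window mode {mode!r}")
        if max_radius is None:
            max_radius = float(spans.min()) / 2.0
        radii = np.linspace(0.0, max_radius, n_radii)
        return cls(area=area, radii=radii, mode=mode,
                   sides=(float(spans[0]), float(spans[1])))


def ripley_l(
    points: np.ndarray,
    window: Window,
    *,
    edge_correction: str = "none",
) -> pd.DataFrame:
    """Ripley's K and variance-stabilized L over the window's radius grid.

    ``edge_correction="none"`` (default) is the uncorrected estimator;
    ``"translation"`` weights each pair by |A| / ((Dx−|dx|)(Dy−|dy|)).
    Returns a DataFrame with columns ``r, K, L``; requires n ≥ 2 points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = len(pts)
    if n < 2:
        raise UndefinedCurveError(f"Ripley curve undefined for n = {n} points")
    radii = window.radii
    d = pdist(pts)

    if edge_correction == "none":
        order = np.sort(d)
        # ordered pairs = 2 × unordered pairs within radius
        pair_counts = 2.0 * np.searchsorted(order, radii, side="right")
        k = window.area / (n * (n - 1)) * pair_counts
    elif edge_correction == "translation":
        if window.sides is None:
            raise ValueError("translation correction needs window side lengths")
        dx = np.abs(pdist(pts[:, :1]))
        dy = np.abs(pdist(pts[:, 1:]))
        overlap = (window.sides[0] - dx) * (window.sides[1] - dy)
        # pairs spanning a full window side have no valid translation
        w = np.where(overlap > 0, window.area / np.where(overlap > 0, overlap, 1.0),
                     0.0)
        k = np.array([2.0 * w[d <= r].sum() for r in radii]) / (n * (n - 1)) \
            * window.area
    else:
        raise ValueError(f"unknown edge correction {edge_correction!r}")

    return pd.DataFrame({"r": radii, "K": k, "L": np.sqrt(k / np.pi)})


def ripley_by_type(
    points: np.ndarray,
    labels: np.ndarray,
    window: Window,
    type_names: list[str] | tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-type Ripley curves; types with fewer than 2 spots are skipped."""
    labels = np.asarray(labels)
    frames = []
    for t in pd.unique(labels):
        pts = np.asarray(points)[labels == t]
        if len(pts) < 2:
            logger.warning("spot type %r has %d spot(s); Ripley curve skipped",
                           t, len(pts))
            continue
        curve = ripley_l(pts, window)
        curve.insert(0, "spot_type", t if type_names is None else type_names[t])
        curve["n_points"] = len(pts)
        frames.append(curve)
    if not frames:
        raise UndefinedCurveError("no spot type has two or more points")
    return pd.concat(frames, ignore_index=True)


def random_label_envelope(
    points: np.ndarray,
    type_counts: dict,
    window: Window,
    n_sim: int = 99,
    seed: int | np.random.Generator = 0,
    *,
    lower_pct: float = 2.5,
    upper_pct: float = 97.5,
) -> dict:
    """Pointwise random-labeling envelopes of L(r) per spot type.

    Labels are reassigned uniformly at random without replacement over
    the fixed retained-spot positions ``n_sim`` times; for each type the
    (lower_pct, upper_pct) pointwise percentiles of the simulated L
    curves form the envelope.  Types with count < 2 are skipped.
    Deterministic given ``seed``.
    """
    if n_sim < 39:
        raise ValueError("need at least 39 simulations for a 95% envelope")
    pts = np.asarray(points, dtype=float)
    rng = np.random.default_rng(seed)
    counts = {t: int(c) for t, c in type_counts.items()}
    if sum(counts.values()) > len(pts):
        raise ValueError("type counts exceed the number of spots")

    sims: dict = {t: [] for t, c in counts.items() if c >= 2}
    for t, c in counts.items():
        if c < 2:
            logger.warning("type %r has count %d < 2; envelope skipped", t, c)
    for _ in range(n_sim):
        perm = rng.permutation(len(pts))
        start = 0
        for t, c in counts.items():
            idx = perm[start:start + c]
            start += c
            if c >= 2:
                sims[t].append(ripley_l(pts[idx], window)["L"].to_numpy())
    out = {}
    for t, curves in sims.items():
        arr = np.vstack(curves)
        out[t] = pd.DataFrame(
            {
                "r": window.radii,
                "env_lo": np.percentile(arr, lower_pct, axis=0),
                "env_hi": np.percentile(arr, upper_pct, axis=0),
            }
        )
    return out


def loess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.75,
    degree: int = 1,
    x_out: np.ndarray | None = None,
) -> np.ndarray:
    """Tricube-weighted local polynomial (default linear) regression.

    At each query point the ``span`` fraction of nearest observations is
    weighted by (1 − (d/h)³)³ with h the span radius, and a degree-
    ``degree`` weighted least squares fit is evaluated.  Query points
    whose window holds fewer than degree + 1 points with positive weight
    yield NaN.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct x values")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    if x_out is None:
        x_out = x
    x_out = np.asarray(x_out, dtype=float).ravel()

    n = x.size
    k = max(int(np.ceil(span * n)), degree + 1)
    k = min(k, n)
    fitted = np.full(x_out.size, np.nan)
    for i, x0 in enumerate(x_out):
        d = np.abs(x - x0)
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            # all window points coincide with x0; fall back to their mean
            fitted[i] = y[d == 0].mean()
            continue
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        active = w > 0
        if np.unique(x[active]).size < degree + 1:
            continue
        design = np.vander(x[active] - x0, degree + 1, increasing=True)
        wts = w[active]
        lhs = design.T * wts @ design
        rhs = design.T @ (wts * y[active])
        try:
            beta = np.linalg.solve(lhs, rhs)
        except np.linalg.LinAlgError:
            beta, *_ = np.linalg.lstsq(lhs, rhs, rcond=None)
        fitted[i] = beta[0]
    return fitted


def aggregate_stage_curves(
    curves: pd.DataFrame,
    span: float = 0.75,
    common_r: np.ndarray | None = None,
) -> pd.DataFrame:
    """Pool per-sample Ripley curves by (stage, spot type) and loess-smooth.

    ``curves`` is long-format with columns ``sample, stage, spot_type, r,
    L``.  All (r, L) points of a cell are pooled and smoothed onto
    ``common_r`` (default: 50 points spanning the pooled radius range).
    Cells with no curve are omitted with a warning.  Returns columns
    ``stage, spot_type, r, L, n_samples``.
    """
    required = {"sample", "stage", "spot_type", "r", "L"}
    missing = required - set(curves.columns)
    if missing:
        raise ValueError(f"curves table lacks columns: {sorted(missing)}")
    if common_r is None:
        common_r = np.linspace(curves["r"].min(), curves["r"].max(), 50)

    frames = []
    for (stage, spot_type), cell in curves.groupby(["stage", "spot_type"],
                                                   sort=True):
        n_samples = cell["sample"].nunique()
        smoothed = loess_smooth(cell["r"].to_numpy(), cell["L"].to_numpy(),
                                span=span, x_out=common_r)
        frames.append(
            pd.DataFrame(
                {
                    "stage": stage,
                    "spot_type": spot_type,
                    "r": common_r,
                    "L": smoothed,
                    "n_samples": n_samples,
                }
            )
        )
    if not frames:
        logger.warning("no (stage, spot type) cell had any curve to aggregate")
        return pd.DataFrame(columns=["stage", "spot_type", "r", "L", "n_samples"])
    return pd.concat(frames, ignore_index=True)
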