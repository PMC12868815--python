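"""Synthetic multi-sample Visium-like study generator.

Produces Space Ranger-style per-sample bundles (position table,
scale-factors record, eosin-stained image, MatrixMarket counts, study
metadata) with known ground truth, emulating the statistical structure a
prenatal-lung spot analysis assumes:

* a parity hex lattice of 55 µm spots at 100 µm spacing,
* spatially clustered categorical spot types (10 lung spot classes),
* negative-binomial counts with type-specific marker genes and a
  Y-chromosome male-signature block,
* Beer–Lambert-rendered two-stain RGB images with transparent background
  and a planted fraction of tissue-sparse spots,
* a two-stage design (6 pseudoglandular + 6 canalicular samples) with a
  configurable composition shift and clustering-intensity shift between
  stages.

Everything is deterministic given ``SyntheticStudyConfig.random_seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import sparse
from scipy.io import mmwrite
from scipy.spatial import cKDTree
from skimage.draw import disk as _disk

from .composition import MALE_SIGNATURE_GENES
from .grids import GridGeometry, make_hex_grid
from .stain_qc import StainBasis

#: The ten spot classes annotated in mid-gestation lung Visium sections.
SPOT_TYPES: tuple[str, ...] = (
    "distal_parenchyma",
    "distal_airway",
    "proximal_airway",
    "mesenchyme_parenchyma",
    "mesenchyme_vessel_adjacent",
    "pulmonary_vessels",
    "pulmonary_vessels_small",
    "megakaryocyte_infiltrated_parenchyma",
    "lymphatic_tissue",
    "cartilage",
)

# Ruifrok-Johnston OD absorbance directions for hematoxylin and eosin.
EOSIN_OD = np.array([0.07, 0.99, 0.11]) / np.linalg.norm([0.07, 0.99, 0.11])
HEMATOXYLIN_OD = np.array([0.65, 0.70, 0.29]) / np.linalg.norm([0.65, 0.70, 0.29])

_PSEUDOGLANDULAR = {
    "distal_parenchyma": 0.25,
    "distal_airway": 0.10,
    "proximal_airway": 0.05,
    "mesenchyme_parenchyma": 0.25,
    "mesenchyme_vessel_adjacent": 0.12,
    "pulmonary_vessels": 0.08,
    "pulmonary_vessels_small": 0.05,
    "megakaryocyte_infiltrated_parenchyma": 0.04,
    "lymphatic_tissue": 0.03,
    "cartilage": 0.03,
}
# Canalicular stage: distal (alveolar) parenchyma up, mesenchymal
# parenchyma down — the developmental shift the composition tests target.
_CANALICULAR = dict(
    _PSEUDOGLANDULAR, distal_parenchyma=0.40, mesenchyme_parenchyma=0.10
)


def _stage_defaults() -> dict[str, np.ndarray]:
    return {
        "pseudoglandular": np.array([_PSEUDOGLANDULAR[t] for t in SPOT_TYPES]),
        "canalicular": np.array([_CANALICULAR[t] for t in SPOT_TYPES]),
    }


@dataclass
class SyntheticStudyConfig:
    """Study-level parameters of the generator.

    Defaults mirror a 12-sample two-stage design: six pseudoglandular
    samples (13–16 weeks) and six canalicular samples (17–20 weeks),
    mixed sexes, four trisomy-21 cases, tighter spot-type clustering in
    the canalicular stage and a +0.15 shift of distal parenchyma.
    """

    n_samples_per_stage: int = 6
    stage_order: tuple[str, str] = ("pseudoglandular", "canalicular")
    stage_composition: dict[str, np.ndarray] = field(default_factory=_stage_defaults)
    #: Gaussian positional-noise scale of the type field, µm; lower = tighter clusters.
    clustering_dispersion: dict[str, float] = field(
        default_factory=lambda: {"pseudoglandular": 300.0, "canalicular": 150.0}
    )
    n_type_centers: int = 100
    geometry: GridGeometry = field(default_factory=GridGeometry)
    tissue_radius_frac: float = 0.9

    # count model
    n_genes: int = 2000
    markers_per_type: int = 20
    nb_mean: float = 6.0
    baseline_mean: float = 0.25
    male_mean: float = 3.0
    nb_dispersion: float = 2.0
    sparse_spot_fraction: float = 0.05
    #: multiplicative shrinkage of all gene means in tissue-sparse spots
    sparse_count_factor: float = 0.1

    # image model
    background_intensity: float = 255.0
    eosin_mean_od: float = 1.3
    hematoxylin_mean_od: float = 0.1

    # per-sample metadata (Table-1-like 12-sample design)
    gestational_weeks: tuple[int, ...] = (13, 13, 15, 16, 16, 16, 17, 17, 18, 18, 19, 20)
    sex_assignments: tuple[str, ...] = (
        "female", "male", "male", "female", "female", "male",
        "female", "female", "female", "female", "male", "male",
    )
    conditions: tuple[str, ...] = (
        "normal", "normal", "normal", "trisomy21", "normal", "trisomy21",
        "normal", "trisomy21", "normal", "normal", "trisomy21", "normal",
    )
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_stage < 1:
            raise ValueError("need at least one sample per stage")
        for stage, props in self.stage_composition.items():
            props = np.asarray(props, dtype=float)
            if props.shape != (len(SPOT_TYPES),):
                raise ValueError(f"{stage}: need {len(SPOT_TYPES)} type proportions")
            if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
                raise ValueError(f"{stage}: proportions must be >= 0 and sum to 1")
            self.stage_composition[stage] = props
        if any(d <= 0 for d in self.clustering_dispersion.values()):
            raise ValueError("clustering dispersions must be positive")
        if not 0.0 <= self.sparse_spot_fraction <= 1.0:
            raise ValueError("sparse_spot_fraction must lie in [0, 1]")
        if self.nb_mean < 0 or self.baseline_mean < 0 or self.male_mean < 0:
            raise ValueError("negative-binomial means must be non-negative")
        if self.nb_dispersion <= 0:
            raise ValueError("negative-binomial dispersion must be positive")
        n = self.n_samples()
        for name in ("gestational_weeks", "sex_assignments", "conditions"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have one entry per sample ({n})")

    def n_samples(self) -> int:
        return self.n_samples_per_stage * len(self.stage_order)

    def sample_table(self) -> pd.DataFrame:
        """Study-level metadata table (one row per sample)."""
        stages = [s for s in self.stage_order for _ in range(self.n_samples_per_stage)]
        names = [f"sample_{i + 1:02d}" for i in range(self.n_samples())]
        return pd.DataFrame(
            {
                "sample": names,
                "gestational_week": list(self.gestational_weeks),
                "stage": stages,
                "condition": list(self.conditions),
                "sex": list(self.sex_assignments),
            }
        )


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    spots: pd.DataFrame      # sample, spot_id, true_type, tissue_sparse
    samples: pd.DataFrame    # sample, gestational_week, stage, condition, sex
    genes: pd.DataFrame      # gene, marker_type
    stain_basis: StainBasis


# ---------------------------------------------------------------------------
# type field


def _largest_remainder(proportions: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation proportional to ``proportions`` summing to total."""
    quota = proportions * total
    alloc = np.floor(quota).astype(int)
    remainder = total - alloc.sum()
    if remainder > 0:
        order = np.argsort(-(quota - alloc), kind="stable")
        alloc[order[:remainder]] += 1
    return alloc


def simulate_type_field(
    grid: pd.DataFrame,
    proportions: np.ndarray,
    dispersion: float,
    seed: int | np.random.Generator,
    *,
    n_centers: int = 100,
    coord_cols: tuple[str, str] = ("px_row", "px_col"),
) -> np.ndarray:
    """Spatially clustered categorical labels over the spots of ``grid``.

    ``n_centers`` cluster centers are drawn uniformly over the bounding
    box of the spot coordinates, with the count per type proportional to
    its target proportion (largest-remainder allocation).  Each spot is
    labeled by the type of its nearest center under independent isotropic
    Gaussian positional noise of scale ``dispersion`` (same units as the
    coordinates) per spot-center comparison.  Small dispersions make
    nearby spots share a center — clustered type domains; as the
    dispersion grows the winning center becomes uniform over centers, so
    labels converge to independent multinomial draws with the configured
    proportions.  Proportions finer than 1 / n_centers need more centers.
    Deterministic given ``seed``.
    """
    proportions = np.asarray(proportions, dtype=float)
    if abs(proportions.sum() - 1.0) > 1e-9 or np.any(proportions < 0):
        raise ValueError("proportions must be non-negative and sum to 1")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if len(grid) == 0:
        raise ValueError("empty grid")
    rng = np.random.default_rng(seed)

    pts = grid[list(coord_cols)].to_numpy(dtype=float)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    centers = rng.uniform(lo, hi, size=(n_centers, 2))
    counts = _largest_remainder(proportions, n_centers)
    center_types = np.repeat(np.arange(len(proportions)), counts)

    # perturbed displacement of every spot-center pair; block over spots
    # to bound memory on large grids
    labels = np.empty(len(pts), dtype=np.intp)
    block = max(1, int(2_000_000 / n_centers))
    for start in range(0, len(pts), block):
        chunk = pts[start:start + block]
        disp = chunk[:, None, :] - centers[None, :, :]
        disp = disp + rng.normal(scale=dispersion, size=disp.shape)
        nearest = np.argmin((disp ** 2).sum(axis=2), axis=1)
        labels[start:start + block] = center_types[nearest]
    return labels


# ---------------------------------------------------------------------------
# counts


def build_gene_panel(
    n_genes: int,
    markers_per_type: int,
    type_names: tuple[str, ...] = SPOT_TYPES,
) -> pd.DataFrame:
    """Gene list: per-type markers, the 7 male-signature genes, background."""
    if markers_per_type < 1:
        raise ValueError("markers_per_type must be >= 1")
    names, roles = [], []
    for t in type_names:
        for j in range(markers_per_type):
            names.append(f"{t.upper()}_M{j + 1}")
            roles.append(t)
    names.extend(MALE_SIGNATURE_GENES)
    roles.extend(["male_signature"] * len(MALE_SIGNATURE_GENES))
    n_bg = n_genes - len(names)
    if n_bg < 0:
        raise ValueError("n_genes too small for the marker panel")
    names.extend(f"BG{j + 1}" for j in range(n_bg))
    roles.extend(["background"] * n_bg)
    return pd.DataFrame({"gene": names, "marker_type": roles})


def simulate_counts(
    labels: np.ndarray,
    panel: pd.DataFrame,
    sex: str,
    seed: int | np.random.Generator,
    *,
    type_names: tuple[str, ...] = SPOT_TYPES,
    nb_mean: float = 6.0,
    baseline_mean: float = 0.25,
    male_mean: float = 3.0,
    nb_dispersion: float = 2.0,
    sparse_flags: np.ndarray | None = None,
    sparse_count_factor: float = 0.1,
) -> sparse.csr_matrix:
    """Negative-binomial genes × spots counts for one sample.

    Marker genes have mean ``nb_mean`` in spots of their own type and
    ``baseline_mean`` elsewhere; the male-signature genes have mean
    ``male_mean`` iff ``sex == "male"`` and are exactly zero otherwise;
    tissue-sparse spots have all means shrunk by ``sparse_count_factor``
    so their totals fall below the minimum-count QC threshold.
    """
    if nb_mean < 0 or baseline_mean < 0 or male_mean < 0:
        raise ValueError("negative-binomial means must be non-negative")
    if nb_dispersion <= 0:
        raise ValueError("negative-binomial dispersion must be positive")
    labels = np.asarray(labels)
    if labels.size < 1:
        raise ValueError("need at least one spot")
    rng = np.random.default_rng(seed)

    n_spots = labels.size
    roles = panel["marker_type"].to_numpy()
    means = np.full((len(panel), n_spots), baseline_mean, dtype=float)
    for k, t in enumerate(type_names):
        gene_rows = np.flatnonzero(roles == t)
        if gene_rows.size:
            means[np.ix_(gene_rows, labels == k)] = nb_mean
    male_rows = np.flatnonzero(roles == "male_signature")
    means[male_rows, :] = male_mean if sex == "male" else 0.0
    if sparse_flags is not None:
        means[:, np.asarray(sparse_flags, dtype=bool)] *= sparse_count_factor

    theta = nb_dispersion
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(means > 0, theta / (theta + means), 1.0)
    counts = rng.negative_binomial(theta, p)
    return sparse.csr_matrix(counts)


# ---------------------------------------------------------------------------
# image


def render_stain_image(
    concentration_maps: np.ndarray,
    basis: StainBasis,
    background_intensity: float = 255.0,
    *,
    grid: pd.DataFrame | None = None,
) -> np.ndarray:
    """Beer–Lambert forward render of per-pixel stain concentrations.

    ``concentration_maps`` has shape (n_stains, H, W); channel intensity
    is I_c = I0 · 10^(−Σ_s C_s · S_{s,c}), quantized to 8 bit by
    truncation.  Pixels with zero total concentration render exactly at
    the background intensity I0.  ``grid`` is accepted for interface
    symmetry with the other renderers and is not used.
    """
    conc = np.asarray(concentration_maps, dtype=float)
    if conc.ndim != 3:
        raise ValueError("concentration_maps must have shape (n_stains, H, W)")
    if np.any(conc < 0):
        raise ValueError("stain concentrations must be non-negative")
    vectors = basis.matrix
    if vectors.shape[0] != conc.shape[0]:
        raise ValueError(
            f"{conc.shape[0]} concentration maps but {vectors.shape[0]} stain vectors"
        )
    od = np.tensordot(conc, vectors, axes=(0, 0))  # (H, W, 3)
    img = background_intensity * np.power(10.0, -od)
    return np.clip(np.floor(img), 0, 255).astype(np.uint8)


def build_concentration_maps(
    grid: pd.DataFrame,
    sparse_flags: np.ndarray,
    geometry: GridGeometry,
    seed: int | np.random.Generator,
    *,
    eosin_mean_od: float = 1.3,
    hematoxylin_mean_od: float = 0.1,
    sparse_od_scale: float = 0.03,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Per-pixel (eosin, hematoxylin) concentration fields for one sample.

    Each in-tissue spot paints a disk of its capture diameter.  Non-sparse
    spots draw an eosin concentration from a shifted gamma (well separated
    from zero); tissue-sparse spots get a near-transparent trace.  An
    independent, much smaller hematoxylin concentration keeps eosin the
    dominant source of OD variance.
    """
    rng = np.random.default_rng(seed)
    tissue = grid[grid["in_tissue"] == 1]
    sparse_flags = np.asarray(sparse_flags, dtype=bool)
    if len(tissue) != sparse_flags.size:
        raise ValueError("sparse_flags must align with in-tissue spots")

    if shape is None:
        margin = int(np.ceil(geometry.spacing_px))
        h = int(grid["px_row"].max()) + margin + 1
        w = int(grid["px_col"].max()) + margin + 1
        shape = (h, w)
    maps = np.zeros((2, *shape), dtype=float)
    radius = geometry.spot_diameter_um / 2.0 / geometry.microns_per_pixel

    n = len(tissue)
    # shifted gamma: min 0.6·mean keeps dense spots far from the sparse trace
    base = 0.6 * eosin_mean_od
    eosin = base + rng.gamma(4.0, (eosin_mean_od - base) / 4.0, size=n)
    eosin[sparse_flags] = rng.uniform(0.2, 1.0, sparse_flags.sum()) * sparse_od_scale
    hema = rng.gamma(2.0, hematoxylin_mean_od / 2.0, size=n)
    hema[sparse_flags] = 0.0

    rows = tissue["px_row"].to_numpy()
    cols = tissue["px_col"].to_numpy()
    for i in range(n):
        rr, cc = _disk((rows[i], cols[i]), radius, shape=shape)
        maps[0, rr, cc] = eosin[i]
        maps[1, rr, cc] = hema[i]
    return maps


# ---------------------------------------------------------------------------
# study assembly


def _tissue_mask(grid: pd.DataFrame, geometry: GridGeometry, frac: float) -> np.ndarray:
    """Spots inside a central disk covering ``frac`` of the short half-extent."""
    pts = grid[["px_row", "px_col"]].to_numpy(dtype=float)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    center = (lo + hi) / 2.0
    radius = frac * (hi - lo).min() / 2.0
    return np.linalg.norm(pts - center, axis=1) <= radius


def simulate_sample(
    config: SyntheticStudyConfig,
    stage: str,
    sex: str,
    sample_index: int,
) -> dict:
    """All in-memory artifacts of one synthetic sample."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.random_seed, sample_index])
    )
    grid = make_hex_grid(config.geometry)
    grid["in_tissue"] = _tissue_mask(grid, config.geometry, config.tissue_radius_frac
                                     ).astype(np.int64)
    tissue = grid[grid["in_tissue"] == 1].reset_index(drop=True)
    if len(tissue) == 0:
        raise ValueError("tissue mask removed every spot; enlarge the grid")

    labels = simulate_type_field(
        tissue,
        config.stage_composition[stage],
        config.clustering_dispersion[stage] / config.geometry.microns_per_pixel,
        rng,
        n_centers=config.n_type_centers,
    )
    n_sparse = int(round(config.sparse_spot_fraction * len(tissue)))
    sparse_flags = np.zeros(len(tissue), dtype=bool)
    sparse_flags[rng.choice(len(tissue), size=n_sparse, replace=False)] = True

    panel = build_gene_panel(config.n_genes, config.markers_per_type)
    counts = simulate_counts(
        labels, panel, sex, rng,
        nb_mean=config.nb_mean, baseline_mean=config.baseline_mean,
        male_mean=config.male_mean, nb_dispersion=config.nb_dispersion,
        sparse_flags=sparse_flags, sparse_count_factor=config.sparse_count_factor,
    )

    basis = StainBasis(eosin=EOSIN_OD.copy(), second=HEMATOXYLIN_OD.copy())
    conc = build_concentration_maps(
        grid, sparse_flags, config.geometry, rng,
        eosin_mean_od=config.eosin_mean_od,
        hematoxylin_mean_od=config.hematoxylin_mean_od,
    )
    image = render_stain_image(conc, basis, config.background_intensity)

    return {
        "grid": grid,
        "tissue": tissue,
        "labels": labels,
        "sparse_flags": sparse_flags,
        "panel": panel,
        "counts": counts,
        "image": image,
        "basis": basis,
    }


def write_bundle(sample_dir: Path, sample: dict, geometry: GridGeometry) -> None:
    """Write one Space Ranger-style bundle (v1 position-table dialect)."""
    sample_dir = Path(sample_dir)
    sample_dir.mkdir(parents=True, exist_ok=True)

    grid = sample["grid"]
    positions = grid[["spot_id", "in_tissue", "array_row", "array_col",
                      "px_row", "px_col"]]
    positions.to_csv(sample_dir / "tissue_positions_list.csv", header=False,
                     index=False)

    scalefactors = {
        "spot_diameter_fullres": geometry.spot_diameter_um / geometry.microns_per_pixel,
        "fiducial_diameter_fullres": 85.0 / geometry.microns_per_pixel,
        "tissue_hires_scalef": 1.0,
    }
    (sample_dir / "scalefactors_json.json").write_text(
        json.dumps(scalefactors, sort_keys=True, indent=1)
    )

    Image.fromarray(sample["image"]).save(sample_dir / "image_hires.png")

    mmwrite(sample_dir / "matrix.mtx", sparse.coo_matrix(sample["counts"]))
    panel = sample["panel"]
    pd.DataFrame({"gene_id": panel["gene"], "gene_name": panel["gene"],
                  "feature_type": "Gene Expression"}).to_csv(
        sample_dir / "features.tsv", sep="\t", header=False, index=False)
    sample["tissue"]["spot_id"].to_csv(sample_dir / "barcodes.tsv",
                                       header=False, index=False)

    truth = pd.DataFrame(
        {
            "spot_id": sample["tissue"]["spot_id"].to_numpy(),
            "true_type": [SPOT_TYPES[k] for k in sample["labels"]],
            "tissue_sparse": sample["sparse_flags"].astype(int),
        }
    )
    truth.to_csv(sample_dir / "ground_truth.tsv", sep="\t", index=False)


def generate_study(config: SyntheticStudyConfig, out_dir: str | Path) -> GroundTruth:
    """Generate a complete multi-sample study on disk.

    One directory per sample plus a study-level ``samples.tsv``; returns
    the :class:`GroundTruth`.  Byte-identical across runs at a fixed
    ``config.random_seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = config.sample_table()

    spot_frames = []
    panel = build_gene_panel(config.n_genes, config.markers_per_type)
    basis = StainBasis(eosin=EOSIN_OD.copy(), second=HEMATOXYLIN_OD.copy())
    for i, row in meta.iterrows():
        sample = simulate_sample(config, row["stage"], row["sex"], int(i))
        write_bundle(out_dir / row["sample"], sample, config.geometry)
        spot_frames.append(
            pd.DataFrame(
                {
                    "sample": row["sample"],
                    "spot_id": sample["tissue"]["spot_id"].to_numpy(),
                    "true_type": [SPOT_TYPES[k] for k in sample["labels"]],
                    "tissue_sparse": sample["sparse_flags"],
                }
            )
        )
    meta.to_csv(out_dir / "samples.tsv", sep="\t", index=False)
    return GroundTruth(
        spots=pd.concat(spot_frames, ignore_index=True),
        samples=meta,
        genes=panel,
        stain_basis=basis,
    )
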