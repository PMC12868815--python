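"""End-to-end orchestration: simulate → QC → geometry → Ripley → composition.

The pipeline consumes a YAML config (unknown keys rejected, thresholds
validated on load), runs each stage as a pure function of (inputs,
config, seed), writes all stage outputs as TSV/MTX into the output
directory, and records a manifest with a config hash so reruns are
verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import sparse
from scipy.io import mmwrite

from . import composition as comp_mod
from . import geometry as geom_mod
from . import io as io_mod
from . import spatial_stats, stain_qc, synthetic

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


@dataclass
class QCConfig:
    transparency_od: float = 0.15
    sparse_od_threshold: float | None = None   # None = Otsu split
    min_counts: int = 200
    spot_quantile: float = 0.90
    reference_value: float = 1.0
    reference_quantile: float = 0.99

    def validate(self) -> None:
        if self.transparency_od < 0:
            raise ConfigError("transparency_od must be >= 0")
        if self.min_counts < 0:
            raise ConfigError("min_counts must be >= 0")
        if not 0 < self.spot_quantile <= 1:
            raise ConfigError("spot_quantile must lie in (0, 1]")
        if not 0 < self.reference_quantile <= 1:
            raise ConfigError("reference_quantile must lie in (0, 1]")


@dataclass
class GeometryConfig:
    peripheral_um: float = 500.0
    fallback_threshold_px: float = 150.0
    threshold_mode: str = "um"                 # "um" or "px"
    manual_border_files: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.peripheral_um <= 0 or self.fallback_threshold_px <= 0:
            raise ConfigError("peripheral thresholds must be positive")
        if self.threshold_mode not in ("um", "px"):
            raise ConfigError("threshold_mode must be 'um' or 'px'")


@dataclass
class RipleyConfig:
    n_radii: int = 50
    loess_span: float = 0.75
    n_envelope_sim: int = 0                    # 0 = skip envelopes

    def validate(self) -> None:
        if self.n_radii < 2:
            raise ConfigError("need at least two radii")
        if not 0 < self.loess_span <= 1:
            raise ConfigError("loess_span must lie in (0, 1]")
        if self.n_envelope_sim not in (0,) and self.n_envelope_sim < 39:
            raise ConfigError("n_envelope_sim must be 0 or >= 39")


@dataclass
class CompositionConfig:
    n_perm: int = 9999
    target_type: str = "distal_parenchyma"
    sex_threshold: float = 0.2
    signature_max_rank: int = 1500

    def validate(self) -> None:
        if self.n_perm < 999:
            raise ConfigError("n_perm must be >= 999")
        if self.signature_max_rank < 1:
            raise ConfigError("signature_max_rank must be positive")


@dataclass
class StudyConfig:
    simulate: bool = True
    input_dir: str | None = None
    n_samples_per_stage: int = 6
    n_rows: int = 40
    n_cols: int = 60
    sparse_spot_fraction: float = 0.05

    def validate(self) -> None:
        if not self.simulate and self.input_dir is None:
            raise ConfigError("either simulate or provide input_dir")


@dataclass
class PipelineConfig:
    seed: int = 0
    study: StudyConfig = field(default_factory=StudyConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    ripley: RipleyConfig = field(default_factory=RipleyConfig)
    composition: CompositionConfig = field(default_factory=CompositionConfig)

    def validate(self) -> None:
        for section in (self.study, self.qc, self.geometry, self.ripley,
                        self.composition):
            section.validate()

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        def build(dc_type, payload, path):
            if not isinstance(payload, dict):
                raise ConfigError(f"config section '{path}' must be a mapping")
            names = {f.name for f in dataclasses.fields(dc_type)}
            unknown = set(payload) - names
            if unknown:
                raise ConfigError(
                    f"unknown config key(s) under '{path}': {sorted(unknown)}"
                )
            return dc_type(**payload)

        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        sections = {
            "study": StudyConfig, "qc": QCConfig, "geometry": GeometryConfig,
            "ripley": RipleyConfig, "composition": CompositionConfig,
        }
        kwargs = {
            name: build(sections[name], value or {}, name)
            if name in sections else value
            for name, value in data.items()
        }
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def run_sample_qc(bundle: io_mod.SampleBundle, qc_cfg: QCConfig) -> pd.DataFrame:
    """QC one sample: OD → eosin vector → normalize → spot q90 → filters."""
    od = stain_qc.rgb_to_od(bundle.image[..., :3])
    basis = stain_qc.estimate_eosin_vector(od, qc_cfg.transparency_od)
    gray = stain_qc.normalize_eosin(od, basis, qc_cfg.reference_value,
                                    qc_cfg.reference_quantile)
    radius_px = bundle.scalefactors["spot_diameter_fullres"] / 2.0
    qvals = stain_qc.spot_od_quantile(gray, bundle.positions, radius_px,
                                      qc_cfg.spot_quantile)
    return stain_qc.spot_qc_table(
        bundle.positions, qvals, bundle.counts,
        sparse_threshold=qc_cfg.sparse_od_threshold,
        min_total=qc_cfg.min_counts,
    )


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage; returns the in-memory result bundle.

    On a stage failure, partial outputs are kept and a ``FAILED`` marker
    naming the stage is written before the exception propagates.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # ------------------------------------------------------ simulate
        stage = "simulate"
        if config.study.simulate:
            study_dir = out_dir / "study"
            syn_cfg = synthetic.SyntheticStudyConfig(
                n_samples_per_stage=config.study.n_samples_per_stage,
                geometry=synthetic.GridGeometry(
                    n_rows=config.study.n_rows, n_cols=config.study.n_cols
                ),
                sparse_spot_fraction=config.study.sparse_spot_fraction,
                random_seed=config.seed,
            )
            synthetic.generate_study(syn_cfg, study_dir)
        else:
            study_dir = Path(config.study.input_dir)
        meta, bundles = io_mod.read_study(study_dir)

        # ------------------------------------------------------------ qc
        stage = "qc"
        qc_tables, annotations, curves, periph_rows = {}, [], [], []
        geo_tables: list[pd.DataFrame] = []
        sex_scores = {}
        pseudo_parts = []
        for _, srow in meta.iterrows():
            name = srow["sample"]
            bundle = bundles[name]
            qc = run_sample_qc(bundle, config.qc)
            qc.insert(0, "sample", name)
            qc_tables[name] = qc
            logger.info(
                "%s: %d in-tissue → %d retained", name,
                int(qc["in_tissue"].sum()), int(qc["retained"].sum()),
            )

            # ---------------------------------------------------- geometry
            stage = "geometry"
            mpp = geom_mod.microns_per_pixel(bundle.scalefactors)
            manual = config.geometry.manual_border_files.get(name)
            border = geom_mod.select_border_spots(
                bundle.positions, qc["edge_flag"].to_numpy(), manual,
                retained_flags=qc["retained"].to_numpy(),
            )
            retained = qc[qc["retained"]].reset_index(drop=True)
            params = geom_mod.PeripheryParams(
                threshold_um=config.geometry.peripheral_um,
                fallback_threshold_px=config.geometry.fallback_threshold_px,
            )
            geo = geom_mod.border_distance_table(retained, border, mpp, params)
            if config.geometry.threshold_mode == "px":
                geo["peripheral_flag"] = geom_mod.flag_peripheral(
                    geo["dist_px"], mpp, params, mode="px").to_numpy()
            geo.insert(0, "sample", name)
            geo_tables.append(geo)

            # types for retained spots from the bundle's annotation table
            stage = "annotation"
            if bundle.ground_truth is None:
                raise ConfigError(
                    f"{name}: no spot annotation table (ground_truth.tsv)"
                )
            types = bundle.ground_truth.set_index("spot_id")["true_type"]
            ann = retained[["spot_id"]].copy()
            ann["sample"] = name
            ann["spot_type"] = types.reindex(ann["spot_id"]).to_numpy()
            ann = ann.merge(geo[["spot_id", "peripheral_flag"]], on="spot_id")
            annotations.append(ann)
            periph_rows.append(
                {
                    "sample": name,
                    "peripheral": _type_freq(ann, config.composition.target_type,
                                             True),
                    "non_peripheral": _type_freq(
                        ann, config.composition.target_type, False),
                }
            )

            # ------------------------------------------------------ ripley
            stage = "ripley"
            pts = retained[["px_row", "px_col"]].to_numpy(dtype=float)
            window = spatial_stats.Window.from_points(pts, config.ripley.n_radii)
            sample_curves = spatial_stats.ripley_by_type(
                pts, ann["spot_type"].to_numpy(), window
            )
            sample_curves.insert(0, "sample", name)
            sample_curves.insert(1, "stage", srow["stage"])
            sample_curves["r_um"] = sample_curves["r"] * mpp
            sample_curves["L_um"] = sample_curves["L"] * mpp
            curves.append(sample_curves)

            # --------------------------------------------------- signature
            stage = "signature"
            totals = pd.Series(
                np.asarray(bundle.counts.sum(axis=1)).ravel(),
                index=bundle.genes["gene_name"].to_numpy(),
            )
            r_max = min(config.composition.signature_max_rank, totals.size - 1)
            sig = comp_mod.SignatureSet(comp_mod.MALE_SIGNATURE_GENES, r_max)
            sex_scores[name] = comp_mod.signature_score(totals, sig)

            pseudo_parts.append((name, bundle, ann))

        # ----------------------------------------------------- aggregate
        stage = "aggregate"
        all_curves = pd.concat(curves, ignore_index=True)
        # pool in micron units so samples with different scales are comparable
        agg_input = all_curves[["sample", "stage", "spot_type"]].copy()
        agg_input["r"] = all_curves["r_um"]
        agg_input["L"] = all_curves["L_um"]
        aggregated = spatial_stats.aggregate_stage_curves(
            agg_input, span=config.ripley.loess_span
        )

        # --------------------------------------------------- composition
        stage = "composition"
        ann_all = pd.concat(annotations, ignore_index=True)
        comp = comp_mod.composition_table(
            ann_all, meta, known_types=list(synthetic.SPOT_TYPES)
        )
        stage_tests = comp_mod.stage_composition_tests(comp)
        freq = comp.pivot_table(index="sample", columns="spot_type",
                                values="frequency", observed=False).fillna(0.0)
        cond = meta.set_index("sample").loc[freq.index, "condition"]
        perm = comp_mod.permutation_composition_test(
            freq, cond.to_numpy(), config.composition.n_perm, config.seed
        )
        periph = pd.DataFrame(periph_rows)
        try:
            tres = comp_mod.student_t_peripheral(
                periph["peripheral"], periph["non_peripheral"]
            )
            periph_stat = {"t": tres.statistic, "p": tres.pvalue}
        except ValueError as exc:
            periph_stat = {"t": float("nan"), "p": float("nan"),
                           "note": str(exc)}

        # pseudobulk across samples × spot types
        stage = "pseudobulk"
        gene_names = pseudo_parts[0][1].genes["gene_name"].to_numpy()
        counts_cat = sparse.hstack(
            [b.counts[:, _retained_cols(b, a)] for _, b, a in pseudo_parts]
        ).tocsr()
        sample_ids = np.concatenate(
            [np.repeat(n, len(a)) for n, _, a in pseudo_parts]
        )
        clusters = np.concatenate([a["spot_type"].to_numpy()
                                   for _, _, a in pseudo_parts])
        pseudobulk, colmeta = comp_mod.pseudobulk_aggregate(
            counts_cat, sample_ids, clusters, gene_names
        )
        colmeta = colmeta.merge(meta[["sample", "stage", "sex"]], on="sample")

        sex_calls = comp_mod.call_sex(pd.Series(sex_scores),
                                      config.composition.sex_threshold)
        sex_calls.insert(0, "sample", sex_calls.index)

        # --------------------------------------------------------- write
        stage = "write"
        pd.concat(qc_tables.values(), ignore_index=True).to_csv(
            out_dir / "qc_spots.tsv", sep="\t", index=False)
        pd.concat(geo_tables, ignore_index=True).to_csv(
            out_dir / "border_distance.tsv", sep="\t", index=False)
        all_curves.to_csv(out_dir / "ripley_curves.tsv", sep="\t", index=False)
        aggregated.to_csv(out_dir / "ripley_stage_aggregate.tsv", sep="\t",
                          index=False)
        comp.to_csv(out_dir / "composition.tsv", sep="\t", index=False)
        stage_tests.to_csv(out_dir / "composition_tests.tsv", sep="\t",
                           index=False)
        sex_calls.to_csv(out_dir / "sex_calls.tsv", sep="\t", index=False)
        mmwrite(out_dir / "pseudobulk.mtx",
                sparse.coo_matrix(pseudobulk.to_numpy()))
        colmeta.to_csv(out_dir / "pseudobulk_columns.tsv", sep="\t", index=False)
        pd.Series(gene_names, name="gene").to_csv(
            out_dir / "pseudobulk_genes.tsv", sep="\t", index=False)

        manifest = {
            "config": config.to_dict(),
            "config_sha256": _config_hash(config),
            "seed": config.seed,
            "permutation_test": {"statistic": perm.statistic,
                                 "pvalue": perm.pvalue, "n_perm": perm.n_perm},
            "peripheral_t_test": periph_stat,
            "n_spots": {
                name: {
                    "in_tissue": int(t["in_tissue"].sum()),
                    "retained": int(t["retained"].sum()),
                }
                for name, t in qc_tables.items()
            },
            "versions": _versions(),
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True, default=str)
        )
        return {
            "meta": meta,
            "qc": qc_tables,
            "curves": all_curves,
            "aggregated": aggregated,
            "composition": comp,
            "stage_tests": stage_tests,
            "permutation": perm,
            "peripheral_t": periph_stat,
            "sex_calls": sex_calls,
            "pseudobulk": pseudobulk,
            "pseudobulk_columns": colmeta,
            "manifest": manifest,
        }
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise


def _type_freq(ann: pd.DataFrame, target: str, peripheral: bool) -> float:
    region = ann[ann["peripheral_flag"] == peripheral]
    if len(region) == 0:
        return float("nan")
    return float((region["spot_type"] == target).mean())


def _retained_cols(bundle: io_mod.SampleBundle, ann: pd.DataFrame) -> np.ndarray:
    lookup = pd.Series(np.arange(len(bundle.barcodes)),
                       index=bundle.barcodes.to_numpy())
    return lookup.loc[ann["spot_id"]].to_numpy()


def _versions() -> dict:
    import scipy
    import skimage

    from . import __version__

    return {
        "lungspatial": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-image": skimage.__version__,
    }
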