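"""Readers for Space Ranger-style per-sample bundles.

A bundle directory holds ``tissue_positions_list.csv`` (headerless v1
dialect), ``scalefactors_json.json``, ``image_hires.png``, and a
MatrixMarket count triplet (``matrix.mtx`` + ``features.tsv`` +
``barcodes.tsv``); synthetic bundles additionally carry a
``ground_truth.tsv`` with the generator's spot labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import sparse
from scipy.io import mmread

POSITION_COLUMNS = [
    "spot_id", "in_tissue", "array_row", "array_col", "px_row", "px_col",
]


@dataclass
class SampleBundle:
    """One sample's on-disk artifacts, loaded."""

    name: str
    positions: pd.DataFrame
    scalefactors: dict
    image: np.ndarray
    counts: sparse.csr_matrix      # genes x barcodes
    genes: pd.DataFrame
    barcodes: pd.Series
    ground_truth: pd.DataFrame | None = None


def read_positions(path: str | Path) -> pd.DataFrame:
    """Headerless v1 tissue-position table."""
    df = pd.read_csv(path, header=None, names=POSITION_COLUMNS)
    if ((df["array_row"] + df["array_col"]) % 2 != 0).any():
        raise ValueError(f"{path}: positions violate the hex parity convention")
    return df


def read_scalefactors(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def read_counts(bundle_dir: str | Path):
    """MatrixMarket counts with gene/barcode sidecars."""
    bundle_dir = Path(bundle_dir)
    counts = sparse.csr_matrix(mmread(bundle_dir / "matrix.mtx"))
    genes = pd.read_csv(bundle_dir / "features.tsv", sep="\t", header=None,
                        names=["gene_id", "gene_name", "feature_type"])
    barcodes = pd.read_csv(bundle_dir / "barcodes.tsv", header=None
                           ).iloc[:, 0].rename("spot_id")
    if counts.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"{bundle_dir}: matrix is {counts.shape} but sidecars describe "
            f"({len(genes)}, {len(barcodes)})"
        )
    return counts, genes, barcodes


def read_bundle(bundle_dir: str | Path) -> SampleBundle:
    bundle_dir = Path(bundle_dir)
    counts, genes, barcodes = read_counts(bundle_dir)
    truth_path = bundle_dir / "ground_truth.tsv"
    return SampleBundle(
        name=bundle_dir.name,
        positions=read_positions(bundle_dir / "tissue_positions_list.csv"),
        scalefactors=read_scalefactors(bundle_dir / "scalefactors_json.json"),
        image=np.asarray(Image.open(bundle_dir / "image_hires.png")),
        counts=counts,
        genes=genes,
        barcodes=barcodes,
        ground_truth=pd.read_csv(truth_path, sep="\t") if truth_path.exists()
        else None,
    )


def read_study(study_dir: str | Path) -> tuple[pd.DataFrame, dict[str, SampleBundle]]:
    """Study metadata plus every sample bundle listed in samples.tsv."""
    study_dir = Path(study_dir)
    meta = pd.read_csv(study_dir / "samples.tsv", sep="\t")
    bundles = {s: read_bundle(study_dir / s) for s in meta["sample"]}
    return meta, bundles


def bundle_to_anndata(bundle: SampleBundle):
    """AnnData view of a bundle (spots × genes), spatial coords in .obsm."""
    import anndata as ad

    pos = bundle.positions.set_index("spot_id").loc[bundle.barcodes]
    adata = ad.AnnData(
        X=bundle.counts.T.tocsr(),
        obs=pos.reset_index().set_index("spot_id"),
        var=bundle.genes.set_index("gene_name"),
    )
    adata.obsm["spatial"] = pos[["px_col", "px_row"]].to_numpy()
    adata.uns["scalefactors"] = bundle.scalefactors
    return adata
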