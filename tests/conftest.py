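import numpy as np
import pytest

from lungspatial import GridGeometry
from lungspatial import stain_qc as sq
from lungspatial import synthetic as syn

SMALL_GEOM = GridGeometry(n_rows=24, n_cols=36)


@pytest.fixture(scope="session")
def full_sample():
    """One default-size simulated sample (grid, labels, counts, image)."""
    cfg = syn.SyntheticStudyConfig()
    return cfg, syn.simulate_sample(cfg, "pseudoglandular", "male", 0)


@pytest.fixture(scope="session")
def full_sample_qc(full_sample):
    """The QC chain run once on the default sample."""
    cfg, s = full_sample
    od = sq.rgb_to_od(s["image"])
    basis = sq.estimate_eosin_vector(od)
    gray = sq.normalize_eosin(od, basis)
    radius = cfg.geometry.spot_diameter_um / 2 / cfg.geometry.microns_per_pixel
    qvals = sq.spot_od_quantile(gray, s["grid"], radius, 0.9)
    qc = sq.spot_qc_table(s["grid"], qvals, s["counts"], min_total=200)
    return cfg, s, qvals, qc


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A complete small-grid 12-sample study written to disk."""
    cfg = syn.SyntheticStudyConfig(geometry=SMALL_GEOM, random_seed=7)
    out = tmp_path_factory.mktemp("study")
    truth = syn.generate_study(cfg, out)
    return cfg, out, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
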