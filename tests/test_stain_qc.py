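import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from lungspatial import GridGeometry, make_hex_grid
from lungspatial import stain_qc as sq
from lungspatial import synthetic as syn

UNIT_GRAY = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)


class TestRgbToOd:
    def test_background_pixel_zero_od(self):
        od = sq.rgb_to_od(np.full((1, 1, 3), 255.0), 255.0)
        assert (od == 0).all()

    def test_tenfold_attenuation_unit_od(self):
        od = sq.rgb_to_od(np.full((1, 1, 3), 25.5), 255.0)
        assert np.allclose(od, 1.0, atol=0.02)

    def test_all_256_intensities_finite_nonnegative(self):
        od = sq.rgb_to_od(np.arange(256, dtype=float).reshape(1, -1, 1), 255.0)
        assert np.isfinite(od).all() and (od >= 0).all()

    def test_invalid_background(self):
        with pytest.raises(ValueError):
            sq.rgb_to_od(np.zeros((1, 1, 3)), 0.0)


class TestEstimateEosinVector:
    def test_single_stain_recovery(self, rng):
        conc = rng.uniform(0.3, 2.0, size=(1, 40, 40))
        basis = sq.StainBasis(eosin=UNIT_GRAY)
        img = syn.render_stain_image(conc, basis, 255.0)
        est = sq.estimate_eosin_vector(sq.rgb_to_od(img))
        assert abs(est.eosin @ UNIT_GRAY) >= 0.999

    def test_two_stain_within_5_degrees(self):
        """When eosin dominates the OD variance the estimate stays within
        5° of the generator's eosin vector, across seeds."""
        geom = GridGeometry(n_rows=24, n_cols=40)
        grid = make_hex_grid(geom)
        basis = sq.StainBasis(eosin=syn.EOSIN_OD, second=syn.HEMATOXYLIN_OD)
        for seed in range(5):
            conc = syn.build_concentration_maps(
                grid, np.zeros(len(grid), dtype=bool), geom, seed)
            img = syn.render_stain_image(conc, basis, 255.0)
            est = sq.estimate_eosin_vector(sq.rgb_to_od(img))
            cos = np.clip(abs(est.eosin @ syn.EOSIN_OD), -1.0, 1.0)
            assert np.degrees(np.arccos(cos)) <= 5.0

    def test_constant_od_rejected(self):
        od = np.full((10, 10, 3), 0.5)
        with pytest.raises(sq.StainEstimationError, match="degenerate"):
            sq.estimate_eosin_vector(od)

    def test_too_few_pixels_rejected(self):
        od = np.zeros((5, 5, 3))  # everything transparent
        with pytest.raises(sq.StainEstimationError, match="non-transparent"):
            sq.estimate_eosin_vector(od)

    def test_invariant_to_pixel_order_and_scale(self, rng):
        od = rng.uniform(0.2, 1.5, size=(30, 30, 3))
        a = sq.estimate_eosin_vector(od).eosin
        shuffled = od.reshape(-1, 3)[rng.permutation(900)].reshape(30, 30, 3)
        b = sq.estimate_eosin_vector(shuffled).eosin
        c = sq.estimate_eosin_vector(2.5 * od).eosin
        assert np.allclose(abs(a @ b), 1.0)
        assert np.allclose(abs(a @ c), 1.0)


class TestNormalizeEosin:
    def test_fixed_point(self, rng):
        od = rng.uniform(0.2, 1.5, size=(20, 20, 3))
        basis = sq.StainBasis(eosin=UNIT_GRAY)
        proj = od @ UNIT_GRAY
        ref = np.quantile(proj[(od > 0.15).all(-1)], 0.99)
        out = sq.normalize_eosin(od, basis, reference_value=ref)
        assert np.allclose(out, proj)

    def test_scale_invariance(self, rng):
        # values either 0 or well above β so the transparency mask is stable
        od = np.where(rng.random((20, 20, 1)) < 0.3, 0.0,
                      rng.uniform(0.4, 1.5, size=(20, 20, 3)))
        basis = sq.StainBasis(eosin=UNIT_GRAY)
        a = sq.normalize_eosin(od, basis)
        b = sq.normalize_eosin(1.7 * od, basis)
        assert np.allclose(a, b)

    def test_exposure_invariance_through_render(self, rng):
        """Two exposures of the same stain field normalize identically."""
        conc = rng.uniform(0.4, 1.8, size=(1, 40, 40))
        basis = sq.StainBasis(eosin=UNIT_GRAY)
        outs = []
        for i0 in (255.0, 200.0):
            img = syn.render_stain_image(conc, basis, i0)
            outs.append(sq.normalize_eosin(sq.rgb_to_od(img, i0), basis))
        assert np.abs(outs[0] - outs[1]).max() < 0.05

    def test_zero_spread_rejected(self):
        basis = sq.StainBasis(eosin=UNIT_GRAY)
        with pytest.raises(sq.StainEstimationError):
            sq.normalize_eosin(np.zeros((5, 5, 3)), basis)


def _one_spot_grid(py, px):
    return pd.DataFrame({"spot_id": ["s0"], "array_row": [0], "array_col": [0],
                         "px_row": [py], "px_col": [px], "in_tissue": [1]})


class TestSpotOdQuantile:
    def test_constant_image_any_quantile(self):
        gray = np.full((20, 20), 0.7)
        grid = _one_spot_grid(10, 10)
        for q in (0.1, 0.5, 0.9, 1.0):
            assert sq.spot_od_quantile(gray, grid, 3.0, q).iloc[0] == 0.7

    def test_linear_interpolation_oracle(self):
        """q-quantile matches the manual interpolation formula
        x[i] + frac · (x[i+1] − x[i]) with i = floor((n−1)·q)."""
        gray = np.zeros((9, 9))
        grid = _one_spot_grid(4, 4)
        r = 1.8  # disk of 9 pixels: center, 4 axial, 4 diagonal
        values = np.array([5, 1, 9, 3, 7, 2, 8, 4, 6], dtype=float)
        gray[4, 4] = values[0]
        for v, (dy, dx) in zip(values[1:], [(-1, 0), (1, 0), (0, -1), (0, 1),
                                            (-1, -1), (-1, 1), (1, -1), (1, 1)]):
            gray[4 + dy, 4 + dx] = v
        got = sq.spot_od_quantile(gray, grid, r, 0.9).iloc[0]
        srt = np.sort(values)
        h = (len(srt) - 1) * 0.9
        expected = srt[int(h)] + (h - int(h)) * (srt[int(h) + 1] - srt[int(h)])
        assert got == pytest.approx(expected)

    def test_q1_is_maximum(self, rng):
        gray = rng.random((30, 30))
        grid = _one_spot_grid(15, 15)
        r = 4.0
        got = sq.spot_od_quantile(gray, grid, r, 1.0).iloc[0]
        dy, dx = np.mgrid[-4:5, -4:5]
        inside = dy**2 + dx**2 <= 16
        assert got == gray[15 + dy[inside], 15 + dx[inside]].max()

    def test_offgrid_spot_missing(self):
        gray = np.zeros((10, 10))
        assert np.isnan(sq.spot_od_quantile(gray, _one_spot_grid(500, 500),
                                            2.0).iloc[0])

    def test_invalid_parameters(self):
        gray = np.zeros((5, 5))
        grid = _one_spot_grid(2, 2)
        with pytest.raises(ValueError):
            sq.spot_od_quantile(gray, grid, 2.0, 0.0)
        with pytest.raises(ValueError):
            sq.spot_od_quantile(gray, grid, -1.0)


class TestFlagSparse:
    def test_threshold_extremes(self):
        q = pd.Series([0.1, 0.5, 0.9])
        assert not sq.flag_sparse_spots(q, 0.0).any()
        assert sq.flag_sparse_spots(q, 1.0).all()

    def test_planted_sparse_spots_fully_recovered(self, full_sample_qc):
        """Otsu split of the q90 distribution recovers the generator's
        tissue-sparse spots with precision = recall = 1."""
        cfg, s, qvals, qc = full_sample_qc
        truth = s["sparse_flags"]
        called = qc.loc[qc["in_tissue"] == 1, "sparse_flag"].to_numpy()
        assert (called == truth).all()


def brute_force_edges(grid, background):
    tissue = {(r, c) for r, c, bg in zip(grid["array_row"], grid["array_col"],
                                         background) if not bg}
    out = []
    for r, c, bg in zip(grid["array_row"], grid["array_col"], background):
        if bg:
            out.append(False)
            continue
        nbs = [(r, c - 2), (r, c + 2), (r - 1, c - 1), (r - 1, c + 1),
               (r + 1, c - 1), (r + 1, c + 1)]
        out.append(any(n not in tissue for n in nbs))
    return np.array(out)


class TestEdgeLabeling:
    def test_isolated_spot_is_edge(self):
        grid = make_hex_grid(GridGeometry(n_rows=5, n_cols=8))
        bg = np.ones(len(grid), dtype=bool)
        bg[7] = False
        flags = sq.label_edge_spots(grid, bg)
        assert flags.to_numpy()[7] and flags.sum() == 1

    def test_solid_disk_edge_is_outer_ring(self):
        geom = GridGeometry(n_rows=15, n_cols=26)
        grid = make_hex_grid(geom, round_pixels=False)
        pts = grid[["px_row", "px_col"]].to_numpy(dtype=float)
        center = pts.mean(axis=0)
        bg = np.linalg.norm(pts - center, axis=1) > 5.2 * geom.spacing_px
        flags = sq.label_edge_spots(grid, bg)
        assert (flags.to_numpy() == brute_force_edges(grid, bg)).all()
        # the ring is a connected, nonempty proper subset of tissue
        assert 0 < flags.sum() < (~bg).sum()

    @pytest.mark.parametrize("seed", range(30))
    def test_random_masks_match_brute_force(self, seed):
        grid = make_hex_grid(GridGeometry(n_rows=10, n_cols=18))
        rng = np.random.default_rng(seed)
        bg = rng.random(len(grid)) < 0.4
        flags = sq.label_edge_spots(grid, bg)
        assert (flags.to_numpy() == brute_force_edges(grid, bg)).all()


class TestFilterMinCounts:
    def test_boundary_at_200(self):
        counts = np.array([[199, 200]])
        assert sq.filter_min_counts(counts).tolist() == [False, True]

    def test_toy_matrix(self):
        counts = sparse.csr_matrix(np.array([[0, 150, 200, 201, 1000]]))
        assert sq.filter_min_counts(counts).sum() == 3

    def test_zero_threshold_retains_all(self):
        assert sq.filter_min_counts(np.zeros((3, 4)), 0).all()

    def test_idempotent(self, rng):
        counts = rng.integers(0, 100, size=(20, 30))
        keep = sq.filter_min_counts(counts, 500)
        again = sq.filter_min_counts(counts[:, keep], 500)
        assert again.all()


class TestSpotQcTable:
    def test_filter_chain_and_retained_flag(self, full_sample_qc):
        cfg, s, qvals, qc = full_sample_qc
        assert (qc["retained"] == (qc["in_tissue"].astype(bool)
                                   & ~qc["sparse_flag"]
                                   & qc["min_count_pass"])).all()
        # edge flags are only set on retained spots
        assert not qc.loc[~qc["retained"], "edge_flag"].any()
        # re-filtering the retained counts changes nothing
        totals = qc.loc[qc["in_tissue"] == 1, "total_counts"].to_numpy()
        retained_tissue = qc.loc[qc["in_tissue"] == 1, "retained"].to_numpy()
        assert (totals[retained_tissue] >= 200).all()
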