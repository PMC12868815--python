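from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lungspatial import (
    MALE_SIGNATURE_GENES,
    SignatureSet,
    call_sex,
    composition_table,
    permutation_composition_test,
    pseudobulk_aggregate,
    signature_score,
    student_t_peripheral,
    wilcoxon_rank_sum,
)
from lungspatial import synthetic as syn
from lungspatial.composition import stage_composition_tests


def midranks(values):
    """Independent mid-rank computation (no scipy)."""
    values = np.asarray(values, dtype=float)
    ranks = np.empty(len(values))
    order = np.argsort(values, kind="stable")
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def enumerate_wilcoxon_p(x, y):
    """Brute-force two-sided exact p over all label assignments."""
    pooled = np.concatenate([x, y])
    ranks = midranks(pooled)
    nx, n = len(x), len(pooled)
    w_obs = ranks[:nx].sum()
    ws = [sum(ranks[list(idx)]) for idx in combinations(range(n), nx)]
    lo = sum(w <= w_obs + 1e-9 for w in ws) / len(ws)
    hi = sum(w >= w_obs - 1e-9 for w in ws) / len(ws)
    return min(1.0, 2.0 * min(lo, hi))


class TestCompositionTable:
    def test_simple_frequencies(self):
        ann = pd.DataFrame({"sample": ["s1"] * 4,
                            "spot_type": ["a", "a", "a", "b"]})
        comp = composition_table(ann)
        assert comp["frequency"].tolist() == [0.75, 0.25]

    def test_per_sample_frequencies_sum_to_one(self, rng):
        ann = pd.DataFrame({
            "sample": rng.choice(["s1", "s2", "s3"], 300),
            "spot_type": rng.choice(list("abcd"), 300),
        })
        comp = composition_table(ann)
        sums = comp.groupby("sample")["frequency"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_unknown_labels_rejected_with_names(self):
        ann = pd.DataFrame({"sample": ["s1", "s1"],
                            "spot_type": ["a", "mystery"]})
        with pytest.raises(ValueError, match="mystery"):
            composition_table(ann, known_types=["a", "b"])

    def test_generator_frequencies_multinomial_oracle(self):
        """Empirical frequencies from a weakly clustered field match the
        configured proportions within 3 multinomial standard errors."""
        from lungspatial import GridGeometry, make_hex_grid

        grid = make_hex_grid(GridGeometry(n_rows=40, n_cols=100))
        p = np.array([0.3, 0.2, 0.2, 0.1, 0.05, 0.05, 0.04, 0.03, 0.02, 0.01])
        counts = np.zeros(10)
        for seed in range(10):
            labels = syn.simulate_type_field(grid, p, dispersion=1e5, seed=seed)
            counts += np.bincount(labels, minlength=10)
        freq = counts / counts.sum()
        se = np.sqrt(p * (1 - p) / counts.sum())
        assert (np.abs(freq - p) <= 3 * se + 1e-12).all()


class TestWilcoxon:
    def test_textbook_example(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.pvalue == pytest.approx(1 / 3)
        assert wilcoxon_rank_sum([1, 2], [3, 4], "less").pvalue == \
            pytest.approx(1 / 6)

    def test_identical_multisets_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]).pvalue == 1.0

    def test_all_constant_warns_p_one(self):
        with pytest.warns(UserWarning):
            res = wilcoxon_rank_sum([5, 5], [5, 5, 5])
        assert res.pvalue == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_enumeration_oracle_6v6(self, seed):
        rng = np.random.default_rng(seed)
        x = np.round(rng.normal(size=6), 1)  # rounding induces ties
        y = np.round(rng.normal(0.5, 1, size=6), 1)
        assert wilcoxon_rank_sum(x, y).pvalue == \
            pytest.approx(enumerate_wilcoxon_p(x, y))

    def test_exact_matches_scipy_without_ties(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=6)
        ours = wilcoxon_rank_sum(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert ours.pvalue == pytest.approx(ref.pvalue)
        assert ours.statistic == pytest.approx(ref.statistic)

    def test_large_samples_use_normal_approximation(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(1.0, 1.0, size=30)
        ours = wilcoxon_rank_sum(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic")
        assert ours.pvalue == pytest.approx(ref.pvalue)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestStudentT:
    def test_identical_vectors_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            student_t_peripheral([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_symmetric_differences_t_zero(self):
        res = student_t_peripheral([2.0, 1.0, 2.0, 1.0],
                                   [1.0, 2.0, 1.0, 2.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_paired_closed_form_oracle(self):
        a = np.array([0.31, 0.27, 0.35, 0.30, 0.24, 0.33])
        b = np.array([0.22, 0.25, 0.28, 0.21, 0.23, 0.26])
        d = a - b
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_manual = 2 * stats.t.sf(abs(t_manual), df=len(d) - 1)
        res = student_t_peripheral(a, b)
        assert res.statistic == pytest.approx(t_manual)
        assert res.pvalue == pytest.approx(p_manual)

    def test_unpaired_pooled_variance(self, rng):
        a, b = rng.normal(size=6), rng.normal(0.5, 1, size=8)
        res = student_t_peripheral(a, b, paired=False)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(ref.statistic)


class TestPermutationTest:
    def test_identical_compositions_p_one(self):
        freq = pd.DataFrame(np.tile([0.6, 0.4], (8, 1)))
        cond = np.array(["x"] * 4 + ["y"] * 4)
        res = permutation_composition_test(freq, cond, n_perm=999, seed=0)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_exact_enumeration_matches_brute_force(self, rng):
        freq = rng.dirichlet(np.ones(5), size=12)
        cond = np.array(["x"] * 4 + ["y"] * 8)
        res = permutation_composition_test(pd.DataFrame(freq), cond, exact=True)
        assert res.n_perm == 495
        # independent brute force
        obs = ((freq[:4].mean(0) - freq[4:].mean(0)) ** 2).sum()
        count = 0
        for idx in combinations(range(12), 4):
            mask = np.zeros(12, dtype=bool)
            mask[list(idx)] = True
            t = ((freq[mask].mean(0) - freq[~mask].mean(0)) ** 2).sum()
            count += t >= obs - 1e-15
        assert res.pvalue == pytest.approx(count / 495)

    def test_single_condition_rejected(self):
        freq = pd.DataFrame(np.random.dirichlet(np.ones(3), size=6))
        with pytest.raises(ValueError):
            permutation_composition_test(freq, np.array(["x"] * 6), 999, 0)

    def test_deterministic_given_seed(self, rng):
        freq = pd.DataFrame(rng.dirichlet(np.ones(4), size=10))
        cond = np.array(["x"] * 5 + ["y"] * 5)
        r1 = permutation_composition_test(freq, cond, 999, seed=42)
        r2 = permutation_composition_test(freq, cond, 999, seed=42)
        assert r1.pvalue == r2.pvalue


class TestPseudobulk:
    def test_single_group_is_row_sums(self, rng):
        counts = rng.integers(0, 10, size=(8, 15))
        mat, meta = pseudobulk_aggregate(counts, ["s1"] * 15, ["c1"] * 15)
        assert np.array_equal(mat.to_numpy().ravel(), counts.sum(axis=1))

    def test_grand_total_conserved(self, rng):
        counts = rng.integers(0, 10, size=(30, 100))
        mat, _ = pseudobulk_aggregate(
            counts, rng.choice(["s1", "s2"], 100), rng.choice(list("abc"), 100))
        assert mat.to_numpy().sum() == counts.sum()

    def test_brute_force_group_sums(self, rng):
        counts = rng.integers(0, 20, size=(50, 200))
        samples = rng.choice(["s1", "s2", "s3"], 200)
        clusters = rng.choice(list("abcd"), 200)
        mat, meta = pseudobulk_aggregate(counts, samples, clusters)
        for _, row in meta.iterrows():
            mask = (samples == row["sample"]) & (clusters == row["cluster"])
            assert np.array_equal(mat[row["column"]].to_numpy(),
                                  counts[:, mask].sum(axis=1))

    def test_missing_label_rejected(self, rng):
        counts = rng.integers(0, 5, size=(3, 4))
        with pytest.raises(ValueError):
            pseudobulk_aggregate(counts, ["s1", "s1", None, "s1"], ["c"] * 4)


class TestSignatureScore:
    @pytest.fixture
    def expr(self):
        genes = [f"G{i}" for i in range(2000)]
        return pd.Series(np.arange(2000, 0, -1, dtype=float), index=genes)

    def test_top_ranked_signature_scores_one(self, expr):
        sig = SignatureSet(tuple(f"G{i}" for i in range(7)), 1500)
        assert signature_score(expr, sig) == pytest.approx(1.0)

    def test_all_beyond_rmax_scores_floor(self, expr):
        expr.iloc[:7] = -1.0  # push the 7 signature genes past r_max
        sig = SignatureSet(tuple(f"G{i}" for i in range(7)), 1500)
        # pre-clip value (7−1)/(2·1500) = 0.002
        assert signature_score(expr, sig) == pytest.approx(0.002, abs=1e-12)

    def test_single_gene_at_rmax(self):
        genes = [f"G{i}" for i in range(2000)]
        expr = pd.Series(np.arange(2000, 0, -1, dtype=float), index=genes)
        sig = SignatureSet(("G1499",), 1500)  # rank exactly r_max
        assert signature_score(expr, sig) == pytest.approx(1.0 / 1500)

    def test_monotone_transform_invariance(self, rng):
        genes = [f"G{i}" for i in range(500)]
        expr = pd.Series(rng.random(500), index=genes)
        sig = SignatureSet(tuple(rng.choice(genes, 7, replace=False)), 300)
        assert signature_score(expr, sig) == \
            pytest.approx(signature_score(np.exp(5 * expr), sig))

    def test_errors(self, expr):
        with pytest.raises(ValueError, match="no signature gene"):
            signature_score(expr, SignatureSet(("ABSENT",), 1500))
        with pytest.raises(ValueError, match="max_rank"):
            signature_score(expr.iloc[:100], SignatureSet(("G1",), 1500))


class TestCallSex:
    def test_threshold_logic(self):
        calls = call_sex(pd.Series({"a": 0.9, "b": 0.01, "c": 0.2}))
        assert calls["sex_call"].tolist() == ["male", "female", "female"]

    def test_degenerate_threshold_all_female(self):
        calls = call_sex(pd.Series([0.5, 0.99]), threshold=1.1)
        assert (calls["sex_call"] == "female").all()

    def test_recovery_from_simulated_counts(self):
        panel = syn.build_gene_panel(2000, 20)
        scores = {}
        for seed, sex in enumerate(["male", "female"] * 3):
            counts = syn.simulate_counts(np.zeros(40, dtype=int), panel, sex,
                                         seed)
            totals = pd.Series(np.asarray(counts.sum(axis=1)).ravel(),
                               index=panel["gene"].to_numpy())
            scores[(seed, sex)] = signature_score(totals)
        for (seed, sex), score in scores.items():
            assert (score > 0.2) == (sex == "male")


class TestStageTests:
    def test_shifted_type_detected_on_small_study(self, small_study):
        cfg, out, truth = small_study
        ann = truth.spots.rename(columns={"true_type": "spot_type"})
        comp = composition_table(ann[["sample", "spot_type"]], truth.samples,
                                 known_types=list(syn.SPOT_TYPES))
        tests = stage_composition_tests(comp)
        row = tests[tests["spot_type"] == "distal_parenchyma"].iloc[0]
        assert row["p_adj"] < 0.05
        assert {"statistic", "p_raw", "p_adj", "method"} <= set(tests.columns)
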