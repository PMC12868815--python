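"""Spot-type composition tables, the study's inferential comparisons,
pseudobulk aggregation and rank-based sex-signature scoring.

Stage comparisons of per-sample spot-type frequencies use the Wilcoxon
rank-sum test (exact enumeration at the study's 6-vs-6 scale), condition
comparisons use an omnibus label-permutation test on the vector of mean
frequency differences, and the peripheral vs non-peripheral frequency of
a target type uses a Student t test.  Biological sex is called from a
seven-gene Y-chromosome signature (RPS4Y1, UTY, KDM5D, DDX3Y, USP9Y,
VCX, VCY) scored with a UCell-style rank statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Y-chromosome male gene signature used to call sample sex.
MALE_SIGNATURE_GENES: tuple[str, ...] = (
    "RPS4Y1", "UTY", "KDM5D", "DDX3Y", "USP9Y", "VCX", "VCY",
)

#: combined sample size up to which the Wilcoxon p is enumerated exactly
EXACT_WILCOXON_MAX_N = 12


class TestResult(NamedTuple):
    statistic: float
    pvalue: float


@dataclass(frozen=True)
class SignatureSet:
    """A gene signature with the UCell rank cutoff r_max."""

    genes: tuple[str, ...]
    max_rank: int = 1500

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError("signature must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")
        if self.max_rank < 1:
            raise ValueError("max_rank must be positive")


MALE_SIGNATURE = SignatureSet(genes=MALE_SIGNATURE_GENES)


# ---------------------------------------------------------------------------
# composition table


def composition_table(
    annotations: pd.DataFrame,
    sample_meta: pd.DataFrame | None = None,
    known_types: list | tuple | None = None,
) -> pd.DataFrame:
    """Per-(sample, spot type) counts and frequencies.

    ``annotations`` needs columns ``sample`` and ``spot_type``; optional
    ``sample_meta`` (indexed or keyed by ``sample``) is merged in.  With
    ``known_types``, labels outside the list raise an error naming the
    offenders, and every known type appears (zero-filled) in each sample.
    Rows are ordered by sample then type; per-sample frequencies sum to 1.
    """
    if not {"sample", "spot_type"} <= set(annotations.columns):
        raise ValueError("annotations need 'sample' and 'spot_type' columns")
    types = annotations["spot_type"]
    if known_types is not None:
        bad = sorted(set(types) - set(known_types))
        if bad:
            raise ValueError(f"unknown spot type labels: {', '.join(map(str, bad))}")
        types = pd.Categorical(types, categories=list(known_types))
    counts = (
        annotations.assign(spot_type=types)
        .groupby(["sample", "spot_type"], observed=False)
        .size()
        .rename("count")
        .reset_index()
        .sort_values(["sample", "spot_type"], kind="stable")
        .reset_index(drop=True)
    )
    totals = counts.groupby("sample")["count"].transform("sum")
    counts["frequency"] = counts["count"] / totals
    if sample_meta is not None:
        meta = sample_meta.reset_index() if sample_meta.index.name == "sample" \
            else sample_meta
        counts = counts.merge(meta, on="sample", how="left")
    return counts


# ---------------------------------------------------------------------------
# rank / t / permutation tests


def _exact_wilcoxon(x: np.ndarray, y: np.ndarray, alternative: str) -> TestResult:
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # mid-ranks under ties
    n, nx = pooled.size, x.size
    w_obs = ranks[:nx].sum()
    combos = np.fromiter(
        (c for idx in combinations(range(n), nx) for c in idx), dtype=np.intp
    ).reshape(-1, nx)
    w_all = ranks[combos].sum(axis=1)
    total = comb(n, nx)
    p_lo = np.count_nonzero(w_all <= w_obs + 1e-9) / total
    p_hi = np.count_nonzero(w_all >= w_obs - 1e-9) / total
    if alternative == "less":
        p = p_lo
    elif alternative == "greater":
        p = p_hi
    else:
        p = min(1.0, 2.0 * min(p_lo, p_hi))
    u = w_obs - nx * (nx + 1) / 2.0
    return TestResult(statistic=float(u), pvalue=float(p))


def wilcoxon_rank_sum(
    x, y, alternative: str = "two-sided"
) -> TestResult:
    """Wilcoxon rank-sum (Mann–Whitney) test of two frequency samples.

    Exact enumeration of all label assignments (mid-ranks under ties) for
    combined n ≤ 12 — the scale of a 12-sample study — and the tie-
    corrected normal approximation above.  The statistic reported is the
    Mann–Whitney U of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups need at least one observation")
    if np.ptp(np.concatenate([x, y])) == 0:
        warnings.warn("all values identical across both groups; p = 1")
        return TestResult(statistic=float(x.size * y.size / 2.0), pvalue=1.0)
    if x.size + y.size <= EXACT_WILCOXON_MAX_N:
        return _exact_wilcoxon(x, y, alternative)
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return TestResult(statistic=float(res.statistic), pvalue=float(res.pvalue))


def student_t_peripheral(
    peripheral_freq, nonperipheral_freq, paired: bool = True
) -> TestResult:
    """Student t test of a type's frequency, peripheral vs non-peripheral.

    Paired across samples by default (each sample contributes both
    regions); the unpaired version is the pooled-variance two-sample t.
    Zero variance of the paired differences is an error (t undefined).
    """
    a = np.asarray(peripheral_freq, dtype=float)
    b = np.asarray(nonperipheral_freq, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired test needs equal-length vectors")
        if a.size < 2:
            raise ValueError("need at least two samples")
        d = a - b
        if np.allclose(d.std(ddof=1), 0.0):
            raise ValueError("zero variance of paired differences; t undefined")
        res = stats.ttest_rel(a, b)
    else:
        if min(a.size, b.size) < 2:
            raise ValueError("need at least two samples per region")
        res = stats.ttest_ind(a, b, equal_var=True)
    return TestResult(statistic=float(res.statistic), pvalue=float(res.pvalue))


class PermutationResult(NamedTuple):
    statistic: float
    pvalue: float
    n_perm: int
    method: str


def permutation_composition_test(
    freq: pd.DataFrame,
    condition: pd.Series | np.ndarray,
    n_perm: int = 9999,
    seed: int | np.random.Generator = 0,
    *,
    exact: bool = False,
) -> PermutationResult:
    """Omnibus permutation test of spot-type composition between conditions.

    ``freq`` is a samples × types frequency matrix (rows sum to 1) and
    ``condition`` a two-level label per sample.  The statistic is
    T = Σ_types (mean freq in condition 1 − mean freq in condition 2)²;
    sample labels are permuted uniformly.  The Monte Carlo p uses the
    add-one correction p = (1 + #{T* ≥ T}) / (n_perm + 1); with
    ``exact=True`` all distinct assignments are enumerated and
    p = #{T* ≥ T} / #assignments (the identity assignment included).
    """
    f = np.asarray(freq, dtype=float)
    cond = np.asarray(condition)
    levels = pd.unique(cond)
    if len(levels) < 2:
        raise ValueError("need two conditions")
    if len(levels) > 2:
        raise ValueError("permutation test supports exactly two conditions")
    g = cond == levels[0]
    n1, n0 = int(g.sum()), int((~g).sum())
    if min(n1, n0) < 2:
        raise ValueError("need at least two samples per condition")

    def statistic(mask: np.ndarray) -> float:
        return float(((f[mask].mean(axis=0) - f[~mask].mean(axis=0)) ** 2).sum())

    t_obs = statistic(g)
    n = len(f)
    if exact:
        idx_sets = list(combinations(range(n), n1))
        t_perm = np.empty(len(idx_sets))
        for i, idx in enumerate(idx_sets):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            t_perm[i] = statistic(mask)
        p = np.count_nonzero(t_perm >= t_obs - 1e-15) / len(idx_sets)
        return PermutationResult(t_obs, float(p), len(idx_sets), "exact")

    if n_perm < 999:
        raise ValueError("use at least 999 permutations")
    rng = np.random.default_rng(seed)
    # vectorized: indicator matrix of condition-1 membership per permutation
    perms = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n1]
    member = np.zeros((n_perm, n), dtype=float)
    np.put_along_axis(member, perms, 1.0, axis=1)
    mean1 = member @ f / n1
    mean0 = (1.0 - member) @ f / n0
    t_perm = ((mean1 - mean0) ** 2).sum(axis=1)
    p = (1 + np.count_nonzero(t_perm >= t_obs - 1e-15)) / (n_perm + 1)
    return PermutationResult(t_obs, float(p), n_perm, "monte-carlo")


def stage_composition_tests(
    comp: pd.DataFrame,
    stage_col: str = "stage",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-type Wilcoxon comparison of frequencies across the two stages.

    Returns one row per spot type with the Mann–Whitney U, raw two-sided
    p and the Benjamini–Hochberg adjusted p across the types tested.
    """
    stages = pd.unique(comp[stage_col])
    if len(stages) != 2:
        raise ValueError("stage comparison needs exactly two stages")
    rows = []
    for t, cell in comp.groupby("spot_type", observed=True, sort=True):
        x = cell.loc[cell[stage_col] == stages[0], "frequency"].to_numpy()
        y = cell.loc[cell[stage_col] == stages[1], "frequency"].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = wilcoxon_rank_sum(x, y)
        rows.append({"spot_type": t, "statistic": res.statistic,
                     "p_raw": res.pvalue, "method": "wilcoxon"})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"], alpha=alpha, method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# pseudobulk


def pseudobulk_aggregate(
    counts,
    sample_ids,
    cluster_labels,
    gene_names=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sum genes × spots counts into genes × (sample, cluster) pseudobulk.

    Conservation holds exactly: the grand total of the output equals that
    of the input.  Spots with a missing sample or cluster label raise.
    Returns the pseudobulk matrix (DataFrame, columns "sample|cluster")
    and a column-metadata table.
    """
    samples = pd.Series(sample_ids).reset_index(drop=True)
    clusters = pd.Series(cluster_labels).reset_index(drop=True)
    if samples.isna().any() or clusters.isna().any():
        raise ValueError("every spot needs a sample id and a cluster label")
    n_spots = counts.shape[1]
    if len(samples) != n_spots or len(clusters) != n_spots:
        raise ValueError("labels must align with count-matrix columns")

    key = samples.astype(str) + "|" + clusters.astype(str)
    cats = pd.Categorical(key)
    indicator = sp.csr_matrix(
        (np.ones(n_spots), (np.arange(n_spots), cats.codes)),
        shape=(n_spots, len(cats.categories)),
    )
    mat = counts @ indicator if sp.issparse(counts) else np.asarray(counts) @ \
        indicator.toarray()
    mat = np.asarray(mat.todense()) if sp.issparse(mat) else np.asarray(mat)
    columns = list(cats.categories)
    index = pd.Index(gene_names, name="gene") if gene_names is not None else None
    pseudobulk = pd.DataFrame(mat.astype(np.int64), columns=columns, index=index)
    colmeta = pd.DataFrame(
        {
            "column": columns,
            "sample": [c.split("|", 1)[0] for c in columns],
            "cluster": [c.split("|", 1)[1] for c in columns],
        }
    )
    return pseudobulk, colmeta


# ---------------------------------------------------------------------------
# signature scoring and sex calls


def signature_score(
    expression,
    signature: SignatureSet = MALE_SIGNATURE,
    gene_names=None,
) -> float | pd.Series:
    """UCell-style rank score of a gene signature, in [0, 1].

    Genes are ranked by decreasing expression (ties get mid-ranks; ranks
    beyond ``signature.max_rank`` are clamped to max_rank + 1); with n
    signature genes present,

        U′ = Σ ranks(signature) − n(n+1)/2,
        score = 1 − U′ / (n · max_rank),  clipped to [0, 1].

    Rank-based, hence invariant to any monotone transform of expression.
    Accepts a Series (gene-indexed), a (genes, values) pair via
    ``gene_names``, or a genes × samples DataFrame (scores per column).
    """
    if isinstance(expression, pd.DataFrame):
        return expression.apply(
            lambda col: signature_score(col, signature), axis=0
        ).rename("signature_score")
    if not isinstance(expression, pd.Series):
        if gene_names is None:
            raise ValueError("gene_names required for array input")
        expression = pd.Series(np.asarray(expression, dtype=float),
                               index=pd.Index(gene_names))
    r_max = signature.max_rank
    if r_max >= expression.size:
        raise ValueError("max_rank must be smaller than the number of genes")
    present = [g for g in signature.genes if g in expression.index]
    if not present:
        raise ValueError("no signature gene present in the expression vector")
    ranks = pd.Series(
        stats.rankdata(-expression.to_numpy(dtype=float)), index=expression.index
    )
    ranks = ranks.where(ranks <= r_max, r_max + 1)
    n = len(present)
    u = ranks.loc[present].sum() - n * (n + 1) / 2.0
    return float(np.clip(1.0 - u / (n * r_max), 0.0, 1.0))


def call_sex(scores: pd.Series, threshold: float = 0.2) -> pd.DataFrame:
    """Male ⟺ signature score strictly above ``threshold``; scores reported."""
    scores = pd.Series(scores)
    if scores.size < 1:
        raise ValueError("need at least one sample score")
    return pd.DataFrame(
        {
            "signature_score": scores,
            "sex_call": np.where(scores > threshold, "male", "female"),
        }
    )
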