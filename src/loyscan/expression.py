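"""Count normalization, dosage screening, DE filtering, and enrichment.

The DE contract is a filter, not a shrinkage estimator: a gene passes when
|fold change| >= 1.5, p below the stratum threshold, and CPM > 1 in at least
as many samples as the smaller comparison group. The test statistic is
pluggable (Welch t on log2 CPM by default, rank-sum as the alternative).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CPM_METHODS = ("library_size", "tmm")


def cpm_normalize(counts: pd.DataFrame, method: str = "library_size") -> pd.DataFrame:
    """Convert a gene x sample count matrix to counts per million.

    ``cpm(g, s) = count * 1e6 / (library_size_s * factor_s)`` where the
    factors are 1 (``library_size``) or TMM normalization factors scaled to
    geometric mean 1 (``tmm``).
    """
    if method not in CPM_METHODS:
        raise ValueError(f"method must be one of {CPM_METHODS}, got {method!r}")
    lib = counts.sum(axis=0).astype(float)
    zero = lib.index[lib == 0]
    if len(zero):
        raise ValueError(f"sample(s) with all-zero counts: {', '.join(map(str, zero))}")
    factors = tmm_factors(counts) if method == "tmm" else pd.Series(1.0, index=counts.columns)
    return counts.div(lib * factors, axis=1) * 1e6


def tmm_factors(
    counts: pd.DataFrame,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The reference is the sample whose upper-quartile (of relative
    abundances) is nearest the cohort mean upper-quartile. For each sample,
    genes expressed in both it and the reference are trimmed by 30% on M
    (log ratio) and 5% on A (log abundance) from each tail, and the factor
    is 2 ** mean(M) over the kept genes.
    """
    lib = counts.sum(axis=0).astype(float)
    rel = counts.div(lib, axis=1)
    uq = rel.apply(lambda col: np.percentile(col[col > 0], 75), axis=0)
    ref_sample = (uq - uq.mean()).abs().idxmin()
    ref = rel[ref_sample]

    factors = {}
    for sample in counts.columns:
        if sample == ref_sample:
            factors[sample] = 1.0
            continue
        obs = rel[sample]
        ok = (obs > 0) & (ref > 0)
        m = np.log2(obs[ok] / ref[ok])
        a = 0.5 * np.log2(obs[ok] * ref[ok])
        keep = _double_trim_mask(m.values, a.values, m_trim, a_trim)
        if keep.sum() == 0:
            logger.warning("tmm_factors: no genes survive trimming for %s", sample)
            factors[sample] = 1.0
            continue
        factors[sample] = float(2.0 ** m.values[keep].mean())
    f = pd.Series(factors).reindex(counts.columns)
    return f / stats.gmean(f)


def _double_trim_mask(m: np.ndarray, a: np.ndarray, m_trim: float, a_trim: float) -> np.ndarray:
    n = m.size
    m_rank = stats.rankdata(m, method="average")
    a_rank = stats.rankdata(a, method="average")
    keep_m = (m_rank > n * m_trim) & (m_rank <= n * (1 - m_trim))
    keep_a = (a_rank > n * a_trim) & (a_rank <= n * (1 - a_trim))
    return keep_m & keep_a


def y_gene_screen(
    cpm: pd.DataFrame,
    y_indices: pd.Series,
    rho_threshold: float = 0.5,
    return_all: bool = False,
) -> pd.DataFrame:
    """Genes whose expression tracks the Y copy-number index (Spearman).

    Ranks use average-rank tie handling. Returns genes with
    ``rho > rho_threshold`` in descending order (all genes when
    ``return_all``).
    """
    y_indices = pd.Series(y_indices).dropna()
    shared = [s for s in cpm.columns if s in y_indices.index]
    if len(shared) < 10:
        raise ValueError(f"need >= 10 overlapping samples, got {len(shared)}")
    expr = cpm[shared].to_numpy(dtype=float)
    y = y_indices[shared].to_numpy(dtype=float)

    y_rank = stats.rankdata(y)
    expr_rank = stats.rankdata(expr, axis=1)
    y_c = y_rank - y_rank.mean()
    e_c = expr_rank - expr_rank.mean(axis=1, keepdims=True)
    denom = np.sqrt((e_c ** 2).sum(axis=1) * (y_c ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (e_c @ y_c) / denom
    result = pd.DataFrame({"rho": rho}, index=cpm.index)
    result = result.sort_values("rho", ascending=False)
    if return_all:
        return result
    return result[result["rho"] > rho_threshold]


DE_TESTS = ("welch", "ranksum")


def de_test(
    expr: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    p_threshold: float = 0.05,
    fc_threshold: float = 1.5,
    cpm_floor: float = 1.0,
    test: str = "welch",
) -> pd.DataFrame:
    """Filter-based differential expression between two sample groups.

    ``expr`` is a gene x sample CPM matrix. Fold change is the ratio of
    group means of CPM (0.5 pseudo-count); the p-value is a Welch t-test on
    ``log2(CPM + 0.5)`` (or a rank-sum test). ``passes_filters`` requires
    |fold change| >= ``fc_threshold``, ``p < p_threshold``, and CPM >
    ``cpm_floor`` in at least ``min(len(a), len(b))`` of the compared
    samples. No multiple-testing correction is applied here.
    """
    group_a, group_b = list(group_a), list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("both groups need at least 3 samples")
    if test not in DE_TESTS:
        raise ValueError(f"test must be one of {DE_TESTS}, got {test!r}")

    a = expr[group_a].to_numpy(dtype=float)
    b = expr[group_b].to_numpy(dtype=float)
    log_a = np.log2(a + 0.5)
    log_b = np.log2(b + 0.5)
    if test == "welch":
        res = stats.ttest_ind(log_a, log_b, axis=1, equal_var=False)
        pvals = res.pvalue
    else:
        res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided")
        pvals = res.pvalue
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)

    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    fc = (mean_a + 0.5) / (mean_b + 0.5)
    log2_fc = np.log2(fc)

    smaller = min(len(group_a), len(group_b))
    n_expressed = (np.concatenate([a, b], axis=1) > cpm_floor).sum(axis=1)
    passes = (
        (np.abs(log2_fc) >= np.log2(fc_threshold))
        & (pvals < p_threshold)
        & (n_expressed >= smaller)
    )
    out = pd.DataFrame(
        {
            "log2_fold_change": log2_fc,
            "p_value": pvals,
            "mean_cpm_a": mean_a,
            "mean_cpm_b": mean_b,
            "n_expressed": n_expressed,
            "passes_filters": passes,
        },
        index=expr.index,
    )
    return out.sort_values("p_value")


def sex_concordance(
    expr: pd.DataFrame,
    reported_sex: pd.Series,
    y_markers: Iterable[str],
) -> pd.Series:
    """Flag samples whose Y-marker signal contradicts their reported sex.

    The per-sample score is the mean ``log2(CPM + 0.5)`` over the marker
    genes; a sample is flagged when its score falls on the wrong side of the
    midpoint between the male and female group means.
    """
    reported_sex = pd.Series(reported_sex)
    sexes = set(reported_sex.dropna())
    if not {"male", "female"} <= sexes:
        raise ValueError("sex_concordance requires both male and female samples")
    markers = [g for g in y_markers if g in expr.index]
    if not markers:
        raise ValueError("none of the Y marker genes are present in the matrix")
    score = np.log2(expr.loc[markers] + 0.5).mean(axis=0)
    score = score[reported_sex.index.intersection(score.index)]
    male_mean = score[reported_sex == "male"].mean()
    female_mean = score[reported_sex == "female"].mean()
    midpoint = 0.5 * (male_mean + female_mean)
    looks_male = score > midpoint if male_mean > female_mean else score < midpoint
    flagged = (looks_male & (reported_sex == "female")) | (
        ~looks_male & (reported_sex == "male")
    )
    return flagged.rename("sex_discordant")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT gene-set file: name, description, then member genes."""
    gene_sets: dict[str, set[str]] = {}
    with Path(path).open() as handle:
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            gene_sets[fields[0]] = {g for g in fields[2:] if g}
    return gene_sets


def enrich(
    hits: Iterable[str],
    universe: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric gene-set over-representation.

    Per term: overlap ``k``, term size ``K`` (after intersecting with the
    universe), hit count ``n``, universe size ``N``; fold enrichment is
    ``(k/n) / (K/N)``; the p-value is the upper hypergeometric tail
    ``P(X >= k)``; BH adjustment is applied across the tested terms. Terms
    with no overlap are reported with fold enrichment 0 and p = 1.
    """
    universe = set(universe)
    hits = set(hits)
    if not universe:
        raise ValueError("universe is empty")
    stray = hits - universe
    if stray:
        raise ValueError(f"hit genes outside the universe: {sorted(stray)[:5]}")
    N = len(universe)
    n = len(hits)
    rows = []
    for term, members in gene_sets.items():
        members = set(members) & universe
        K = len(members)
        k = len(members & hits)
        if k == 0 or n == 0 or K == 0:
            fold = 0.0
            p = 1.0
        else:
            fold = (k / n) / (K / N)
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N,
                     "fold_enrichment": fold, "p_value": p})
    out = pd.DataFrame(rows).set_index("term")
    if len(out):
        out["p_adjusted"] = multipletests(out["p_value"].values, method="fdr_bh")[1]
        out = out.sort_values("p_value")
    else:
        out["p_adjusted"] = pd.Series(dtype=float)
    return out
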