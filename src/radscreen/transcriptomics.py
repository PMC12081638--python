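"""Bulk-RNA expression layer: TMM normalization, differential expression,
per-sample gene-set scoring, and the transcriptional response-rate statistic.

The normalization is the trimmed mean of M-values (TMM): one sample is taken
as reference, and every other sample's scaling factor is a precision-weighted
mean of gene-wise log-ratios (M-values) after trimming the most extreme 30%
of M-values and 5% of average log-abundances (A-values). Factors are rescaled
to geometric mean 1.

Differential expression is a deliberately simple, dependency-light procedure:
equal-variance two-sample t tests on TMM-normalized log2-CPM, with
Benjamini-Hochberg control of the false discovery rate at 1%. This has
correct error control but not the empirical-Bayes variance moderation of
limma; small designs therefore have less power than a moderated analysis.

Per-sample gene-set enrichment is a standardized mean-rank score: within each
sample genes are ranked by expression, and a set's score is its members' mean
rank z-scaled under the exact hypergeometric (sampling without replacement)
null, giving mean 0 / variance 1 for random sets of any size.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "tmm_factors",
    "TMMNormalizer",
    "log_cpm",
    "filter_low_expression",
    "bh_adjust",
    "differential_expression",
    "TwoGroupDifferentialExpression",
    "enrichment_scores",
    "RankGeneSetScorer",
    "differential_gene_sets",
    "response_rate",
    "read_counts",
    "read_sample_sheet",
]


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
) -> float:
    """Trimmed, precision-weighted mean M-value of one sample vs the reference."""
    ok = (obs > 0) & (ref > 0)
    obs, ref = obs[ok].astype(float), ref[ok].astype(float)
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / lib_obs, ref / lib_ref

    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic (delta-method) variance of M; weights are its inverse
    var = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)

    if np.max(np.abs(m)) < 1e-6:  # identical composition
        return 1.0

    n = m.size
    m_rank = stats.rankdata(m, method="ordinal")
    a_rank = stats.rankdata(a, method="ordinal")
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n + 1 - (np.floor(n * logratio_trim) + 1)
    lo_a, hi_a = np.floor(n * abundance_trim) + 1, n + 1 - (np.floor(n * abundance_trim) + 1)
    keep = (m_rank >= lo_m) & (m_rank <= hi_m) & (a_rank >= lo_a) & (a_rank <= hi_a)
    if not keep.any():
        return 1.0
    weighted_mean_m = np.sum(m[keep] / var[keep]) / np.sum(1.0 / var[keep])
    return float(2.0**weighted_mean_m)


def tmm_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample TMM normalization factors (geometric mean 1).

    The reference is the sample whose upper-quartile count fraction is
    closest to the mean upper quartile across samples.
    """
    values = counts.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = values.sum(axis=0)
    if np.any(lib <= 0):
        empty = list(counts.columns[lib <= 0])
        raise ValueError(f"samples with all-zero counts: {empty}")

    q75 = np.array(
        [np.quantile(values[:, j] / lib[j], 0.75) for j in range(values.shape[1])]
    )
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))

    factors = np.array(
        [
            _tmm_pair(values[:, j], values[:, ref_idx], lib[j], lib[ref_idx])
            for j in range(values.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def log_cpm(
    counts: pd.DataFrame, factors: pd.Series | None = None, prior_count: float = 0.5
) -> pd.DataFrame:
    """log2 counts-per-million on effective (factor-adjusted) library sizes."""
    values = counts.to_numpy(dtype=float)
    lib = values.sum(axis=0)
    if factors is not None:
        lib = lib * factors.reindex(counts.columns).to_numpy()
    cpm = (values + prior_count) / (lib + 1.0)[None, :] * 1e6
    return pd.DataFrame(np.log2(cpm), index=counts.index, columns=counts.columns)


class TMMNormalizer(BaseEstimator):
    """TMM normalization as a fit/transform estimator.

    ``fit`` computes ``factors_`` and ``lib_sizes_``; ``transform`` returns
    the TMM-normalized log2-CPM matrix.
    """

    def __init__(self, prior_count: float = 0.5):
        self.prior_count = prior_count

    def fit(self, counts: pd.DataFrame, y=None):
        self.factors_ = tmm_factors(counts)
        self.lib_sizes_ = counts.sum(axis=0).astype(float)
        return self

    def transform(self, counts: pd.DataFrame) -> pd.DataFrame:
        return log_cpm(counts, factors=self.factors_, prior_count=self.prior_count)

    def fit_transform(self, counts: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(counts).transform(counts)


def filter_low_expression(
    counts: pd.DataFrame, min_cpm: float = 1.0, min_samples: int = 3
) -> pd.DataFrame:
    """Keep genes with CPM >= ``min_cpm`` in at least ``min_samples`` samples."""
    if min_cpm < 0 or min_samples < 0:
        raise ValueError("thresholds must be >= 0")
    if min_cpm == 0:
        return counts
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    cpm = counts.to_numpy(dtype=float) / lib[None, :] * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError("all genes removed by the low-expression filter")
    return counts.loc[keep]


# ---------------------------------------------------------------------------
# multiple testing and differential expression
# ---------------------------------------------------------------------------


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sorted p-values are scaled by m/rank and a cumulative minimum from the
    largest down enforces monotonicity; the result is capped at 1 and is
    order-preserving in the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _two_group_ttest(
    matrix: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise equal-variance t tests; returns (diff b-a, t, p)."""
    a, b = matrix[:, mask_a], matrix[:, mask_b]
    diff = b.mean(axis=1) - a.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, pvals = stats.ttest_ind(b, a, axis=1, equal_var=True)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    return diff, t_stat, pvals


def _group_masks(columns, groups) -> tuple[np.ndarray, np.ndarray, str, str]:
    groups = pd.Series(groups)
    if groups.index.inferred_type == "string" and set(columns) <= set(groups.index):
        labels = groups.reindex(columns)
    else:
        if len(groups) != len(columns):
            raise ValueError("groups must map every sample to a label")
        labels = pd.Series(list(groups), index=columns)
    names = sorted(labels.dropna().unique())
    if len(names) != 2:
        raise ValueError(f"exactly two groups required, got {names}")
    mask_a = (labels == names[0]).to_numpy()
    mask_b = (labels == names[1]).to_numpy()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("each group needs at least two samples")
    return mask_a, mask_b, names[0], names[1]


def differential_expression(
    counts: pd.DataFrame,
    groups,
    fdr: float = 0.01,
    min_cpm: float = 1.0,
    min_samples: int = 3,
) -> pd.DataFrame:
    """Two-group differential expression on TMM-normalized log2-CPM.

    Returns one row per gene with ``log2_fc`` (second group minus first, in
    sorted label order), raw and BH-adjusted p-values, and a ``significant``
    flag at adjusted p < ``fdr``.
    """
    mask_a, mask_b, name_a, name_b = _group_masks(counts.columns, groups)
    filtered = filter_low_expression(counts, min_cpm=min_cpm, min_samples=min_samples)
    expr = TMMNormalizer().fit_transform(filtered)

    diff, t_stat, pvals = _two_group_ttest(expr.to_numpy(), mask_a, mask_b)
    adjusted = bh_adjust(pvals)
    result = pd.DataFrame(
        {
            "gene": filtered.index,
            "log2_fc": diff,
            "t_statistic": t_stat,
            "p_value": pvals,
            "p_adjusted": adjusted,
            "significant": adjusted < fdr,
        }
    ).set_index("gene")
    result.attrs["contrast"] = f"{name_b} vs {name_a}"
    return result


class TwoGroupDifferentialExpression(BaseEstimator):
    """Estimator facade over :func:`differential_expression`.

    ``fit(counts, groups)`` stores the result table in ``results_`` and the
    contrast direction in ``contrast_``.
    """

    def __init__(self, fdr: float = 0.01, min_cpm: float = 1.0, min_samples: int = 3):
        self.fdr = fdr
        self.min_cpm = min_cpm
        self.min_samples = min_samples

    def fit(self, counts: pd.DataFrame, groups):
        self.results_ = differential_expression(
            counts,
            groups,
            fdr=self.fdr,
            min_cpm=self.min_cpm,
            min_samples=self.min_samples,
        )
        self.contrast_ = self.results_.attrs["contrast"]
        return self


# ---------------------------------------------------------------------------
# per-sample gene-set scoring
# ---------------------------------------------------------------------------


def enrichment_scores(
    expression: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Standardized mean-rank enrichment score per set per sample.

    For a sample with G genes, a set with m members present has mean member
    rank r̄; under the null of a uniformly random m-subset (sampling without
    replacement) E[r̄] = (G+1)/2 and Var[r̄] = (G-m)(G+1)/(12m), so
    ``z = (r̄ - (G+1)/2) / sqrt((G-m)(G+1)/(12m))`` has mean 0 and variance 1
    for random sets. Positive scores mean the set sits among the highly
    expressed genes of that sample. Sets with fewer than ``min_coverage`` of
    their genes present (or fewer than 2) are dropped with a warning.
    """
    genes = expression.index
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    ranks = stats.rankdata(expression.to_numpy(dtype=float), axis=0)

    rows, kept_ids = [], []
    for set_id, members in gene_sets.items():
        idx = [gene_pos[g] for g in members if g in gene_pos]
        m = len(idx)
        if m < 2 or (len(members) > 0 and m / len(members) < min_coverage):
            warnings.warn(
                f"gene set '{set_id}' dropped: {m}/{len(members)} genes present",
                stacklevel=2,
            )
            continue
        mean_rank = ranks[idx, :].mean(axis=0)
        null_mean = (n_genes + 1) / 2.0
        null_sd = np.sqrt((n_genes - m) * (n_genes + 1) / (12.0 * m))
        rows.append((mean_rank - null_mean) / null_sd)
        kept_ids.append(set_id)

    if not rows:
        raise ValueError("no gene set had sufficient coverage in the expression matrix")
    return pd.DataFrame(rows, index=pd.Index(kept_ids, name="gene_set"), columns=expression.columns)


class RankGeneSetScorer(BaseEstimator):
    """Per-sample gene-set scoring as a transformer.

    ``fit`` records the gene universe; ``transform(expression)`` returns the
    set x sample score matrix.
    """

    def __init__(self, gene_sets: dict[str, list[str]] | None = None, min_coverage: float = 0.5):
        self.gene_sets = gene_sets
        self.min_coverage = min_coverage

    def fit(self, expression: pd.DataFrame, y=None):
        if not self.gene_sets:
            raise ValueError("gene_sets must be provided")
        self.gene_universe_ = list(expression.index)
        return self

    def transform(self, expression: pd.DataFrame) -> pd.DataFrame:
        return enrichment_scores(expression, self.gene_sets, self.min_coverage)

    def fit_transform(self, expression: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(expression).transform(expression)


def differential_gene_sets(
    scores: pd.DataFrame, groups, fdr: float = 0.01
) -> pd.DataFrame:
    """Two-group comparison of enrichment scores with BH control.

    One row per gene set: mean score difference (second group minus first),
    ``direction`` (up/down in the second group), raw and adjusted p, and the
    significance flag at adjusted p < ``fdr``.
    """
    mask_a, mask_b, name_a, name_b = _group_masks(scores.columns, groups)
    diff, t_stat, pvals = _two_group_ttest(scores.to_numpy(dtype=float), mask_a, mask_b)
    adjusted = bh_adjust(pvals)
    result = pd.DataFrame(
        {
            "gene_set": scores.index,
            "mean_difference": diff,
            "direction": np.where(diff >= 0, "up", "down"),
            "t_statistic": t_stat,
            "p_value": pvals,
            "p_adjusted": adjusted,
            "significant": adjusted < fdr,
        }
    ).set_index("gene_set")
    result.attrs["contrast"] = f"{name_b} vs {name_a}"
    return result


def response_rate(p_adjusted, fold_change) -> np.ndarray | float:
    """Transcriptional response rate: ``-log10(p_adj) * log2(fold_change)``.

    ``fold_change`` is the linear fold change (the log2 is taken here), so
    the statistic is antisymmetric under inverting the fold change. Accepts
    scalars or arrays.
    """
    p = np.asarray(p_adjusted, dtype=float)
    fc = np.asarray(fold_change, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("adjusted p-values must lie in (0, 1]")
    if np.any(fc <= 0):
        raise ValueError("fold changes must be > 0")
    out = -np.log10(p) * np.log2(fc)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------


def read_counts(path) -> pd.DataFrame:
    """Read a gene x sample counts TSV (gene ids in the first column)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.index.duplicated().any():
        dupes = counts.index[counts.index.duplicated()].unique()[:5]
        raise ValueError(f"duplicate gene ids in counts file: {list(dupes)}")
    return counts


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet CSV; requires ``sample`` and ``group`` columns."""
    sheet = pd.read_csv(path)
    missing = {"sample", "group"} - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet is missing columns: {sorted(missing)}")
    return sheet
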