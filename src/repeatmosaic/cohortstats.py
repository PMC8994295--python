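"""Cohort-level statistics for repeat-length and instability data.

Covers the genotype-phenotype layer of a somatic-instability study: ordinary
least-squares regressions of age at onset / age at death / disease duration
on inherited repeat length, automatic Pearson-vs-Spearman correlation choice
by normality, pairwise Wilcoxon rank-sum tissue comparisons with Bonferroni
adjustment, per-tissue expansion-index ~ repeat-length regressions,
cross-locus correlation of per-tissue mean indices, and a z-scored heatmap
matrix clustered with Manhattan distance (pairwise-complete over missing
tissues).
"""
from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "RegressionResult",
    "CorrelationResult",
    "HeatmapClusterResult",
    "COHORT_COLUMNS",
    "validate_cohort",
    "fit_length_phenotype",
    "correlate",
    "pairwise_tissue_tests",
    "index_length_regression_per_tissue",
    "cross_locus_correlation",
    "heatmap_cluster",
]

logger = logging.getLogger(__name__)

COHORT_COLUMNS = (
    "individual_id",
    "tissue",
    "locus",
    "repeat_length",
    "expansion_index",
    "aao",
    "aad",
)


@dataclass(frozen=True)
class RegressionResult:
    """Simple OLS fit of response on a single predictor."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    predictor: str
    response: str
    slope_se: float
    slope_ci: tuple[float, float]
    n_dropped: int = 0

    def ci_covers(self, value: float) -> bool:
        return self.slope_ci[0] <= value <= self.slope_ci[1]


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "pearson" or "spearman"
    coefficient: float
    p_value: float
    n: int


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Validate a tidy cohort table and derive disease duration (aad - aao)."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns and c != "locus"]
    if missing:
        raise ValueError(f"cohort table missing column(s) {missing}")
    df = cohort.copy()
    if "locus" not in df.columns:
        df["locus"] = "XDP"
    dup = df.duplicated(subset=["individual_id", "tissue", "locus"])
    if dup.any():
        raise ValueError("cohort table has duplicate individual x tissue x locus rows")
    both = df["aao"].notna() & df["aad"].notna()
    if (df.loc[both, "aad"] < df.loc[both, "aao"]).any():
        raise ValueError("age at death before age at onset")
    df["duration"] = df["aad"] - df["aao"]
    return df


def _ols(x: np.ndarray, y: np.ndarray, predictor: str, response: str,
         n_dropped: int = 0) -> RegressionResult:
    if np.ptp(x) == 0:
        raise ValueError(f"constant predictor {predictor!r}; regression undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.f_pvalue),
        n=int(model.nobs),
        predictor=predictor,
        response=response,
        slope_se=float(model.bse[1]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        n_dropped=n_dropped,
    )


def fit_length_phenotype(
    cohort: pd.DataFrame,
    response: str = "aao",
    tissue: str | None = None,
) -> RegressionResult:
    """OLS of a phenotype (aao / aad / duration) on inherited repeat length.

    One row per individual is used (the first row per individual after any
    tissue filter).  Rows with a missing response or repeat length are
    dropped with a logged count.  The p-value is the regression F-test
    (identical to the slope t-test for a single predictor).
    """
    df = validate_cohort(cohort)
    if tissue is not None:
        df = df[df["tissue"] == tissue]
    df = df.drop_duplicates(subset="individual_id")
    complete = df.dropna(subset=["repeat_length", response])
    n_dropped = len(df) - len(complete)
    if n_dropped:
        logger.info("fit_length_phenotype(%s): dropped %d incomplete row(s)",
                    response, n_dropped)
    if len(complete) < 3:
        raise ValueError(f"need >= 3 complete rows, have {len(complete)}")
    return _ols(
        complete["repeat_length"].to_numpy(float),
        complete[response].to_numpy(float),
        predictor="repeat_length",
        response=response,
        n_dropped=n_dropped,
    )


def correlate(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Correlation with automatic method choice by normality.

    Shapiro-Wilk is run on both variables at the given alpha; Pearson is used
    only when neither rejects normality, otherwise Spearman.  The chosen
    method is reported alongside the coefficient.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; correlation undefined")
    normal = all(stats.shapiro(v).pvalue > alpha for v in (x, y))
    if normal:
        r, p = stats.pearsonr(x, y)
        return CorrelationResult("pearson", float(r), float(p), int(x.size))
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult("spearman", float(rho), float(p), int(x.size))


def pairwise_tissue_tests(
    cohort: pd.DataFrame,
    value: str = "expansion_index",
    min_n: int = 2,
) -> pd.DataFrame:
    """All pairwise two-sided Wilcoxon rank-sum tests between tissues.

    Returns a symmetric tissue x tissue matrix of Bonferroni-adjusted
    p-values (raw p times the number of pairs tested, capped at 1); the
    diagonal is NaN.  Tissues with fewer than ``min_n`` values are skipped
    with a warning.
    """
    df = cohort.dropna(subset=[value])
    groups = {t: g[value].to_numpy(float) for t, g in df.groupby("tissue")}
    skipped = [t for t, v in groups.items() if v.size < min_n]
    for t in skipped:
        warnings.warn(f"tissue {t!r} has < {min_n} values; skipped", stacklevel=2)
        del groups[t]
    tissues = sorted(groups)
    if len(tissues) < 2:
        raise ValueError("need at least 2 tissues with enough values")
    pairs = list(itertools.combinations(tissues, 2))
    m = len(pairs)
    mat = pd.DataFrame(np.nan, index=tissues, columns=tissues)
    for a, b in pairs:
        stat = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        adj = min(1.0, float(stat.pvalue) * m)
        mat.loc[a, b] = adj
        mat.loc[b, a] = adj
    return mat


def index_length_regression_per_tissue(
    cohort: pd.DataFrame, value: str = "expansion_index"
) -> dict[str, RegressionResult]:
    """Per-tissue OLS of expansion index on inherited repeat length."""
    df = validate_cohort(cohort)
    out: dict[str, RegressionResult] = {}
    for tissue, group in df.groupby("tissue"):
        complete = group.dropna(subset=["repeat_length", value])
        if len(complete) < 3 or complete["repeat_length"].nunique() < 2:
            warnings.warn(
                f"tissue {tissue!r}: too few usable rows for regression; skipped",
                stacklevel=2,
            )
            continue
        out[str(tissue)] = _ols(
            complete["repeat_length"].to_numpy(float),
            complete[value].to_numpy(float),
            predictor="repeat_length",
            response=value,
            n_dropped=len(group) - len(complete),
        )
    return out


def cross_locus_correlation(
    means_a: Mapping[str, float], means_b: Mapping[str, float]
) -> CorrelationResult:
    """Pearson correlation of per-tissue mean indices between two loci.

    Only tissues present in both maps enter; at least 4 shared tissues are
    required.  Pearson is used directly (tissue means, small n), matching the
    usual presentation of cross-locus instability comparisons.
    """
    shared = sorted(set(means_a) & set(means_b))
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared tissues, have {len(shared)}")
    a = np.array([means_a[t] for t in shared], dtype=float)
    b = np.array([means_b[t] for t in shared], dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return CorrelationResult("pearson", 1.0 if np.allclose(a - a.mean(), b - b.mean()) else np.nan,
                                 np.nan, len(shared))
    r, p = stats.pearsonr(a, b)
    return CorrelationResult("pearson", float(r), float(p), len(shared))


@dataclass(frozen=True)
class HeatmapClusterResult:
    """Scaled matrix plus clustering output.

    ``matrix`` is individuals x tissues, z-scored within each tissue column
    (ddof=1) over non-missing entries, with missing cells preserved as NaN.
    Row/column orders are dendrogram leaf orders; ``column_clusters`` maps
    tissue -> flat cluster id.
    """

    matrix: pd.DataFrame
    row_order: list[str]
    column_order: list[str]
    row_linkage: np.ndarray
    column_linkage: np.ndarray
    column_clusters: dict[str, int]
    dropped_tissues: list[str]
    dropped_individuals: list[str]


def _scale_columns(mat: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    dropped = []
    out = {}
    for col in mat.columns:
        v = mat[col]
        sd = v.std(ddof=1, skipna=True)
        if not np.isfinite(sd) or sd == 0:
            dropped.append(str(col))
            continue
        out[col] = (v - v.mean(skipna=True)) / sd
    if dropped:
        warnings.warn(f"dropped constant/empty column(s): {dropped}", stacklevel=3)
    return pd.DataFrame(out, index=mat.index), dropped


def _pairwise_manhattan(x: np.ndarray) -> np.ndarray:
    """Condensed pairwise-complete Manhattan distances between rows of x.

    For each pair, |differences| are summed over entries observed in both
    rows and rescaled by the fraction of shared entries (so sparsely shared
    pairs are not spuriously close).  Pairs with no shared entries get the
    largest finite distance observed.
    """
    n, p = x.shape
    d = np.full(n * (n - 1) // 2, np.nan)
    idx = 0
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~np.isnan(x[i]) & ~np.isnan(x[j])
            k = int(shared.sum())
            if k > 0:
                d[idx] = np.abs(x[i, shared] - x[j, shared]).sum() * (p / k)
            idx += 1
    if np.isnan(d).any():
        finite = d[~np.isnan(d)]
        fill = (finite.max() * 2.0) if finite.size else 1.0
        warnings.warn("row/column pair(s) with no shared entries; distance imputed "
                      "as twice the maximum observed", stacklevel=3)
        d[np.isnan(d)] = fill
    return d


def heatmap_cluster(
    cohort: pd.DataFrame,
    value: str = "expansion_index",
    min_measures_per_tissue: int = 12,
    min_tissues_per_individual: int = 6,
    linkage_method: str = "average",
    n_column_clusters: int = 2,
) -> HeatmapClusterResult:
    """Exclusion-filtered, z-scored, Manhattan-clustered instability heatmap.

    Tissues with fewer than ``min_measures_per_tissue`` measurements and
    individuals with fewer than ``min_tissues_per_individual`` measured
    tissues are excluded (to avoid poor normalization during scaling); the
    remaining matrix is z-scored per tissue column and clustered on both axes
    by agglomerative (default average-linkage) clustering with
    pairwise-complete Manhattan distance.  Missing cells stay missing in the
    returned matrix.
    """
    df = cohort.dropna(subset=[value])
    mat = df.pivot_table(index="individual_id", columns="tissue", values=value,
                         aggfunc="mean")
    thin_tissues = [str(c) for c in mat.columns
                    if mat[c].notna().sum() < min_measures_per_tissue]
    mat = mat.drop(columns=thin_tissues)
    thin_individuals = [str(i) for i in mat.index
                        if mat.loc[i].notna().sum() < min_tissues_per_individual]
    mat = mat.drop(index=thin_individuals)
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("matrix degenerate after exclusions "
                         f"({mat.shape[0]} individuals x {mat.shape[1]} tissues)")
    scaled, dropped_cols = _scale_columns(mat)
    if scaled.shape[1] < 2:
        raise ValueError("fewer than 2 tissues left after dropping constant columns")
    x = scaled.to_numpy(float)
    row_link = hierarchy.linkage(_pairwise_manhattan(x), method=linkage_method)
    col_link = hierarchy.linkage(_pairwise_manhattan(x.T), method=linkage_method)
    row_order = [str(scaled.index[i]) for i in hierarchy.leaves_list(row_link)]
    col_order = [str(scaled.columns[i]) for i in hierarchy.leaves_list(col_link)]
    flat = hierarchy.fcluster(col_link, t=n_column_clusters, criterion="maxclust")
    col_clusters = {str(c): int(k) for c, k in zip(scaled.columns, flat)}
    return HeatmapClusterResult(
        matrix=scaled,
        row_order=row_order,
        column_order=col_order,
        row_linkage=row_link,
        column_linkage=col_link,
        column_clusters=col_clusters,
        dropped_tissues=thin_tissues + dropped_cols,
        dropped_individuals=thin_individuals,
    )
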