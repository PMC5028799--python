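"""Normalisation, biomass partitioning, abundance profiles and statistics.

Intensity matrices are plain pandas DataFrames (proteins/taxa x samples) with
NaN marking non-detection.  Quantile normalisation follows the limma
convention: every column is mapped onto the common distribution of row-sorted
cross-column means, with columns of unequal observed length handled by rank
interpolation.  Between-group tests are Mann-Whitney U (exact when tie-free)
with Benjamini-Hochberg correction; the human-protein path is log2 transform,
constant-floor imputation (PCA only), per-protein one-way ANOVA with BH, and
hierarchical clustering of significant proteins on row mean-centred Euclidean
distances with average linkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError
from .lca import KINGDOM_BACTERIA, LCAAssignment
from .proteingroups import SampleDesign
from .taxonomy import TaxonomyTree

log = logging.getLogger(__name__)

#: log2-scale constant used to impute missing values before PCA; in the study
#: design it equals the lowest measured protein intensity.
IMPUTE_CONSTANT = 19.0

#: pairwise comparisons run for taxon abundance profiles
TAXON_COMPARISONS = (("caries", "healthy"), ("periodontitis", "healthy"))


# -- normalisation ---------------------------------------------------------


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Map every sample column onto the common mean distribution.

    Missing entries stay missing; within-column rank order is preserved and
    tied values receive the mean of their target quantiles.  Raises
    :class:`DegenerateInputError` naming any all-missing column.
    """
    if m.shape[1] < 2:
        raise DegenerateInputError("quantile normalisation needs >= 2 samples")
    for col in m.columns:
        if m[col].isna().all():
            raise DegenerateInputError(f"sample {col!r} has no observed values")

    x = m.to_numpy(dtype=float)
    nrow = x.shape[0]
    grid = np.linspace(0.0, 1.0, nrow) if nrow > 1 else np.array([0.0])
    # reference: mean across columns of each column's observed quantiles
    ref = np.zeros(nrow)
    for j in range(x.shape[1]):
        obs = np.sort(x[~np.isnan(x[:, j]), j])
        ref += np.quantile(obs, grid)
    ref /= x.shape[1]

    out = np.full_like(x, np.nan)
    for j in range(x.shape[1]):
        idx = np.flatnonzero(~np.isnan(x[:, j]))
        vals = x[idx, j]
        order = np.argsort(vals, kind="stable")
        n = len(idx)
        probs = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
        targets = np.interp(probs, grid, ref)
        assigned = np.empty(n)
        assigned[order] = targets
        # average targets over ties so equal inputs stay equal
        series = pd.Series(assigned).groupby(vals).transform("mean").to_numpy()
        out[idx, j] = series
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def log2_and_impute(
    m: pd.DataFrame, impute_constant: float = IMPUTE_CONSTANT, impute: bool = True
) -> pd.DataFrame:
    """log2-transform observed intensities; optionally fill missing cells.

    The imputation constant is already on the log2 scale and is only meant
    for procedures that need complete data (PCA); leave ``impute=False`` for
    the ANOVA path, which works on observed values.
    """
    bad = (m <= 0).stack()
    if bad.any():
        where = bad[bad].index[0]
        raise DegenerateInputError(f"non-positive observed intensity at {where}")
    out = np.log2(m)
    if impute:
        out = out.fillna(impute_constant)
    return out


# -- biomass & abundance ---------------------------------------------------


def impute_row_mean(m: pd.DataFrame) -> pd.DataFrame:
    """Fill missing cells with the row mean (neutral after row-centring).

    Used on the clustering path, where the constant-floor imputation meant
    for PCA would turn sporadically-missing cells into distance outliers.
    Rows with no observed value at all are left untouched.
    """
    means = m.mean(axis=1)
    return m.apply(lambda col: col.fillna(means))


def biomass_partition(
    m: pd.DataFrame, assignments: list[LCAAssignment]
) -> dict[str, float]:
    """Fraction of total summed intensity per kingdom; fractions sum to 1."""
    kingdom = {a.group_id: a.kingdom for a in assignments}
    missing = [i for i in m.index if i not in kingdom]
    if missing:
        raise ValueError(f"rows without an assignment: {missing[:5]}")
    totals: dict[str, float] = {}
    row_sums = m.sum(axis=1, skipna=True)
    for gid, s in row_sums.items():
        totals[kingdom[gid]] = totals.get(kingdom[gid], 0.0) + float(s)
    grand = sum(totals.values())
    if grand <= 0:
        raise DegenerateInputError("zero total intensity; biomass undefined")
    return {k: v / grand for k, v in totals.items()}


def taxon_abundance(
    m: pd.DataFrame,
    assignments: list[LCAAssignment],
    tree: TaxonomyTree,
    rank: str,
) -> pd.DataFrame:
    """Relative intensity per rank-level taxon (taxa x samples, columns sum 1).

    A bacterial group contributes to the taxon at ``rank`` found on its LCA
    lineage; groups whose LCA sits above ``rank`` cannot be placed and are
    excluded (from the denominator too, which is the total intensity of
    groups assigned at ``rank`` or below).
    """
    if rank not in ("genus", "species"):
        raise ValueError("rank must be 'genus' or 'species'")
    rows: dict[int, np.ndarray] = {}
    placed_any = False
    for a in assignments:
        if a.kingdom != KINGDOM_BACTERIA or a.lca_taxid is None:
            continue
        if a.group_id not in m.index:
            continue
        taxon = tree.ancestor_at_rank(a.lca_taxid, rank)
        if taxon is None:
            continue
        placed_any = True
        vec = m.loc[a.group_id].fillna(0.0).to_numpy(dtype=float)
        rows[taxon] = rows.get(taxon, np.zeros(m.shape[1])) + vec
    if not placed_any:
        log.warning("no bacterial groups placeable at rank %s", rank)
        return pd.DataFrame(columns=m.columns)
    ab = pd.DataFrame(rows).T
    ab.columns = m.columns
    ab = ab.sort_index()
    colsum = ab.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ab = ab.div(colsum.where(colsum > 0), axis=1)
    return ab


# -- hypothesis testing ----------------------------------------------------


@dataclass(frozen=True)
class TestResult:
    feature: object
    statistic: float
    p: float
    q: float
    comparison: str = ""


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mannwhitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact null distribution when the pooled data is tie-free, otherwise the
    normal approximation with tie correction.  Fully tied data (zero variance
    of ranks) gets U = n1*n2/2 and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return x.size * y.size / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "asymptotic" if has_ties else "exact"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(res.pvalue)
    return float(res.statistic), min(p, 1.0) if np.isfinite(p) else 1.0


def compare_taxa(
    abundance: pd.DataFrame,
    design: SampleDesign,
    comparisons=TAXON_COMPARISONS,
) -> list[TestResult]:
    """Per-taxon two-group Mann-Whitney tests with BH within each comparison."""
    results: list[TestResult] = []
    for ga, gb in comparisons:
        sa = [s for s in design.members(ga) if s in abundance.columns]
        sb = [s for s in design.members(gb) if s in abundance.columns]
        if len(sa) < 2 or len(sb) < 2:
            raise ValueError(f"comparison {ga} vs {gb}: need >= 2 samples per group")
        stats_p = [
            mannwhitney(abundance.loc[t, sa], abundance.loc[t, sb])
            for t in abundance.index
        ]
        qs = bh_adjust([p for _, p in stats_p])
        label = f"{ga}_vs_{gb}"
        results.extend(
            TestResult(t, u, p, q, label)
            for t, (u, p), q in zip(abundance.index, stats_p, qs)
        )
    return results


def anova_screen(
    m: pd.DataFrame, design: SampleDesign, alpha: float = 0.05
) -> list[TestResult]:
    """Per-protein one-way fixed-effects ANOVA on observed (non-imputed) values.

    Proteins with fewer than two observed values in any group, or with zero
    between- and within-group variance (F undefined), are skipped and logged.
    BH correction is applied over the tested proteins; callers select the
    significant set as ``q < alpha``.
    """
    groups = design.groups
    cols = {g: [s for s in design.members(g)] for g in groups}
    x = {g: m[cols[g]].to_numpy(dtype=float) for g in groups}

    feats, fstats, ps = [], [], []
    for i, feat in enumerate(m.index):
        vals = [v[i][~np.isnan(v[i])] for v in x.values()]
        if any(len(v) < 2 for v in vals):
            log.debug("anova skip %s reason=insufficient_observations", feat)
            continue
        grand = np.concatenate(vals).mean()
        ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in vals)
        ssw = sum(((v - v.mean()) ** 2).sum() for v in vals)
        dfb = len(vals) - 1
        dfw = sum(len(v) for v in vals) - len(vals)
        if ssw <= 0 and ssb <= 1e-12:
            log.debug("anova skip %s reason=degenerate_variance", feat)
            continue
        if ssw <= 0:
            f, p = np.inf, 0.0
        else:
            f = (ssb / dfb) / (ssw / dfw)
            p = float(stats.f.sf(f, dfb, dfw))
        feats.append(feat)
        fstats.append(f)
        ps.append(p)
    qs = bh_adjust(ps)
    return [
        TestResult(f, s, p, q, "anova")
        for f, s, p, q in zip(feats, fstats, ps, qs)
    ]


# -- multivariate ----------------------------------------------------------


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    explained: np.ndarray  # variance-explained fractions, decreasing
    loadings: pd.DataFrame  # features x components


def pca_scores(m: pd.DataFrame) -> PCAResult:
    """PCA of samples over protein features (matrix is proteins x samples).

    Requires a complete matrix (impute first).  Components are ordered by
    decreasing explained variance; the sign of each component is fixed so its
    largest-magnitude loading is positive.
    """
    if m.isna().any().any():
        raise ValueError("PCA requires a complete matrix; impute missing values")
    X = m.to_numpy(dtype=float).T  # samples x features
    if np.allclose(X, X[0]):
        raise DegenerateInputError("constant matrix; PCA undefined")
    pca = PCA()
    scores = pca.fit_transform(X)
    load = pca.components_.T  # features x components
    for k in range(load.shape[1]):
        j = np.argmax(np.abs(load[:, k]))
        if load[j, k] < 0:
            load[:, k] *= -1
            scores[:, k] *= -1
    comp_names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=m.columns, columns=comp_names),
        explained=pca.explained_variance_ratio_,
        loadings=pd.DataFrame(load, index=m.index, columns=comp_names),
    )


@dataclass
class ClusterResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list
    col_order: list

    def cut_rows(self, k: int) -> np.ndarray:
        return hierarchy.fcluster(self.row_linkage, t=k, criterion="maxclust")


def cluster_rows(m: pd.DataFrame) -> ClusterResult:
    """Hierarchical clustering of the (ANOVA-significant) protein subset.

    Rows are mean-centred (row mean subtracted) before Euclidean distances;
    Ward linkage (robust against chaining); leaf orders are deterministic
    for a fixed input order.
    """
    if m.shape[0] < 2:
        raise DegenerateInputError("clustering needs >= 2 rows")
    if m.isna().any().any():
        raise ValueError("clustering requires a complete matrix; impute first")
    centred = m.sub(m.mean(axis=1), axis=0).to_numpy(dtype=float)
    row_link = hierarchy.linkage(pdist(centred), method="ward")
    col_link = hierarchy.linkage(pdist(centred.T), method="ward")
    return ClusterResult(
        row_linkage=row_link,
        col_linkage=col_link,
        row_order=[m.index[i] for i in hierarchy.leaves_list(row_link)],
        col_order=[m.columns[i] for i in hierarchy.leaves_list(col_link)],
    )


def results_frame(results: list[TestResult]) -> pd.DataFrame:
    """Statistical output table: feature, statistic, p, q, comparison."""
    return pd.DataFrame(
        [(r.feature, r.statistic, r.p, r.q, r.comparison) for r in results],
        columns=["feature", "statistic", "p", "q", "comparison"],
    )
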