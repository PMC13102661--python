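"""Cohort-level analyses over the sites x cells editing-level matrix.

Per-cell site calls are combined into an editing matrix whose rows are the
sites significant in at least 5% of cells (``min_samples``). On that matrix
this module runs PCA, hierarchical biclustering, cell-type-specific-site
detection (Pearson correlation against 0/1 cell-type indicator vectors,
specific when r > 0.3 and P < 0.05), within-type variance tiers
(std == 0 / <= 0.2 / <= 0.3 / > 0.3), and differential editing against a
reference cell type (two-sided Mann-Whitney U with Benjamini-Hochberg
correction per comparison).

Cells with coverage but no variant at a site contribute a level of 0;
cells with no coverage are NA in the matrix and are imputed to 0 for PCA,
clustering and correlation (undetected editing at zero depth is treated as
no observed editing); the TSV output keeps NA so users can re-impute.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.stats import mannwhitneyu, rankdata
from sklearn.decomposition import PCA

from .site_calling import SampleProfile, bh_adjust

logger = logging.getLogger(__name__)

DEFAULT_PREVALENCE = 0.05
DEFAULT_R_MIN = 0.3
DEFAULT_ALPHA = 0.05
DEFAULT_STD_LOW = 0.2
DEFAULT_STD_HIGH = 0.3


class CohortError(ValueError):
    pass


@dataclass
class EditingMatrix:
    """Sites x cells editing levels with per-cell type labels."""

    levels: pd.DataFrame  # rows: site names; columns: cell ids; NaN = no coverage
    cell_types: pd.Series  # index: cell ids

    def __post_init__(self) -> None:
        if self.levels.index.has_duplicates or self.levels.columns.has_duplicates:
            raise CohortError("duplicate site names or cell ids")
        missing = set(self.levels.columns) - set(self.cell_types.index)
        if missing:
            raise CohortError(f"cells without type annotation: {sorted(missing)[:5]}")
        self.cell_types = self.cell_types.loc[self.levels.columns]

    def imputed(self) -> pd.DataFrame:
        """NA (no coverage) imputed to 0."""
        return self.levels.fillna(0.0)


def min_samples(n_samples: int, fraction: float = DEFAULT_PREVALENCE) -> int:
    """Smallest sample count meeting a prevalence fraction: ceil(f * n)."""
    if n_samples < 1:
        raise CohortError("n_samples must be >= 1")
    if not 0.0 < fraction <= 1.0:
        raise CohortError("fraction must lie in (0, 1]")
    return math.ceil(fraction * n_samples)


def combine_samples(
    profiles: Sequence[SampleProfile],
    min_prevalence: float = DEFAULT_PREVALENCE,
) -> EditingMatrix:
    """Merge per-cell profiles into an editing matrix.

    Rows are the sites significant in at least ``min_samples`` cells. A cell's
    entry is its level for the site, 0 when the position is covered but the
    variant unobserved, NA when the cell has no coverage there.
    """
    if len(profiles) < 2:
        raise CohortError("need at least two sample profiles")
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise CohortError("duplicate cell ids among profiles")
    threshold = min_samples(len(profiles), min_prevalence)
    sig_counts: dict = {}
    for p in profiles:
        for c in p.significant_calls():
            sig_counts[c.key] = sig_counts.get(c.key, 0) + 1
    keys = sorted(k for k, n in sig_counts.items() if n >= threshold)
    from .reference_io import format_site_name

    names = [format_site_name(k) for k in keys]
    data = np.full((len(keys), len(profiles)), np.nan)
    for j, p in enumerate(profiles):
        levels = {c.key: c.level for c in p.calls}
        for i, k in enumerate(keys):
            if k in levels:
                data[i, j] = levels[k]
            elif p.coverage.get((k.precursor, k.position), 0.0) > 0:
                data[i, j] = 0.0
    levels = pd.DataFrame(data, index=names, columns=ids)
    cell_types = pd.Series({p.sample_id: p.cell_type for p in profiles})
    return EditingMatrix(levels=levels, cell_types=cell_types)


@dataclass
class PCAResult:
    scores: pd.DataFrame  # cells x components
    loadings: pd.DataFrame  # sites x components
    explained_variance_ratio: np.ndarray


def pca(matrix: EditingMatrix, n_components: int = 3) -> PCAResult:
    """Principal components of cells in editing-level space.

    Column-mean centered, unscaled SVD. Component signs are fixed by making
    each loading vector's largest-magnitude entry positive.
    """
    X = matrix.imputed().to_numpy().T  # cells x sites
    if X.shape[0] < 2:
        raise CohortError("PCA needs at least 2 cells")
    n_components = min(n_components, min(X.shape))
    if np.allclose(X, X[0]):
        logger.warning("pca: constant matrix, zero variance explained")
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T  # sites x components
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.levels.columns, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=matrix.levels.index, columns=comp_names),
        explained_variance_ratio=model.explained_variance_ratio_,
    )


@dataclass
class BiclusterResult:
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None
    row_order: list[str]
    col_order: list[str]
    reordered: pd.DataFrame


def _newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _newick(node.get_left(), labels)
    right = _newick(node.get_right(), labels)
    return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    return _newick(to_tree(Z), list(labels)) + ";"


def hier_bicluster(matrix: EditingMatrix) -> BiclusterResult:
    """Agglomerative clustering of rows and columns independently.

    Euclidean distance, complete linkage, deterministic leaf order.
    """
    df = matrix.imputed()

    def cluster(X: np.ndarray, labels: pd.Index):
        if X.shape[0] < 2:
            return None, list(labels)
        Z = linkage(X, method="complete", metric="euclidean")
        order = [labels[i] for i in leaves_list(Z)]
        return Z, order

    row_Z, row_order = cluster(df.to_numpy(), df.index)
    col_Z, col_order = cluster(df.to_numpy().T, df.columns)
    return BiclusterResult(
        row_linkage=row_Z,
        col_linkage=col_Z,
        row_order=row_order,
        col_order=col_order,
        reordered=df.loc[row_order, col_order],
    )


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p from the t statistic with n-2 df."""
    from scipy.stats import t as t_dist

    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    vx, vy = float(xc @ xc), float(yc @ yc)
    # sums-of-squares below ~1e-20 are numerically constant vectors
    if vx <= 1e-20 or vy <= 1e-20 or n < 3:
        return float("nan"), float("nan")
    denom = math.sqrt(vx * vy)
    r = float(xc @ yc) / denom
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2.0 * float(t_dist.sf(abs(t), n - 2))
    return r, p


@dataclass(frozen=True)
class SpecificityResult:
    site: str
    cell_type: str
    r: float
    p: float
    specific: bool


def cell_type_specific_sites(
    matrix: EditingMatrix,
    r_min: float = DEFAULT_R_MIN,
    alpha: float = DEFAULT_ALPHA,
    method: str = "pearson",
) -> list[SpecificityResult]:
    """Correlate each site's levels with each cell type's indicator vector.

    A site is specific to a type when r > ``r_min`` and P < ``alpha``.
    Zero-variance sites or degenerate indicators give undefined r and are
    never specific.
    """
    types = sorted(matrix.cell_types.unique())
    if len(types) < 2:
        raise CohortError("need at least two distinct cell types")
    X = matrix.imputed()
    results: list[SpecificityResult] = []
    for ct in types:
        indicator = (matrix.cell_types == ct).to_numpy(dtype=float)
        if indicator.std() == 0:
            logger.warning("degenerate indicator for type %s", ct)
        for site in X.index:
            y = X.loc[site].to_numpy(dtype=float)
            if method == "spearman":
                xv = rankdata(indicator)
                yv = rankdata(y)
            else:
                xv, yv = indicator, y
            r, p = _pearson_with_p(xv, yv)
            specific = bool(not math.isnan(r) and r > r_min and p < alpha)
            results.append(SpecificityResult(site=site, cell_type=ct, r=r, p=p, specific=specific))
    return results


@dataclass(frozen=True)
class VarianceResult:
    site: str
    cell_type: str
    std: float
    group: str  # zero | low | medium | high


def variance_group(std: float, t_low: float = DEFAULT_STD_LOW, t_high: float = DEFAULT_STD_HIGH) -> str:
    if std == 0.0:
        return "zero"
    if std <= t_low:
        return "low"
    if std <= t_high:
        return "medium"
    return "high"


def variance_groups(
    matrix: EditingMatrix,
    t_low: float = DEFAULT_STD_LOW,
    t_high: float = DEFAULT_STD_HIGH,
) -> list[VarianceResult]:
    """Within-type population standard deviation of each site, tiered.

    The reported "low variance" class downstream is zero plus low
    (std <= ``t_low``); boundary values fall in the lower tier.
    """
    X = matrix.imputed()
    results: list[VarianceResult] = []
    for ct in sorted(matrix.cell_types.unique()):
        cols = matrix.cell_types.index[matrix.cell_types == ct]
        if len(cols) < 2:
            logger.warning("variance_groups: type %s has < 2 cells; skipped", ct)
            continue
        sub = X[cols].to_numpy(dtype=float)
        stds = sub.std(axis=1, ddof=0)
        for site, s in zip(X.index, stds):
            results.append(
                VarianceResult(site=site, cell_type=ct, std=float(s), group=variance_group(float(s), t_low, t_high))
            )
    return results


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null enumeration when the pooled size is at most 16 and there are
    no ties; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise CohortError("Mann-Whitney groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 16 and no_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass(frozen=True)
class DifferentialResult:
    site: str
    cell_type: str
    reference: str
    U: float
    p: float
    p_adj: float
    direction: str  # higher | lower | equal (median in comparison vs reference)
    significant: bool


def differential_editing(
    matrix: EditingMatrix,
    reference_type: str,
    alpha: float = DEFAULT_ALPHA,
    use_adjusted: bool = True,
) -> list[DifferentialResult]:
    """Per-site Mann-Whitney comparison of each type against a reference.

    BH adjustment runs across sites within each type-vs-reference
    comparison; significance uses the adjusted p by default.
    """
    types = sorted(matrix.cell_types.unique())
    if reference_type not in types:
        raise CohortError(f"reference type {reference_type!r} not present")
    X = matrix.imputed()
    ref_cols = matrix.cell_types.index[matrix.cell_types == reference_type]
    results: list[DifferentialResult] = []
    for ct in types:
        if ct == reference_type:
            continue
        cols = matrix.cell_types.index[matrix.cell_types == ct]
        if len(cols) == 0:
            logger.warning("differential_editing: type %s has no cells; skipped", ct)
            continue
        stats, pvals, dirs = [], [], []
        for site in X.index:
            xv = X.loc[site, cols].to_numpy(dtype=float)
            yv = X.loc[site, ref_cols].to_numpy(dtype=float)
            U, p = mann_whitney_u(xv, yv)
            stats.append(U)
            pvals.append(p)
            dm = float(np.median(xv) - np.median(yv))
            dirs.append("higher" if dm > 0 else "lower" if dm < 0 else "equal")
        padj = bh_adjust(pvals)
        for site, U, p, pa, d in zip(X.index, stats, pvals, padj, dirs):
            crit = pa if use_adjusted else p
            results.append(
                DifferentialResult(
                    site=site, cell_type=ct, reference=reference_type,
                    U=U, p=p, p_adj=pa, direction=d, significant=bool(crit < alpha),
                )
            )
    return results


def specificity_to_frame(results: Sequence[SpecificityResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def variance_to_frame(results: Sequence[VarianceResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def differential_to_frame(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
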