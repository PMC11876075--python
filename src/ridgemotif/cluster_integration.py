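"""Bulk gene-cluster construction and bulk/single-cell integration statistics.

Bulk expression is floored at the mean FPKM of a control gene that the
profiled cells do not functionally express (Cd8a in regulatory T cells),
stripped of Ig/TCR V(D)J segment genes, and the differentially expressed
remainder is k-means clustered on per-gene Z-scores. Single cells are
scored against each bulk cluster with expression-bin-matched control
genes; per-subset mean scores are Z-normalized across subsets. Overlap
between bulk clusters and per-subset differential gene sets is tested
with the hypergeometric upper tail, and gene-set shifts in fold change
with the two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .io_formats import DifferentialTable, ExpressionTable

logger = logging.getLogger("ridgemotif")

# V(D)J segment gene symbols: immunoglobulin heavy/kappa/lambda and TCR
# alpha/beta/gamma/delta variable, diversity, joining segments.
DEFAULT_SEGMENT_PATTERNS = (r"^Ig[hkl][vdj]", r"^Tr[abgd][vdj]")


@dataclass
class GeneCluster:
    """One bulk k-means cluster of co-regulated genes."""

    cluster_id: str
    genes: list[str]
    centroid: pd.Series  # per-sample mean of Z-scored expression


@dataclass
class EnrichmentQuery:
    """Hypergeometric draw: q of k signature genes land in an m-gene
    cluster out of m + n detectable genes."""

    q: int
    m: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if not (0 <= self.q <= min(self.m, self.k)):
            raise ValueError(f"q={self.q} outside [0, min(m={self.m}, k={self.k})]")
        if self.n < 0 or self.k > self.m + self.n:
            raise ValueError("need n >= 0 and k <= m + n")


def filter_genes(
    expr: ExpressionTable,
    floor_gene: str = "Cd8a",
    segment_patterns: Sequence[str] = DEFAULT_SEGMENT_PATTERNS,
) -> list[str]:
    """Genes surviving the expression floor and segment-name exclusion.

    Removes genes whose all-sample mean FPKM is below the floor gene's
    mean, genes with zero counts in a strict majority of samples, and
    genes matching any Ig/TCR V(D)J segment pattern.
    """
    if floor_gene not in expr.values.index:
        raise ValueError(f"floor gene {floor_gene!r} absent from expression table")
    floor = float(expr.values.loc[floor_gene].mean())
    means = expr.values.mean(axis=1)
    n_samples = expr.values.shape[1]
    zero_majority = (expr.values == 0).sum(axis=1) > n_samples / 2
    regexes = [re.compile(p) for p in segment_patterns]
    kept = []
    for gene in expr.values.index:
        if means[gene] < floor or zero_majority[gene]:
            continue
        if any(rx.search(gene) for rx in regexes):
            continue
        kept.append(gene)
    return kept


def zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Per-gene Z-score across samples; zero-variance rows map to 0."""
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=0)
    z = values.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0)
    return z.fillna(0.0)


def kmeans_clusters(
    zscores: pd.DataFrame,
    k: int = 7,
    seed: int = 0,
    n_init: int = 50,
) -> list[GeneCluster]:
    """k-means on per-gene Z-score profiles, labels ordered by size.

    Best of ``n_init`` k-means++ restarts; clusters are relabeled
    deterministically by descending size (ties by first gene) as roman
    numerals bI..bVII mirroring the bulk cluster naming convention.
    """
    if k > len(zscores):
        raise ValueError(f"k={k} exceeds {len(zscores)} genes")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(zscores.values)
    order = sorted(
        range(k),
        key=lambda c: (-(labels == c).sum(), zscores.index[labels == c][0] if (labels == c).any() else ""),
    )
    roman = ["bI", "bII", "bIII", "bIV", "bV", "bVI", "bVII", "bVIII", "bIX", "bX"]
    clusters = []
    for rank, c in enumerate(order):
        genes = list(zscores.index[labels == c])
        name = roman[rank] if rank < len(roman) else f"b{rank + 1}"
        clusters.append(GeneCluster(name, genes, zscores.loc[genes].mean(axis=0)))
    return clusters


def module_score(
    logcounts: pd.DataFrame,
    gene_set: Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell module score against expression-matched controls.

    Genes are binned by average expression across cells; for every set
    gene, ``n_ctrl`` control genes are drawn with replacement from its
    bin. The score is the mean expression of the set genes minus the
    mean expression of the pooled controls, per cell.
    """
    present = [g for g in gene_set if g in logcounts.columns]
    if not present:
        raise ValueError("gene set has no overlap with the matrix genes")
    rng = np.random.default_rng(seed)
    avg = logcounts.mean(axis=0)
    # rank-based binning is robust to ties and skew
    ranks = avg.rank(method="first")
    bins = pd.cut(ranks, bins=min(n_bins, len(avg)), labels=False)
    bin_members: dict[int, np.ndarray] = {
        int(b): avg.index[bins == b].to_numpy() for b in np.unique(bins)
    }
    ctrl_genes: list[str] = []
    for g in present:
        pool = bin_members[int(bins[g])]
        ctrl_genes.extend(rng.choice(pool, size=n_ctrl, replace=True))
    set_mean = logcounts[present].mean(axis=1)
    ctrl_mean = logcounts[ctrl_genes].mean(axis=1)
    return set_mean - ctrl_mean


@dataclass
class ModuleScoreTable:
    """Per-subset mean module scores, Z-normalized across subsets."""

    means: pd.DataFrame  # subsets x gene clusters, raw means
    zscores: pd.DataFrame  # same shape, Z across subsets per gene cluster
    excluded_subsets: list[str]


def subset_score_matrix(
    scores: pd.DataFrame,
    subset_labels: pd.Series,
    min_cells: int = 20,
) -> ModuleScoreTable:
    """Mean score per cell subset, then Z across subsets per gene cluster.

    Subsets with fewer than ``min_cells`` cells are excluded before the
    normalization. A gene cluster with identical means across subsets has
    no defined Z-score; it is reported as 0 with a warning.
    """
    subset_labels = subset_labels.reindex(scores.index)
    if subset_labels.isna().any():
        raise ValueError("every cell must carry a subset label")
    counts = subset_labels.value_counts()
    keep = counts[counts >= min_cells].index
    excluded = sorted(set(counts.index) - set(keep))
    if excluded:
        logger.info("subsets excluded for < %d cells: %s", min_cells, excluded)
    mask = subset_labels.isin(keep)
    means = scores[mask].groupby(subset_labels[mask]).mean()
    sd = means.std(axis=0, ddof=0)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning("gene clusters with identical subset means reported as Z=0: %s",
                       list(means.columns[degenerate]))
    z = (means - means.mean(axis=0)) / sd.replace(0, np.nan)
    return ModuleScoreTable(means=means, zscores=z.fillna(0.0), excluded_subsets=excluded)


def hypergeom_enrichment(query: EnrichmentQuery) -> float:
    """Upper-tail P(X >= q) for X ~ Hypergeometric(m, n, k).

    Implemented as the survival function at q - 1, the enrichment tail
    convention of R's ``phyper(q-1, m, n, k, lower.tail = FALSE)``.
    """
    return float(stats.hypergeom.sf(query.q - 1, query.m + query.n, query.m, query.k))


def geneset_shift_test(fc: pd.Series, gene_set: Sequence[str]) -> tuple[float, float]:
    """Two-sided two-sample KS test of the gene set's log2FCs versus all
    genes' log2FCs; returns (D, asymptotic p)."""
    set_vals = fc.loc[[g for g in gene_set if g in fc.index]].dropna()
    if len(set_vals) < 2 or len(fc.dropna()) < 2:
        raise ValueError("need >= 2 genes in the set and in the background")
    res = stats.ks_2samp(set_vals.values, fc.dropna().values,
                         alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def cluster_fc_correlation(
    diff_expr: DifferentialTable,
    diff_atac: DifferentialTable,
    peak_genes: Mapping[str, str],
    clusters: Sequence[GeneCluster],
    comparison: str,
) -> pd.Series:
    """Per-cluster Pearson r of gene expression log2FC vs the log2FC of
    each peak assigned to the gene (the gene's value repeated per peak)."""
    gene_fc = diff_expr.log2fc(comparison)
    peak_fc = diff_atac.log2fc(comparison)
    out = {}
    for cl in clusters:
        xs, ys = [], []
        genes = set(cl.genes)
        for peak, gene in peak_genes.items():
            if gene in genes and gene in gene_fc.index and peak in peak_fc.index:
                xs.append(gene_fc[gene])
                ys.append(peak_fc[peak])
        if len(xs) < 3:
            raise ValueError(f"cluster {cl.cluster_id}: only {len(xs)} gene-peak pairs (need >= 3)")
        out[cl.cluster_id] = float(np.corrcoef(xs, ys)[0, 1])
    return pd.Series(out)
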