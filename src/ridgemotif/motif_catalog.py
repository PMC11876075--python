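"""Motif filtering, grouping, exact scan thresholds and the peak-by-motif matrix.

The scan threshold for each PWM is computed from the exact null
distribution of its log-odds score under the background model: scores
are integerized onto a lattice (a fixed number of bins per position) and
the full distribution over words is accumulated by dynamic programming,
position by position. The threshold is the smallest achievable score
whose upper-tail probability does not exceed the requested p-value; if
even the top score is too probable (short or degenerate motifs) the
motif matches nothing.

Motif similarity for grouping is accepted as a precomputed E-value table
or, failing that, computed internally as a best-offset ungapped Pearson
correlation between the probability matrices converted to an E-value-like
score. This surrogate preserves the grouping logic (threshold, family
guard, gene-uniqueness fixpoint) without reproducing external motif-
comparison statistics bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import BASES, ExpressionTable, Pwm

logger = logging.getLogger("ridgemotif")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifGroup:
    """A set of PWMs grouped by similarity within one protein family."""

    group_id: str
    members: list[str]
    genes: list[str]
    representative: str | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group {self.group_id}: no members")


@dataclass
class PeakMotifMatrix:
    """Binary peaks x motif-groups presence matrix (the ridge design)."""

    values: pd.DataFrame  # index: peak ids, columns: group ids, entries {0,1}

    def __post_init__(self) -> None:
        v = self.values.values
        if not np.isin(v, (0, 1)).all():
            raise ValueError("peak-by-motif matrix entries must be 0/1")

    @property
    def peaks(self) -> list[str]:
        return list(self.values.index)

    @property
    def groups(self) -> list[str]:
        return list(self.values.columns)

    def occurrence_fractions(self) -> pd.Series:
        return self.values.mean(axis=0)


@dataclass
class ScanThreshold:
    """Exact log-odds score cutoff for one PWM at a target p-value.

    ``min_score`` is +inf when no achievable score is rare enough, in
    which case the motif matches nothing. The integerized per-position
    score table and its scale are kept so that scanning happens on the
    same lattice the threshold was computed on.
    """

    pwm_name: str
    background: np.ndarray
    pvalue: float
    min_score: float
    int_scores: np.ndarray = field(repr=False)  # L x 4 integers
    min_score_int: float = field(repr=False, default=np.inf)
    scale: float = field(repr=False, default=1.0)
    offset: float = field(repr=False, default=0.0)


def score_threshold(
    pwm: Pwm,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    pvalue: float = 1e-4,
    precision: int = 1000,
    pseudocount: float = 1e-4,
) -> ScanThreshold:
    """Exact null score distribution by DP on an integerized score lattice.

    Probabilities get a pseudocount and rows are renormalized before the
    log-odds transform; per-position scores are shifted to be nonnegative
    and scaled so the widest position spans ``precision`` integer bins.
    The null distribution of the summed integer score under the i.i.d.
    background is then an L-fold convolution computed exactly.
    """
    bg = np.asarray(background, dtype=float)
    if (bg <= 0).any():
        raise ValueError("background frequencies must be strictly positive")
    bg = bg / bg.sum()
    probs = pwm.matrix + pseudocount
    probs = probs / probs.sum(axis=1, keepdims=True)
    lo = np.log2(probs / bg)  # L x 4 log-odds

    row_min = lo.min(axis=1)
    shifted = lo - row_min[:, None]
    max_range = shifted.max()
    if max_range == 0:  # every word scores identically; tail mass is 1
        int_scores = np.zeros_like(lo, dtype=np.int64)
        return ScanThreshold(pwm.name, bg, pvalue, np.inf, int_scores,
                             min_score_int=np.inf, scale=1.0, offset=float(row_min.sum()))
    scale = precision / max_range
    int_scores = np.rint(shifted * scale).astype(np.int64)

    max_total = int(int_scores.max(axis=1).sum())
    dist = np.zeros(max_total + 1)
    dist[0] = 1.0
    top = 0
    for i in range(pwm.length):
        new = np.zeros(max_total + 1)
        for b in range(4):
            s = int(int_scores[i, b])
            new[s : top + s + 1] += bg[b] * dist[: top + 1]
        row_top = int(int_scores[i].max())
        top += row_top
        dist = new

    tail = np.cumsum(dist[::-1])[::-1]  # tail[t] = P(score >= t)
    achievable = np.nonzero(dist > 0)[0]
    ok = achievable[tail[achievable] <= pvalue]
    offset = float(row_min.sum())
    if len(ok) == 0:
        return ScanThreshold(pwm.name, bg, pvalue, np.inf, int_scores,
                             min_score_int=np.inf, scale=scale, offset=offset)
    t = int(ok[0])
    return ScanThreshold(pwm.name, bg, pvalue, t / scale + offset, int_scores,
                         min_score_int=t, scale=scale, offset=offset)


def sequence_has_hit(seq: str, threshold: ScanThreshold) -> bool:
    """True iff either strand contains a window scoring >= the cutoff.

    Windows overlapping non-ACGT characters are skipped (and logged once
    per sequence).
    """
    if not np.isfinite(threshold.min_score_int):
        return False
    L = threshold.int_scores.shape[0]
    s = seq.upper()
    if len(s) < L:
        return False
    for strand_seq in (s, reverse_complement(s)):
        idx = np.fromiter((_BASE_INDEX.get(c, -1) for c in strand_seq),
                          dtype=np.int64, count=len(strand_seq))
        valid = idx >= 0
        safe = np.where(valid, idx, 0)
        n_win = len(idx) - L + 1
        win_scores = np.zeros(n_win, dtype=np.int64)
        win_valid = np.ones(n_win, dtype=bool)
        for i in range(L):
            win_scores += threshold.int_scores[i, safe[i : i + n_win]]
            win_valid &= valid[i : i + n_win]
        if not win_valid.all():
            logger.debug("windows overlapping non-ACGT characters skipped")
        if (win_scores[win_valid] >= threshold.min_score_int).any():
            return True
    return False


def filter_expressed(pwms: Sequence[Pwm], expr: ExpressionTable, floor: float = 1.0) -> list[Pwm]:
    """Keep PWMs whose TF gene has mean FPKM strictly above the floor in
    at least one population; PWMs with unresolvable genes are dropped."""
    means = expr.population_means()
    kept: list[Pwm] = []
    for p in pwms:
        if p.tf_gene not in means.index:
            logger.warning("PWM %s: TF gene %r not in expression table, dropped", p.name, p.tf_gene)
            continue
        if (means.loc[p.tf_gene] > floor).any():
            kept.append(p)
    return kept


def motif_similarity(pwms: Sequence[Pwm], min_overlap: int = 4) -> dict[tuple[str, str], float]:
    """Best-offset ungapped Pearson similarity as an E-value-like score.

    For each pair, the probability matrices are slid against each other;
    at the best offset (highest correlation over the overlapping columns,
    overlap >= min_overlap or the shorter motif's length) the correlation
    p-value is Bonferroni-scaled by the number of pairs tested, giving a
    score on an E-value-like footing. Symmetric by construction.
    """
    sims: dict[tuple[str, str], float] = {}
    n_pairs = len(pwms) * (len(pwms) - 1) // 2
    for i in range(len(pwms)):
        for j in range(i + 1, len(pwms)):
            a, b = pwms[i], pwms[j]
            need = min(min_overlap, a.length, b.length)
            best_p = 1.0
            for offset in range(-(b.length - need), a.length - need + 1):
                lo_a, hi_a = max(0, offset), min(a.length, offset + b.length)
                if hi_a - lo_a < need:
                    continue
                xa = a.matrix[lo_a:hi_a].ravel()
                xb = b.matrix[lo_a - offset : hi_a - offset].ravel()
                if xa.std() == 0 or xb.std() == 0:
                    continue
                r, p = stats.pearsonr(xa, xb)
                if r > 0 and p / 2 < best_p:  # one-sided (positive similarity)
                    best_p = p / 2
            e = best_p * max(n_pairs, 1)
            sims[(a.name, b.name)] = e
            sims[(b.name, a.name)] = e
    return sims


class _UnionFind:
    def __init__(self, items: Sequence[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller label becomes the root
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def group_motifs(
    pwms: Sequence[Pwm],
    similarity: Mapping[tuple[str, str], float] | None = None,
    e_cut: float = 1e-5,
) -> list[MotifGroup]:
    """Group motifs by similarity within families, then merge by shared gene.

    An edge joins motifs with similarity E below ``e_cut`` AND identical
    family labels; connected components are then repeatedly merged while
    any gene spans two components, so gene -> group ends as a function.
    The fixpoint is order-independent (it is a union-find closure).
    """
    if similarity is None:
        similarity = motif_similarity(pwms)
    by_name = {p.name: p for p in pwms}
    uf = _UnionFind([p.name for p in pwms])
    for (a, b), e in similarity.items():
        if a in by_name and b in by_name and a < b:
            if e < e_cut and by_name[a].family == by_name[b].family:
                uf.union(a, b)
    # gene-uniqueness closure: union all components sharing a gene
    gene_rep: dict[str, str] = {}
    for p in sorted(pwms, key=lambda q: q.name):
        if not p.tf_gene:
            continue
        if p.tf_gene in gene_rep:
            uf.union(gene_rep[p.tf_gene], p.name)
        else:
            gene_rep[p.tf_gene] = p.name

    comps: dict[str, list[str]] = {}
    for p in pwms:
        comps.setdefault(uf.find(p.name), []).append(p.name)
    groups: list[MotifGroup] = []
    for i, root in enumerate(sorted(comps)):
        members = sorted(comps[root])
        genes = sorted({by_name[m].tf_gene for m in members if by_name[m].tf_gene})
        groups.append(MotifGroup(group_id=f"G{i:03d}", members=members, genes=genes))
    return groups


def scan_matrix(
    sequences: Mapping[str, str],
    groups: Sequence[MotifGroup],
    thresholds: Mapping[str, ScanThreshold],
) -> PeakMotifMatrix:
    """Binary presence matrix: 1 iff any member PWM of the group has at
    least one above-threshold window on either strand of the peak."""
    data = np.zeros((len(sequences), len(groups)), dtype=np.int8)
    peak_ids = list(sequences)
    for j, g in enumerate(groups):
        ths = [thresholds[m] for m in g.members if m in thresholds]
        for i, pid in enumerate(peak_ids):
            seq = sequences[pid]
            if any(sequence_has_hit(seq, th) for th in ths):
                data[i, j] = 1
    return PeakMotifMatrix(pd.DataFrame(data, index=peak_ids,
                                        columns=[g.group_id for g in groups]))


def enrichment_filter(
    groups: Sequence[MotifGroup],
    matrix: PeakMotifMatrix,
    background_matrix: PeakMotifMatrix,
    alpha: float = 0.01,
) -> list[MotifGroup]:
    """Keep groups enriched in the atlas over background sequences.

    One-sided Fisher exact test of occurrence counts per group, atlas vs
    background, Benjamini-Hochberg corrected across groups; groups with
    adjusted p < alpha survive.
    """
    from statsmodels.stats.multitest import multipletests

    n_atlas = len(matrix.peaks)
    n_bg = len(background_matrix.peaks)
    pvals = []
    for g in groups:
        a = int(matrix.values[g.group_id].sum())
        b = int(background_matrix.values[g.group_id].sum())
        if a == 0 and b == 0:
            pvals.append(1.0)
            continue
        _, p = stats.fisher_exact([[a, n_atlas - a], [b, n_bg - b]], alternative="greater")
        pvals.append(p)
    if not groups:
        return []
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    kept = [g for g, q in zip(groups, padj) if q < alpha]
    for g, q in zip(groups, padj):
        if q >= alpha:
            logger.info("group %s dropped by enrichment filter (adj p = %.3g)", g.group_id, q)
    return kept


def prevalence_filter(matrix: PeakMotifMatrix, min_frac: float = 0.02) -> PeakMotifMatrix:
    """Drop columns occurring in fewer than ``min_frac`` of peaks (strict <)."""
    frac = matrix.occurrence_fractions()
    keep = frac[frac >= min_frac].index
    if len(keep) == 0:
        raise ValueError(
            "prevalence filter removed every motif group; review the scan "
            "threshold or the prevalence cutoff"
        )
    return PeakMotifMatrix(matrix.values[list(keep)])


def pick_representative(group: MotifGroup, member_fractions: Mapping[str, float]) -> str:
    """Member detected in the highest fraction of peaks; ties break
    lexicographically by motif name (logged)."""
    best = max(group.members, key=lambda m: (member_fractions.get(m, 0.0), ))
    top = member_fractions.get(best, 0.0)
    tied = sorted(m for m in group.members if member_fractions.get(m, 0.0) == top)
    if len(tied) > 1:
        logger.info("group %s: representative tie among %s, keeping %s",
                    group.group_id, tied, tied[0])
    group.representative = tied[0]
    return tied[0]


def member_occurrence_fractions(
    sequences: Mapping[str, str], thresholds: Mapping[str, ScanThreshold]
) -> dict[str, float]:
    """Per-PWM fraction of sequences with at least one hit."""
    out: dict[str, float] = {}
    n = max(len(sequences), 1)
    for name, th in thresholds.items():
        hits = sum(1 for seq in sequences.values() if sequence_has_hit(seq, th))
        out[name] = hits / n
    return out
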