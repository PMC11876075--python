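"""Merged peak-atlas construction from per-population peak calls.

Overlapping peaks (>= 1 bp shared, half-open semantics; bookended
intervals do not touch) are clustered by transitive closure. Each cluster
is merged to a single consensus peak when every summit falls inside the
cluster's common core [max(starts), min(ends)) — the fully overlapping
case — or split into one peak per distinct summit otherwise. Filters then
drop over-wide peaks, repeat-dominated peaks and peaks off the declared
chromosomes, and surviving peaks are assigned to genes by promoter /
intragenic / intergenic precedence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from .io_formats import AtlasPeak, GeneModel, Peak

logger = logging.getLogger("ridgemotif")


@dataclass
class PeakCluster:
    """Peaks on one chromosome connected by chained >= 1 bp overlaps."""

    peaks: list[Peak]
    cluster_id: int

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("empty peak cluster")
        chroms = {p.chrom for p in self.peaks}
        if len(chroms) > 1:
            raise ValueError(f"cluster {self.cluster_id} spans chromosomes {sorted(chroms)}")


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (order-free)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def cluster_peaks(peaks: Sequence[Peak]) -> list[PeakCluster]:
    """Partition peaks into overlap clusters (bedtools ``cluster -d -1``).

    Two peaks share a cluster iff they are connected by a chain of pairwise
    overlaps of at least one base. With half-open coordinates a sweep over
    (chrom, start)-sorted peaks suffices: a peak opens a new cluster when
    its start is at or past the running maximum end of the current one.
    """
    clusters: list[PeakCluster] = []
    cid = 0
    ordered = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
    current: list[Peak] = []
    current_end = -1
    current_chrom: str | None = None
    for p in ordered:
        if current and (p.chrom != current_chrom or p.start >= current_end):
            clusters.append(PeakCluster(current, cid))
            cid += 1
            current = []
        if not current:
            current_chrom = p.chrom
            current_end = p.end
        current.append(p)
        current_end = max(current_end, p.end)
    if current:
        clusters.append(PeakCluster(current, cid))
    return clusters


def merge_cluster(cluster: PeakCluster) -> list[AtlasPeak]:
    """Merge one overlap cluster into consensus atlas peak(s).

    Fully overlapping case — every summit inside the common core
    [max(starts), min(ends)): one peak at the rounded mean start, summit
    and end of all members. Otherwise (multiple distinct summits): one
    peak per distinct summit coordinate ``s``, bounded by the closest
    member start at or before ``s`` and the closest member end after it.
    """
    peaks = cluster.peaks
    n = len(peaks)
    starts = [p.start for p in peaks]
    ends = [p.end for p in peaks]
    summits = [p.summit for p in peaks]
    chrom = peaks[0].chrom
    core_lo, core_hi = max(starts), min(ends)
    score = max(p.score for p in peaks)

    if all(core_lo <= s < core_hi for s in summits):
        start = _round_half_away(sum(starts) / n)
        summit = _round_half_away(sum(summits) / n)
        end = _round_half_away(sum(ends) / n)
        if start >= end:  # rounding collapsed a 1-bp interval
            end = start + 1
        summit = min(max(summit, start), end - 1)
        return [
            AtlasPeak(chrom, start, end, summit, score=score,
                      origin_cluster=cluster.cluster_id, n_source_peaks=n)
        ]

    out: list[AtlasPeak] = []
    for s in sorted(set(summits)):
        start = max(st for st in starts if st <= s)
        end = min(en for en in ends if en > s)
        out.append(
            AtlasPeak(chrom, start, end, s, score=score,
                      origin_cluster=cluster.cluster_id, n_source_peaks=n)
        )
    return out


def build_atlas(peaks: Sequence[Peak]) -> list[AtlasPeak]:
    """Cluster then merge; peak ids are assigned in genomic order."""
    atlas: list[AtlasPeak] = []
    for cluster in cluster_peaks(peaks):
        atlas.extend(merge_cluster(cluster))
    for i, p in enumerate(atlas):
        p.name = f"peak_{i}"
    return atlas


def repeat_fraction(peak: Peak, sequence: str | None = None,
                    repeat_intervals: Sequence[tuple[str, int, int]] | None = None) -> float:
    """Fraction of the peak covered by repeats.

    From a soft-masked sequence: fraction of lowercase bases. From a BED
    of repeat intervals: covered bp / width. The sequence wins when both
    are supplied.
    """
    if sequence is not None:
        if len(sequence) != peak.width:
            raise ValueError(
                f"{peak.name}: sequence length {len(sequence)} != width {peak.width}"
            )
        return sum(1 for c in sequence if c.islower()) / peak.width
    if repeat_intervals is not None:
        covered = 0
        for chrom, start, end in repeat_intervals:
            if chrom == peak.chrom:
                covered += max(0, min(end, peak.end) - max(start, peak.start))
        return min(covered, peak.width) / peak.width
    return 0.0


def filter_atlas(
    atlas: Sequence[AtlasPeak],
    max_width: int = 3500,
    repeat_frac: float = 0.70,
    sequences: dict[str, str] | None = None,
    repeat_intervals: Sequence[tuple[str, int, int]] | None = None,
    chromosomes: set[str] | None = None,
) -> list[AtlasPeak]:
    """Retain peaks with width <= max_width, repeat fraction <= repeat_frac
    (strictly greater is eliminated) and chromosome in the declared set."""
    kept: list[AtlasPeak] = []
    for p in atlas:
        if p.width > max_width:
            continue
        if chromosomes is not None and p.chrom not in chromosomes:
            continue
        seq = sequences.get(p.name) if sequences else None
        if (seq is not None or repeat_intervals is not None) and \
                repeat_fraction(p, seq, repeat_intervals) > repeat_frac:
            continue
        kept.append(p)
    return kept


def assign_peaks_to_genes(
    atlas: Sequence[AtlasPeak],
    genes: Sequence[GeneModel],
    promoter_up: int = 2000,
    promoter_down: int = 500,
    intergenic_window: int = 100_000,
) -> list[AtlasPeak]:
    """Assign each peak a category and closest gene, in place.

    Precedence promoter > intragenic > intergenic > unassigned. Promoter:
    summit within ``promoter_up`` bp 5' or ``promoter_down`` bp 3' of a
    TSS (strand-aware). Intragenic: summit inside a gene body. Intergenic:
    summit within ``intergenic_window`` bp of a gene body. Closest gene is
    by summit-to-TSS distance for promoters and summit-to-body distance
    otherwise; ties break lexicographically by gene symbol and are logged.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    for p in atlas:
        candidates = by_chrom.get(p.chrom, [])
        s = p.summit
        best: tuple[int, int, str] | None = None  # (category_rank, distance, gene)
        for g in candidates:
            tss_dist = abs(s - g.tss)
            if g.strand == "+":
                in_promoter = g.tss - promoter_up <= s <= g.tss + promoter_down
            else:
                in_promoter = g.tss - promoter_down <= s <= g.tss + promoter_up
            body_dist = max(g.tx_start - s, s - (g.tx_end - 1), 0)
            if in_promoter:
                cand = (0, tss_dist, g.gene)
            elif body_dist == 0:
                cand = (1, 0, g.gene)
            elif body_dist <= intergenic_window:
                cand = (2, body_dist, g.gene)
            else:
                continue
            if best is None or cand < best:
                best = cand
            elif cand[:2] == best[:2] and cand[2] != best[2]:
                logger.info("peak %s: tie between genes %s and %s, keeping %s",
                            p.name, best[2], cand[2], min(best[2], cand[2]))
                best = min(best, cand)
        if best is None:
            p.category, p.gene = "unassigned", None
        else:
            p.category = ("promoter", "intragenic", "intergenic")[best[0]]
            p.gene = best[2]
    return list(atlas)
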