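"""Synthetic study generator with planted ground truth.

Emulates the statistical structure of the profiled study design — three
cell populations with three replicates each, replicate peak calls
jittered around latent loci (a controlled fraction with two summits, so
the merge rule's split branch is exercised), peak sequences with planted
motif instances, per-peak log2 fold changes that are a linear function
of motif presence plus Gaussian noise, negative-binomial bulk counts
with seven planted expression archetypes, cell-by-gene matrices with
program structure aligned to the bulk clusters, and clonotype tables
sampled to match a target phenotype-overlap matrix.

One global seed fans out to per-component streams through named
SeedSequence spawn keys, so adding a component never perturbs another
component's draws.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    BASES,
    ClonotypeRecord,
    DifferentialTable,
    ExpressionTable,
    GeneModel,
    Peak,
    Pwm,
)

POPULATIONS = ("neg", "recent", "stable")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    n_peaks: int = 400  # latent accessible loci
    n_groups: int = 8  # motif groups with catalog PWMs
    planted_betas: dict[str, float] = field(
        default_factory=lambda: {"G000": 0.8, "G001": 0.5, "G002": -0.8}
    )
    noise_sd: float = 0.5
    n_populations: int = 3
    n_replicates: int = 3
    nb_dispersion: float = 0.1
    n_genes: int = 600
    n_cells: int = 1200
    n_programs: int = 7
    n_mice: int = 3
    n_clones_per_phenotype: int = 200
    clonal_overlap_target: np.ndarray | None = None
    multi_summit_frac: float = 0.18
    peak_width_mean: int = 600
    jitter_sd: int = 30
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    placement_prob: float = 0.35

    def rng(self, component: str) -> np.random.Generator:
        """Named per-component random stream derived from the global seed."""
        key = zlib.crc32(component.encode()) & 0x7FFFFFFF
        return np.random.default_rng(np.random.SeedSequence(entropy=(self.seed, key)))


@dataclass
class GroundTruth:
    """Everything planted, for downstream assertions."""

    latent_loci: list[dict] = field(default_factory=list)
    motif_placements: list[dict] = field(default_factory=list)
    true_betas: dict[str, dict[str, float]] = field(default_factory=dict)
    gene_cluster_labels: dict[str, str] = field(default_factory=dict)
    cell_programs: dict[str, str] = field(default_factory=dict)
    clonal_overlap_target: list[list[float]] | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# peak calls


def simulate_peak_calls(cfg: SimulationConfig) -> tuple[dict[str, list[Peak]], GroundTruth]:
    """Per-population replicate peak calls around latent loci.

    Most loci yield fully overlapping calls (the merge rule's averaging
    branch); a ``multi_summit_frac`` fraction carries two latent summits
    far enough apart that the calls form a distinct-summit cluster.
    """
    rng = cfg.rng("peaks")
    gt = GroundTruth()
    spacing = 6000
    calls: dict[str, list[Peak]] = {pop: [] for pop in POPULATIONS[: cfg.n_populations]}
    for i in range(cfg.n_peaks):
        center = spacing * (i + 1)
        width = int(max(200, rng.normal(cfg.peak_width_mean, 80)))
        multi = rng.random() < cfg.multi_summit_frac
        if multi:
            # two summits ~2/3 width apart: calls still overlap, but the
            # summits fall outside the cluster core, forcing a split
            summit_positions = [center - width // 3, center + width // 3]
        else:
            summit_positions = [center]
        gt.latent_loci.append(
            {"locus": i, "center": center, "width": width, "summits": summit_positions}
        )
        for p_idx, pop in enumerate(calls):
            summit = summit_positions[p_idx % len(summit_positions)]
            jitter = int(rng.normal(0, cfg.jitter_sd))
            start = summit - width // 2 + jitter
            end = summit + width // 2 + jitter
            start = min(start, summit)
            end = max(end, summit + 1)
            calls[pop].append(
                Peak("chr1", start, end, summit, score=float(rng.uniform(1, 100)),
                     source=pop, name=f"{pop}_locus{i}")
            )
    return calls, gt


def simulate_gene_models(cfg: SimulationConfig, n_genes: int = 50) -> list[GeneModel]:
    """Gene bodies interleaved with the latent loci for peak assignment."""
    rng = cfg.rng("gene_models")
    genes = []
    for i in range(n_genes):
        start = 4000 + i * (6000 * cfg.n_peaks // max(n_genes, 1))
        length = int(rng.integers(2000, 20000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"Gene{i:04d}", "chr1", strand, start, start + length))
    return genes


# ---------------------------------------------------------------------------
# motifs and sequences


def catalog_pwms(cfg: SimulationConfig, length: int = 8, sharpness: float = 0.85) -> list[Pwm]:
    """One discriminative PWM per motif group, with TF gene and family."""
    rng = cfg.rng("pwms")
    pwms = []
    for g in range(cfg.n_groups):
        consensus = rng.integers(0, 4, size=length)
        mat = np.full((length, 4), (1 - sharpness) / 3)
        mat[np.arange(length), consensus] = sharpness
        pwms.append(
            Pwm(name=f"M{g:03d}", matrix=mat, tf_gene=f"Tf{g:03d}", family=f"Fam{g % 4}")
        )
    return pwms


def simulate_sequences(
    atlas_peaks: Sequence[Peak],
    pwms: Sequence[Pwm],
    cfg: SimulationConfig,
    placement_prob: float | Mapping[str, float] | None = None,
) -> tuple[dict[str, str], GroundTruth]:
    """Background sequences with planted motif instances.

    Per (peak, PWM), with the placement probability an instance sampled
    from the PWM's probability rows is inserted at a uniform offset on a
    uniformly chosen strand; placements are recorded in the ground truth.
    """
    from .motif_catalog import reverse_complement

    rng = cfg.rng("sequences")
    if placement_prob is None:
        placement_prob = cfg.placement_prob
    probs = (
        {p.name: float(placement_prob) for p in pwms}
        if not isinstance(placement_prob, Mapping)
        else dict(placement_prob)
    )
    gt = GroundTruth()
    freqs = np.asarray(cfg.base_freqs)
    seqs: dict[str, str] = {}
    for peak in atlas_peaks:
        seq = list(rng.choice(list(BASES), size=peak.width, p=freqs))
        for pwm in pwms:
            if rng.random() >= probs.get(pwm.name, 0.0):
                continue
            if pwm.length > peak.width:
                raise ValueError(
                    f"motif {pwm.name} (L={pwm.length}) longer than peak {peak.name}"
                )
            inst = "".join(
                BASES[rng.choice(4, p=pwm.matrix[i])] for i in range(pwm.length)
            )
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                inst = reverse_complement(inst)
            off = int(rng.integers(0, peak.width - pwm.length + 1))
            seq[off : off + pwm.length] = list(inst)
            gt.motif_placements.append(
                {"peak": peak.name, "pwm": pwm.name, "offset": off, "strand": strand}
            )
        seqs[peak.name] = "".join(seq)
    return seqs, gt


def simulate_design(cfg: SimulationConfig, occurrence: float = 0.3) -> pd.DataFrame:
    """Random binary peak-by-motif design for large-scale model studies.

    Columns are independent Bernoulli(occurrence) presence indicators —
    the statistical shape of the scanned matrix without the sequence
    round trip, usable at sizes where scanning would dominate runtime.
    """
    rng = cfg.rng("design")
    X = (rng.random((cfg.n_peaks, cfg.n_groups)) < occurrence).astype(np.int8)
    return pd.DataFrame(
        X,
        index=[f"peak_{i}" for i in range(cfg.n_peaks)],
        columns=[f"G{j:03d}" for j in range(cfg.n_groups)],
    )


# ---------------------------------------------------------------------------
# differential accessibility


def simulate_accessibility(
    X: pd.DataFrame,
    cfg: SimulationConfig,
    betas_svn: Mapping[str, float] | None = None,
    betas_svr: Mapping[str, float] | None = None,
) -> tuple[DifferentialTable, GroundTruth]:
    """Per-peak log2FC = X beta + Gaussian noise, for both comparisons.

    Adjusted p-values are a rank-based stand-in: peaks in the upper
    |log2FC| quantile get small padj, the rest large, so significance
    filters downstream are exercised without re-implementing count-based
    differential testing.
    """
    rng = cfg.rng("accessibility")
    betas_svn = dict(betas_svn) if betas_svn is not None else dict(cfg.planted_betas)
    betas_svr = dict(betas_svr) if betas_svr is not None else {
        k: 0.75 * v for k, v in betas_svn.items()
    }
    gt = GroundTruth(true_betas={"svn": betas_svn, "svr": betas_svr})

    def one(betas: Mapping[str, float]) -> np.ndarray:
        b = np.array([betas.get(c, 0.0) for c in X.columns])
        return X.values @ b + rng.normal(0, cfg.noise_sd, size=len(X))

    y_svn, y_svr = one(betas_svn), one(betas_svr)

    def padj_for(y: np.ndarray) -> np.ndarray:
        cut = np.quantile(np.abs(y), 0.7)
        out = np.where(
            np.abs(y) >= cut,
            rng.uniform(1e-8, 0.04, size=len(y)),
            rng.uniform(0.06, 1.0, size=len(y)),
        )
        return out

    table = pd.DataFrame(
        {
            "log2fc_svn": y_svn,
            "padj_svn": padj_for(y_svn),
            "log2fc_svr": y_svr,
            "padj_svr": padj_for(y_svr),
        },
        index=X.index,
    )
    return DifferentialTable(table=table, comparisons=["svn", "svr"]), gt


# ---------------------------------------------------------------------------
# bulk RNA counts


_ARCHETYPES = {
    # per-population multiplicative effects (neg, recent, stable);
    # every archetype is differential somewhere, mirroring a clustering
    # that runs on differentially expressed genes only
    "bI": (1.0, 1.0, 3.0),  # up in stable vs both
    "bII": (3.0, 1.0, 1.0),  # down in recent/stable
    "bIII": (1.0, 3.0, 1.0),  # transiently up
    "bIV": (3.0, 2.0, 1.0),  # monotone down
    "bV": (1.0, 2.0, 3.0),  # monotone up
    "bVI": (2.0, 1.0, 2.0),  # dip in recent
    "bVII": (1.0, 3.0, 3.0),  # up in recent and stable
}


def simulate_bulk_counts(cfg: SimulationConfig) -> tuple[ExpressionTable, DifferentialTable, GroundTruth]:
    """Negative-binomial bulk counts with seven planted archetypes.

    Genes are split evenly across archetypes; per-sample counts are
    NB(mean, dispersion) around population-specific means and library-
    size normalized to FPKM-like values. A floor gene ``Cd8a`` is planted
    at a known low mean, a block of genes below it, and a few Ig/TCR
    V(D)J segment-named genes, so the filtering rules all fire.
    """
    rng = cfg.rng("bulk")
    pops = list(POPULATIONS[: cfg.n_populations])
    samples = [f"{p}_r{r + 1}" for p in pops for r in range(cfg.n_replicates)]
    archetype_names = list(_ARCHETYPES)
    genes, means, labels = [], [], {}
    n_special = 24  # floor gene + below-floor block + segment genes
    n_main = cfg.n_genes - n_special
    for i in range(n_main):
        name = f"Gene{i:04d}"
        arch = archetype_names[i % len(archetype_names)]
        base = rng.lognormal(mean=3.0, sigma=0.5)
        effect = np.array(_ARCHETYPES[arch])
        noise = rng.lognormal(0, 0.05, size=len(pops))
        genes.append(name)
        means.append(np.repeat(base * effect * noise, cfg.n_replicates))
        labels[name] = arch
    # floor gene: modest constant expression
    genes.append("Cd8a")
    means.append(np.full(len(samples), 5.0))
    # genes planted below the floor
    for i in range(15):
        genes.append(f"LowGene{i:02d}")
        means.append(np.full(len(samples), float(rng.uniform(0.1, 2.0))))
    # Ig/TCR segment genes (high enough to otherwise survive)
    for name in ("Trbv13-1", "Trav14-2", "Ighv1-55", "Igkv4-50", "Trdj1", "Trgv2", "Ighj3", "Iglv1"):
        genes.append(name)
        means.append(np.full(len(samples), 50.0))

    mean_mat = np.vstack(means)
    # NB via gamma-Poisson; dispersion -> 0 recovers Poisson
    if cfg.nb_dispersion > 0:
        shape = 1.0 / cfg.nb_dispersion
        lam = rng.gamma(shape, mean_mat / shape)
    else:
        lam = mean_mat
    counts = rng.poisson(lam).astype(float)
    libsize = counts.sum(axis=0)
    fpkm = counts / libsize * libsize.mean()
    expr = ExpressionTable(
        values=pd.DataFrame(fpkm, index=genes, columns=samples),
        populations={s: s.rsplit("_", 1)[0] for s in samples},
    )

    # differential table from the true means, padj small where planted
    pop_means = {p: mean_mat[:, [i for i, s in enumerate(samples) if s.startswith(p)]].mean(axis=1)
                 for p in pops}
    eps = 1e-9
    fc_svn = np.log2((pop_means["stable"] + eps) / (pop_means["neg"] + eps))
    fc_svr = np.log2((pop_means["stable"] + eps) / (pop_means["recent"] + eps))
    diff_planted = np.array([labels.get(g, "") != "" for g in genes])
    table = pd.DataFrame(
        {
            "log2fc_svn": fc_svn + rng.normal(0, 0.05, len(genes)),
            "padj_svn": np.where(diff_planted, rng.uniform(1e-10, 0.01, len(genes)),
                                 rng.uniform(0.2, 1.0, len(genes))),
            "log2fc_svr": fc_svr + rng.normal(0, 0.05, len(genes)),
            "padj_svr": np.where(diff_planted, rng.uniform(1e-10, 0.01, len(genes)),
                                 rng.uniform(0.2, 1.0, len(genes))),
        },
        index=genes,
    )
    gt = GroundTruth(gene_cluster_labels=labels)
    return expr, DifferentialTable(table=table, comparisons=["svn", "svr"]), gt


# ---------------------------------------------------------------------------
# single cells


def simulate_cells(
    cfg: SimulationConfig,
    program_gene_sets: Mapping[str, Sequence[str]] | None = None,
    program_effect: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Log-normal cell-by-gene counts with planted program structure.

    Cells are assigned a program (aligned with the bulk archetypes when
    ``program_gene_sets`` comes from the bulk simulation) and an origin
    label (tdTomato-like positive/negative); program genes are shifted up
    by ``program_effect`` in their program's cells.
    """
    rng = cfg.rng("cells")
    if program_gene_sets is None:
        program_gene_sets = {
            f"P{i}": [f"Gene{j:04d}" for j in range(i * 30, i * 30 + 30)]
            for i in range(cfg.n_programs)
        }
    programs = list(program_gene_sets)
    all_genes = sorted({g for gs in program_gene_sets.values() for g in gs})
    n_extra = max(0, cfg.n_genes - len(all_genes))
    all_genes = all_genes + [f"Bg{i:04d}" for i in range(n_extra)]

    cell_ids = [f"cell{i:05d}" for i in range(cfg.n_cells)]
    prog_assign = [programs[i % len(programs)] for i in range(cfg.n_cells)]
    origin = ["pos" if rng.random() < 0.5 else "neg" for _ in range(cfg.n_cells)]

    base = rng.lognormal(mean=0.5, sigma=0.4, size=len(all_genes))
    mat = rng.lognormal(mean=0.0, sigma=0.3, size=(cfg.n_cells, len(all_genes))) * base
    gene_idx = {g: i for i, g in enumerate(all_genes)}
    for ci, prog in enumerate(prog_assign):
        idx = [gene_idx[g] for g in program_gene_sets[prog] if g in gene_idx]
        mat[ci, idx] *= program_effect
    counts = pd.DataFrame(np.log1p(mat), index=cell_ids, columns=all_genes)
    cells = pd.DataFrame(
        {"cluster": prog_assign, "origin": origin,
         "subset": [f"{p}_{o}" for p, o in zip(prog_assign, origin)]},
        index=cell_ids,
    )
    gt = GroundTruth(cell_programs=dict(zip(cell_ids, prog_assign)))
    return counts, cells, gt


# ---------------------------------------------------------------------------
# clonotypes


def _random_cdr3(rng: np.random.Generator, length: int = 39) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def simulate_clonotypes(
    cfg: SimulationConfig,
    phenotypes: Sequence[str] = ("cI", "cII", "cIII", "cIV", "cV"),
) -> tuple[list[ClonotypeRecord], np.ndarray, GroundTruth]:
    """Clonotype tables matching a target phenotype-overlap matrix.

    Per mouse, every phenotype receives a fixed clone budget; for each
    phenotype pair (i, j) with target Jaccard J, s = 2 n J / (1 + J)
    clones are shared between the two phenotypes and the remainder stay
    private, so the realized pairwise Jaccard approximates the target.
    Each clone has a unique TRA+TRB CDR3 pair; each membership emits one
    cell.
    """
    rng = cfg.rng("clonotypes")
    target = cfg.clonal_overlap_target
    if target is not None:
        K = np.asarray(target).shape[0]
        phenotypes = list(phenotypes)[:K] + [f"c{i + 1}" for i in range(len(phenotypes), K)]
    else:
        K = len(phenotypes)
    if target is None:
        # asymmetric chain of overlaps: no nontrivial label permutation
        # preserves it, so exact Mantel p can resolve below 1/K!
        target = np.eye(K)
        target[0, 1] = target[1, 0] = 0.30
        if K > 2:
            target[1, 2] = target[2, 1] = 0.15
    target = np.asarray(target, dtype=float)
    if target.shape != (K, K) or not np.allclose(target, target.T):
        raise ValueError("overlap target must be a symmetric K x K matrix")
    if not np.allclose(np.diag(target), 1.0) or (target - np.eye(K) > 1 - 1e-12).any():
        raise ValueError("infeasible overlap target: diagonal must be 1 and dominate")

    n = cfg.n_clones_per_phenotype
    shared = np.zeros((K, K), dtype=int)
    for i in range(K):
        for j in range(i + 1, K):
            shared[i, j] = shared[j, i] = int(round(2 * n * target[i, j] / (1 + target[i, j])))
    private = n - shared.sum(axis=1)
    if (private < 0).any():
        raise ValueError("infeasible overlap target: shared clones exceed phenotype budget")

    # membership patterns (private or pair-shared) with target-derived
    # weights; each mouse draws its clone patterns multinomially, so the
    # realized matrices scatter around the target rather than repeating it
    patterns: list[tuple[int, ...]] = []
    weights: list[float] = []
    for i in range(K):
        if private[i] > 0:
            patterns.append((i,))
            weights.append(float(private[i]))
        for j in range(i + 1, K):
            if shared[i, j] > 0:
                patterns.append((i, j))
                weights.append(float(shared[i, j]))
    total = int(round(sum(weights)))
    probs = np.asarray(weights) / sum(weights)

    records: list[ClonotypeRecord] = []
    cell_counter = 0
    for m in range(cfg.n_mice):
        mouse = f"mouse{m + 1}"
        counts = rng.multinomial(total, probs)
        memberships = [p for p, c in zip(patterns, counts) for _ in range(c)]
        for member in memberships:
            tra, trb = _random_cdr3(rng), _random_cdr3(rng)
            for ph_idx in member:
                records.append(
                    ClonotypeRecord(
                        cell_id=f"cell{cell_counter:06d}",
                        mouse_id=mouse,
                        phenotype=phenotypes[ph_idx],
                        chains=[("TRA", tra), ("TRB", trb)],
                    )
                )
                cell_counter += 1
    gt = GroundTruth(clonal_overlap_target=target.tolist())
    return records, target, gt
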