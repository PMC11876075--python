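"""Readers and writers for every external format the pipeline touches.

All in-memory coordinates are 0-based half-open; BED-family files are
written without conversion. Summits are stored as absolute coordinates
(not offsets) so they survive merging arithmetic, and are converted back
to offsets on write.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ridgemotif")

BASES = "ACGT"


class ParseError(ValueError):
    """A malformed record in an external file, with its line number."""


@dataclass
class Peak:
    """A called ATAC peak: 0-based half-open interval with a summit.

    ``summit`` is an absolute coordinate satisfying start <= summit < end.
    """

    chrom: str
    start: int
    end: int
    summit: int
    score: float = 0.0
    source: str = ""
    name: str = "."
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"peak {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"peak {self.chrom}:{self.start}-{self.end}: summit {self.summit} "
                "outside [start, end)"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class AtlasPeak(Peak):
    """A merged atlas peak, carrying provenance and gene assignment."""

    origin_cluster: int = -1
    n_source_peaks: int = 1
    category: str = "unassigned"  # promoter | intragenic | intergenic | unassigned
    gene: str | None = None


@dataclass
class Pwm:
    """Position probability matrix over A,C,G,T with TF metadata."""

    name: str
    matrix: np.ndarray  # L x 4, rows sum to 1
    tf_gene: str = ""
    family: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 1:
            raise ValueError(f"PWM {self.name}: matrix must be L x 4 with L >= 1")
        if (self.matrix < 0).any():
            raise ValueError(f"PWM {self.name}: negative probability")
        sums = self.matrix.sum(axis=1)
        if np.abs(sums - 1).max() > 1e-9:
            raise ValueError(f"PWM {self.name}: rows do not sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


@dataclass
class ExpressionTable:
    """FPKM matrix (genes x samples) with a sample -> population map."""

    values: pd.DataFrame  # index: genes, columns: samples
    populations: dict[str, str]  # sample -> population

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression table contains negative values")
        missing = set(self.values.columns) - set(self.populations)
        if missing:
            raise ValueError(f"samples without population assignment: {sorted(missing)}")

    def population_means(self) -> pd.DataFrame:
        """Per-gene mean FPKM within each population."""
        groups = pd.Series(self.populations)
        return self.values.T.groupby(groups).mean().T


@dataclass
class DifferentialTable:
    """Per-feature log2FC and adjusted p for one or more comparisons.

    ``table`` has a unique feature index and, per comparison ``c``, columns
    ``log2fc_<c>`` and ``padj_<c>`` (padj may be NaN).
    """

    table: pd.DataFrame
    comparisons: list[str]

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("duplicate feature ids in differential table")
        for c in self.comparisons:
            for col in (f"log2fc_{c}", f"padj_{c}"):
                if col not in self.table.columns:
                    raise ValueError(f"missing column {col}")
            p = self.table[f"padj_{c}"].dropna()
            if ((p < 0) | (p > 1)).any():
                raise ValueError(f"padj outside [0,1] for comparison {c}")

    def log2fc(self, comparison: str) -> pd.Series:
        return self.table[f"log2fc_{comparison}"]

    def padj(self, comparison: str) -> pd.Series:
        return self.table[f"padj_{comparison}"]


@dataclass
class ClonotypeRecord:
    """One cell's TCR chains: (chain_type, CDR3 nucleotide string) pairs."""

    cell_id: str
    mouse_id: str
    phenotype: str
    chains: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for _, cdr3 in self.chains:
            if not re.fullmatch("[ACGT]+", cdr3):
                raise ValueError(f"cell {self.cell_id}: CDR3 not over ACGT: {cdr3!r}")

    def chain_key(self) -> tuple[tuple[str, str], ...]:
        """Canonical (sorted) chain multiset used for clonotype identity."""
        return tuple(sorted(self.chains))


# ---------------------------------------------------------------------------
# narrowPeak


def read_narrowpeak(path: str | Path, source: str = "") -> list[Peak]:
    """Read an ENCODE narrowPeak (BED6+4) file into a list of peaks.

    Column 10 is the summit offset from the start; a value of -1 means the
    caller reported no summit, in which case the interval midpoint is used
    and a warning is logged.
    """
    peaks: list[Peak] = []
    source = source or Path(path).stem
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 10:
                raise ParseError(f"{path}:{lineno}: expected 10 narrowPeak columns, got {len(fields)}")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                score = float(fields[6])  # signalValue
                strand = fields[5]
                offset = int(fields[9])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start {start} >= end {end}")
            if offset >= 0:
                summit = start + offset
            else:
                summit = (start + end) // 2
                logger.warning("%s:%d: summit offset -1, using interval midpoint", path, lineno)
            if not (start <= summit < end):
                raise ParseError(f"{path}:{lineno}: summit {summit} outside [{start},{end})")
            peaks.append(Peak(chrom, start, end, summit, score=score, source=source,
                              name=name, strand=strand))
    return peaks


def write_atlas(atlas: Sequence[AtlasPeak | Peak], path: str | Path) -> None:
    """Write peaks as narrowPeak, converting absolute summits to offsets.

    A write -> read round trip reproduces the peaks exactly.
    """
    with open(path, "w") as fh:
        for i, p in enumerate(atlas):
            name = p.name if p.name != "." else f"peak_{i}"
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t0\t{p.strand}\t"
                f"{p.score:g}\t-1\t-1\t{p.summit - p.start}\n"
            )


def write_atlas_annotation(atlas: Sequence[AtlasPeak], path: str | Path) -> None:
    rows = [
        {
            "peak_id": p.name,
            "chrom": p.chrom,
            "start": p.start,
            "end": p.end,
            "summit": p.summit,
            "category": p.category,
            "gene": p.gene if p.gene is not None else "",
            "n_source_peaks": p.n_source_peaks,
        }
        for p in atlas
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MEME minimal motif format


def read_meme_pwms(path: str | Path, tf_genes: dict[str, str] | None = None,
                   families: dict[str, str] | None = None) -> list[Pwm]:
    """Read PWMs from a MEME minimal-format motif file.

    Probability rows off from sum 1 by <= 1e-3 are renormalized; larger
    deviations raise. ``tf_genes`` / ``families`` optionally map motif
    names to gene symbols and protein families (the MEME format itself
    carries neither).
    """
    pwms: list[Pwm] = []
    name: str | None = None
    rows: list[list[float]] = []
    expect_rows = 0

    def flush() -> None:
        nonlocal name, rows
        if name is None:
            return
        if not rows:
            raise ParseError(f"{path}: motif {name} has no probability rows")
        mat = np.array(rows, dtype=float)
        sums = mat.sum(axis=1)
        if (sums == 0).any():
            raise ParseError(f"{path}: motif {name} has an all-zero row")
        dev = np.abs(sums - 1)
        if dev.max() > 1e-3:
            raise ParseError(
                f"{path}: motif {name} row sums deviate from 1 by {dev.max():.4g} (> 1e-3)"
            )
        mat = mat / sums[:, None]
        pwms.append(
            Pwm(
                name=name,
                matrix=mat,
                tf_gene=(tf_genes or {}).get(name, ""),
                family=(families or {}).get(name, ""),
            )
        )
        name, rows = None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("MOTIF"):
                flush()
                parts = line.split()
                if len(parts) < 2:
                    raise ParseError(f"{path}:{lineno}: MOTIF line without a name")
                name = parts[1]
                expect_rows = 0
            elif line.startswith("letter-probability"):
                m = re.search(r"w\s*=\s*(\d+)", line)
                expect_rows = int(m.group(1)) if m else 0
            elif name is not None and line and line[0] in "0123456789.":
                try:
                    vals = [float(x) for x in line.split()]
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric matrix cell") from exc
                if len(vals) != 4:
                    raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(vals)}")
                rows.append(vals)
    flush()
    return pwms


def write_meme_pwms(pwms: Sequence[Pwm], path: str | Path,
                    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25)) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:g}" for b, f in zip(BASES, background)) + "\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {p.length}\n")
            for row in p.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# BED3 (repeat mask) and FASTA


def read_bed3(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a minimal BED3 interval file (0-based half-open)."""
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            out.append((fields[0], start, end))
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} dict."""
    seqs: dict[str, list[str]] = {}
    current: str | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                current = line[1:].split()[0]
                if current in seqs:
                    raise ParseError(f"{path}: duplicate sequence name {current}")
                seqs[current] = []
            elif current is not None:
                seqs[current].append(line)
            elif line.strip():
                raise ParseError(f"{path}: sequence data before first header")
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# TSV tables


def read_expression_tsv(path: str | Path, populations: dict[str, str] | None = None) -> ExpressionTable:
    """Read a genes x samples FPKM TSV.

    When ``populations`` is not given, sample names of the form
    ``<population>_r<replicate>`` are parsed for the assignment.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if populations is None:
        populations = {c: c.rsplit("_", 1)[0] for c in df.columns}
    return ExpressionTable(values=df, populations=populations)


def write_expression_tsv(expr: ExpressionTable, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t")


def read_differential_tsv(path: str | Path, comparisons: Sequence[str] | None = None) -> DifferentialTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if comparisons is None:
        comparisons = [c[len("log2fc_"):] for c in df.columns if c.startswith("log2fc_")]
    return DifferentialTable(table=df, comparisons=list(comparisons))


def write_differential_tsv(diff: DifferentialTable, path: str | Path) -> None:
    diff.table.to_csv(path, sep="\t")


def read_clonotype_tsv(path: str | Path) -> list[ClonotypeRecord]:
    """Read a flat clonotype TSV: one row per cell-chain.

    Columns: cell_id, mouse_id, phenotype, chain (TRA/TRB), cdr3_nt.
    Cells may span several rows (one per chain); a cell with an empty
    chain field contributes a record with no chains.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"cell_id", "mouse_id", "phenotype", "chain", "cdr3_nt"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    records: dict[str, ClonotypeRecord] = {}
    for row in df.itertuples(index=False):
        rec = records.get(row.cell_id)
        if rec is None:
            rec = ClonotypeRecord(row.cell_id, row.mouse_id, row.phenotype, [])
            records[row.cell_id] = rec
        else:
            if (rec.mouse_id, rec.phenotype) != (row.mouse_id, row.phenotype):
                raise ParseError(f"{path}: cell {row.cell_id} has inconsistent metadata")
        if row.chain:
            rec.chains.append((row.chain, row.cdr3_nt))
            rec.__post_init__()
    return list(records.values())


def write_clonotype_tsv(records: Sequence[ClonotypeRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        if rec.chains:
            for chain, cdr3 in rec.chains:
                rows.append((rec.cell_id, rec.mouse_id, rec.phenotype, chain, cdr3))
        else:
            rows.append((rec.cell_id, rec.mouse_id, rec.phenotype, "", ""))
    pd.DataFrame(rows, columns=["cell_id", "mouse_id", "phenotype", "chain", "cdr3_nt"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# MTX cell-by-gene counts


def read_counts_mtx(mtx_path: str | Path, genes_path: str | Path,
                    cells_path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a cell-by-gene MTX with gene and cell annotation TSVs.

    Returns (counts, cell_annotations): counts is a dense cells x genes
    DataFrame, annotations carry at least cluster/origin labels.
    """
    from scipy.io import mmread

    mat = mmread(mtx_path).tocsr()
    genes = pd.read_csv(genes_path, sep="\t")["gene"].tolist()
    cells = pd.read_csv(cells_path, sep="\t")
    if mat.shape != (len(cells), len(genes)):
        raise ParseError(
            f"matrix shape {mat.shape} does not match {len(cells)} cells x {len(genes)} genes"
        )
    counts = pd.DataFrame(mat.toarray(), index=cells["cell_id"].tolist(), columns=genes)
    return counts, cells.set_index("cell_id")


def write_counts_mtx(counts: pd.DataFrame, cells: pd.DataFrame, out_dir: str | Path) -> None:
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(str(out / "counts.mtx"), csr_matrix(counts.values))
    pd.DataFrame({"gene": counts.columns}).to_csv(out / "genes.tsv", sep="\t", index=False)
    cells.reset_index().rename(columns={"index": "cell_id"}).to_csv(
        out / "cells.tsv", sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Gene models (TSS table)


@dataclass
class GeneModel:
    """A gene body with a strand-aware TSS, 0-based half-open."""

    gene: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene}: strand must be + or -")
        if self.tx_start >= self.tx_end:
            raise ValueError(f"gene {self.gene}: tx_start >= tx_end")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1


def read_gene_models_tsv(path: str | Path, one_based: bool = False) -> list[GeneModel]:
    """Read gene models from a TSV (gene, chrom, strand, tx_start, tx_end).

    With ``one_based=True`` (GTF-derived tables) starts are shifted down by
    one on read; this is the single point of coordinate conversion.
    """
    df = pd.read_csv(path, sep="\t")
    shift = 1 if one_based else 0
    return [
        GeneModel(r.gene, r.chrom, r.strand, int(r.tx_start) - shift, int(r.tx_end))
        for r in df.itertuples(index=False)
    ]
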