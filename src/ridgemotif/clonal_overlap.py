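"""Clonotype calling, Jaccard overlap matrices and the Mantel test.

Cells sharing identical nucleotide-level CDR3 sequences across their TCR
chains form a clonotype. Per phenotype (and optionally per mouse), the
set of clonotypes with at least one member cell defines a clonotype set;
pairwise Jaccard overlaps J = |intersection| / |union| form a symmetric
similarity matrix. Reproducibility of the clonal structure across mice
is probed with the Mantel matrix-permutation test on the off-diagonal
entries, permuting phenotype labels jointly on rows and columns.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io_formats import ClonotypeRecord

logger = logging.getLogger("ridgemotif")

MatchMode = Literal["strict", "any-chain"]


@dataclass
class ClonotypeTable:
    """Cells with assigned clonotype ids."""

    records: list[ClonotypeRecord]
    clonotype_ids: dict[str, int]  # cell_id -> clonotype id (assigned cells only)
    assigned_fraction: float

    def clonotype_set(self, phenotype: str | None = None, mouse_id: str | None = None) -> set[int]:
        """Clonotypes with >= 1 cell of the given phenotype/mouse scope."""
        out = set()
        for rec in self.records:
            if rec.cell_id not in self.clonotype_ids:
                continue
            if phenotype is not None and rec.phenotype != phenotype:
                continue
            if mouse_id is not None and rec.mouse_id != mouse_id:
                continue
            out.add(self.clonotype_ids[rec.cell_id])
        return out

    @property
    def phenotypes(self) -> list[str]:
        return sorted({r.phenotype for r in self.records})

    @property
    def mice(self) -> list[str]:
        return sorted({r.mouse_id for r in self.records})


@dataclass
class OverlapMatrix:
    """Symmetric phenotype-by-phenotype Jaccard matrix in [0, 1]."""

    phenotypes: list[str]
    J: np.ndarray
    scope: str = "pooled"

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=float)
        if not np.allclose(self.J, self.J.T):
            raise ValueError("overlap matrix must be symmetric")
        if (self.J < 0).any() or (self.J > 1).any():
            raise ValueError("Jaccard values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.J, index=self.phenotypes, columns=self.phenotypes)


@dataclass
class MantelResult:
    r_observed: float
    p: float
    n_perm: int | str  # permutation count, or "exact"


def call_clonotypes(records: Sequence[ClonotypeRecord],
                    match_mode: MatchMode = "strict") -> ClonotypeTable:
    """Group cells into clonotypes by identical nucleotide CDR3 chains.

    ``strict`` (default): cells share a clonotype iff their full
    (chain type, CDR3) multisets are identical. ``any-chain``: cells
    sharing at least one identical chain are merged transitively. Cells
    with no chains stay unassigned and are excluded from overlap sets.
    """
    seen: set[str] = set()
    for rec in records:
        if rec.cell_id in seen:
            raise ValueError(f"duplicate cell_id {rec.cell_id}")
        seen.add(rec.cell_id)

    with_chains = [r for r in records if r.chains]
    ids: dict[str, int] = {}
    if match_mode == "strict":
        key_to_id: dict[tuple, int] = {}
        for rec in with_chains:
            key = rec.chain_key()
            if key not in key_to_id:
                key_to_id[key] = len(key_to_id)
            ids[rec.cell_id] = key_to_id[key]
    elif match_mode == "any-chain":
        parent = list(range(len(with_chains)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        chain_owner: dict[tuple[str, str], int] = {}
        for i, rec in enumerate(with_chains):
            for chain in rec.chains:
                if chain in chain_owner:
                    ri, rj = find(i), find(chain_owner[chain])
                    if ri != rj:
                        parent[max(ri, rj)] = min(ri, rj)
                else:
                    chain_owner[chain] = i
        root_to_id: dict[int, int] = {}
        for i, rec in enumerate(with_chains):
            r = find(i)
            if r not in root_to_id:
                root_to_id[r] = len(root_to_id)
            ids[rec.cell_id] = root_to_id[r]
    else:
        raise ValueError(f"unknown match mode {match_mode!r}")

    frac = len(ids) / len(records) if records else 0.0
    return ClonotypeTable(records=list(records), clonotype_ids=ids, assigned_fraction=frac)


def jaccard(c1: set, c2: set) -> float:
    """|C1 ∩ C2| / (|C1| + |C2| - |C1 ∩ C2|); 0 (with a warning) when
    both sets are empty."""
    inter = len(c1 & c2)
    denom = len(c1) + len(c2) - inter
    if denom == 0:
        logger.warning("Jaccard of two empty clonotype sets reported as 0")
        return 0.0
    return inter / denom


def overlap_matrices(table: ClonotypeTable) -> tuple[OverlapMatrix, list[OverlapMatrix]]:
    """Pooled and per-mouse phenotype overlap matrices over the shared
    ordered phenotype list. Empty phenotypes give zero rows (warned)."""
    phenos = table.phenotypes

    def build(mouse: str | None, scope: str) -> OverlapMatrix:
        sets = {ph: table.clonotype_set(ph, mouse) for ph in phenos}
        for ph, s in sets.items():
            if not s:
                logger.warning("phenotype %s has no assigned clonotypes in scope %s", ph, scope)
        J = np.zeros((len(phenos), len(phenos)))
        for i, a in enumerate(phenos):
            for j, b in enumerate(phenos):
                if i <= j:
                    J[i, j] = J[j, i] = jaccard(sets[a], sets[b])
        return OverlapMatrix(phenotypes=phenos, J=J, scope=scope)

    pooled = build(None, "pooled")
    per_mouse = [build(m, m) for m in table.mice]
    return pooled, per_mouse


def _offdiag_upper(J: np.ndarray) -> np.ndarray:
    iu = np.triu_indices_from(J, k=1)
    return J[iu]


def mantel_test(
    A: OverlapMatrix,
    B: OverlapMatrix,
    n_perm: int = 9999,
    seed: int = 0,
    exact_max_labels: int = 8,
) -> MantelResult:
    """Mantel permutation test between two overlap matrices.

    r is the Pearson correlation over upper-triangle off-diagonal
    entries; the null permutes B's labels jointly on rows and columns.
    With <= ``exact_max_labels`` phenotypes all label permutations are
    enumerated (p = fraction of permutations with r >= observed);
    otherwise Monte-Carlo with the +1 correction, one-sided (greater).
    """
    if A.phenotypes != B.phenotypes:
        raise ValueError("matrices must share the same ordered phenotype labels")
    n = len(A.phenotypes)
    if n < 3:
        raise ValueError("Mantel test needs >= 3 phenotypes")
    a = _offdiag_upper(A.J)
    if a.std() == 0:
        raise ValueError("zero variance in the first matrix's off-diagonal entries")
    if _offdiag_upper(B.J).std() == 0:
        raise ValueError("zero variance in the second matrix's off-diagonal entries")

    def r_for(perm: Sequence[int]) -> float:
        Jp = B.J[np.ix_(perm, perm)]
        b = _offdiag_upper(Jp)
        if b.std() == 0:
            return -np.inf
        return float(np.corrcoef(a, b)[0, 1])

    r_obs = r_for(range(n))
    if n <= exact_max_labels:
        rs = [r_for(p) for p in itertools.permutations(range(n))]
        total = math.factorial(n)
        hits = sum(1 for r in rs if r >= r_obs - 1e-12)
        return MantelResult(r_observed=r_obs, p=hits / total, n_perm="exact")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if r_for(rng.permutation(n)) >= r_obs - 1e-12:
            hits += 1
    return MantelResult(r_observed=r_obs, p=(1 + hits) / (1 + n_perm), n_perm=n_perm)


def matrix_reproducibility(
    per_mouse: Sequence[OverlapMatrix],
    n_perm: int = 9999,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise Mantel tests between mouse-level overlap matrices.

    Each pair is restricted to phenotypes nonempty (nonzero diagonal) in
    both mice; pairs with < 3 common phenotypes are skipped with a
    warning. Returns a table (mouse_a, mouse_b, n_phenotypes, r, p).
    """
    rows = []
    for i in range(len(per_mouse)):
        for j in range(i + 1, len(per_mouse)):
            A, B = per_mouse[i], per_mouse[j]
            common = [
                k for k, ph in enumerate(A.phenotypes)
                if A.J[k, k] > 0 and B.J[k, k] > 0
            ]
            if len(common) < 3:
                logger.warning("pair (%s, %s): only %d common phenotypes, skipped",
                               A.scope, B.scope, len(common))
                continue
            phs = [A.phenotypes[k] for k in common]
            subA = OverlapMatrix(phs, A.J[np.ix_(common, common)], A.scope)
            subB = OverlapMatrix(phs, B.J[np.ix_(common, common)], B.scope)
            try:
                res = mantel_test(subA, subB, n_perm=n_perm, seed=seed)
            except ValueError as exc:
                logger.warning("pair (%s, %s): %s; skipped", A.scope, B.scope, exc)
                continue
            rows.append((A.scope, B.scope, len(common), res.r_observed, res.p))
    return pd.DataFrame(rows, columns=["mouse_a", "mouse_b", "n_phenotypes", "r", "p"])
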