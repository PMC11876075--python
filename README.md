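# ridgemotif

Regulatory-genomics analysis pipeline for studies that profile a few
sorted cell populations by bulk ATAC-seq, bulk RNA-seq, scRNA-seq and
single-cell TCR-seq — the design used to dissect effector regulatory
T-cell differentiation (e.g. *Il10*-fate-mapped colonic Treg subsets).
It is aimed at computational biologists who have upstream peak calls,
count tables and clonotype tables in hand and need the bespoke
downstream statistics as tested, reusable code:

1. **Summit-aware peak atlas** — overlapping replicate peak calls are
   clustered (≥1 bp overlap, half-open coordinates); a cluster whose
   summits all fall inside its common core `[max(starts), min(ends))`
   merges to one peak at the rounded mean start/summit/end, otherwise
   it is split into one peak per distinct summit. Width (>3,500 bp),
   repeat-content (>70 %) and chromosome filters follow, then
   promoter / intragenic / intergenic gene assignment
   (−2,000/+500 bp of the TSS; 100 kb windows).
2. **Motif catalog and exact scanning** — TF PWMs are filtered by
   expression (mean FPKM > 1 in ≥1 population), grouped by similarity
   within protein families (E < 1e−5) with a gene-uniqueness fixpoint,
   and scanned with cutoffs from the *exact* null score distribution
   (dynamic programming on an integerized log-odds lattice, P < 1e−4),
   yielding a binary peak-by-motif matrix after enrichment and 2 %
   prevalence filters.
3. **Ridge attribution** — per-peak log2FC in accessibility is modeled
   as `y = b₀ + Xβ + ε` on the motif-presence matrix, with the penalty
   chosen by the Cule–De Iorio semi-automatic estimator
   `λ_r = r·σ̂²_r / ‖α̂_r‖²` (PCA generalization of Hoerl–Kennard–Baldwin,
   candidate with minimal exact leave-one-out error retained) and
   Cule-style normal tests on coefficients. Each motif is withheld in
   turn ("zeroed-out" refits) and **Δcor** — the drop in Pearson
   correlation between observed and predicted log2FC on a peak subset —
   attributes the subset's accessibility change to motifs.
4. **Bulk ↔ single-cell integration** — expression floor at a control
   gene (*Cd8a*), Ig/TCR V(D)J-segment exclusion, k-means (k = 7) on
   per-gene Z-scores, per-cell module scores against expression-matched
   controls, per-subset score Z-maps, hypergeometric enrichment
   (`P(X ≥ q)` for q/m/n/k), and two-sample KS tests for gene-set
   fold-change shifts.
5. **Clonal overlap** — clonotypes from identical nucleotide CDR3 chain
   multisets; pooled and per-mouse phenotype Jaccard matrices
   `J = |C₁∩C₂| / (|C₁|+|C₂|−|C₁∩C₂|)`; Mantel permutation tests
   (exhaustive over label permutations for ≤8 phenotypes) for
   mouse-to-mouse reproducibility.
6. **Synthetic studies** — a deterministic generator plants ground truth
   for every stage (latent loci with multi-summit clusters, motif
   instances, linear accessibility effects, NB bulk counts with seven
   expression archetypes, program-structured cells, target-matched
   clonal overlap), so the whole pipeline runs and is tested without
   any data download.

## Worked example

`examples/03_ridge_attribution.py` simulates 5,000 peaks × 40 motif
groups with three planted effects and noise sd 0.5, fits the two
comparison models and attributes a peak subset:

```
svn model: lambda = 6.529
planted effects vs estimates:
  G000: beta* = +0.80, beta = +0.796, p = 0.00e+00
  G001: beta* = +0.50, beta = +0.507, p = 1.21e-236
  G002: beta* = -0.80, beta = -0.796, p = 0.00e+00
significant in both models: 3 of 40 groups
log2FC concordance on 1500 shared significant peaks: r = 0.650
delta-cor on 2453 peaks (top 3):
  G000: +0.514
  G002: +0.003
  G001: +0.001
```

The three planted motif groups are recovered with the largest
coefficients at P < 0.001 and nothing else reaches significance; on the
subset of peaks where G000's presence varies, withholding G000 costs the
model 0.51 units of correlation while every other motif is ≈ 0 — the
subset's accessibility change is attributed to G000. The other examples
(`examples/01…05`) walk the atlas, scanning, integration and clonotype
stages the same way, each printing what it computes and why.

A thin CLI mirrors the stages:

```bash
ridgemotif simulate --seed 1 --out simdata/
ridgemotif atlas --peaks simdata/neg.narrowPeak simdata/recent.narrowPeak \
    simdata/stable.narrowPeak --out atlas.narrowPeak
ridgemotif run --seed 1 --out report/        # end-to-end with manifest
```

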