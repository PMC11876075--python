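# Methods

## Peak atlas construction

Peaks are 0-based half-open intervals carrying an absolute summit
coordinate (`start ≤ summit < end`). narrowPeak summit offsets are
converted to absolute coordinates on read and back to offsets on write;
a missing summit (offset −1) falls back to the interval midpoint with a
warning. Gene models read from 1-based (GTF-derived) tables are shifted
at the reader — the single point of coordinate conversion.

Clustering uses ≥1 bp overlap with transitive closure; bookended
intervals (end == start) do **not** cluster, matching `bedtools cluster
-d -1` semantics. Because input is swept in (chrom, start) order the
implementation is O(n log n); tests compare it against an O(n²)
union-find oracle.

Merging distinguishes two cases. If every member summit lies inside the
cluster core `[max(starts), min(ends))` the cluster merges to one peak
at the mean start, summit and end of its members. Otherwise the cluster
is split into one peak per distinct summit coordinate `s`, bounded by
`max{start : start ≤ s}` and `min{end : end > s}` over all members.
Numerical choices, made where the merge rule is silent:

- Mean coordinates round half away from zero (deterministic,
  order-free); if rounding collapses an interval, the end is widened by
  1 bp and the summit clamped inside.
- "Distinct summit" means exact coordinate equality; summits 1 bp apart
  stay distinct.
- Split outputs may mutually overlap and are retained as-is; the split
  boundaries may come from any cluster member, not only the peak owning
  the summit.

Filters retain peaks with width ≤ 3,500 bp, repeat fraction ≤ 0.70
(strictly greater eliminates) and chromosome in the declared set.
Repeat fraction comes from lowercase bases of a soft-masked sequence or
from covered bp of a repeat BED; the sequence wins when both are given.
Gene assignment has precedence promoter > intragenic > intergenic >
unassigned, with strand-aware promoter windows (2,000 bp 5′, 500 bp 3′
of the TSS), gene-body containment for intragenic, and a 100 kb body
window for intergenic. The closest gene is by summit-to-TSS distance
for promoters and summit-to-body distance otherwise; exact ties break
lexicographically by gene symbol and are logged.

## Motif catalog

PWMs are probability matrices over A,C,G,T. The scan cutoff for each
PWM comes from the exact null distribution of its log-odds score under
an i.i.d. background: probabilities get a pseudocount (1e−4, rows
renormalized) before the log2-odds transform; per-position scores are
shifted to be nonnegative and scaled so the widest position spans 1,000
integer bins (a documented knob); the distribution of the summed
integer score is an L-fold convolution computed exactly. The cutoff is
the smallest *achievable* score whose upper tail is ≤ the target
p-value (1e−4 by default). Short or degenerate motifs whose top score
is already too probable (e.g. any 1-mer under a uniform background at
P < 1e−4) receive an infinite sentinel and match nothing — the correct
behavior, not an error. Scanning runs both strands on the same integer
lattice; windows overlapping non-ACGT characters are skipped.

Grouping follows the catalog pipeline order: expression filter (mean
FPKM strictly > 1 in at least one population; unresolvable TF genes
dropped with a warning) → similarity grouping within protein families
(edge iff E < 1e−5 and same family; connected components; then
components sharing any TF gene are merged to a fixpoint so gene → group
is a function — implemented as a union-find closure, hence
order-independent) → per-group representative (member detected in the
highest fraction of peaks, ties lexicographic) → enrichment filter
(one-sided Fisher exact of occurrence atlas vs background,
Benjamini–Hochberg across groups, keep adjusted p < 0.01) → binary
peak-by-group matrix → prevalence filter (drop columns in < 2 % of
peaks). Motif-comparison E-values are accepted as a precomputed table;
when absent they are computed internally as a best-offset ungapped
Pearson correlation between probability matrices, converted to an
E-value-like score (one-sided correlation p-value, Bonferroni-scaled by
the number of pairs). This surrogate preserves the grouping logic
(threshold, family guard, fixpoint) without claiming bit-equality with
external motif-comparison software.

## Ridge models and Δcor attribution

Per-peak log2FC between two populations is fit as
`y = b₀ + Xβ + ε` with `β = (XᵀX + λI)⁻¹ Xᵀy` on column-centered X and
an unpenalized intercept. Columns are centered but **not** scaled —
the predictors are presence/absence indicators and scaling would
distort their semantics. With λ = 0 the fit reduces to OLS (tested
against the normal equations); a singular design with λ = 0 raises.

Automatic penalty selection generalizes the Hoerl–Kennard–Baldwin
estimator over principal components: for each r = 1..rank,
`λ_r = r·σ̂²_r / ‖α̂_r‖²` where α̂ holds the first r PC regression
coefficients and σ̂²_r the residual variance of the r-component fit; the
candidate minimizing exact ridge leave-one-out error (hat-diagonal
identity, including the intercept's 1/n) is retained. The exact
candidate-selection rule of the original semi-automatic estimator is
not recoverable from its description, so this sweep is the package's
documented interpretation.

Coefficient significance is a normal test on the ridge estimator's
asymptotic variance `σ̂² V diag(s²/(s²+λ)²) Vᵀ` with
`σ̂² = RSS/(n − tr(H))` — no multiplicity correction, matching raw
P < 0.001 usage downstream. Zeroed-out models refit with one column
deleted; the penalty is re-selected per reduced model by default, with
a flag to freeze the full model's λ.

`Δcor(m) = cor(y_S, ŷ_full,S) − cor(y_S, ŷ_zeroed(m),S)` on a peak
subset S (≥3 peaks, nonzero variance required), reported together with
the mean observed log2FC of subset peaks containing m and the
subset-wide mean as reference. One property worth knowing: if motif m
is present in (or absent from) *every* peak of S, removing it shifts
predictions on S by approximately a constant, and Pearson correlation
is location-invariant — Δcor(m) ≈ 0 regardless of β_m. Informative
attribution therefore needs subsets on which the motif's presence
varies; the examples and tests use such subsets.

## Bulk and single-cell integration

Gene filtering removes genes whose all-sample mean FPKM falls below the
mean of a floor gene functionally absent from the profiled cells
(*Cd8a* for Treg cells), genes with zero counts in a strict majority of
samples, and genes matching configurable Ig/TCR V(D)J segment patterns
(defaults `^Ig[hkl][vdj]`, `^Tr[abgd][vdj]`). k-means runs on per-gene
Z-scores of the differential genes with k = 7, 50 k-means++ restarts
and a fixed seed; clusters are relabeled deterministically by
descending size (bI, bII, …).

Module scores bin genes by average expression (24 rank-based bins) and
draw 100 control genes per set gene with replacement from the gene's
bin; the score is mean(set) − mean(pooled controls) per cell. Controls
are drawn only from genes present in the matrix, so padding a set with
absent genes does not change the score. Per-subset mean scores are
Z-normalized across subsets within each gene cluster after excluding
subsets with fewer than 20 cells; a gene cluster with identical subset
means is reported as Z = 0 with a warning.

Enrichment uses the hypergeometric upper tail `P(X ≥ q)` (survival
function at q−1) for q signature genes inside an m-gene cluster out of
m + n detectable genes with a k-gene signature. Gene-set fold-change
shifts use the two-sided two-sample KS test of the set's log2FCs
against *all* genes' log2FCs (asymptotic p). Per-cluster
expression-accessibility coupling is the Pearson correlation of gene
log2FC against each linked peak's log2FC, the gene value repeated per
peak; clusters with fewer than three linked pairs raise.

## Clonal overlap

Clonotype identity defaults to strict: cells share a clonotype iff
their (chain type, CDR3 nucleotide) multisets are identical. A lax
`any-chain` mode merges cells transitively on any shared chain; both
are provided because upstream vendor semantics for partial-chain
matches are not reproduced here. Chainless cells stay unassigned and
are excluded from overlap sets; the assigned fraction is reported.

Jaccard overlap `|C₁∩C₂| / (|C₁|+|C₂|−|C₁∩C₂|)` (the denominator is
the union) is computed over clonotype sets per phenotype, pooled and
per mouse, on a shared ordered phenotype list. The Mantel test
correlates upper-triangle off-diagonals and permutes one matrix's
labels jointly on rows and columns; with ≤8 labels all permutations are
enumerated (p = fraction with r ≥ observed), otherwise Monte-Carlo with
the +1 correction, one-sided (greater). Mouse-pair reproducibility
restricts each pair to phenotypes nonempty in both and skips pairs with
fewer than three.

## Synthetic studies

The generator emulates the profiled design: three populations × three
replicates. One global seed fans out to named per-component streams
(SeedSequence with a CRC-derived spawn key), so adding a component
never perturbs another's draws and identical configurations give
byte-identical outputs.

Defaults, chosen once as the study conditions: 400 latent loci spaced
6 kb on one synthetic chromosome, peak width ≈ N(600, 80), start/end
jitter sd 30 bp, 18 % of loci carrying two summits ~2/3 of a width
apart (overlapping calls whose summits escape the cluster core, forcing
the split branch); uniform base frequencies and placement probability
0.35 for motif instances sampled from the PWM rows; accessibility
log2FC = Xβ + N(0, 0.5²) with planted β = {+0.8, +0.5, −0.8} among 40
groups at 5,000 peaks for model studies; negative-binomial bulk counts
(gamma–Poisson, dispersion 0.1) over seven planted population
archetypes — all differential, since the clustering they feed runs on
differential genes only — plus a floor gene, a below-floor block and
V(D)J-segment-named genes so every filter fires; log-normal cell
programs aligned to the bulk archetype gene blocks; clonotypes drawn
per mouse by multinomial sampling of membership patterns whose weights
`s_ij = 2nJ/(1+J)` reproduce a target Jaccard matrix in expectation
(default: a 5-phenotype chain with J₁₂ = 0.30, J₂₃ = 0.15, chosen
asymmetric so exact Mantel enumeration is not floored by label
automorphisms).

Adjusted p-values in synthetic differential tables are a rank-based
stand-in (small for features in the upper |log2FC| quantile), enough to
exercise significance filters; count-based differential testing remains
upstream. What the generator does **not** model: genomic sequence
composition (GC/repeat structure), peak-width–signal coupling,
mean-variance trends beyond a single NB dispersion, doublets and
ambient RNA, or biased V(D)J recombination — passing tests demonstrate
the pipeline's statistical machinery, not robustness to those artifacts.

Problem sizes used by the test suite and the acceptance script (e.g.
200 oracle peak sets, 50 enumerated PWMs, 20 recovery seeds at
5,000 × 40, 200 calibration replicates) were chosen to make the checks
statistically meaningful while keeping a full run in the
tens-of-seconds range on one CPU.

## Known limitations

- Motif similarity is a correlation surrogate, not a reimplementation
  of external motif-comparison statistics; grouping near the E-value
  threshold can differ from MEME-suite output.
- The ridge λ sweep interprets "semi-automatic" penalty selection; with
  strongly collinear designs the selected λ (and hence p-values) can
  differ from other implementations, though coefficients at fixed λ are
  exact.
- Δcor at subsets where a motif's presence is constant is ≈ 0 by
  construction (see above) — attribution questions must be posed on
  subsets with presence variation.
- The hypergeometric enrichment treats gene lists as given; computing
  per-subset differential gene sets from the single-cell matrix is out
  of scope.
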