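"""Ridge model of differential accessibility with delta-cor attribution.

Fits per-peak log2 fold change as a linear ridge function of motif
presence (penalty chosen semi-automatically, Cule-style significance),
then withholds each motif in turn and measures the correlation drop on
a peak subset to attribute the subset's accessibility change to motifs.
"""

from ridgemotif import compare_models, delta_cor, fit_ridge, shared_fc_concordance, zeroed_out_fits
from ridgemotif.synthetic import SimulationConfig, simulate_accessibility, simulate_design

cfg = SimulationConfig(seed=1, n_peaks=5000, n_groups=40, noise_sd=0.5)
X = simulate_design(cfg)
diff, truth = simulate_accessibility(X, cfg)

svn = fit_ridge(X, diff.log2fc("svn"), "auto", comparison="svn")
svr = fit_ridge(X, diff.log2fc("svr"), "auto", comparison="svr")
print(f"svn model: lambda = {svn.lam:.3f}")
print("planted effects vs estimates:")
for g, b in truth.true_betas["svn"].items():
    print(f"  {g}: beta* = {b:+.2f}, beta = {svn.coefficients[g]:+.3f}, "
          f"p = {svn.pvalues[g]:.2e}")

paired = compare_models(svn, svr, alpha=0.001)
print("significant in both models:", (paired["category"] == "both").sum(),
      "of", len(paired), "groups")

r, n = shared_fc_concordance(diff, ("svn", "svr"), alpha=0.05)
print(f"log2FC concordance on {n} shared significant peaks: r = {r:.3f}")

# attribution: on a subset where the dominant planted motif varies,
# withholding it causes the largest correlation drop
y = diff.log2fc("svn")
zeroed = zeroed_out_fits(X, y, "auto")
g = "G000"
others = [h for h in truth.true_betas["svn"] if h != g]
subset = list(X.index[(X[others] == 0).all(axis=1)])
rep = delta_cor(svn, zeroed, subset, y, X, subset_label="G000-subset")
top = rep.table["delta_cor"].nlargest(3)
print(f"delta-cor on {len(subset)} peaks (top 3):")
for name, val in top.items():
    print(f"  {name}: {val:+.3f}")
# A positive delta-cor means the model loses predictive correlation on
# the subset when that motif is withheld - the motif disproportionately
# explains accessibility change at those peaks.
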