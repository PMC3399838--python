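"""Why low-LD panels need adaptive (weighted) bin scores.

With markers 100 cM apart, the LD within a bin is essentially nil, so the
plain bin average cancels opposite-signed marker effects and predicts
nothing.  Weighting each marker by its single-marker regression estimate
(relative to the mean absolute estimate in its bin) re-aligns the effects
and restores predictability.  Weights here follow the published workflow:
a preliminary whole-sample marker scan feeds the cross-validation.
"""

from binsel import design_preset, scan_bin_sizes, simulate_dataset

ds = simulate_dataset(design_preset("IV", scale=0.02, n=500), seed=11)
vy = ds.phenotypes.variance
print(f"{ds.design.n} individuals x {ds.map.n_markers} unlinked markers "
      f"(100 cM spacing), var(y) = {vy:.1f}\n")

profile = scan_bin_sizes(
    ds.genotypes, ds.map, ds.phenotypes,
    sizes=[1000.0, 10_000.0], unit="cM",
    modes=("unweighted", "adaptive"), k=10, seed=1,
    weights="whole-data", cv_folds_inner=5,
)
df = profile.to_frame()
print(df.to_string(index=False))

unw = df[df["mode"] == "unweighted"]["mse"].min()
ada = df[df["mode"] == "adaptive"]["mse"].min()
print(f"\nunweighted bin model: best MSE {unw:.1f} vs var(y) {vy:.1f} "
      f"-> {'no ' if unw >= vy else ''}predictability")
print(f"adaptive bin model:   best MSE {ada:.1f} "
      f"-> R2 = {1 - ada / vy:.3f}")
print("\n(With fold-recomputed weights — weights='fold' — the adaptive "
      "advantage\nremains but is smaller: part of the gain above reflects "
      "the whole-sample scan.)")
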