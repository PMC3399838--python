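"""Simulate an F2 population and inspect its genetic architecture.

Builds a scaled-down oligogenic design (2400 cM genome, 1 cM marker grid,
20 QTL plus 20 epistatic pairs) and prints the realized variance components
and the Mendelian / linkage structure of the genotypes.
"""

import numpy as np

from binsel import design_preset, f2_covariance, simulate_dataset

design = design_preset("I", scale=0.02, n=1000, seed=1)
ds = simulate_dataset(design)

print(f"markers: {ds.map.n_markers}, individuals: {design.n}")
print(f"residual variance sigma2_e = {design.sigma2_e}")
print(f"realized main-effect variance : {ds.var_main:8.2f}  (target 64.12)")
print(f"realized epistatic variance   : {ds.var_epistatic:8.2f}  (target ~26.5)")
print(f"realized heritability h2      : {ds.h2_realized:8.3f}")
print(f"expected heritability h2      : {ds.h2_expected:8.3f}")

# genotype frequencies at one marker: F2 segregates 1 AA : 2 Aa : 1 aa
z = ds.genotypes.values[:, 600]
freq = [(z == v).mean() for v in (1, 0, -1)]
print(f"\ngenotype frequencies (AA, Aa, aa) at marker 601: "
      f"{freq[0]:.3f}, {freq[1]:.3f}, {freq[2]:.3f}  (expect 0.25/0.50/0.25)")

# LD decays with map distance following (1 - 2r) under the Haldane map
print("\nmap distance d (cM) | empirical corr | theory 1 - 2 r(d)")
Z = ds.genotypes.values
for lag in (1, 5, 20, 100):
    d = lag * design.marker_spacing
    emp = np.mean([np.corrcoef(Z[:, j], Z[:, j + lag])[0, 1]
                   for j in range(0, 2000, 97)])
    print(f"{d:12.0f}        | {emp:+.3f}         | {2 * f2_covariance(d):+.3f}")
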