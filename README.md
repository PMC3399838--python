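# binsel — bin-based infinitesimal model for genomic prediction

`binsel` implements a marker-based infinitesimal model for quantitative-trait
genomic prediction and QTL mapping.  Instead of estimating one effect per SNP
— hopeless when panels reach 10⁵–10⁶ markers — the genome is partitioned into
*bins* (contiguous intervals), the markers inside each bin are collapsed into
a single covariate, and the resulting finite model is fitted by L1-penalized
regression.  It is aimed at quantitative geneticists and breeders working
with line-cross populations (F2, BC, DH) or outbred panels such as
SNP-genotyped livestock.

## The model

Genotypes are coded per locus as Z ∈ {+1, 0, −1} for AA / Aa / aa, so that in
an F2 population Var(Z) = 1/2 and Cov(Z_h, Z_l) = (1 − 2 r_hl)/2 with r the
Haldane recombination fraction.  With the genome cut into m bins, bin k
holding p_k markers, the working model is

    y_j = β₀ + Σ_k γ_k · Z̄_jk + ε_j,      Z̄_jk = (1/p_k) Σ_h Z_jhk

fitted by the Lasso, min (1/2n)‖y − β₀ − B γ‖² + λ‖γ‖₁, with λ chosen by
seeded k-fold cross-validation on a 50-point logarithmic grid.  Nonzero bin
effects are tested with an approximate Wald statistic W_k = γ̂_k²/Var(γ̂_k)
and LOD_k = W_k/(2 ln 10), using LOD ≥ 3 as the significance criterion.

The unweighted average requires high within-bin LD and effect homogeneity.
For low-LD populations the **adaptive** variant first runs a single-marker
regression scan, weights each marker by w_hk = b̂_hk / mean_h|b̂_hk| (signed,
with mean |w| = 1 per bin), and uses the weighted score
S_jk = (1/p_k) Σ_h w_hk Z_jhk instead — aligning the within-bin effect
directions that plain averaging would cancel.

Predictive ability is measured by 10-fold cross-validation:
MSE = (1/n) Σ (y_j − ŷ_j)² with every data-dependent step re-run inside each
training fold, and the predictability R² = 1 − MSE/var(y).  Scanning bin
sizes locates the optimum: under high LD the MSE-vs-bin-size profile is
U-shaped; without LD only the adaptive model predicts at all, improving as
bins grow.

A built-in F2 simulator (Haldane map, Markov gamete walks, 1:2:1
segregation) provides four preset trait architectures — oligogenic,
clustered polygenic, uniform polygenic, and oligogenic without LD — with
additive QTL, optional pairwise epistasis and Gaussian error.

## Worked example

```python
from binsel import design_preset, scan_bin_sizes, simulate_dataset

ds = simulate_dataset(design_preset("I", scale=0.02, n=300, sigma2_e=50.0),
                      seed=4)
profile = scan_bin_sizes(ds.genotypes, ds.map, ds.phenotypes,
                         sizes=[1, 2, 5, 10, 20, 40, 100], unit="cM",
                         modes=("unweighted",), k=10, seed=1,
                         cv_folds_inner=5)
print(profile.to_frame()[["bin_size", "m", "mse", "r2"]].to_string(index=False))
print(profile.best())
```

prints (300 F2 individuals on a 2400 cM chromosome, 1 cM marker grid,
var(y) = 155.8):

```
 bin_size    m        mse       r2
        1 2400 102.823904 0.339927
        2 1200 102.815657 0.339980
        5  480 102.677052 0.340869
       10  240 105.101953 0.325303
       20  120 110.586166 0.290097
       40   60 110.751369 0.289037
      100   24 119.049167 0.235769
```

The optimum sits at 5 cM bins (480 bins): MSE 102.7 ± 8.3, predictability
R² = 0.341 — about a third of the phenotypic variance is predicted out of
sample.  Fine bins overfit slightly; 100 cM bins merge distinct QTL and lose
a tenth of the predictability.  The `examples/` directory walks through the
simulator, the bin-size scan, the low-LD adaptive rescue, and LOD-based QTL
mapping, each printing and explaining its numbers.

The same pipeline is scriptable from the shell:

```sh
binsel simulate --design I --scale 0.02 --n 300 --seed 4 --out sim
binsel scan --sizes 1,2,5,10,20,40,100 --unit cM --modes unweighted \
       --geno sim.geno.tsv --map sim.map.tsv --pheno sim.pheno.tsv \
       --k 10 --seed 1 --out scan
binsel report --profile scan.profile.tsv --out fig
```

## Layout

- `src/binsel/data.py` — marker map, genotype/phenotype/covariate containers
  and delimited-text I/O
- `src/binsel/qc.py` — MAF filter, covariate pre-adjustment, imputation
- `src/binsel/simulate.py` — F2 simulator and the four design presets
- `src/binsel/binning.py` — bin partition, bin averages, variance theory
- `src/binsel/adaptive.py` — marker scan, weights, weighted scores
- `src/binsel/fit.py` — Lasso fit, Wald/LOD bin tests
- `src/binsel/evaluate.py` — k-fold CV, predictability, bin-size scan
- `src/binsel/cli.py` — `binsel` command group
- `docs/methods.md` — modeling assumptions, defaults and their rationale
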