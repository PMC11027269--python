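# gxekit

Genotype-by-environment (G×E) interaction encoding for genome-wide
association studies and genomic selection.

## The problem

Traits measured in several environments (or several correlated traits)
carry two kinds of genetic signal: an **additive** component — the average
marker effect across environments — and an **interactive** component — the
environment-specific deviation from a baseline environment. Conventional
single-trait analyses either average the environments away (the *mean value
method*) or analyse each environment separately, and in both cases the
interaction signal is lost. `gxekit` makes the interaction usable by any
standard single-trait GWAS or prediction model, at the cost of nothing more
than a larger genotype matrix.

## The encoding

Given a 0/1/2 genotype matrix **G** (*n* individuals × *m* markers) and *s*
environments, build the environment design **E** (*s* × *s*): the first
column is all ones (additive), and column *j* ≥ 2 is the indicator of
environment *j*, with environment 1 as baseline. The expanded genotype is
the Kronecker product

```
E ⊗ G   =   [ G  0 ]     (s = 2)
            [ G  G ]
```

an (*s·n*) × (*s·m*) matrix whose first *m* columns `[G; G]` carry additive
effects and whose remaining columns `[0; G]` carry the interaction.
Phenotypes are z-scored per environment and stacked in the same
environment-major row order. The expanded pair then enters:

* a **mixed linear model** scan `y = PCs + SNPᵢ + u + e`, with
  `u ~ N(0, σ²_g K)` and kinship **K** built from the *full* expanded
  matrix (VanRaden centered cross-product), variance components estimated
  once under the null by eigendecomposition REML (P3D) and each marker
  tested with a two-sided *t* statistic;
* **Power/FDR** benchmarking against simulation truth: at each rank cut of
  the p-value-sorted marker list, power = detected QTNs / all QTNs and FDR
  (as conventionally printed in this literature) = declared non-QTNs / all
  non-QTNs;
* **genomic prediction**: GBLUP (REML or ML) on the whole expanded
  kinship — exactly equivalent to ridge regression (rrBLUP) on centered
  markers — and Gibbs samplers for BRR, BayesA, BayesB, BayesCπ and the
  Bayesian LASSO with separate additive and interactive marker blocks;
* **cross-validation** with missing-environment schemes: masking one
  environment of the inference individuals (the other environment stays in
  training and informs the prediction through the kinship) or all of them.

A multi-environment phenotype simulator (QTN effects drawn from a
compound-symmetric multivariate normal with genetic correlation *r*,
residuals scaled to a target heritability *h²*) makes every analysis fully
self-contained.

## Worked example

```python
import numpy as np
import gxekit as gk
from gxekit.cli import run_gwas

# synthetic panel: 200 individuals, 500 unlinked markers
G = gk.data_io.generate_synthetic_genotypes(n=200, m=500, seed=1)

# two environments, 20 QTNs, h2 = 0.5, genetic correlation r = 0.2
sim = gk.simulate.simulate(G, nqtn=20, h2=0.5, r=0.2, s=2, seed=1)
print("realized h2:", np.round(sim.realized_h2, 3))

# G-by-E scan (collapsing each marker's additive/interactive copies to its
# best p-value) vs the mean-value comparator
res = gk.gwas.collapse_pvalues(run_gwas(G, sim.phenotypes, mode="gbye"))
curve = gk.evaluate.curve_from_results(res, sim.truth, G.marker_map)
print("GbyE power at FDR 0.1:", round(gk.evaluate.power_at_fdr(curve, 0.1), 3))

res_m = run_gwas(G, sim.phenotypes, mode="mean")
curve_m = gk.evaluate.curve_from_results(res_m, sim.truth, G.marker_map)
print("Mean-method power at FDR 0.1:", round(gk.evaluate.power_at_fdr(curve_m, 0.1), 3))

# genomic prediction with one environment's phenotypes masked
cvres = gk.crossval.run_cv(
    G, sim.phenotypes,
    gk.crossval.CVScheme(k=5, reps=3, masking="single_env_missing", seed=1),
)
print(gk.crossval.compare_methods(cvres).to_string(index=False))
```

Output:

```
realized h2: [0.555 0.5  ]
GbyE power at FDR 0.1: 0.65
Mean-method power at FDR 0.1: 0.5
method  mean_accuracy       sd  relative_change_vs_baseline  paired_p
  gbye       0.294577 0.038539                     0.163703   0.24483
  mean       0.253138 0.055643                     0.000000   1.00000
```

At low genetic correlation the interaction carries real signal: the
expanded encoding finds 65% of the QTNs at an FDR of 0.1 where averaging
the environments finds 50%, and cross-validated prediction of the masked
environment is ~16% more accurate (here non-significant at only 3
repeats; the full benchmark in `scripts/acceptance.py` uses more).

The same pipeline is scriptable from the shell:

```bash
gxekit fixtures --n 300 --m 1000 --seed 42 --out fixtures/   # 3x3 (h2, r) grid
gxekit pipeline --n 100 --m 500 --nqtn 10 --reps 5 --seed 1 --out run/
gxekit cv --geno g.tsv --marker-map map.tsv --pheno p.tsv \
          --engine gblup --scheme single_env_missing --reps 10 --seed 7 --out cv/
```

Every command writes a `MANIFEST.json` with the parameter echo, package
version and content hashes of its outputs, so a run is reproducible from
its record.

## Layout

| module | contents |
| --- | --- |
| `gxekit.data_io` | HapMap / numeric genotype readers, phenotype tables, synthetic panel generator |
| `gxekit.encoding` | environment design, Kronecker expansion, phenotype stacking, mean comparator |
| `gxekit.simulate` | QTN sampling, correlated effect draws, heritability-scaled phenotypes |
| `gxekit.gwas` | kinship, PCA covariates, REML, P3D mixed-model scan, p-value collapsing |
| `gxekit.evaluate` | Power/FDR curves, replicate averaging, plotting |
| `gxekit.gs` | GBLUP (REML/ML) and Gibbs samplers (BRR, BayesA/B/Cπ, LASSO) |
| `gxekit.crossval` | k-fold CV, missing-environment masking, method comparison |
| `gxekit.fixtures` | reproducible (h², r) study grids |
| `gxekit.cli` | `gxekit` command-line entry point |

See `docs/methods.md` for the statistical details and design choices.
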