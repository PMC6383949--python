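# gridgwas

Grid-search linear mixed models for genome-wide genetics.

`gridgwas` fits LMMs with multiple random effects by discretizing the
variance-component *proportions* on a simplex grid. Writing
`h2 = (h2_1, ..., h2_L, h2_e)` for the fraction of phenotypic variance
attributed to each random effect and to the residual, the marginal
covariance at a grid vertex is

    V = sum_l h2_l Z_l K_l Z_l^T + h2_e I,

which is factored **once per vertex** (lower Cholesky) and reused across
every marker or trait. This turns a genome-wide scan with several random
effects — where no closed-form or single-eigendecomposition shortcut
exists — into one cheap generalized-least-squares solve per test and
vertex, yielding:

- approximate (but highly accurate) **REML Wald tests** and **ML
  likelihood-ratio tests** per marker, with the variance proportions
  re-optimized over the grid for every test;
- **Bayesian grid posteriors** of the variance-component proportions and
  per-marker **Bayes factors** under a conjugate normal-inverse-gamma
  prior (flat improper priors on shared covariates and the scale cancel
  exactly in the ratios);
- three **accelerated searches** that avoid the full grid while never
  under-performing the two-step ("variance fixed under the null")
  approximation, because the search is pegged to the null-model estimate;
- support for additive, pairwise-epistatic (Hadamard square), signed
  gene-by-environment (`D Z K Z^T D`) and categorical relationship
  matrices, and a synthetic-data module for structured populations.

Cost model (per scan, documentation only): a full grid with `g` vertices
costs `O(g (n^3 + p n^2))` for `n` observations and `p` tests against
`O(t p n^3)` for re-optimizing each test directly; the accelerated search
replaces `g` by the null-model optimization plus a few balls/rings of
vertices around it.

## Layout

| module | contents |
| --- | --- |
| `gridgwas.kinships` | relationship-matrix construction and normalization |
| `gridgwas.lmm_core` | rotation, GLS, ML/REML profiles, Wald and LR tests |
| `gridgwas.grid_engine` | simplex grid, vectorized full-grid scans |
| `gridgwas.bayes_engine` | NIG marginals, grid posteriors, Bayes factors, prior discretization |
| `gridgwas.fast_search` | ball / adaptive-refinement / concentric-ring heuristics |
| `gridgwas.gwas` | association scans, G×E designs, genomic control, multi-trait variance components |
| `gridgwas.simulate` | structured genotypes, phenotypes with chosen variance fractions, population expansion |
| `gridgwas.io_cli` | text + PLINK I/O, sample alignment, CLI |

## Python usage

```python
import numpy as np
from gridgwas import (ModelSpec, ScanConfig, additive_kinship,
                      run_association_scan)
from gridgwas.simulate import simulate_structured_genotypes, simulate_phenotype

G = simulate_structured_genotypes(n=300, p=1000, blocks=15, seed=1)
K = additive_kinship(G)
y, truth = simulate_phenotype([K], (0.5,), marker=G.dosages[:, 3],
                              effect_fraction=0.05, seed=2)
spec = ModelSpec(y, np.ones((300, 1)), None, [(None, K)])
table = run_association_scan(spec, G, ScanConfig(method="wald",
                                                 search="fast", m=100))
print(table.frame.head())
print("genomic control lambda:", table.gc.lambda_)
```

Multi-trait variance components (REML point estimates plus grid
posteriors, no MCMC):

```python
from gridgwas import variance_component_scan
res = variance_component_scan(traits, spec, m=20)
res.frame[["h2_1_reml", "h2_1_postmean", "p_nonzero_1"]]
```

## Command line

```sh
gridgwas simulate --n 200 --p 500 --blocks 10 --h2 0.4 --seed 1 --out sim
gridgwas kinship  --genotypes sim.geno.tsv --type additive --out sim.K.tsv
gridgwas scan --genotypes sim.geno.tsv --phenotypes sim.pheno.tsv \
              --kinship sim.kinship.tsv --method wald --grid-step 0.01 \
              --fast --seed 1 --out results
gridgwas vc   --phenotypes sim.pheno.tsv --kinship sim.kinship.tsv \
              --grid-step 0.05 --out vc
```

`scan` accepts `--method {wald,lrt,bayes}`, `--fast` / `--full-grid` /
`--null-vertex`, `--env-col` (±1 column, switches to interaction tests),
and either a delimited text genotype matrix or a PLINK prefix. Output
tables are tab-separated with a self-describing commented header
(version, config hash, seed); numbers round-trip at 17 significant
digits.

## Caveats

- Grid estimates of variance proportions are accurate but limited to the
  grid resolution; posterior *interval boundaries* in particular may not
  be reliable, although posterior means are.
- Non-Gaussian responses and correlated random effects are out of scope.
- The accelerated searches assume an (approximately) unimodal likelihood
  or posterior surface; a diagnostic rerun of the full grid on a random
  subset of tests can be enabled to audit this.
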