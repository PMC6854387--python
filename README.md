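# picrisk

Phylogenetic comparative analysis of predation-risk effect sizes from
predator-exclusion experiments.

## The problem

Field ecologists measure how much a predator guild (here: ants foraging on
forest trees) suppresses each herbivore species in a community by pairing
control branches with exclusion branches and counting the herbivores
(caterpillars) found on each. The per-species effect size is the log
response ratio of pooled population densities,

```
LRR = ln( control density / exclusion density ),
```

negative when predators suppress the species. The comparative question is
which species traits predict that risk — diet breadth, behavioral defense,
mobility, body size, abundance — but species are not independent data
points: close relatives share traits by descent. `picrisk` implements the
full inference chain that handles this correctly:

* **Host phylodiversity (HPD)** as the diet-breadth metric: the total branch
  length (millions of years) of the minimal subtree linking a species'
  recorded host plants (Faith-style phylogenetic diversity).
* **Species-level behavioral predictors** from individual assay records:
  frequency of behavioral response to simulated attack (FBR), frequency of
  fleeing from ant encounters (FF), field mobility, mean body length,
  log-transformed abundance.
* **Felsenstein's independent contrasts (PICs)**: for each internal node
  with child values x_i, x_j on adjusted branch lengths v_i, v_j, the
  standardized contrast (x_i − x_j)/√(v_i + v_j) is an independent draw from
  N(0, σ²) under Brownian trait evolution. Unit and Grafen branch-length
  schemes are provided for undated trees.
* **Two-stage AICc multimodel inference through the origin** (regressions on
  contrasts have no intercept): all 2⁵ subsets of the five predictor
  contrasts are ranked by AICc = −2lnL + 2k + 2k(k+1)/(n−k−1); relative
  variable importance RVI(x) = Σ wᵢ over models containing x; the top three
  predictors by rank are refit as an 8-model set with Akaike-weighted model
  averaging and Buckland unconditional standard errors.
* **Treatment-contingency ANCOVA**: contrasts computed separately per bird
  stratum are stacked and fit with the no-intercept model
  `y = x + group + x:group`, tested with sequential (type-I) F tests
  (dfs 1 / 2 / 1, residual n − 4), plus per-stratum through-origin
  regressions and Pearson correlations between contrast sets.
* **A synthetic-data generator** producing trees, correlated Brownian tip
  traits, and Poisson branch-count experiments whose true per-species log
  ratio is known exactly, so every stage is verifiable without field data.

The statistical core is exposed as scikit-learn-style estimators
(`IndependentContrasts`, `OriginRegression`, `AICcModelSelection`,
`TwoStageModelSelection`, `ContrastAncova`) with plain functions as thin
wrappers.

## Worked example

Simulate a 20-species study at the package defaults (two bird strata, 280
branches per arm per stratum, baseline density 0.05 caterpillars/m², true
standardized effects +0.39 diet breadth, +0.41 behavioral response, −0.42
abundance) and run the full pipeline:

```python
import numpy as np, picrisk as pk
from picrisk.simulate import build_species_table

cfg = pk.SimulationConfig(seed=11)
rng = np.random.default_rng(cfg.seed)
tree = pk.simulate_tree(cfg.n_species, cfg.tree_model, rng, cfg.branch_lengths)
traits = pk.simulate_bm_traits(tree, cfg.trait_cov, rng, cfg.trait_names)
samples = pk.simulate_experiment(traits, cfg, rng)
table = build_species_table(traits, samples, rng)
res = pk.run_analysis(table, {"tree1": tree})
print(res["tree1"]["rvi"].to_string(index=False))
print(res["tree1"]["averaged"].round(3).to_string(index=False))
```

```
predictor      rvi
      hpd 0.999940
      fbr 0.999927
abundance 0.998582
 mobility 0.249896
length_mm 0.167702

predictor   beta    se  ci_lower  ci_upper   rvi
      hpd  0.277 0.041     0.196     0.358 1.000
      fbr  0.246 0.040     0.168     0.325 1.000
abundance -0.184 0.039    -0.260    -0.108 0.999
```

The stage-1 screen ranks exactly the three traits that truly carry an
effect (RVI ≈ 1.0) far above the two pure-noise traits, and the
model-averaged slopes on the contrast scale recover the signs of the
generating effects: risk falls (LRR rises) with diet breadth and behavioral
responsiveness, and rises with abundance. `res["tree1"]["models"]` holds
the full 8-model AICc table and `res["tree1"]["ancova"]` the bird-treatment
interaction tests.

The same pipeline runs from the shell:

```bash
picrisk simulate --out-dir fixture --seed 11
picrisk run-all --config run.yaml --out-dir results/
```

where `run.yaml` names the species table, the tree file(s), the
branch-length scheme and thresholds.

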