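# imdforest

Unsupervised cross-omics feature selection with multivariate random forests
and inverse-minimal-depth importance.

## The problem

Given two or more omics blocks measured on the same samples — say gene
expression and DNA methylation matrices `X (n x p)` and `Y (n x q)` — which
features in each block carry signal that is *shared* across blocks?  There
is no outcome variable: the goal is to find cross-correlated feature sets,
including nonlinear and interaction-driven dependence that linear
integrators (sparse PLS, CCA variants) miss.

## The method

One block is treated as a multivariate response and the other as
predictors, and a forest of regression trees is grown.  At each node the
responses are standardized within the node and a split is scored by the
summed per-response statistic

    G*(s,t) = Σ_j [ (Σ_{i∈t_L} Y*_ij)² / n_L  +  (Σ_{i∈t_R} Y*_ij)² / n_R ],

whose maximization is equivalent to minimizing the within-daughter sum of
squares over the responses.  Importance comes from tree shape rather than
permutation: a variable's **minimal depth** `D_v` is the depth of the
shallowest node that splits on it, and its **inverse minimal depth**

    M_v = 1 / (D_v + 1)   (0 if the variable is absent from the tree)

is averaged over trees to give the forest IMD.  Response-side importance
uses the **maximal splitting response variable** (MSRV): the response with
the largest `G_j` at each node inherits the node's depth, so both blocks
get a ranking from a single model.  Three selectors turn the IMD profile
into a feature set:

* **filter** — keep IMD > τ·σ_m, with τ tuned on a 0.1-step grid by
  refitting the forest and tracking out-of-bag error;
* **mixture** — zero-inflated two-component mixture on the forest IMD,
  fit by EM; keep variables with posterior noise probability < 0.05;
* **transformation** — t-score `(M_v − μ)/SE(M_v)`; keep scores beyond the
  0.05-level t boundary with `df = ntree − 1`.

With more than two blocks, pair directions are inferred by fitting both
directions on PCA-reduced data and keeping the direction with the lower
out-of-bag error, a spanning tree of directed models is fit, and IMD is
averaged per block across the models it participates in.

## Worked example

```python
from imdforest import (RunSettings, ForestConfig, pairwise_select,
                       precision_recall, generate_latent, latent_scenario)

data = generate_latent(latent_scenario("S1", seed=3))   # 2 blocks, 20 true each
sel = pairwise_select(data.blocks[0], data.blocks[1], "mixture",
                      settings=RunSettings(forest=ForestConfig(n_trees=300)),
                      seed=3)
edge = sel.graph.edges[0]
print(f"inferred direction: {edge.response} <- {edge.predictor}")
p, r = precision_recall(sel.selected, data.truth_all)
print(f"selected {sel.model_size} of 400 features, precision {p:.2f}, recall {r:.2f}")
```

prints

```
inferred direction: block2 <- block1
selected 48 of 400 features, precision 0.77, recall 0.93
```

i.e. on a latent-factor benchmark with 20 planted cross-correlated features
per 200-feature block, the pipeline chose to model block 2 as the response,
and the mixture selector returned 48 features covering 37 of the 40 true
ones.  Precision and recall here score one replicate; the benchmark driver
below averages them over seeds.

The same pipeline is scriptable from the shell:

```bash
imdforest simulate --model latent --scenario S1 --seed 7 --outdir sim/
imdforest select --blocks sim/block1.tsv --blocks sim/block2.tsv \
                 --strategy mixture --seed 7 --outdir out/
imdforest evaluate --selection out/selection_block1.tsv \
                   --selection out/selection_block2.tsv \
                   --truth sim/truth.json --out out/metrics.tsv
imdforest benchmark --model latent --scenario S1 --strategy mixture \
                    --replicates 10 --seed 1 --out bench.tsv
```

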