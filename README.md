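# netwarp

Disease-gene prioritization by random walk with restart over a **warped**
protein-interaction network.

An undirected, unweighted network is warped by two features before scores are
diffused over it:

1. **Internal feature — edge curvature.** Every edge gets the augmented
   Forman–Ricci curvature `κ_e = 4 − deg(u) − deg(v) + 3·|common neighbors|`,
   which is large and positive inside dense complexes and strongly negative on
   hub spokes. Curvatures are standardized over the edge set and squashed
   through a sigmoid scaled by `β`, giving a symmetric weight matrix `K`
   (`β = 0` recovers the unweighted network).
2. **External feature — prior knowledge.** A set of known relevant genes is
   diffused to the stationary distribution `π` of the column-stochastic
   restart kernel `P_ji = (1−γ)·K_ji/Σ_k K_ki + γ·φ_j`, where `φ` is uniform
   on the prior genes. The final warped adjacency is `A*_ji = K_ji·π_j` —
   asymmetric, i.e. an implicitly *directed* network.

Omics-derived gene scores `v⁰` are then propagated by random walk with
restart, `v ← (1−q)·A*D*⁻¹·v + q·v⁰`, and genes are ranked by the fixed
point `v*`.

## Package layout

| module | contents |
| --- | --- |
| `netwarp.network` | `Network` type, edge-list readers (plain / STRING-style / BioGRID-style dialects, confidence filtering), induced subgraphs, largest connected component |
| `netwarp.curvature` | augmented Forman–Ricci curvature, node averages, sigmoid warping `K(β)` |
| `netwarp.prior` | prior vector `φ`, restart kernel, stationary distribution `π` (sparse closed-form solve and power iteration), warped adjacency `A*` |
| `netwarp.diffusion` | random walk with restart (closed-form solve and power iteration), score-table IO |
| `netwarp.scoring` | per-stratum case/control Welch t-tests, Fisher combination, Z-scores |
| `netwarp.evaluation` | train/test splits of the ground truth, average precision, precision@k, paired one-sided t-tests with Benjamini–Hochberg adjustment |
| `netwarp.synthetic` | the 11-node toy graph and a planted-clique/hub benchmark generator |
| `netwarp.pipeline`, `netwarp.cli` | `RunConfig`, method variants, the `netwarp` command |

Method variants (all configuration of the same pipeline):
`warped` (full method, defaults `β=0.5`, `γ=0.5`, `q=0.3`),
`warped_nocurv` (`β` forced to 0), `rwr` (plain restart walk on the
adjacency), `rwr_curvature` (restart walk on `K` without any prior).

## CLI

```sh
# generate a synthetic benchmark (edge list, truth, priors, scores)
netwarp generate --out-dir data --seed 7

# run the full method
netwarp run --method warped --network data/network.tsv \
    --priors data/priors.txt --scores data/scores.tsv \
    --beta 0.5 --gamma 0.5 --q 0.3 --output results/run1

# per-edge curvature / weight table
netwarp curvature --network data/network.tsv --beta 0.5 --output curv.tsv

# score rankings against a relevant-gene list
netwarp evaluate --ranking results/run1/ranked_scores.tsv \
    --relevant data/truth.txt --exclude data/priors.txt --k 100 --k 200
```

`run` writes `ranked_scores.tsv` plus a `manifest.json` capturing all
parameters, input hashes and library versions; re-running an identical
configuration reproduces byte-identical output. Exit codes: 0 ok, 1 input
error, 2 numerical failure. A flat YAML config can be passed via
`--config`; explicit flags override its keys.

## Notes on conventions

- Degree/`D*` normalization is by **column sums**, making the propagation
  matrix column-stochastic (the standard restart-walk convention).
- STRING-style confidence filtering keeps rows with combined score
  **strictly greater** than the threshold; 0–1000-scaled scores are
  auto-detected and rescaled.
- Sample standard deviation of curvatures uses the unbiased (n−1)
  denominator over the unordered edge set; if it is 0 every edge weight
  falls back to 1/2 (the `β = 0` semantics) with a warning.
- `Z = Φ⁻¹(1−p)`: the upper-tail standard-normal quantile of the combined
  p-value.
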