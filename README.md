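# ndseq

Analysis of complex networks through their **neighbourhood degree
sequences** — for each node, the nondecreasing list of its neighbours'
degrees. The library computes five sequence-based topology indices,
classical comparison indices, degree-preserving configuration-model nulls,
and the statistics used to compare observed networks against those nulls.

## Indices

| Symbol | Name | Meaning |
|---|---|---|
| `S` | neighbourhood similarity | fraction of nodes whose sequence equals that of at least one other node |
| `V_n` | node heterogeneity | mean variance of neighbourhood degree sequences (nodes of degree > 1) |
| `V_hat_n` | relative node heterogeneity | `V_n` divided by the global degree variance |
| `Omega` | neighbourhood organisation | 1 − mean multi-orderedness `omega_p` over degrees held by ≥ 2 nodes |
| `R` | hierarchical complexity | mean positional variance of equal-length sequences |
| `R_Omega` | corrected hierarchical complexity | `R` with each degree's term weighted by `omega_p` (always ≤ `R`) |

Classical indices (`C` transitivity, `v` degree variance, `L`
characteristic path length, `r` assortativity, `Q` modularity) are included
so correlation and null analyses can be run alongside.

Notable conventions (all selectable, all recorded in report provenance):

* Isolated nodes are excluded from sequence tables and from every index.
* Variance convention defaults to *population*; the *sample* convention is
  the one that reproduces the published karate-club heterogeneity value.
* `R`/`R_Omega` default to the formula as written; published reference
  values for real networks use an additional division by the node count,
  available as `per_node_normalised_complexity=True` (`--table-scale` on
  the CLI).
* Undefined results (e.g. `V_hat_n` on a regular graph) are reported as
  `None` with a flag, never silently zeroed.

## Library quick start

```python
import ndseq

g = ndseq.fixtures("karate")          # packaged 34-node / 78-edge fixture
rep = ndseq.compute_all(g, variance_convention="sample",
                        per_node_normalised_complexity=True)
print(rep.S, rep.V_hat_n, rep.Omega, rep.R, rep.R_Omega)

ens = ndseq.null_ensemble(g, n_realisations=10, seed=0)
print(ens.mean("S"))                  # configuration-model null mean
```

Graphs can be read from edge lists (2–3 columns, `#` comments), Matrix
Market adjacency (`.mtx`), GraphML, or dense adjacency CSV via
`ndseq.read_graph(path)`; weighted/directed input is symmetrised, or
thresholded with `binarize_density=` to keep the largest-weight pairs.

## CLI

```sh
ndseq compute graphs/*.edgelist --out indices.csv        # all indices per graph
ndseq nullcmp graphs/*.edgelist --realisations 10 \
      --seed 1 --out-prefix run                          # observed vs null means + tests
ndseq corr indices.csv --out corr.csv                    # Spearman matrix
ndseq models watts_strogatz --n 100 --k 4 --beta 0.1 \
      --seed 7 --out ws.edgelist                         # generators
ndseq snapshots t0.edgelist t1.edgelist t2.edgelist      # ordered time series
ndseq fixtures karate --out karate.edgelist              # canonical graphs
```

Exit codes: 0 success, 1 partial (some inputs failed), 2 all failed.
Every stochastic output is bit-reproducible under a fixed `--seed`.

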