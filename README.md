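# mrsupertree

Split-based majority-rule (MR) supertrees for unrooted phylogenetic trees:

* **Exact score computation** for the three MR variants on bifurcating
  supertrees via a relationship matrix of split relations
  (subsplit / compatible / incompatible):
  * `d⁻ = 2C (+ m)` — RF distance between the pruned supertree and the
    input tree (multifurcating inputs allowed, `m` multifurcations),
  * `d⁺g = B + C` — minimum RF over extensions placing missing taxa onto
    edges or nodes,
  * `d⁺ = 2B` — minimum RF over bifurcating edge-only extensions,

  where `C` counts input-tree splits incompatible with at least one
  supertree split and `B` counts supertree splits incompatible with at
  least one input split, after collapsing supertree subtrees that contain
  no input taxa into dummy taxa.
* **Heuristic search** over bifurcating supertrees minimizing the summed
  distance: step-wise addition starting tree, NNI hill climbing, TDR
  (taxa-deletion-reinsertion) restarts, and a broadening stage that
  collects *all* best-scoring trees found.
* **Consensus post-processing**: strict consensus of the optimal trees,
  deletion of splits contradicted by ≥ 50% of the input trees, and `x/y`
  support labels (`x` = inputs not contradicting the split, `y` = inputs
  supporting it with a nontrivial subsplit).
* **Simulation pipeline**: Yule model trees, input generation by random
  taxon deletion, NNI perturbation for incompatible inputs, and
  normalized evaluation metrics.
* **Brute-force oracles** certifying the closed forms on small instances:
  prune-and-RF, exhaustive edge / edge-or-node grafting, a constructive
  good/bad-taxon witness, and exhaustive supertree enumeration (≤ 8 taxa).

Splits are bitmasks over a global taxon index; trees are canonical split
sets, so equality, hashing, and RF distances are set operations.

## Command line

```sh
# score a supertree against a multi-tree Newick file
mrst score supertree.nwk trees.nwk --method minus      # minus | plus | plusg

# compute the MR supertree (writes supertree.nwk, optimal_trees.nwk,
# manifest.json into -o)
mrst supertree trees.nwk --method minus --seed 1 -o out/
mrst supertree trees.nwk --no-contract --oracle        # -version methods;
                                                       # exhaustive check n<=8

# run a simulation experiment from a JSON config
echo '{"n_taxa": 16, "n_input_trees": 10, "p_delete": 0.25,
       "p_nni": 0.0, "replicates": 10, "seed": 1}' > config.json
mrst simulate config.json -o out/
```

Rooted inputs can be handled with `--root-as-taxon`, which attaches an
artificial taxon at each root before unrooting. Every output directory
receives a JSON manifest (parameters, seed, input digests, wall time) that
reproduces the run exactly.

## Library example

```python
import mrsupertree as m

inputs = m.read_trees("trees.nwk")
res = m.mr_supertree(inputs, m.SearchConfig(method=m.Method.MINUS, seed=1))
print(res.search.best_score, len(res.search.optimal_trees))
print(m.write_newick(res.tree, res.label_strings))
```
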