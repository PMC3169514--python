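"""Simulation study: Yule model trees, taxon-deletion input trees, optional
NNI perturbation, supertree reconstruction, and evaluation metrics.

All generators are topology-only (the downstream computations ignore branch
lengths) and draw exclusively from the RNG passed in, so whole experiments
are reproducible from a single seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .splits import PhyloTree, TaxonIndex, _bits, _canon, restrict_tree, rf_distance
from .scoring import Method, total_score
from .search import SearchConfig, _nni_alternatives
from .consensus import MRResult, mr_supertree

__all__ = [
    "SimConfig",
    "EvalMetrics",
    "yule_tree",
    "make_inputs",
    "nni_perturb",
    "evaluate",
    "run_experiment",
]

RESAMPLE_CAP = 10_000


@dataclass
class SimConfig:
    n_taxa: int = 32
    n_input_trees: int = 10
    p_delete: float = 0.25
    p_nni: float = 0.0
    replicates: int = 100
    seed: Optional[int] = None
    method: Method = Method.MINUS
    contract: bool = True
    tdr_fraction: float = 0.25
    max_iterations: Optional[int] = None
    discard_limit: Optional[int] = None
    max_optimal_trees: int = 100_000

    def __post_init__(self):
        if isinstance(self.method, str):
            self.method = Method.from_string(self.method)
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be at least 4")
        if self.n_input_trees < 1:
            raise ValueError("n_input_trees must be positive")
        if not 0.0 <= self.p_delete < 1.0:
            raise ValueError("p_delete must be in [0, 1)")
        if not 0.0 <= self.p_nni <= 1.0:
            raise ValueError("p_nni must be in [0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be positive")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["method"] = self.method.value
        return d


@dataclass
class EvalMetrics:
    rf_norm: float
    missing_frac: float
    incorrect_frac: float
    success: Optional[bool] = None
    n_optimal_trees: Optional[int] = None
    n_inner_splits: Optional[int] = None


def yule_tree(
    n: int, rng: random.Random, index: Optional[TaxonIndex] = None
) -> PhyloTree:
    """Pure-birth (Yule) topology: starting from two lineages, a uniformly
    random extant lineage splits until there are n tips; returned unrooted.

    Branch lengths are never generated; taxon labels are assigned to the
    tips uniformly at random.
    """
    if n < 4:
        raise ValueError("need at least 4 taxa")
    if index is None:
        width = len(str(n))
        index = TaxonIndex(["t%0*d" % (width, i + 1) for i in range(n)])
    if len(index) < n:
        raise ValueError("index too small")

    children: Dict[int, List[int]] = {0: [1, 2]}
    leaves = [1, 2]
    next_id = 3
    while len(leaves) < n:
        pos = rng.randrange(len(leaves))
        node = leaves[pos]
        a, b = next_id, next_id + 1
        next_id += 2
        children[node] = [a, b]
        leaves[pos] = a
        leaves.append(b)

    bit_order = [1 << i for i in _bits(index.full_mask)][: n]
    rng.shuffle(bit_order)
    leaf_bit = dict(zip(leaves, bit_order))
    taxa_mask = 0
    for b in leaf_bit.values():
        taxa_mask |= b

    splits = set()

    def mask_of(node: int) -> int:
        if node in children:
            m = 0
            for ch in children[node]:
                m |= mask_of(ch)
        else:
            m = leaf_bit[node]
        if node != 0:
            c = m.bit_count()
            if 2 <= c <= n - 2:
                splits.add(_canon(m, taxa_mask))
        return m

    mask_of(0)
    return PhyloTree(index, taxa_mask, splits, validate=False)


def make_inputs(
    model: PhyloTree,
    k: int,
    p_delete: float,
    rng: random.Random,
    min_taxa: int = 4,
) -> List[PhyloTree]:
    """k restrictions of the model tree with each taxon independently
    deleted with probability `p_delete`; the whole dataset is resampled
    until every taxon survives in at least one tree and every tree keeps at
    least `min_taxa` taxa."""
    if not model.is_bifurcating:
        raise ValueError("model tree must be bifurcating")
    bits = [1 << i for i in _bits(model.taxa_mask)]
    for attempt in range(RESAMPLE_CAP):
        masks = []
        ok = True
        union = 0
        for _ in range(k):
            keep = 0
            for b in bits:
                if rng.random() >= p_delete:
                    keep |= b
            if keep.bit_count() < min_taxa:
                ok = False
            masks.append(keep)
            union |= keep
        if ok and union == model.taxa_mask:
            return [restrict_tree(model, m) for m in masks]
    raise RuntimeError(
        "could not sample a valid dataset in %d attempts" % RESAMPLE_CAP
    )


def nni_perturb(t: PhyloTree, p_nni: float, rng: random.Random) -> PhyloTree:
    """Each inner split of the original tree undergoes an NNI with
    probability p_nni (the two alternatives equally likely).

    The original splits are visited once, in random order; splits created by
    earlier swaps are never re-perturbed.
    """
    if not t.is_bifurcating:
        raise ValueError("NNI perturbation requires a bifurcating tree")
    splits = set(t.inner_splits)
    order = sorted(t.inner_splits)
    rng.shuffle(order)
    for s in order:
        if rng.random() < p_nni:
            alts = _nni_alternatives(splits, t.taxa_mask, s)
            new = alts[rng.randrange(2)]
            splits.discard(s)
            splits.add(new)
    return PhyloTree(t.index, t.taxa_mask, splits, validate=False)


def evaluate(
    supertree: PhyloTree,
    model: PhyloTree,
    best_score: Optional[int] = None,
    n_optimal_trees: Optional[int] = None,
) -> EvalMetrics:
    """Normalized distances of a (possibly multifurcating) supertree to the
    bifurcating model tree: RF / (2n-6), missing and incorrect split
    fractions / (n-3)."""
    if supertree.taxa_mask != model.taxa_mask:
        raise ValueError("supertree and model tree must share their taxa")
    n = model.n_taxa
    missing = len(model.inner_splits - supertree.inner_splits)
    incorrect = len(supertree.inner_splits - model.inner_splits)
    rf = missing + incorrect
    success = None
    if best_score is not None:
        success = best_score == 0 and incorrect == 0
    return EvalMetrics(
        rf_norm=rf / (2 * n - 6),
        missing_frac=missing / (n - 3),
        incorrect_frac=incorrect / (n - 3),
        success=success,
        n_optimal_trees=n_optimal_trees,
        n_inner_splits=len(supertree.inner_splits),
    )


def run_replicate(config: SimConfig, seed: int) -> dict:
    """One replicate: model -> inputs -> (perturbation) -> supertree -> metrics."""
    rng = random.Random(seed)
    model = yule_tree(config.n_taxa, rng)
    inputs = make_inputs(model, config.n_input_trees, config.p_delete, rng)
    if config.p_nni > 0:
        inputs = [nni_perturb(G, config.p_nni, rng) for G in inputs]
    else:
        # compatible inputs always admit a score of 0 (the model attains it)
        assert total_score(model, inputs, config.method) == 0
    sc = SearchConfig(
        method=config.method,
        tdr_fraction=config.tdr_fraction,
        max_iterations=config.max_iterations,
        discard_limit=config.discard_limit,
        seed=rng.randrange(2**63),
        max_optimal_trees=config.max_optimal_trees,
    )
    res: MRResult = mr_supertree(inputs, sc, contract=config.contract)
    metrics = evaluate(
        res.tree,
        model,
        best_score=res.search.best_score,
        n_optimal_trees=len(res.search.optimal_trees),
    )
    return {
        "seed": seed,
        "n_taxa": config.n_taxa,
        "method": config.method.value,
        "p_delete": config.p_delete,
        "p_nni": config.p_nni,
        "best_score": res.search.best_score,
        "n_optimal_trees": len(res.search.optimal_trees),
        "n_inner_splits_strict": len(res.strict.inner_splits),
        "n_inner_splits": metrics.n_inner_splits,
        "rf_norm": metrics.rf_norm,
        "missing_frac": metrics.missing_frac,
        "incorrect_frac": metrics.incorrect_frac,
        "success": metrics.success,
        "iterations": res.search.iterations_used,
    }


def run_experiment(config: SimConfig) -> Tuple[pd.DataFrame, dict]:
    """Run all replicates; returns the per-replicate table and a summary."""
    master = random.Random(config.seed)
    rows = []
    for r in range(config.replicates):
        rep_seed = master.randrange(2**63)
        row = run_replicate(config, rep_seed)
        row["replicate"] = r + 1
        rows.append(row)
    df = pd.DataFrame(rows)
    front = ["replicate"]
    df = df[front + [c for c in df.columns if c not in front]]
    summary = {
        "config": config.to_jsonable(),
        "n_replicates": len(df),
        "success_rate": float(df["success"].mean()),
        "mean_rf_norm": float(df["rf_norm"].mean()),
        "mean_missing_frac": float(df["missing_frac"].mean()),
        "mean_incorrect_frac": float(df["incorrect_frac"].mean()),
        "mean_inner_splits": float(df["n_inner_splits"].mean()),
        "mean_inner_splits_strict": float(df["n_inner_splits_strict"].mean()),
        "mean_optimal_trees": float(df["n_optimal_trees"].mean()),
        "mean_best_score": float(df["best_score"].mean()),
    }
    return df, summary
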