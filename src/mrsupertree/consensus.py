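"""Post-processing of the optimal tree set into the final MR supertree.

The strict consensus of all optimal bifurcating trees is taken, then splits
contradicted by at least 50% of the input trees are deleted (restoring the
majority-rule property), and each remaining split is labeled x/y: x input
trees do not contradict it, y of those actively support it with a
nontrivial subsplit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .splits import (
    PhyloTree,
    Split,
    _compatible_masks,
    _is_subsplit_masks,
)
from .scoring import Method
from .search import SearchConfig, SearchResult, run_search

__all__ = [
    "SupportLabel",
    "MRResult",
    "strict_consensus",
    "contradiction_count",
    "contract_majority_violations",
    "support_labels",
    "mr_supertree",
]


@dataclass(frozen=True)
class SupportLabel:
    """x = input trees not contradicting the split; y = trees supporting it
    with a nontrivial subsplit; x - y trees are irrelevant to the split."""

    x: int
    y: int

    def __str__(self) -> str:
        return "%d/%d" % (self.x, self.y)


def strict_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """Tree containing exactly the splits present in all input trees."""
    if not trees:
        raise ValueError("no trees")
    first = trees[0]
    common = set(first.inner_splits)
    for t in trees[1:]:
        if t.taxa_mask != first.taxa_mask or t.index.names != first.index.names:
            raise ValueError("strict consensus requires identical taxon sets")
        common &= t.inner_splits
    return PhyloTree(first.index, first.taxa_mask, common, validate=False)


def contradiction_count(s: Split, inputs: Sequence[PhyloTree]) -> int:
    """Number of input trees containing a split incompatible with `s`."""
    m, u = s.mask, s.universe
    count = 0
    for G in inputs:
        gu = G.taxa_mask
        for g in G.inner_splits:
            if not _compatible_masks(g, gu, m, u):
                count += 1
                break
    return count


def contract_majority_violations(
    t: PhyloTree, inputs: Sequence[PhyloTree]
) -> PhyloTree:
    """Delete every split contradicted by >= 50% of the input trees."""
    if not inputs:
        return t
    k = len(inputs)
    keep = []
    for s in t.splits():
        if contradiction_count(s, inputs) / k < 0.5:
            keep.append(s.mask)
    return PhyloTree(t.index, t.taxa_mask, keep, validate=False)


def support_labels(
    t: PhyloTree, inputs: Sequence[PhyloTree]
) -> Dict[Split, SupportLabel]:
    """x/y support per inner split of `t` (x >= y always)."""
    k = len(inputs)
    out: Dict[Split, SupportLabel] = {}
    for s in t.splits():
        x = k - contradiction_count(s, inputs)
        y = 0
        for G in inputs:
            gu = G.taxa_mask
            for g in G.inner_splits:
                if _is_subsplit_masks(g, gu, s.mask, s.universe):
                    y += 1
                    break
        out[s] = SupportLabel(x=x, y=y)
    return out


@dataclass
class MRResult:
    """Final MR supertree plus the intermediate artefacts."""

    tree: PhyloTree  # contracted (or strict consensus when contract=False)
    strict: PhyloTree
    labels: Dict[Split, SupportLabel]
    search: SearchResult

    @property
    def label_strings(self) -> Dict[Split, str]:
        return {s: str(lab) for s, lab in self.labels.items()}


def mr_supertree(
    inputs: Sequence[PhyloTree],
    config: Optional[SearchConfig] = None,
    contract: bool = True,
) -> MRResult:
    """Full pipeline: search -> strict consensus -> contraction -> labels.

    With `contract=False` the strict consensus itself is returned (the
    "-version" of the method, which is no longer a majority-rule
    generalization but corresponds to MRC for MR(+)).
    """
    if config is None:
        config = SearchConfig()
    result = run_search(inputs, config)
    strict = strict_consensus(result.optimal_trees)
    final = contract_majority_violations(strict, inputs) if contract else strict
    labels = support_labels(final, inputs)
    return MRResult(tree=final, strict=strict, labels=labels, search=result)
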