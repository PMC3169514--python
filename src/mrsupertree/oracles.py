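"""Brute-force reference implementations.

These certify the closed-form distance computations and the heuristic
search on small instances: prune-and-RF for d-, exhaustive taxon grafting
for d+ and d+g, the constructive good/bad-taxon witness, and exhaustive
supertree enumeration.  Everything here is deliberately independent of the
relationship-matrix formulas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, List, Optional, Sequence, Tuple

from .splits import (
    PhyloTree,
    TaxonIndex,
    _attach_at_node,
    _attach_on_edge,
    _bits,
    _canon,
    _compatible_masks,
    _edge_masks,
    _node_keys,
    restrict_tree,
    rf_distance,
)
from .scoring import Method, modify_supertree, total_score

__all__ = [
    "d_minus_oracle",
    "enumerate_bifurcating_trees",
    "enumerate_edge_extensions",
    "enumerate_node_or_edge_extensions",
    "d_plus_oracle",
    "d_plus_g_oracle",
    "construct_witness",
    "exhaustive_supertree",
    "WitnessExtension",
]

MAX_MISSING = 6
MAX_EXHAUSTIVE_TAXA = 8


def d_minus_oracle(S: PhyloTree, G: PhyloTree) -> int:
    """Prune-and-compare: RF between the restrictions to the shared taxa."""
    shared = S.taxa_mask & G.taxa_mask
    if shared.bit_count() < 3:
        raise ValueError("fewer than 3 shared taxa")
    return rf_distance(restrict_tree(S, shared), restrict_tree(G, shared))


# ---------------------------------------------------------------------------
# Tree enumeration and extension streams
# ---------------------------------------------------------------------------


def enumerate_bifurcating_trees(
    index: TaxonIndex, taxa: Optional[object] = None
) -> Iterator[PhyloTree]:
    """All (2n-5)!! unrooted bifurcating trees on the given taxa."""
    taxa_mask = index.full_mask if taxa is None else index.mask_of(taxa)
    bits = [1 << i for i in _bits(taxa_mask)]
    if len(bits) < 3:
        raise ValueError("need at least 3 taxa")

    def rec(k: int, u: int, splits: frozenset):
        if k == len(bits):
            yield splits
            return
        x = bits[k]
        for edge in _edge_masks(splits, u):
            yield from rec(k + 1, u | x, _attach_on_edge(splits, u, edge, x))

    u0 = bits[0] | bits[1] | bits[2]
    for splits in rec(3, u0, frozenset()):
        yield PhyloTree(index, taxa_mask, splits, validate=False)


def _extension_stream(G: PhyloTree, missing: Sequence[int], allow_nodes: bool):
    """Distinct split sets reachable by grafting `missing` taxa in order."""
    if len(missing) > MAX_MISSING:
        raise ValueError("too many missing taxa for exhaustive grafting")
    u0 = G.taxa_mask
    full = u0
    for x in missing:
        full |= x
    seen = set()

    def rec(k: int, u: int, splits: frozenset):
        if k == len(missing):
            if splits not in seen:
                seen.add(splits)
                yield splits
            return
        x = missing[k]
        for edge in _edge_masks(splits, u):
            yield from rec(k + 1, u | x, _attach_on_edge(splits, u, edge, x))
        if allow_nodes:
            for node in _node_keys(splits, u):
                yield from rec(k + 1, u | x, _attach_at_node(splits, u, node, x))

    yield from rec(0, u0, frozenset(G.inner_splits))


def _missing_bits(G: PhyloTree, missing) -> list:
    if missing is None:
        return []
    if isinstance(missing, int):
        return [1 << i for i in _bits(missing)]
    return [1 << G.index.position[lab] for lab in missing]


def enumerate_edge_extensions(G: PhyloTree, missing) -> Iterator[PhyloTree]:
    """Every bifurcating tree obtained by placing missing taxa onto edges."""
    if not G.is_bifurcating:
        raise ValueError("edge-only extension requires a bifurcating tree")
    bits = _missing_bits(G, missing)
    full = G.taxa_mask
    for b in bits:
        full |= b
    for splits in _extension_stream(G, bits, allow_nodes=False):
        yield PhyloTree(G.index, full, splits, validate=False)


def enumerate_node_or_edge_extensions(G: PhyloTree, missing) -> Iterator[PhyloTree]:
    """Extensions placing taxa onto edges or nodes (no multifurcation of G
    is resolved; node placements create or grow multifurcations)."""
    bits = _missing_bits(G, missing)
    full = G.taxa_mask
    for b in bits:
        full |= b
    for splits in _extension_stream(G, bits, allow_nodes=True):
        yield PhyloTree(G.index, full, splits, validate=False)


def _min_rf_extension(S: PhyloTree, G: PhyloTree, allow_nodes: bool) -> int:
    shared = S.taxa_mask & G.taxa_mask
    if shared.bit_count() < 3:
        raise ValueError("fewer than 3 shared taxa")
    Gr = G if (G.taxa_mask & ~shared) == 0 else restrict_tree(G, shared)
    S_mod = modify_supertree(S, Gr.taxa_mask)
    missing = [1 << i for i in _bits(S_mod.taxa_mask & ~Gr.taxa_mask)]
    target = S_mod.inner_splits
    best = None
    for splits in _extension_stream(Gr, missing, allow_nodes=allow_nodes):
        d = len(splits ^ target)
        if best is None or d < best:
            best = d
            if best == 0:
                break
    return best


def d_plus_oracle(S: PhyloTree, G: PhyloTree) -> int:
    """Minimum RF over all bifurcating edge-only extensions of G."""
    if not G.is_bifurcating:
        raise ValueError("input tree must be bifurcating")
    return _min_rf_extension(S, G, allow_nodes=False)


def d_plus_g_oracle(S: PhyloTree, G: PhyloTree) -> int:
    """Minimum RF over all edge-or-node extensions of G."""
    if not G.is_bifurcating:
        raise ValueError("input tree must be bifurcating")
    return _min_rf_extension(S, G, allow_nodes=True)


# ---------------------------------------------------------------------------
# Constructive witness (good / bad taxa)
# ---------------------------------------------------------------------------


@dataclass
class WitnessExtension:
    """An explicit extension of G achieving an RF distance of at most B + C.

    Good taxa are placed onto edges at zero cost (their position is pinned
    by a supertree split restricting to an existing edge plus that taxon);
    bad taxa are placed onto nodes, each costing one split.
    """

    extended_tree: PhyloTree
    n_good: int
    n_bad: int
    good_taxa: tuple
    bad_taxa: tuple
    achieved_rf: int


def construct_witness(S_mod: PhyloTree, G: PhyloTree) -> WitnessExtension:
    """Place the taxa missing from G following the good/bad-taxon scheme."""
    shared = S_mod.taxa_mask & G.taxa_mask
    Gr = G if (G.taxa_mask & ~shared) == 0 else restrict_tree(G, shared)
    u = Gr.taxa_mask
    splits = frozenset(Gr.inner_splits)
    missing = [1 << i for i in _bits(S_mod.taxa_mask & ~u)]
    good: List[int] = []
    bad: List[int] = []

    # good taxa: subdividing an edge of G* with x creates two split pieces;
    # x is good on that edge iff both pieces are realized by (restrictions
    # of) supertree splits, so the placement costs nothing.  Iterate to a
    # fixpoint since placements enable further placements.
    progress = True
    while progress and missing:
        progress = False
        for x in list(missing):
            nu = u | x
            n_nu = nu.bit_count()
            realized = set()
            for s in S_mod.inner_splits:
                rs = s & nu
                if 2 <= rs.bit_count() <= n_nu - 2:
                    realized.add(_canon(rs, nu))
            for edge in _edge_masks(splits, u):
                other = u ^ edge
                p1 = _canon(edge | x, nu) if other.bit_count() >= 2 else None
                p2 = _canon(edge, nu) if edge.bit_count() >= 2 else None
                ok1 = p1 is None or p1 in realized
                ok2 = p2 is None or p2 in realized
                pinned = (p1 is not None and p1 in realized) or (
                    p2 is not None and p2 in realized
                )
                if ok1 and ok2 and pinned:
                    splits = _attach_on_edge(splits, u, edge, x)
                    u = nu
                    good.append(x)
                    missing.remove(x)
                    progress = True
                    break
            if progress:
                break

    # bad taxa: placed onto a node adjacent to a conflicting split, choosing
    # the candidate that keeps the running RF to the pruned supertree lowest
    for x in sorted(missing):
        conflicting = [
            g
            for g in splits
            if any(
                not _compatible_masks(g, u, s, S_mod.taxa_mask)
                for s in S_mod.inner_splits
            )
        ]
        nodes = _node_keys(splits, u)
        if conflicting:
            adjacent = [
                nd
                for nd in nodes
                if any(d in (g, u ^ g) for g in conflicting for d in nd)
            ]
            if adjacent:
                nodes = adjacent
        best = None
        new_u = u | x
        target = restrict_tree(S_mod, new_u & S_mod.taxa_mask).inner_splits
        for nd in nodes:
            cand = _attach_at_node(splits, u, nd, x)
            d = len(cand ^ target)
            if best is None or d < best[0]:
                best = (d, cand)
        splits = best[1]
        u = new_u
        bad.append(x)

    tree = PhyloTree(S_mod.index, u, splits, validate=False)
    achieved = len(splits ^ S_mod.inner_splits)
    return WitnessExtension(
        extended_tree=tree,
        n_good=len(good),
        n_bad=len(bad),
        good_taxa=S_mod.index.labels_of(sum(good)) if good else (),
        bad_taxa=S_mod.index.labels_of(sum(bad)) if bad else (),
        achieved_rf=achieved,
    )


# ---------------------------------------------------------------------------
# Exhaustive supertree search
# ---------------------------------------------------------------------------


def exhaustive_supertree(
    inputs: Sequence[PhyloTree], method: Method, max_taxa: int = MAX_EXHAUSTIVE_TAXA
) -> Tuple[int, List[PhyloTree]]:
    """Exact minimum score and all optimal bifurcating supertrees.

    Enumerates every bifurcating tree on the taxon union (guarded to at
    most `max_taxa` taxa).
    """
    if not inputs:
        raise ValueError("no input trees")
    index = inputs[0].index
    union = 0
    for G in inputs:
        if G.index.names != index.names:
            raise ValueError("all input trees must share one taxon index")
        union |= G.taxa_mask
    if union.bit_count() > max_taxa:
        raise ValueError("taxon union too large for exhaustive enumeration")
    best = None
    optima: List[PhyloTree] = []
    for tree in enumerate_bifurcating_trees(index, union):
        score = total_score(tree, inputs, method)
        if best is None or score < best:
            best = score
            optima = [tree]
        elif score == best:
            optima.append(tree)
    return best, optima
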