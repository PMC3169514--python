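"""Heuristic minimization over bifurcating supertrees.

Two-stage search: an *exploration* stage alternating taxa-deletion-
reinsertion (TDR) restarts with NNI hill climbing, followed by a
*broadening* stage that NNI-explores every best-scoring tree found so that
the whole optimal neighborhood is collected.  All randomness flows through
one seeded RNG, so results are reproducible.

Incremental scoring: for MR(-) the per-input conflict counts are maintained
as hit counters and updated per NNI move; MR(+)/MR(+)g fall back to full
rescoring (their dummy-taxon modification depends on the whole topology).
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .splits import (
    PhyloTree,
    Split,
    TaxonIndex,
    _attach_on_edge,
    _bits,
    _canon,
    _compatible_masks,
    _edge_masks,
    _side_children,
    restrict_tree,
)
from .scoring import Method, distance, total_score

__all__ = [
    "SearchConfig",
    "SearchResult",
    "stepwise_addition_tree",
    "random_bifurcating_tree",
    "nni_variants",
    "nni_sweep",
    "tdr_step",
    "run_search",
]


@dataclass
class SearchConfig:
    method: Method = Method.MINUS
    tdr_fraction: float = 0.25
    max_iterations: Optional[int] = None  # default: l^2, l = n - 3
    discard_limit: Optional[int] = None  # default: l
    seed: Optional[int] = None
    starting_tree: Optional[PhyloTree] = None
    max_optimal_trees: int = 100_000

    def __post_init__(self):
        if not 0.0 < self.tdr_fraction < 1.0:
            raise ValueError("tdr_fraction must be in (0, 1)")
        if self.max_iterations is not None and self.max_iterations <= 0:
            raise ValueError("max_iterations must be positive")
        if self.discard_limit is not None and self.discard_limit <= 0:
            raise ValueError("discard_limit must be positive")


@dataclass
class SearchResult:
    best_score: int
    optimal_trees: Tuple[PhyloTree, ...]
    iterations_used: int
    stage_log: List[dict] = field(default_factory=list)
    starting_tree: Optional[PhyloTree] = None


# ---------------------------------------------------------------------------
# Scoring contexts
# ---------------------------------------------------------------------------


class _MinusScorer:
    """MR(-) score over raw split sets, with O(#inputs) NNI move deltas.

    For every supertree split s and input tree i a *conflict bitmask* is
    cached: bit j is set iff input split j is incompatible with s.  The
    score is then 2 * popcount(OR of the masks) per input, and an NNI move
    delta reduces to a handful of integer operations against two running
    masks (input splits hit exactly once / not hit at all).
    """

    def __init__(self, inputs: Sequence[PhyloTree], taxa_mask: int):
        self.items = []  # (g_universe, g_masks tuple, conflict cache)
        self.const = 0
        for G in inputs:
            shared = G.taxa_mask & taxa_mask
            if shared.bit_count() < 3:
                continue
            Gr = G if (G.taxa_mask & ~shared) == 0 else restrict_tree(G, shared)
            self.items.append((Gr.taxa_mask, tuple(sorted(Gr.inner_splits)), {}))
            self.const += Gr.multifurcation_count
        self.taxa_mask = taxa_mask
        self._conf_all_cache: dict = {}

    def _conf(self, item, s: int) -> int:
        """Bitmask over the input's splits that are incompatible with s."""
        gu, gms, cache = item
        bm = cache.get(s)
        if bm is None:
            a = s & gu
            b = (self.taxa_mask ^ s) & gu
            bm = 0
            if a and b:
                bit = 1
                for g in gms:
                    g2 = gu ^ g
                    if (a & g) and (a & g2) and (b & g) and (b & g2):
                        bm |= bit
                    bit <<= 1
            cache[s] = bm
        return bm

    def score(self, splits) -> int:
        total = self.const
        for item in self.items:
            acc = 0
            for s in splits:
                acc |= self._conf(item, s)
            total += 2 * acc.bit_count()
        return total

    # state per input: [hit counts per input split, zero-hit mask, one-hit mask]
    def make_state(self, splits):
        state = []
        for item in self.items:
            counts = [0] * len(item[1])
            for s in splits:
                bm = self._conf(item, s)
                while bm:
                    lb = bm & -bm
                    counts[lb.bit_length() - 1] += 1
                    bm ^= lb
            zero = 0
            ones = 0
            for j, c in enumerate(counts):
                if c == 0:
                    zero |= 1 << j
                elif c == 1:
                    ones |= 1 << j
            state.append([counts, zero, ones])
        return state

    def _conf_all(self, s: int) -> tuple:
        got = self._conf_all_cache.get(s)
        if got is None:
            got = tuple(self._conf(item, s) for item in self.items)
            self._conf_all_cache[s] = got
        return got

    def move_delta(self, state, splits, s_old: int, s_new: int) -> int:
        to = self._conf_all(s_old)
        tn = self._conf_all(s_new)
        if to == tn:
            return 0
        d = 0
        for bo, bn, st in zip(to, tn, state):
            if bo == bn:
                continue
            d -= 2 * ((bo & ~bn) & st[2]).bit_count()
            d += 2 * ((bn & ~bo) & st[1]).bit_count()
        return d

    def apply_move(self, state, s_old: int, s_new: int) -> None:
        for item, st in zip(self.items, state):
            bo = self._conf(item, s_old)
            bn = self._conf(item, s_new)
            counts, zero, ones = st
            removed = bo & ~bn
            while removed:
                lb = removed & -removed
                removed ^= lb
                j = lb.bit_length() - 1
                counts[j] -= 1
                if counts[j] == 0:
                    ones &= ~lb
                    zero |= lb
                elif counts[j] == 1:
                    ones |= lb
            added = bn & ~bo
            while added:
                lb = added & -added
                added ^= lb
                j = lb.bit_length() - 1
                counts[j] += 1
                if counts[j] == 1:
                    zero &= ~lb
                    ones |= lb
                elif counts[j] == 2:
                    ones &= ~lb
            st[1] = zero
            st[2] = ones


class _FullScorer:
    """Fallback scorer: full recomputation (MR(+) and MR(+)g)."""

    def __init__(
        self,
        inputs: Sequence[PhyloTree],
        taxa_mask: int,
        method: Method,
        index: TaxonIndex,
    ):
        self.inputs = [G for G in inputs if (G.taxa_mask & taxa_mask).bit_count() >= 3]
        self.method = method
        self.index = index
        self.taxa_mask = taxa_mask

    def score(self, splits) -> int:
        tree = PhyloTree(self.index, self.taxa_mask, splits, validate=False)
        return sum(distance(tree, G, self.method) for G in self.inputs)

    def make_state(self, splits):
        return None

    def move_delta(self, state, splits, s_old: int, s_new: int) -> int:
        cand = set(splits)
        cand.discard(s_old)
        cand.add(s_new)
        return self.score(cand) - self.score(splits)

    def apply_move(self, state, s_old: int, s_new: int) -> None:
        pass


def _make_scorer(inputs, taxa_mask, method, index):
    if method is Method.MINUS:
        return _MinusScorer(inputs, taxa_mask)
    return _FullScorer(inputs, taxa_mask, method, index)


# ---------------------------------------------------------------------------
# NNI moves
# ---------------------------------------------------------------------------


def _nni_alternatives(splits, taxa_mask: int, s: int) -> Tuple[int, int]:
    """The two splits that can replace inner split `s` (bifurcating tree)."""
    bx = _side_children(splits, taxa_mask, s)
    by = _side_children(splits, taxa_mask, taxa_mask ^ s)
    if len(bx) != 2 or len(by) != 2:
        raise ValueError("NNI requires an inner split of a bifurcating tree")
    x1, x2 = bx
    y1, y2 = by
    return _canon(x1 | y1, taxa_mask), _canon(x1 | y2, taxa_mask)


def _nni_alt_map(splits, u: int) -> Dict[int, Tuple[int, int]]:
    """All NNI alternatives of a bifurcating tree in one pass.

    Builds the laminar forest of clades (sides not containing the lowest
    taxon) once, then reads off the two alternative splits for every edge.
    Equivalent to calling :func:`_nni_alternatives` per split, but far
    cheaper when a whole tree's neighborhood is scanned.
    """
    low = u & -u
    clades = sorted(
        ((m ^ u) if m & low else m for m in splits), key=int.bit_count
    )
    parent: Dict[int, int] = {}
    children: Dict[int, list] = {c: [] for c in clades}
    top = []
    for i, c in enumerate(clades):
        for d in clades[i + 1 :]:
            if (c & ~d) == 0:
                parent[c] = d
                children[d].append(c)
                break
        else:
            top.append(c)

    def blocks_below(c: int) -> list:
        out = list(children[c])
        covered = 0
        for b in out:
            covered |= b
        rest = c & ~covered
        while rest:
            lb = rest & -rest
            out.append(lb)
            rest ^= lb
        return out

    covered = 0
    for c in top:
        covered |= c
    topblocks = list(top)
    rest = (u ^ low) & ~covered
    while rest:
        lb = rest & -rest
        topblocks.append(lb)
        rest ^= lb
    topblocks.append(low)

    alt: Dict[int, Tuple[int, int]] = {}
    for c in clades:
        bc = blocks_below(c)
        if len(bc) != 2:
            raise ValueError("NNI map requires a bifurcating tree")
        x1 = bc[0]
        p = parent.get(c)
        if p is None:
            ys = [b for b in topblocks if b != c]
        else:
            sibs = [b for b in blocks_below(p) if b != c]
            ys = [sibs[0], u ^ p]
        if len(ys) != 2:
            raise ValueError("NNI map requires a bifurcating tree")
        key = c if c & low else u ^ c
        alt[key] = (_canon(x1 | ys[0], u), _canon(x1 | ys[1], u))
    return alt


def nni_variants(t: PhyloTree, s: Split) -> Tuple[PhyloTree, PhyloTree]:
    """The two trees obtained by replacing inner split `s` across its edge."""
    if not t.is_bifurcating:
        raise ValueError("NNI is defined on bifurcating trees")
    m = _canon(s.mask if isinstance(s, Split) else s, t.taxa_mask)
    if m not in t.inner_splits:
        raise ValueError("split is not an inner split of the tree")
    a, b = _nni_alternatives(t.inner_splits, t.taxa_mask, m)
    out = []
    for alt in (a, b):
        new = set(t.inner_splits)
        new.remove(m)
        new.add(alt)
        out.append(PhyloTree(t.index, t.taxa_mask, new, validate=False))
    return tuple(out)


class _Budget:
    """Iteration counter shared across the search (NNI moves + TDR ops)."""

    def __init__(self, limit: int):
        self.limit = limit
        self.used = 0

    def spend(self, k: int = 1) -> None:
        self.used += k

    @property
    def exhausted(self) -> bool:
        return self.used >= self.limit


def _sweep(splits, taxa_mask, scorer, rng, budget: Optional[_Budget] = None):
    """NNI hill climbing until no replacement improves the score.

    Returns (final_splits, final_score, ties, n_moves) where `ties` are the
    equal-scoring neighbors encountered while the score already equaled the
    final score.
    """
    cur: Set[int] = set(splits)
    score = scorer.score(cur)
    state = scorer.make_state(cur)
    ties: Dict[int, Set[frozenset]] = {}
    n_moves = 0
    improved = True
    while improved:
        improved = False
        order = sorted(cur)
        rng.shuffle(order)
        alt_map = _nni_alt_map(cur, taxa_mask)
        for s in order:
            if s not in cur:
                continue
            alts = alt_map[s]
            for s_new in alts:
                if s_new in cur or s_new == s:
                    continue
                d = scorer.move_delta(state, cur, s, s_new)
                if d < 0:
                    scorer.apply_move(state, s, s_new)
                    cur.remove(s)
                    cur.add(s_new)
                    score += d
                    n_moves += 1
                    improved = True
                    if budget is not None:
                        budget.spend()
                    break
                if d == 0:
                    tie = frozenset((cur - {s}) | {s_new})
                    ties.setdefault(score, set()).add(tie)
            if improved:
                break
        if budget is not None and budget.exhausted:
            break
    return frozenset(cur), score, ties.get(score, set()), n_moves


def nni_sweep(t: PhyloTree, inputs: Sequence[PhyloTree], method: Method,
              rng: Optional[random.Random] = None) -> Set[PhyloTree]:
    """Optimize all splits of `t` by NNI; return the set of trees at the
    final score (the optimum reached plus equal-scoring alternatives)."""
    if rng is None:
        rng = random.Random(0)
    scorer = _make_scorer(inputs, t.taxa_mask, method, t.index)
    final, score, ties, _ = _sweep(t.inner_splits, t.taxa_mask, scorer, rng)
    out = {PhyloTree(t.index, t.taxa_mask, final, validate=False)}
    for f in ties:
        out.add(PhyloTree(t.index, t.taxa_mask, f, validate=False))
    return out


# ---------------------------------------------------------------------------
# Step-wise addition / insertion machinery
# ---------------------------------------------------------------------------


class _Inserter:
    """Evaluates taxon insertion points against the informative input trees.

    d- strategy: candidates are compared via the summed prune-and-RF
    distance on the taxa placed so far.  Each candidate edge is mapped to
    its insertion position in the input-restricted tree (several edges
    collapse onto one position), and each distinct position is scored once
    as a split-set symmetric difference.  d+ strategy: candidates are
    compared by the total number of input trees each supertree split
    contradicts.
    """

    def __init__(self, inputs: Sequence[PhyloTree], rng: random.Random):
        self.inputs = inputs
        self.rng = rng
        self._g_cache: List[dict] = [dict() for _ in inputs]

    def _restricted_input(self, i: int, shared: int) -> frozenset:
        cache = self._g_cache[i]
        got = cache.get(shared)
        if got is None:
            G = self.inputs[i]
            n = shared.bit_count()
            gms = set()
            for m in G.inner_splits:
                mm = m & shared
                if 2 <= mm.bit_count() <= n - 2:
                    gms.add(_canon(mm, shared))
            got = frozenset(gms)
            cache[shared] = got
        return got

    def informative(self, u: int, x_bit: int) -> List[int]:
        out = []
        for i, G in enumerate(self.inputs):
            if G.taxa_mask & x_bit and (G.taxa_mask & u).bit_count() >= 3:
                out.append(i)
        return out

    @staticmethod
    def _region_pos(splits, u: int, sh: int, empty_side: int, cache: dict) -> int:
        """Restricted insertion position for an edge inside a region that
        carries none of the input's taxa.

        The whole region collapses onto one point of the restricted tree: a
        suppressed degree-2 node sitting in the middle of the edge that
        separates the two shared-taxa subtrees flanking the region.
        """
        low = empty_side & -empty_side
        pos = cache.get(low)
        if pos is None:
            # the maximal input-taxon-free side through this edge
            block = empty_side
            bc = block.bit_count()
            for s in splits:
                for side in (s, u ^ s):
                    if side & low and (side & sh) == 0:
                        c = side.bit_count()
                        if c > bc:
                            block, bc = side, c
            # one subtree flanking the region = a maximal side inside the
            # block's complement (falls back to a leaf for tiny complements)
            far = u ^ block
            child, cc = None, 1
            for s in splits:
                for side in (s, u ^ s):
                    if side != far and (side & ~far) == 0:
                        c = side.bit_count()
                        if c > cc:
                            child, cc = side, c
            if child is None:
                child = far & -far
            pos = _canon(child & sh, sh)
            for i in _bits(block):
                cache[1 << i] = pos
        return pos

    def insert(self, splits: frozenset, u: int, x_bit: int, strategy: Method):
        """Insert taxon x at the best point; ties resolved uniformly."""
        candidates = _edge_masks(splits, u)
        info = self.informative(u, x_bit)
        nu = u | x_bit
        if strategy is Method.PLUS:
            best_val = None
            best: List[int] = []
            for edge in candidates:
                cand = _attach_on_edge(splits, u, edge, x_bit)
                val = self._plus_value(cand, nu, info)
                if best_val is None or val < best_val:
                    best_val, best = val, [edge]
                elif val == best_val:
                    best.append(edge)
            pick = best[0] if len(best) == 1 else self.rng.choice(best)
            return _attach_on_edge(splits, u, pick, x_bit), nu

        # d- strategy
        per_input = []
        for i in info:
            G = self.inputs[i]
            sh = G.taxa_mask & u
            g_set = self._restricted_input(i, sh | x_bit)
            n_sh = sh.bit_count()
            base_r = set()
            for m in splits:
                mm = m & sh
                if 2 <= mm.bit_count() <= n_sh - 2:
                    base_r.add(_canon(mm, sh))
            per_input.append((sh, frozenset(base_r), g_set, {}, {}))

        best_val = None
        best = []
        for edge in candidates:
            total = 0
            for sh, base_r, g_set, posval, regions in per_input:
                a1 = edge & sh
                a2 = (u ^ edge) & sh
                if a1 and a2:
                    pos = _canon(a1, sh)
                else:
                    pos = self._region_pos(
                        splits, u, sh, edge if a1 == 0 else u ^ edge, regions
                    )
                v = posval.get(pos)
                if v is None:
                    cand_r = _attach_on_edge(base_r, sh, pos, x_bit)
                    v = len(cand_r ^ g_set)
                    posval[pos] = v
                total += v
            if best_val is None or total < best_val:
                best_val, best = total, [edge]
            elif total == best_val:
                best.append(edge)
        pick = best[0] if len(best) == 1 else self.rng.choice(best)
        return _attach_on_edge(splits, u, pick, x_bit), nu

    def _plus_value(self, cand: frozenset, nu: int, info: List[int]) -> int:
        total = 0
        for s in cand:
            for i in info:
                G = self.inputs[i]
                gu = G.taxa_mask
                for g in G.inner_splits:
                    if not _compatible_masks(g, gu, s, nu):
                        total += 1
                        break
        return total


def _strategy_cycle(method: Method):
    """Insertion strategy per step: d- or d+; MR(+)g alternates the two."""
    if method is Method.PLUS:
        while True:
            yield Method.PLUS
    elif method is Method.MINUS:
        while True:
            yield Method.MINUS
    else:
        while True:
            yield Method.MINUS
            yield Method.PLUS


def random_bifurcating_tree(
    index: TaxonIndex, taxa, rng: random.Random
) -> PhyloTree:
    """Uniformly random sequential-addition bifurcating tree (not uniform
    over topologies; used as a search fallback and for tests)."""
    taxa_mask = index.mask_of(taxa)
    bits = [1 << i for i in _bits(taxa_mask)]
    if len(bits) < 3:
        raise ValueError("need at least 3 taxa")
    rng.shuffle(bits)
    u = bits[0] | bits[1] | bits[2]
    splits: frozenset = frozenset()
    for x in bits[3:]:
        edge = rng.choice(_edge_masks(splits, u))
        splits = _attach_on_edge(splits, u, edge, x)
        u |= x
    return PhyloTree(index, taxa_mask, splits, validate=False)


def _quartet_votes(inputs, quartet_mask: int):
    votes: Dict[int, int] = {}
    for G in inputs:
        if quartet_mask & ~G.taxa_mask:
            continue
        n = 4
        for m in G.inner_splits:
            mm = m & quartet_mask
            if mm.bit_count() == 2:
                votes[_canon(mm, quartet_mask)] = votes.get(_canon(mm, quartet_mask), 0) + 1
                break
    return votes


def stepwise_addition_tree(
    inputs: Sequence[PhyloTree],
    method: Method,
    rng: random.Random,
    inserter: Optional[_Inserter] = None,
    taxa_mask: Optional[int] = None,
) -> PhyloTree:
    """Step-wise addition starting tree over a random taxon order.

    The first four taxa are joined with the quartet topology most frequent
    among the input trees (advancing through the order if the leading
    quartet is uninformative); each remaining taxon is inserted at the point
    minimizing the method's criterion over the informative input trees.
    Ties are resolved uniformly at random.
    """
    index = inputs[0].index
    if taxa_mask is None:
        taxa_mask = 0
        for G in inputs:
            taxa_mask |= G.taxa_mask
    if taxa_mask.bit_count() < 4:
        raise ValueError("need at least 4 taxa in the union")
    if inserter is None:
        inserter = _Inserter(list(inputs), rng)

    order = [1 << i for i in _bits(taxa_mask)]
    rng.shuffle(order)

    # seed quartet: slide a window along the order until informative
    seed = None
    for start in range(len(order) - 3):
        qbits = order[start : start + 4]
        qmask = qbits[0] | qbits[1] | qbits[2] | qbits[3]
        votes = _quartet_votes(inputs, qmask)
        if votes:
            top = max(votes.values())
            choices = sorted(m for m, v in votes.items() if v == top)
            pick = choices[0] if len(choices) == 1 else rng.choice(choices)
            seed = (qmask, frozenset([pick]))
            placed = qbits
            break
    if seed is None:
        return random_bifurcating_tree(index, taxa_mask, rng)

    u, splits = seed[0], seed[1]
    remaining = [b for b in order if not b & u]
    strat = _strategy_cycle(method)
    for x in remaining:
        splits, u = inserter.insert(splits, u, x, next(strat))
    return PhyloTree(index, taxa_mask, splits, validate=False)


def tdr_step(
    t: PhyloTree,
    fraction: float,
    inputs: Sequence[PhyloTree],
    method: Method,
    rng: random.Random,
    inserter: Optional[_Inserter] = None,
) -> PhyloTree:
    """Taxa-deletion-reinsertion: delete ceil(fraction*n) random taxa and
    reinsert them in random order by step-wise addition."""
    if inserter is None:
        inserter = _Inserter(list(inputs), rng)
    u = t.taxa_mask
    n = u.bit_count()
    k = math.ceil(fraction * n)
    if n - k < 4:
        k = n - 4
    if k <= 0:
        return t
    bits = [1 << i for i in _bits(u)]
    deleted = rng.sample(bits, k)
    keep = u
    for b in deleted:
        keep ^= b
    base = restrict_tree(t, keep)
    splits, cu = frozenset(base.inner_splits), keep
    rng.shuffle(deleted)
    strat = _strategy_cycle(method)
    for x in deleted:
        splits, cu = inserter.insert(splits, cu, x, next(strat))
    return PhyloTree(t.index, u, splits, validate=False)


# ---------------------------------------------------------------------------
# The two-stage search
# ---------------------------------------------------------------------------


def run_search(inputs: Sequence[PhyloTree], config: SearchConfig) -> SearchResult:
    """Minimize the supertree score; return all best trees found.

    Stage 1 (exploration): NNI-optimize the starting tree, then alternate
    TDR restarts with NNI optimization; a TDR product that was seen before
    or that NNI cannot improve counts as a discard.  After `discard_limit`
    consecutive discards or l^2 iterations, stage 2 (broadening) NNI-explores
    every best tree not yet analyzed so the optimal region is exhausted.
    """
    if not inputs:
        raise ValueError("no input trees")
    index = inputs[0].index
    for G in inputs:
        if G.index.names != index.names:
            raise ValueError("all input trees must share one taxon index")
    taxa_mask = 0
    for G in inputs:
        taxa_mask |= G.taxa_mask
    n = taxa_mask.bit_count()
    l = n - 3
    rng = random.Random(config.seed)
    max_iter = config.max_iterations if config.max_iterations is not None else l * l
    discard_limit = (
        config.discard_limit if config.discard_limit is not None else max(1, l)
    )
    budget = _Budget(max_iter)
    log: List[dict] = []

    if config.method is not Method.MINUS:
        for G in inputs:
            if not G.is_bifurcating:
                raise ValueError(
                    "MR(+)/MR(+)g accept only bifurcating input trees"
                )

    inserter = _Inserter(list(inputs), rng)
    if config.starting_tree is not None:
        start = config.starting_tree
        if start.taxa_mask != taxa_mask or start.index.names != index.names:
            raise ValueError("starting tree must span the taxon union")
        if not start.is_bifurcating:
            raise ValueError("starting tree must be bifurcating")
    elif n >= 4:
        start = stepwise_addition_tree(
            inputs, config.method, rng, inserter=inserter, taxa_mask=taxa_mask
        )
    else:
        raise ValueError("need at least 4 taxa")

    scorer = _make_scorer(inputs, taxa_mask, config.method, index)

    best_trees: Set[frozenset] = set()
    seen: Set[frozenset] = {frozenset(start.inner_splits)}
    analyzed: Set[frozenset] = set()
    capped = False

    final, best_score, ties, _ = _sweep(
        start.inner_splits, taxa_mask, scorer, rng, budget
    )
    best_trees.add(final)
    best_trees.update(ties)
    seen.add(final)
    analyzed.add(final)
    current = final
    log.append(
        {"stage": "exploration", "event": "start", "iteration": budget.used,
         "score": best_score, "n_best": len(best_trees)}
    )

    def merge(score: int, trees) -> None:
        nonlocal best_score, best_trees, capped
        if score < best_score:
            best_score = score
            best_trees = set()
            analyzed.clear()
            capped = False
        if score == best_score:
            for f in trees:
                if len(best_trees) >= config.max_optimal_trees:
                    if not capped:
                        warnings.warn(
                            "equal-score tree limit reached; result truncated",
                            stacklevel=2,
                        )
                        capped = True
                    break
                best_trees.add(f)

    # ---- stage 1: exploration --------------------------------------------
    discards = 0
    while not budget.exhausted and discards < discard_limit:
        cand = tdr_step(
            PhyloTree(index, taxa_mask, current, validate=False),
            config.tdr_fraction,
            inputs,
            config.method,
            rng,
            inserter=inserter,
        )
        budget.spend()
        key = frozenset(cand.inner_splits)
        if key in seen:
            discards += 1
            continue
        seen.add(key)
        f2, s2, t2, moves = _sweep(key, taxa_mask, scorer, rng, budget)
        seen.add(f2)
        merge(s2, [f2] + list(t2))
        if moves == 0:
            discards += 1
        else:
            discards = 0
            analyzed.add(f2)
        if s2 <= best_score:
            current = f2
        log.append(
            {"stage": "exploration", "event": "tdr", "iteration": budget.used,
             "score": best_score, "n_best": len(best_trees), "discards": discards}
        )

    # ---- stage 2: broadening ---------------------------------------------
    queue = sorted(best_trees - analyzed)
    while queue:
        key = queue.pop()
        if key in analyzed or key not in best_trees:
            continue
        analyzed.add(key)
        cur = set(key)
        state = scorer.make_state(cur)
        alt_map = _nni_alt_map(cur, taxa_mask)
        found_better = False
        for s in sorted(cur):
            for s_new in alt_map[s]:
                if s_new in cur:
                    continue
                d = scorer.move_delta(state, cur, s, s_new)
                if d < 0:
                    neigh = frozenset((cur - {s}) | {s_new})
                    f2, s2, t2, _ = _sweep(neigh, taxa_mask, scorer, rng)
                    merge(s2, [f2] + list(t2))
                    found_better = True
                    break
                if d == 0 and not capped:
                    neigh = frozenset((cur - {s}) | {s_new})
                    if neigh not in best_trees:
                        merge(best_score, [neigh])
                        if neigh in best_trees:
                            queue.append(neigh)
            if found_better:
                break
        if found_better:
            # the score dropped: start over from the new best set
            queue = sorted(best_trees - analyzed)
    log.append(
        {"stage": "broadening", "event": "done", "iteration": budget.used,
         "score": best_score, "n_best": len(best_trees)}
    )

    # independent re-verification of every returned tree: prune-and-RF per
    # input (the definition of the distance, no cached deltas), plus full
    # total_score recomputation on a bounded sample
    ver = []
    for G in inputs:
        sh = G.taxa_mask & taxa_mask
        if sh.bit_count() < 3:
            continue
        Gr = G if (G.taxa_mask & ~sh) == 0 else restrict_tree(G, sh)
        ver.append((sh, frozenset(Gr.inner_splits), Gr.multifurcation_count))
    out = []
    keys = sorted(best_trees)
    for key in keys:
        tree = PhyloTree(index, taxa_mask, key, validate=False)
        if config.method is Method.MINUS:
            check = 0
            for sh, g_set, m_const in ver:
                n_sh = sh.bit_count()
                rs = set()
                for mm in key:
                    r = mm & sh
                    if 2 <= r.bit_count() <= n_sh - 2:
                        rs.add(_canon(r, sh))
                # symmetric difference of the restricted split sets equals
                # 2C + m: absent splits of a bifurcating restriction are
                # necessarily incompatible
                check += len(rs ^ g_set)
        else:
            check = total_score(tree, inputs, config.method)
        if check != best_score:
            raise AssertionError(
                "returned tree re-scores to %d, expected %d" % (check, best_score)
            )
        out.append(tree)
    sample = keys if len(keys) <= 50 else [
        keys[i * (len(keys) - 1) // 49] for i in range(50)
    ]
    for key in sample:
        tree = PhyloTree(index, taxa_mask, key, validate=False)
        if total_score(tree, inputs, config.method) != best_score:
            raise AssertionError("total_score verification failed")
    return SearchResult(
        best_score=best_score,
        optimal_trees=tuple(out),
        iterations_used=budget.used,
        stage_log=log,
        starting_tree=start,
    )
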