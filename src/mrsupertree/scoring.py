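"""Closed-form majority-rule supertree distances via the relationship matrix.

For a bifurcating supertree S and input tree G, after collapsing supertree
subtrees that contain no input taxa into dummy taxa:

* d-  = 2C (+ m for an input tree with m multifurcations),
* d+g = B + C,
* d+  = 2B,

where C counts input-tree splits incompatible with at least one supertree
split and B counts supertree splits incompatible with at least one
input-tree split.  d- equals the RF distance between the pruned supertree
and the input tree; d+ / d+g equal the minimum RF distance over all
edge-only / edge-or-node extensions of the input tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import List, Optional, Sequence, Tuple

from .splits import (
    PhyloTree,
    Split,
    TaxaLike,
    _bits,
    _canon,
    _compatible_masks,
    _is_subsplit_masks,
    restrict_tree,
)

__all__ = [
    "Method",
    "SUBSPLIT",
    "COMPATIBLE",
    "INCOMPATIBLE",
    "RelationshipMatrix",
    "modify_supertree",
    "build_relationship_matrix",
    "conflict_counts",
    "d_minus",
    "d_plus_g",
    "d_plus",
    "distance",
    "total_score",
    "DUMMY_PREFIX",
]


class Method(Enum):
    """The three majority-rule supertree scoring variants."""

    MINUS = "minus"
    PLUS = "plus"
    PLUS_G = "plusg"

    @classmethod
    def from_string(cls, s: str) -> "Method":
        key = s.strip().lower().replace("(", "").replace(")", "").replace("-", "")
        table = {
            "minus": cls.MINUS,
            "mr": cls.MINUS,
            "mrminus": cls.MINUS,
            "plus": cls.PLUS,
            "mrplus": cls.PLUS,
            "plusg": cls.PLUS_G,
            "mrplusg": cls.PLUS_G,
            "g": cls.PLUS_G,
        }
        try:
            return table[key]
        except KeyError:
            raise ValueError("unknown method %r" % s)


SUBSPLIT = "s"
COMPATIBLE = "c"
INCOMPATIBLE = "i"

# reserved label prefix for generated dummy taxa; never emitted in results
DUMMY_PREFIX = "@dummy"


@dataclass
class RelationshipMatrix:
    """Input-split x supertree-split grid of {s, c, i} entries.

    ``c_vector[i]`` is 1 iff row i contains an incompatibility, ``b_vector[j]``
    likewise for column j; C and B are their sums.  Trivial splits can never
    be incompatible, so including them (for subsplit bookkeeping) does not
    change C or B.
    """

    rows: List[Split]
    cols: List[Split]
    entries: List[List[str]] = field(repr=False)

    @property
    def c_vector(self) -> List[int]:
        return [1 if INCOMPATIBLE in row else 0 for row in self.entries]

    @property
    def b_vector(self) -> List[int]:
        return [
            1 if any(row[j] == INCOMPATIBLE for row in self.entries) else 0
            for j in range(len(self.cols))
        ]

    @property
    def C(self) -> int:
        return sum(self.c_vector)

    @property
    def B(self) -> int:
        return sum(self.b_vector)


def _fresh_dummy_names(index, count: int) -> list:
    names = []
    taken = set(index.names)
    k = 1
    while len(names) < count:
        name = "%s%d" % (DUMMY_PREFIX, k)
        if name not in taken:
            names.append(name)
        k += 1
    return names


def modify_supertree(S: PhyloTree, input_taxa: TaxaLike) -> PhyloTree:
    """Collapse supertree subtrees containing no input taxa into dummy taxa.

    Every maximal subtree of S that hangs off a single edge and whose taxa
    are all absent from `input_taxa` is replaced by one fresh dummy taxon.
    Absent taxa that hang alone off a terminal edge are kept as they are
    (they behave exactly like a dummy).  The result is bifurcating and its
    restriction to `input_taxa` equals the restriction of S.
    """
    if not S.is_bifurcating:
        raise ValueError("supertree must be bifurcating")
    input_mask = S.index.mask_of(input_taxa)
    present = S.taxa_mask & input_mask
    if present.bit_count() < 3:
        raise ValueError("fewer than 3 shared taxa")
    absent = S.taxa_mask & ~input_mask
    if absent == 0:
        return S

    u = S.taxa_mask
    sides = set()
    for m in S.inner_splits:
        for side in (m, u ^ m):
            if side & ~absent == 0:
                sides.add(side)
    for i in _bits(absent):
        sides.add(1 << i)
    blocks = [s for s in sides if not any(t != s and s & ~t == 0 for t in sides)]
    big = sorted(b for b in blocks if b.bit_count() >= 2)
    if not big:
        return S

    dummy_names = _fresh_dummy_names(S.index, len(big))
    new_index = S.index.extended(dummy_names)
    base = len(S.index)
    dummy_bits = [1 << (base + i) for i in range(len(big))]

    removed = 0
    for b in big:
        removed |= b
    new_taxa = (u & ~removed) | sum(dummy_bits)

    new_splits = set()
    n_new = new_taxa.bit_count()
    for m in S.inner_splits:
        mm = m
        comp = u ^ m
        drop = False
        for b, d in zip(big, dummy_bits):
            if (mm & ~b) == 0 or (comp & ~b) == 0:
                # the split's edge lies inside the collapsed subtree
                drop = True
                break
            if b & mm == b:
                mm = (mm & ~b) | d
            elif b & mm:
                raise AssertionError("absent block straddles a split")
        if drop:
            continue
        c = (mm & new_taxa).bit_count()
        if 2 <= c <= n_new - 2:
            new_splits.add(_canon(mm & new_taxa, new_taxa))
    result = PhyloTree(new_index, new_taxa, new_splits, validate=False)
    if not result.is_bifurcating:
        raise AssertionError("modification must preserve bifurcation")
    return result


def build_relationship_matrix(
    G: PhyloTree, S_mod: PhyloTree, include_trivial: bool = False
) -> RelationshipMatrix:
    """Classify every (input split, supertree split) pair as s / c / i.

    Rows are the input tree's inner splits, columns the (modified)
    supertree's inner splits.  With `include_trivial`, terminal splits of the
    input tree and terminal supertree splits of shared taxa are appended;
    these are used only for subsplit bookkeeping in the witness construction.
    """
    if G.taxa_mask & ~S_mod.taxa_mask:
        raise ValueError("input tree has taxa missing from the supertree")
    rows = list(G.splits())
    cols = list(S_mod.splits())
    if include_trivial:
        rows += list(G.terminal_splits())
        shared = G.taxa_mask & S_mod.taxa_mask
        cols += [
            Split(1 << i, S_mod.taxa_mask, S_mod.index) for i in _bits(shared)
        ]
    entries = []
    for g in rows:
        row = []
        for s in cols:
            if _is_subsplit_masks(g.mask, g.universe, s.mask, s.universe):
                row.append(SUBSPLIT)
            elif not _compatible_masks(g.mask, g.universe, s.mask, s.universe):
                row.append(INCOMPATIBLE)
            else:
                row.append(COMPATIBLE)
        entries.append(row)
    return RelationshipMatrix(rows=rows, cols=cols, entries=entries)


def conflict_counts(M: RelationshipMatrix) -> Tuple[int, int]:
    """(C, B): conflicted input splits / conflicted supertree splits."""
    return M.C, M.B


def _count_conflicts(
    g_masks: Sequence[int], g_universe: int, s_masks: Sequence[int], s_universe: int
) -> Tuple[int, int]:
    """C and B over raw split masks (inner splits only)."""
    c = 0
    hit_s = set()
    for g in g_masks:
        conflicted = False
        for s in s_masks:
            if not _compatible_masks(g, g_universe, s, s_universe):
                conflicted = True
                hit_s.add(s)
        if conflicted:
            c += 1
    return c, len(hit_s)


def _shared_or_raise(S: PhyloTree, G: PhyloTree) -> int:
    shared = S.taxa_mask & G.taxa_mask
    if shared.bit_count() < 3:
        raise ValueError("supertree and input tree share fewer than 3 taxa")
    return shared


def d_minus(S: PhyloTree, G: PhyloTree) -> int:
    """MR(-) distance: 2C + m.

    Equals the RF distance between the supertree pruned to the input taxa
    and the input tree.  The input tree may be multifurcating; m is its
    multifurcation count (on the shared taxa).
    """
    if not S.is_bifurcating:
        raise ValueError("supertree must be bifurcating")
    shared = _shared_or_raise(S, G)
    Gr = G if (G.taxa_mask & ~shared) == 0 else restrict_tree(G, shared)
    gu = Gr.taxa_mask
    su = S.taxa_mask
    # pre-restrict the supertree splits; trivial restrictions conflict with
    # nothing and are skipped
    pairs = []
    for s in S.inner_splits:
        a = s & gu
        b = (su ^ s) & gu
        if a and b:
            pairs.append((a, b))
    C = 0
    for g in Gr.inner_splits:
        g2 = gu ^ g
        for a, b in pairs:
            if (a & g) and (a & g2) and (b & g) and (b & g2):
                C += 1
                break
    return 2 * C + Gr.multifurcation_count


def _plus_counts(S: PhyloTree, G: PhyloTree) -> Tuple[int, int]:
    if not S.is_bifurcating:
        raise ValueError("supertree must be bifurcating")
    if not G.is_bifurcating:
        raise ValueError("input tree must be bifurcating for MR(+)/MR(+)g")
    shared = _shared_or_raise(S, G)
    Gr = G if (G.taxa_mask & ~shared) == 0 else restrict_tree(G, shared)
    S_mod = modify_supertree(S, Gr.taxa_mask)
    return _count_conflicts(
        sorted(Gr.inner_splits), Gr.taxa_mask, sorted(S_mod.inner_splits), S_mod.taxa_mask
    )


def d_plus_g(S: PhyloTree, G: PhyloTree) -> int:
    """MR(+)g distance: B + C on the dummy-modified supertree.

    Equals the minimum RF distance over all extensions of G that place the
    missing taxa onto edges or nodes.
    """
    c, b = _plus_counts(S, G)
    return b + c


def d_plus(S: PhyloTree, G: PhyloTree) -> int:
    """MR(+) distance: 2B on the dummy-modified supertree.

    Equals the minimum RF distance over all bifurcating edge-only
    extensions of G.
    """
    _, b = _plus_counts(S, G)
    return 2 * b


def distance(S: PhyloTree, G: PhyloTree, method: Method) -> int:
    if method is Method.MINUS:
        return d_minus(S, G)
    if method is Method.PLUS:
        return d_plus(S, G)
    return d_plus_g(S, G)


def total_score(
    S: PhyloTree,
    inputs: Sequence[PhyloTree],
    method: Method,
    require_span: bool = True,
) -> int:
    """Sum of the per-input-tree distances: the score of a supertree.

    Input trees sharing fewer than 3 taxa with S contribute 0 with a
    warning (no overlap check is enforced).
    """
    total = 0
    for i, G in enumerate(inputs):
        if require_span and G.taxa_mask & ~S.taxa_mask:
            raise ValueError(
                "supertree is missing taxa of input tree %d: %s"
                % (i + 1, ", ".join(G.index.labels_of(G.taxa_mask & ~S.taxa_mask)))
            )
        if (S.taxa_mask & G.taxa_mask).bit_count() < 3:
            warnings.warn(
                "input tree %d shares fewer than 3 taxa with the supertree; "
                "it contributes 0 to the score" % (i + 1),
                stacklevel=2,
            )
            continue
        total += distance(S, G, method)
    return total
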