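"""Bipartition (split) algebra and unrooted tree representation.

Trees are identified purely by their taxon set and their set of non-trivial
splits.  A split is stored as a bitmask over a :class:`TaxonIndex`; the
canonical orientation keeps the side containing the lowest-indexed taxon of
the split's own universe, which makes equality and hashing O(1).

All topology comparisons are unrooted; branch lengths and internal-node
labels are read and discarded.
"""

from __future__ import annotations

import io
import warnings
from typing import Iterable, Mapping, Optional, Sequence, Union

import dendropy

__all__ = [
    "TaxonIndex",
    "Split",
    "PhyloTree",
    "parse_newick",
    "read_trees",
    "write_newick",
    "restrict_split",
    "restrict_tree",
    "are_compatible",
    "is_subsplit",
    "rf_distance",
]


class NewickError(ValueError):
    """Raised for malformed or unusable Newick input."""


TaxaLike = Union[int, Iterable[str]]


class TaxonIndex:
    """A fixed, ordered bijection between taxon labels and bit positions."""

    __slots__ = ("names", "position", "full_mask")

    def __init__(self, names: Sequence[str]):
        names = tuple(names)
        if len(set(names)) != len(names):
            raise ValueError("duplicate taxon labels")
        if any(not n for n in names):
            raise ValueError("empty taxon label")
        self.names = names
        self.position = {name: i for i, name in enumerate(names)}
        self.full_mask = (1 << len(names)) - 1

    def __len__(self) -> int:
        return len(self.names)

    def __eq__(self, other) -> bool:
        return isinstance(other, TaxonIndex) and self.names == other.names

    def __hash__(self) -> int:
        return hash(self.names)

    def mask_of(self, taxa: TaxaLike) -> int:
        """Bitmask for an iterable of labels (an int passes through)."""
        if isinstance(taxa, int):
            return taxa
        mask = 0
        for label in taxa:
            mask |= 1 << self.position[label]
        return mask

    def labels_of(self, mask: int) -> tuple:
        return tuple(self.names[i] for i in _bits(mask))

    def extended(self, extra_names: Sequence[str]) -> "TaxonIndex":
        """New index with `extra_names` appended (existing masks stay valid)."""
        return TaxonIndex(self.names + tuple(extra_names))


def _bits(mask: int):
    """Indices of set bits, ascending."""
    while mask:
        low = mask & -mask
        yield low.bit_length() - 1
        mask ^= low


def _canon(mask: int, universe: int) -> int:
    """Orient `mask` so that it contains the lowest taxon of `universe`."""
    low = universe & -universe
    return mask if mask & low else universe ^ mask


def _compatible_masks(m1: int, u1: int, m2: int, u2: int) -> bool:
    """Split compatibility on (possibly different) universes.

    Splits on different taxon sets are compared after restriction to the
    shared taxa; a vanished or trivial restriction is compatible with
    everything.  Otherwise the four-intersection criterion applies: the
    splits are compatible iff one of X1∩Y1, X1∩Y2, X2∩Y1, X2∩Y2 is empty.
    """
    shared = u1 & u2
    a1 = m1 & shared
    b1 = (u1 ^ m1) & shared
    if a1 == 0 or b1 == 0:
        return True
    a2 = m2 & shared
    b2 = (u2 ^ m2) & shared
    if a2 == 0 or b2 == 0:
        return True
    return (a1 & a2) == 0 or (a1 & b2) == 0 or (b1 & a2) == 0 or (b1 & b2) == 0


def _is_subsplit_masks(pm: int, pu: int, qm: int, qu: int) -> bool:
    p1, p2 = pm, pu ^ pm
    q1, q2 = qm, qu ^ qm
    return ((p1 & ~q1) == 0 and (p2 & ~q2) == 0) or (
        (p1 & ~q2) == 0 and (p2 & ~q1) == 0
    )


class Split:
    """A canonical bipartition of a taxon universe.

    `mask` is the side containing the lowest-indexed taxon of `universe`;
    neither side may be empty.
    """

    __slots__ = ("mask", "universe", "index")

    def __init__(self, mask: int, universe: int, index: TaxonIndex):
        if mask & ~universe:
            raise ValueError("split side not contained in its universe")
        if mask == 0 or mask == universe:
            raise ValueError("a split must have two non-empty sides")
        self.mask = _canon(mask, universe)
        self.universe = universe
        self.index = index

    @property
    def other_side(self) -> int:
        return self.universe ^ self.mask

    @property
    def is_trivial(self) -> bool:
        """True iff one side consists of a single taxon (terminal split)."""
        n1 = self.mask.bit_count()
        return n1 == 1 or n1 == self.universe.bit_count() - 1

    def sides(self) -> tuple:
        return (self.index.labels_of(self.mask), self.index.labels_of(self.other_side))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Split)
            and self.mask == other.mask
            and self.universe == other.universe
        )

    def __hash__(self) -> int:
        return hash((self.mask, self.universe))

    def __repr__(self) -> str:
        s1, s2 = self.sides()
        return "Split(%s|%s)" % ("".join(s1), "".join(s2))


class PhyloTree:
    """An unrooted tree: a taxon set plus its canonical non-trivial splits.

    Terminal splits are implied by the taxon set and not stored.  The tree
    is bifurcating iff it has exactly n-3 inner splits.
    """

    __slots__ = ("index", "taxa_mask", "inner_splits")

    def __init__(
        self,
        index: TaxonIndex,
        taxa_mask: int,
        inner_splits: Iterable[int],
        validate: bool = True,
    ):
        self.index = index
        self.taxa_mask = taxa_mask
        splits = frozenset(_canon(m, taxa_mask) for m in inner_splits)
        self.inner_splits = splits
        if validate:
            self._validate()

    def _validate(self) -> None:
        n = self.n_taxa
        if n < 3:
            raise ValueError("a tree needs at least 3 taxa")
        for m in self.inner_splits:
            if m & ~self.taxa_mask:
                raise ValueError("split side outside the taxon set")
            c1 = m.bit_count()
            if c1 < 2 or c1 > n - 2:
                raise ValueError("trivial or empty split stored as inner split")
        if len(self.inner_splits) > n - 3:
            raise ValueError("more than n-3 inner splits")
        sp = sorted(self.inner_splits)
        u = self.taxa_mask
        for i, a in enumerate(sp):
            for b in sp[i + 1 :]:
                if not _compatible_masks(a, u, b, u):
                    raise ValueError("incompatible splits in one tree")

    # -- basic facts ------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return self.taxa_mask.bit_count()

    @property
    def is_bifurcating(self) -> bool:
        return len(self.inner_splits) == self.n_taxa - 3

    @property
    def multifurcation_count(self) -> int:
        """m = (n-3) - number of inner splits (0 for bifurcating trees)."""
        return (self.n_taxa - 3) - len(self.inner_splits)

    @property
    def taxa_labels(self) -> tuple:
        return self.index.labels_of(self.taxa_mask)

    def splits(self) -> tuple:
        return tuple(
            Split(m, self.taxa_mask, self.index) for m in sorted(self.inner_splits)
        )

    def terminal_splits(self) -> tuple:
        u = self.taxa_mask
        return tuple(Split(1 << i, u, self.index) for i in _bits(u))

    def key(self) -> tuple:
        """Canonical hashable identity (taxon set + split set)."""
        return (self.taxa_mask, self.inner_splits)

    def __eq__(self, other) -> bool:
        # indexes may differ by appended (dummy) taxa; existing bit positions
        # are preserved, so comparing the actual taxon labels suffices
        return (
            isinstance(other, PhyloTree)
            and self.taxa_mask == other.taxa_mask
            and self.inner_splits == other.inner_splits
            and (
                self.index.names == other.index.names
                or self.taxa_labels == other.taxa_labels
            )
        )

    def __hash__(self) -> int:
        return hash((self.taxa_mask, self.inner_splits))

    def __repr__(self) -> str:
        return "PhyloTree(n=%d, splits=%d)" % (self.n_taxa, len(self.inner_splits))


# ---------------------------------------------------------------------------
# Newick input
# ---------------------------------------------------------------------------


def _splits_from_dendropy(dtree: "dendropy.Tree", index: TaxonIndex) -> PhyloTree:
    taxa_mask = 0
    node_mask: dict = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            if node.taxon is None or not node.taxon.label:
                raise NewickError("leaf without a label")
            try:
                bit = 1 << index.position[node.taxon.label]
            except KeyError:
                raise NewickError("taxon %r missing from index" % node.taxon.label)
            node_mask[node] = bit
            taxa_mask |= bit
        else:
            m = 0
            for ch in node.child_nodes():
                m |= node_mask[ch]
            node_mask[node] = m
    n = taxa_mask.bit_count()
    if n < 3:
        raise NewickError("fewer than 3 taxa")
    inner = set()
    for node, m in node_mask.items():
        if node is dtree.seed_node:
            continue
        c = m.bit_count()
        if 2 <= c <= n - 2:
            inner.add(_canon(m, taxa_mask))
    return PhyloTree(index, taxa_mask, inner, validate=False)


def _leaf_labels(dtree: "dendropy.Tree") -> list:
    labels = []
    for leaf in dtree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise NewickError("leaf without a label")
        labels.append(leaf.taxon.label)
    if len(set(labels)) != len(labels):
        raise NewickError("duplicate taxon labels")
    return labels


def _attach_root_taxon(dtree: "dendropy.Tree", root_label: str) -> None:
    taxon = dtree.taxon_namespace.new_taxon(label=root_label)
    node = dendropy.Node()
    node.taxon = taxon
    dtree.seed_node.add_child(node)


def parse_newick(
    text: str,
    treat_root_as_taxon: bool = False,
    root_label: str = "ROOT",
    index: Optional[TaxonIndex] = None,
) -> PhyloTree:
    """Parse a single Newick statement into an (unrooted) PhyloTree.

    Branch lengths and internal labels are discarded; degree-2 nodes are
    irrelevant because splits are collected as subtree bitmasks.  With
    `treat_root_as_taxon`, an artificial taxon (`root_label`) is attached at
    the root before unrooting, preserving rooted information.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError("could not parse Newick: %s" % exc) from exc
    if treat_root_as_taxon:
        _attach_root_taxon(dtree, root_label)
    labels = _leaf_labels(dtree)
    if index is None:
        index = TaxonIndex(sorted(labels))
    return _splits_from_dendropy(dtree, index)


def read_trees(
    source: str,
    treat_root_as_taxon: bool = False,
    root_label: str = "ROOT",
    index: Optional[TaxonIndex] = None,
    drop_uninformative: bool = True,
) -> list:
    """Read a multi-tree Newick file (or string) onto one shared TaxonIndex.

    One tree per semicolon-terminated statement; blank lines are ignored.
    Trees with zero inner splits carry no grouping information and are
    dropped with a warning unless `drop_uninformative` is False.
    """
    if "(" in source or ";" in source:
        data = source
    else:
        with open(source) as fh:
            data = fh.read()
    try:
        tlist = dendropy.TreeList.get(
            data=data,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise NewickError("could not parse Newick: %s" % exc) from exc
    if len(tlist) == 0:
        raise NewickError("no trees found")
    if treat_root_as_taxon:
        for i, dtree in enumerate(tlist):
            _attach_root_taxon(dtree, "%s%d" % (root_label, i + 1))
    if index is None:
        all_labels = set()
        for dtree in tlist:
            all_labels.update(_leaf_labels(dtree))
        index = TaxonIndex(sorted(all_labels))
    trees = []
    for i, dtree in enumerate(tlist):
        _leaf_labels(dtree)  # per-tree duplicate check
        tree = _splits_from_dendropy(dtree, index)
        if drop_uninformative and not tree.inner_splits:
            warnings.warn(
                "dropping input tree %d: no inner splits" % (i + 1), stacklevel=2
            )
            continue
        trees.append(tree)
    return trees


# ---------------------------------------------------------------------------
# Newick output
# ---------------------------------------------------------------------------


def _quote_label(label: str) -> str:
    if any(ch in label for ch in "()[]{}:;,= \t\n'\""):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: PhyloTree, labels: Optional[Mapping] = None) -> str:
    """Serialize to Newick; round-trips to the identical canonical split set.

    `labels` optionally maps Split (or canonical side mask) to a string that
    is emitted as the internal-node label of the corresponding split.
    """
    label_by_clade = {}
    if labels:
        for k, v in labels.items():
            m = k.mask if isinstance(k, Split) else _canon(k, tree.taxa_mask)
            label_by_clade[tree.taxa_mask ^ m] = str(v)

    u = tree.taxa_mask
    root_bit = u & -u
    # canonical split masks contain the lowest taxon; the complements are the
    # clades of the tree rooted on the lowest taxon's terminal edge
    clades = sorted((u ^ m for m in tree.inner_splits), key=int.bit_count)

    out = io.StringIO()

    def emit(mask: int, pool: list) -> None:
        inside = [c for c in pool if c & ~mask == 0]
        maximal = [
            c for c in inside if not any(d != c and c & ~d == 0 for d in inside)
        ]
        covered = 0
        parts = []
        for c in maximal:
            parts.append(("clade", c, [d for d in inside if d != c and d & ~c == 0]))
            covered |= c
        for i in _bits(mask & ~covered):
            parts.append(("leaf", 1 << i, None))
        out.write("(")
        for j, (kind, m, sub) in enumerate(parts):
            if j:
                out.write(",")
            if kind == "leaf":
                out.write(_quote_label(tree.index.names[m.bit_length() - 1]))
            else:
                emit(m, sub)
                lab = label_by_clade.get(m)
                if lab is not None:
                    out.write(_quote_label(lab))
        out.write(")")

    top = u ^ root_bit
    pool = list(clades)
    out.write("(")
    out.write(_quote_label(tree.index.names[root_bit.bit_length() - 1]))
    out.write(",")
    # children of the node adjacent to the root taxon
    maximal = [c for c in pool if not any(d != c and c & ~d == 0 for d in pool)]
    covered = 0
    parts = []
    for c in maximal:
        parts.append(c)
        covered |= c
    leftovers = top & ~covered
    first = True
    for c in parts:
        if not first:
            out.write(",")
        first = False
        emit(c, [d for d in pool if d != c and d & ~c == 0])
        lab = label_by_clade.get(c)
        if lab is not None:
            out.write(_quote_label(lab))
    for i in _bits(leftovers):
        if not first:
            out.write(",")
        first = False
        out.write(_quote_label(tree.index.names[i]))
    out.write(");")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Restriction, compatibility, distance
# ---------------------------------------------------------------------------


def restrict_split(s: Split, taxa: TaxaLike) -> Optional[Split]:
    """Intersect both sides with `taxa`; None if the split vanishes."""
    taxa_mask = s.index.mask_of(taxa)
    m1 = s.mask & taxa_mask
    m2 = s.other_side & taxa_mask
    if m1 == 0 or m2 == 0:
        return None
    return Split(m1, m1 | m2, s.index)


def restrict_tree(t: PhyloTree, taxa: TaxaLike) -> PhyloTree:
    """Restriction of `t` to a taxon subset (≥ 3 shared taxa required)."""
    taxa_mask = t.index.mask_of(taxa) & t.taxa_mask
    n = taxa_mask.bit_count()
    if n < 3:
        raise ValueError("restriction needs at least 3 shared taxa")
    inner = set()
    for m in t.inner_splits:
        m1 = m & taxa_mask
        c = m1.bit_count()
        if 2 <= c <= n - 2:
            inner.add(_canon(m1, taxa_mask))
    return PhyloTree(t.index, taxa_mask, inner, validate=False)


def are_compatible(s1: Split, s2: Split) -> bool:
    """True iff the two splits can occur together in one tree.

    For different universes the test is applied after restriction to the
    shared taxa; vanished or trivial restrictions are always compatible.
    """
    return _compatible_masks(s1.mask, s1.universe, s2.mask, s2.universe)


def is_subsplit(partial: Split, plenary: Split) -> bool:
    """True iff `partial`'s sides are contained in `plenary`'s two sides."""
    if partial.universe & ~plenary.universe:
        raise ValueError("partial split's taxa must be a subset of the plenary's")
    return _is_subsplit_masks(
        partial.mask, partial.universe, plenary.mask, plenary.universe
    )


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson-Foulds distance: |T1\\T2| + |T2\\T1| over inner splits."""
    if t1.taxa_mask != t2.taxa_mask or t1.index.names != t2.index.names:
        raise ValueError("RF distance requires identical taxon sets")
    return len(t1.inner_splits ^ t2.inner_splits)


# ---------------------------------------------------------------------------
# Low-level topology surgery on raw split sets (shared by oracles and search)
# ---------------------------------------------------------------------------


def _edge_masks(splits, taxa_mask: int) -> list:
    """All edges of the tree, one side mask each (terminal edges first)."""
    edges = [1 << i for i in _bits(taxa_mask)]
    edges.extend(sorted(splits))
    return edges


def _attach_on_edge(splits, taxa_mask: int, edge_mask: int, x_bit: int) -> frozenset:
    """Split set after subdividing the edge `edge_mask` and attaching taxon x.

    `edge_mask` is one side of the edge (a stored inner split or a terminal
    singleton).  Returns canonical inner splits over taxa_mask | x_bit.
    """
    u = taxa_mask
    new_u = u | x_bit
    comp = u ^ edge_mask
    n_new = new_u.bit_count()
    low = new_u & -new_u
    out = set()
    add = out.add
    for s in splits:
        if s == edge_mask or s == comp:
            continue
        # x joins the side of s that contains the subdivided edge
        if (edge_mask & ~s) == 0 or (comp & ~s) == 0:
            side = s | x_bit
        else:
            side = s
        add(side if side & low else new_u ^ side)
    for side in (edge_mask, comp):
        if 2 <= side.bit_count() <= n_new - 2:
            add(side if side & low else new_u ^ side)
    return frozenset(out)


def _side_children(splits, taxa_mask: int, side: int) -> list:
    """Maximal blocks (subtrees) hanging inside the side `side` of an edge."""
    cands = set()
    for s in splits:
        for m in (s, taxa_mask ^ s):
            if m != side and (m & ~side) == 0:
                cands.add(m)
    maximal = [m for m in cands if not any(t != m and (m & ~t) == 0 for t in cands)]
    covered = 0
    for m in maximal:
        covered |= m
    for i in _bits(side & ~covered):
        maximal.append(1 << i)
    return maximal


def _node_keys(splits, taxa_mask: int) -> list:
    """Inner nodes, each as a frozenset of the direction masks around it."""
    nodes = {}
    for side in _edge_masks(splits, taxa_mask):
        # the inner endpoint of the edge, looking from the `side` component
        far = taxa_mask ^ side
        if far.bit_count() < 2:
            continue
        dirs = frozenset([side] + _side_children(splits, taxa_mask, far))
        nodes[dirs] = dirs
    return list(nodes)


def _attach_at_node(splits, taxa_mask: int, node_dirs, x_bit: int) -> frozenset:
    """Split set after attaching taxon x directly at an inner node.

    The node's degree grows by one (a multifurcation may be created); no
    existing split is refined.
    """
    new_u = taxa_mask | x_bit
    out = set()
    for s in splits:
        # the node lies on the complement side of s iff the whole s-side
        # fits into a single direction away from the node
        if any((s & ~d) == 0 for d in node_dirs):
            side = s
        else:
            side = s | x_bit
        out.add(_canon(side, new_u))
    return frozenset(out)
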