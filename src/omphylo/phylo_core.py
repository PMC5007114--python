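"""Trees, alignments, bipartition algebra and standard-format I/O.

Every other stage of the pipeline is built on the three containers defined
here:

``Tree``
    A binary phylogeny stored as a rooted node structure.  The rooting is a
    *view*: likelihood under reversible models and bipartition comparisons
    treat the tree as unrooted, while Dollo mapping and sequence simulation
    pick an explicit root.  Branch lengths are expected substitutions per
    site; internal edges may carry a bootstrap support in percent.

``Bipartition``
    A canonical two-way split of the taxon set, normalised to the side that
    does not contain the lexicographically smallest taxon, so that equality
    is label-set equality regardless of rotation or rooting.

``Alignment``
    A taxa x columns amino-acid matrix over the 20-letter alphabet plus
    ``-`` (gap) and ``X`` (missing); both are treated as fully ambiguous by
    the likelihood machinery.

Newick parsing is delegated to :mod:`dendropy`; FASTA and relaxed-PHYLIP
alignment I/O to Biopython.  Support values are read from internal node
labels (the dialect written by most ML programs), or optionally from
``[&support=..]`` comments.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np

__all__ = [
    "AA_ALPHABET",
    "GAP",
    "MISSING",
    "NewickError",
    "InvalidMoveError",
    "Node",
    "Tree",
    "Bipartition",
    "Alignment",
    "parse_newick",
    "write_newick",
    "bipartitions",
    "regraft",
    "spr",
    "restrict_to",
    "collapse_low_support",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
MISSING = "X"
#: gap and missing share ambiguity semantics; codes 20 and 21
_CODES = {aa: i for i, aa in enumerate(AA_ALPHABET)}
_CODES[GAP] = 20
_CODES[MISSING] = 21
_LETTERS = AA_ALPHABET + GAP + MISSING
N_STATES = 20


class NewickError(ValueError):
    """Raised for malformed newick input, naming the offending token."""


class InvalidMoveError(ValueError):
    """Raised for an illegal tree-surgery move (non-monophyletic clade,
    target edge inside the pruned clade, ...)."""


# ---------------------------------------------------------------------------
# Tree structure
# ---------------------------------------------------------------------------

class Node:
    """A node of a :class:`Tree`.  Tips carry a unique ``label``; the edge to
    the parent carries ``length`` and, for internal edges, an optional
    ``support`` in percent."""

    __slots__ = ("label", "length", "support", "children", "parent")

    def __init__(self, label=None, length=None, support=None):
        self.label: str | None = label
        self.length: float | None = length
        self.support: float | None = support
        self.children: list[Node] = []
        self.parent: Node | None = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def tip_set(self) -> frozenset[str]:
        return frozenset(n.label for n in self.postorder() if n.is_tip)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.label or 'internal'} len={self.length}>"


class Tree:
    """A phylogeny.  ``rooted`` records whether the root placement is
    meaningful; all bipartition-level comparisons ignore it."""

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        self.validate()

    # -- basic queries ------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_labels(self) -> frozenset[str]:
        return frozenset(n.label for n in self.tips())

    def n_tips(self) -> int:
        return sum(1 for _ in self.tips())

    def validate(self) -> None:
        labels = [n.label for n in self.postorder() if n.is_tip]
        if len(labels) != len(set(labels)):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise NewickError(f"duplicate tip label(s): {', '.join(dup)}")
        for n in self.postorder():
            if n.length is not None and not (np.isfinite(n.length) and n.length >= 0):
                raise NewickError(f"negative or non-finite branch length {n.length!r}")

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            c = Node(node.label, node.length, node.support)
            for ch in node.children:
                c.add(clone(ch))
            return c

        return Tree(clone(self.root), rooted=self.rooted)

    # -- edge addressing ----------------------------------------------------

    def find_edge(self, tip_set: Iterable[str]) -> Node:
        """Return the child node of the edge whose far-from-root tip set is
        exactly ``tip_set``.  Raises ``KeyError`` if no such edge exists."""
        want = frozenset(tip_set)
        for n in self.postorder():
            if n is self.root:
                continue
            if n.tip_set() == want:
                return n
        raise KeyError(f"no edge subtending exactly {sorted(want)}")

    def mrca(self, tip_set: Iterable[str]) -> Node:
        want = frozenset(tip_set)
        best = None
        for n in self.postorder():
            ts = n.tip_set()
            if want <= ts and (best is None or len(ts) < len(best.tip_set())):
                best = n
        assert best is not None
        return best

    # -- rooting views ------------------------------------------------------

    def unrooted(self) -> "Tree":
        """Return a copy whose root is a multifurcation (degree-2 roots are
        suppressed, merging the two root edges)."""
        t = self.copy()
        t.rooted = False
        while len(t.root.children) == 1:
            t.root = t.root.children[0]
            t.root.parent = None
            t.root.length = None
        if len(t.root.children) == 2:
            a, b = t.root.children
            keep, move = (a, b) if not a.is_tip else (b, a)
            if keep.is_tip:  # two-tip tree cannot be unrooted further
                return t
            t.root.children.remove(keep)
            for ch in keep.children:
                t.root.add(ch)
            move.length = (move.length or 0.0) + (keep.length or 0.0)
            if move.support is None:
                move.support = keep.support
        return t

    def rooted_at_edge(self, tip_set: Iterable[str], fraction: float = 0.5) -> "Tree":
        """Return a copy rooted by a new degree-2 node bisecting the edge
        identified by ``tip_set``; ``fraction`` of the length goes to the
        near (old-child) side."""
        t = self.copy()
        child = t.find_edge(tip_set)
        parent = child.parent
        length = child.length if child.length is not None else 0.0
        # path from the attachment point up to the old root; edge i of the
        # path (between path[i] and path[i+1]) has its length/support stored
        # on path[i] and must migrate to path[i+1] when the edge is reversed
        path: list[Node] = []
        p = parent
        while p is not None:
            path.append(p)
            p = p.parent
        old_lens = [n.length for n in path]
        old_sups = [n.support for n in path]
        parent.children.remove(child)
        child.parent = None
        for i in range(len(path) - 1):
            path[i + 1].children.remove(path[i])
        new_root = Node()
        new_root.add(child)
        child.length = length * fraction
        new_root.add(parent)
        parent.parent = new_root
        parent.length = length * (1 - fraction)
        parent.support = child.support
        for i in range(len(path) - 1):
            path[i].add(path[i + 1])
            path[i + 1].length = old_lens[i] if old_lens[i] is not None else 0.0
            path[i + 1].support = old_sups[i]
        _suppress_unifurcations(new_root)
        return Tree(new_root, rooted=True)


def _suppress_unifurcations(root: Node) -> None:
    for n in list(root.postorder()):
        if n is root or n.is_tip:
            continue
        if len(n.children) == 1:
            child = n.children[0]
            p = n.parent
            i = p.children.index(n)
            p.children[i] = child
            child.parent = p
            child.length = (child.length or 0.0) + (n.length or 0.0)
            if child.support is None:
                child.support = n.support
    while len(root.children) == 1 and not root.children[0].is_tip:
        only = root.children[0]
        only.parent = None
        only.length = None
        root.children = only.children
        for ch in root.children:
            ch.parent = root
        root.label = only.label


# ---------------------------------------------------------------------------
# Newick I/O (dendropy backend)
# ---------------------------------------------------------------------------

def parse_newick(
    text: str,
    rooted: bool | None = None,
    support_in_comments: bool = False,
    default_length: float = 0.0,
    warn_missing_lengths: bool = True,
) -> Tree:
    """Parse a newick string into a :class:`Tree`.

    Internal node labels that parse as numbers are interpreted as bootstrap
    supports (the dialect of PhyML/RAxML/IQ-TREE); with
    ``support_in_comments`` supports are taken from ``[&support=..]``
    comments instead.  Branch lengths absent from the input default to
    ``default_length`` (0), with a warning, so that topology-only inputs are
    legal.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            extract_comment_metadata=support_in_comments,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"malformed newick: {exc}") from exc

    missing_lengths = False

    def convert(dnode) -> Node:
        nonlocal missing_lengths
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label
        node = Node()
        if not dnode.child_nodes():
            if label is None:
                raise NewickError("unlabeled tip in newick input")
            node.label = str(label)
        else:
            if label is not None:
                try:
                    node.support = float(label)
                except ValueError:
                    node.label = str(label)
        if support_in_comments:
            for ann in getattr(dnode, "annotations", []):
                if ann.name == "support":
                    node.support = float(ann.value)
        if dnode.edge.length is not None:
            node.length = float(dnode.edge.length)
        else:
            node.length = None
            missing_lengths = True
        for dchild in dnode.child_nodes():
            node.add(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    root.length = None  # the root has no edge
    n_children = len(root.children)
    if rooted is None:
        rooted = n_children == 2
    internal = [n for n in root.postorder() if not n.is_tip and n is not root]
    if missing_lengths and any(
        n.length is None for n in root.postorder() if n is not root
    ):
        if warn_missing_lengths:
            warnings.warn(
                "newick input lacks branch lengths; defaulting to "
                f"{default_length}",
                stacklevel=2,
            )
        for n in root.postorder():
            if n is not root and n.length is None:
                n.length = default_length
    tree = Tree(root, rooted=rooted)
    return tree


def write_newick(
    tree: Tree,
    lengths: bool = True,
    supports: bool = True,
    precision: int = 6,
) -> str:
    """Serialise a tree to newick, with supports as internal node labels."""

    def fmt(x: float) -> str:
        return f"{x:.{precision}g}"

    def rec(node: Node) -> str:
        if node.is_tip:
            s = node.label
        else:
            s = "(" + ",".join(rec(c) for c in node.children) + ")"
            if supports and node.support is not None:
                sup = node.support
                s += fmt(sup) if sup % 1 else str(int(sup))
            elif node.label:
                s += node.label
        if lengths and node.length is not None and node.parent is not None:
            s += ":" + fmt(node.length)
        return s

    return rec(tree.root) + ";"


# ---------------------------------------------------------------------------
# Bipartitions
# ---------------------------------------------------------------------------

class Bipartition:
    """A canonical split of ``taxa`` into two parts, stored as the side not
    containing the reference taxon (the lexicographic minimum)."""

    __slots__ = ("side", "taxa")

    def __init__(self, taxa: Iterable[str], one_side: Iterable[str]):
        taxa = frozenset(taxa)
        side = frozenset(one_side)
        if not side <= taxa:
            raise ValueError("split side is not a subset of the taxon set")
        ref = min(taxa)
        if ref in side:
            side = taxa - side
        self.side = side
        self.taxa = taxa

    def is_trivial(self) -> bool:
        return len(self.side) <= 1 or len(self.side) >= len(self.taxa) - 1

    def restrict(self, taxa: Iterable[str]) -> "Bipartition | None":
        """The split induced on a taxon subset, or None if it degenerates
        (one side empty)."""
        taxa = frozenset(taxa) & self.taxa
        side = self.side & taxa
        if not side or side == taxa:
            return None
        return Bipartition(taxa, side)

    def conflicts_with(self, other: "Bipartition") -> bool:
        """True if the two splits (on the same taxon set) cannot co-occur in
        one tree: all four pairwise side intersections are non-empty."""
        if self.taxa != other.taxa:
            raise ValueError("splits on different taxon sets")
        a1, a2 = self.side, self.taxa - self.side
        b1, b2 = other.side, other.taxa - other.side
        return all((a & b) for a in (a1, a2) for b in (b1, b2))

    def __eq__(self, other):
        return (
            isinstance(other, Bipartition)
            and self.taxa == other.taxa
            and self.side == other.side
        )

    def __hash__(self):
        return hash((self.taxa, self.side))

    def __repr__(self):
        inside = ",".join(sorted(self.side))
        return f"{{{inside}}}"


def bipartitions(tree: Tree, include_trivial: bool = False) -> frozenset[Bipartition]:
    """The set of non-trivial splits induced by the internal edges of the
    (unrooted view of the) tree.  Trees with fewer than four tips induce no
    non-trivial split and return the empty set."""
    taxa = tree.tip_labels()
    out = set()
    for node in tree.postorder():
        if node is tree.root:
            continue
        bp = Bipartition(taxa, node.tip_set())
        if include_trivial or not bp.is_trivial():
            out.add(bp)
    return frozenset(out)


def same_topology(a: Tree, b: Tree) -> bool:
    return a.tip_labels() == b.tip_labels() and bipartitions(a) == bipartitions(b)


# ---------------------------------------------------------------------------
# Tree surgery
# ---------------------------------------------------------------------------

def _detach(tree: Tree, node: Node) -> None:
    """Remove ``node``'s subtree and suppress the resulting unifurcation."""
    parent = node.parent
    parent.children.remove(node)
    node.parent = None
    if len(parent.children) == 1:
        sibling = parent.children[0]
        grand = parent.parent
        if grand is None:
            # parent was the root: sibling becomes the root
            sibling.parent = None
            sibling.length = None
            tree.root = sibling
        else:
            i = grand.children.index(parent)
            grand.children[i] = sibling
            sibling.parent = grand
            sibling.length = (sibling.length or 0.0) + (parent.length or 0.0)
            if sibling.support is None:
                sibling.support = parent.support


def _attach(tree: Tree, subtree: Node, target: Node) -> None:
    """Bisect the edge above ``target`` with a new node and hang ``subtree``
    from it."""
    parent = target.parent
    joint = Node()
    half = (target.length or 0.0) / 2.0
    i = parent.children.index(target)
    parent.children[i] = joint
    joint.parent = parent
    joint.length = half
    joint.support = None
    target.parent = joint
    target.length = half
    joint.children = [target]
    joint.add(subtree)


def spr(tree: Tree, prune_edge: frozenset[str], target_edge: frozenset[str]) -> Tree:
    """Subtree-prune-regraft: cut the edge subtending ``prune_edge`` and
    reattach the pruned subtree onto the edge subtending ``target_edge`` (tip
    sets name edges as in :meth:`Tree.find_edge`; the target is resolved in
    the pruned tree, i.e. net of the pruned tips)."""
    prune_edge = frozenset(prune_edge)
    target_edge = frozenset(target_edge) - prune_edge
    t = tree.copy()
    node = t.find_edge(prune_edge)
    if not target_edge:
        raise InvalidMoveError("target edge lies inside the pruned clade")
    _detach(t, node)
    try:
        target = t.find_edge(target_edge)
    except KeyError as exc:
        raise InvalidMoveError(
            f"target edge {sorted(target_edge)} not present after pruning"
        ) from exc
    _attach(t, node, target)
    return Tree(t.root, rooted=t.rooted)


def regraft(tree: Tree, clade: Iterable[str], target_edge: Iterable[str]) -> Tree:
    """Prune the monophyletic ``clade`` and reattach it onto ``target_edge``.

    The clade is named by its tip-label set and must be subtended by an edge
    of the tree; the target edge is named by the tip set below it (tips of
    the clade itself are ignored, so edges of the original tree remain valid
    addresses).  Raises :class:`InvalidMoveError` for a non-monophyletic
    clade or a target inside the clade.
    """
    clade = frozenset(clade)
    try:
        tree.find_edge(clade)
    except KeyError as exc:
        raise InvalidMoveError(
            f"clade {sorted(clade)} is not monophyletic in the tree"
        ) from exc
    target = frozenset(target_edge)
    if target <= clade:
        raise InvalidMoveError("target edge lies inside the regrafted clade")
    return spr(tree, clade, target)


# ---------------------------------------------------------------------------
# Gene-tree utilities (used by the internode-certainty stage)
# ---------------------------------------------------------------------------

def restrict_to(tree: Tree, taxa: Iterable[str]) -> Tree:
    """Prune the tree down to ``taxa``, suppressing unifurcations."""
    keep = frozenset(taxa)
    t = tree.copy()

    def prune(node: Node) -> Node | None:
        if node.is_tip:
            return node if node.label in keep else None
        new_children = []
        for c in node.children:
            kept = prune(c)
            if kept is not None:
                new_children.append(kept)
        if not new_children:
            return None
        if len(new_children) == 1:
            child = new_children[0]
            child.length = (child.length or 0.0) + (node.length or 0.0)
            if child.support is None:
                child.support = node.support
            return child
        node.children = new_children
        for c in new_children:
            c.parent = node
        return node

    root = prune(t.root)
    if root is None:
        raise ValueError("cannot restrict away the entire tree")
    root.parent = None
    root.length = None
    return Tree(root, rooted=t.rooted)


def collapse_low_support(tree: Tree, threshold: float) -> Tree:
    """Collapse internal edges whose support is strictly below ``threshold``
    percent (edges without a support value are kept), yielding a possibly
    multifurcating tree."""
    t = tree.copy()
    for n in list(t.root.postorder()):
        if n.is_tip or n is t.root:
            continue
        if n.support is not None and n.support < threshold:
            parent = n.parent
            i = parent.children.index(n)
            parent.children[i : i + 1] = n.children
            for ch in n.children:
                ch.parent = parent
    return Tree(t.root, rooted=t.rooted)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

class Alignment:
    """An amino-acid alignment: ordered taxon labels plus a uint8 code
    matrix (rows = taxa).  Codes 0-19 follow ``AA_ALPHABET``; 20 = gap,
    21 = missing; both are fully ambiguous for likelihood purposes."""

    def __init__(self, taxa: Sequence[str], matrix: np.ndarray):
        taxa = list(taxa)
        matrix = np.asarray(matrix, dtype=np.uint8)
        if matrix.ndim != 2 or matrix.shape[0] != len(taxa):
            raise ValueError("matrix shape does not match taxon list")
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon labels in alignment")
        if matrix.size and matrix.max() >= len(_LETTERS):
            raise ValueError("alignment codes outside the amino-acid alphabet")
        self.taxa = taxa
        self.matrix = matrix

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dict(cls, seqs: dict[str, str]) -> "Alignment":
        taxa = list(seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) > 1:
            raise ValueError("unequal sequence lengths in alignment")
        mat = np.zeros((len(taxa), lengths.pop() if lengths else 0), dtype=np.uint8)
        for i, t in enumerate(taxa):
            mat[i] = encode(seqs[t])
        return cls(taxa, mat)

    def to_dict(self) -> dict[str, str]:
        return {t: decode(self.matrix[i]) for i, t in enumerate(self.taxa)}

    # -- shape and access ---------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.matrix[self.taxa.index(taxon)]

    def select_columns(self, cols: np.ndarray) -> "Alignment":
        return Alignment(self.taxa, self.matrix[:, cols])

    def __eq__(self, other):
        return (
            isinstance(other, Alignment)
            and self.taxa == other.taxa
            and self.matrix.shape == other.matrix.shape
            and bool((self.matrix == other.matrix).all())
        )

    # -- file formats -------------------------------------------------------

    @classmethod
    def read(cls, path_or_handle, fmt: str = "fasta") -> "Alignment":
        from Bio import AlignIO

        schema = {"fasta": "fasta", "phylip": "phylip-relaxed"}[fmt]
        aln = AlignIO.read(path_or_handle, schema)
        return cls.from_dict({rec.id: str(rec.seq).upper() for rec in aln})

    def write(self, path_or_handle, fmt: str = "fasta") -> None:
        from Bio import AlignIO
        from Bio.Align import MultipleSeqAlignment
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(decode(self.matrix[i])), id=t, description="")
            for i, t in enumerate(self.taxa)
        ]
        schema = {"fasta": "fasta", "phylip": "phylip-relaxed"}[fmt]
        AlignIO.write(MultipleSeqAlignment(records), path_or_handle, schema)


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODES[c] for c in seq.upper()], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"illegal residue {exc.args[0]!r} in sequence") from exc


def decode(codes: np.ndarray) -> str:
    return "".join(_LETTERS[c] for c in codes)
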