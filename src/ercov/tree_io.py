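"""Reading, validating and canonicalizing phylogenetic trees.

Trees are treated as rooted as written.  Every tree is stored in a canonical
form: node ids are assigned in preorder with the children of each node
sorted by their smallest descendant leaf label, so that two isomorphic trees
always receive identical node numbering.  Species name matching is exact and
case-sensitive after trimming surrounding whitespace and quotes.

Newick parsing and low-level tree reading are delegated to dendropy; this
module owns validation (unique leaf labels, non-negative branch lengths),
canonicalization, leaf-set restriction, and master/gene congruence checks.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "NewickError",
    "TreeValidationError",
    "CongruenceError",
    "PhyloTree",
    "GeneTreeSet",
    "read_newick",
    "write_newick",
    "restrict",
    "validate_congruence",
    "read_gene_trees",
    "load_gene_tree_set",
]


class NewickError(ValueError):
    """Malformed Newick input (message carries line/column when available)."""


class TreeValidationError(ValueError):
    """Structurally valid Newick that violates a tree invariant."""


class CongruenceError(ValueError):
    """A gene tree's topology conflicts with the master tree."""


def _clean_label(label: str) -> str:
    return label.strip().strip("'\"").strip()


# Nested intermediate form: (label_or_None, length_or_None, [children]).
_Nested = tuple


class PhyloTree:
    """Rooted tree with labeled leaves and per-branch lengths.

    Attributes
    ----------
    parent : list[int]
        Parent id per node; ``-1`` for the root (node 0).
    children : list[tuple[int, ...]]
        Child ids per node, in canonical order.
    labels : list[str | None]
        Leaf label per node, ``None`` on internal nodes.
    lengths : numpy.ndarray
        Branch length of the edge above each node (NaN on the root, and on
        any node whose input tree omitted the length).
    """

    __slots__ = ("parent", "children", "labels", "lengths", "_label_to_id", "_leafsets")

    def __init__(self, parent, children, labels, lengths):
        self.parent = list(parent)
        self.children = [tuple(c) for c in children]
        self.labels = list(labels)
        self.lengths = np.asarray(lengths, dtype=float)
        self._label_to_id = {
            lab: i for i, lab in enumerate(self.labels) if lab is not None
        }
        self._leafsets: list[frozenset[str]] | None = None

    # -- basic structure -------------------------------------------------
    @property
    def root(self) -> int:
        return 0

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def is_leaf(self, node: int) -> bool:
        return not self.children[node]

    @property
    def leaf_ids(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def leaf_labels(self) -> set[str]:
        return set(self._label_to_id)

    def leaf_id(self, label: str) -> int:
        return self._label_to_id[label]

    def preorder(self) -> Iterable[int]:
        return range(self.n_nodes)  # canonical numbering is preorder

    def postorder(self) -> list[int]:
        return list(range(self.n_nodes - 1, -1, -1))

    def ancestors(self, node: int) -> list[int]:
        """Proper ancestors of *node*, nearest first, ending at the root."""
        out = []
        p = self.parent[node]
        while p != -1:
            out.append(p)
            p = self.parent[p]
        return out

    def leafset(self, node: int) -> frozenset[str]:
        """Set of leaf labels below (and including) *node*."""
        if self._leafsets is None:
            sets: list[frozenset[str] | None] = [None] * self.n_nodes
            for v in self.postorder():
                if not self.children[v]:
                    sets[v] = frozenset((self.labels[v],))
                else:
                    acc: set[str] = set()
                    for c in self.children[v]:
                        acc.update(sets[c])  # type: ignore[arg-type]
                    sets[v] = frozenset(acc)
            self._leafsets = sets  # type: ignore[assignment]
        return self._leafsets[node]  # type: ignore[return-value]

    def mrca(self, labels: Iterable[str]) -> int:
        """Most recent common ancestor of a set of leaf labels."""
        want = frozenset(labels)
        if not want:
            raise ValueError("mrca of an empty label set")
        missing = want - self.leaf_labels
        if missing:
            raise TreeValidationError(f"labels not in tree: {sorted(missing)}")
        node = self.leaf_id(next(iter(want)))
        while not want <= self.leafset(node):
            node = self.parent[node]
        return node

    def clades(self) -> set[frozenset[str]]:
        """Leaf sets of all internal nodes (the rooted bipartition profile)."""
        return {self.leafset(v) for v in range(self.n_nodes) if self.children[v]}

    def total_length(self) -> float:
        return float(np.nansum(self.lengths))

    def with_lengths(self, lengths: Sequence[float]) -> "PhyloTree":
        """Copy of this tree with branch lengths replaced (root entry ignored)."""
        new = np.asarray(lengths, dtype=float).copy()
        if new.shape != self.lengths.shape:
            raise ValueError("length vector does not match node count")
        new[self.root] = np.nan
        return PhyloTree(self.parent, self.children, self.labels, new)

    # -- equality up to isomorphism --------------------------------------
    def isomorphic(self, other: "PhyloTree", tol: float = 0.0) -> bool:
        """True if topologies match and branch lengths agree within *tol*.

        Canonical numbering makes this a direct elementwise comparison.
        """
        if self.parent != other.parent or self.labels != other.labels:
            return False
        a, b = self.lengths, other.lengths
        both = ~(np.isnan(a) & np.isnan(b))
        return bool(np.all(np.abs(a[both] - b[both]) <= tol))

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree {len(self._label_to_id)} leaves, {self.n_nodes} nodes>"


# ---------------------------------------------------------------------------
# canonical construction
# ---------------------------------------------------------------------------

def _build_canonical(nested: _Nested) -> PhyloTree:
    """Build a canonically numbered PhyloTree from the nested form."""

    def min_label(n: _Nested) -> str:
        label, _, kids = n
        if not kids:
            return label
        return min(min_label(k) for k in kids)

    parent: list[int] = []
    children: list[list[int]] = []
    labels: list[str | None] = []
    lengths: list[float] = []

    def emit(n: _Nested, par: int) -> int:
        label, length, kids = n
        node = len(parent)
        parent.append(par)
        children.append([])
        labels.append(label if not kids else None)
        lengths.append(np.nan if length is None else float(length))
        if par != -1:
            children[par].append(node)
        for k in sorted(kids, key=min_label):
            emit(k, node)
        return node

    nested = (nested[0], None, nested[2])  # the root carries no edge
    emit(nested, -1)
    return PhyloTree(parent, children, labels, lengths)


def _validate_nested(nested: _Nested, require_lengths: bool) -> None:
    seen: set[str] = set()

    def walk(n: _Nested, is_root: bool) -> None:
        label, length, kids = n
        if not kids:
            if not label:
                raise TreeValidationError("leaf with empty label")
            if label in seen:
                raise TreeValidationError(f"duplicate leaf label: {label!r}")
            seen.add(label)
        if not is_root:
            if length is None:
                if require_lengths:
                    raise TreeValidationError(
                        f"missing branch length above {label or 'an internal node'}"
                    )
            elif length < 0:
                raise TreeValidationError(f"negative branch length: {length}")
        for k in kids:
            walk(k, False)

    walk(nested, True)


def _nested_from_dendropy(node: "dendropy.Node") -> _Nested:
    if node.is_leaf():
        if node.taxon is None or node.taxon.label is None:
            raise TreeValidationError("leaf with empty label")
        return (_clean_label(node.taxon.label), node.edge.length, [])
    kids = [_nested_from_dendropy(c) for c in node.child_nodes()]
    return (None, node.edge.length, kids)


def read_newick(text: str, require_lengths: bool = True) -> PhyloTree:
    """Parse one Newick string into a canonical :class:`PhyloTree`.

    Parameters
    ----------
    text : str
        A single well-formed Newick tree.
    require_lengths : bool
        If True (the default, appropriate for gene trees) every non-root
        branch must carry a parseable, non-negative length.

    Raises
    ------
    NewickError
        On malformed input, with the parser's line/column position.
    TreeValidationError
        On duplicate leaf labels, empty labels, negative or (when required)
        missing branch lengths.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        if "Duplicate taxon labels" in str(exc):
            raise TreeValidationError(f"duplicate leaf label(s): {exc}") from exc
        line = getattr(exc, "line_num", None)
        col = getattr(exc, "col_num", None)
        pos = f" (line {line}, column {col})" if line is not None else ""
        raise NewickError(f"malformed Newick{pos}: {exc}") from exc
    nested = _nested_from_dendropy(dtree.seed_node)
    _validate_nested(nested, require_lengths)
    return _build_canonical(nested)


def _fmt_len(x: float) -> str:
    return f"{x:.10g}"


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree to canonical Newick (deterministic child order,
    branch lengths with 10 significant digits)."""

    def render(node: int) -> str:
        if tree.is_leaf(node):
            core = tree.labels[node]
        else:
            core = "(" + ",".join(render(c) for c in tree.children[node]) + ")"
        if node == tree.root or np.isnan(tree.lengths[node]):
            return core
        return f"{core}:{_fmt_len(tree.lengths[node])}"

    return render(tree.root) + ";"


# ---------------------------------------------------------------------------
# restriction and congruence
# ---------------------------------------------------------------------------

def restrict(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    """Restrict *tree* to the leaf set *keep*.

    Unary internal nodes are suppressed with their branch lengths summed;
    if the root becomes unary it is suppressed too, so the result's root is
    the MRCA of *keep* and a restriction to S species has 2|S|-2 edges on a
    binary tree.
    """
    keep = set(keep)
    missing = keep - tree.leaf_labels
    if missing:
        raise TreeValidationError(f"species not in tree: {sorted(missing)}")
    if len(keep) < 2:
        raise TreeValidationError("restriction needs at least 2 species")

    def walk(node: int) -> _Nested | None:
        length = float(tree.lengths[node]) if not np.isnan(tree.lengths[node]) else None
        if tree.is_leaf(node):
            if tree.labels[node] in keep:
                return (tree.labels[node], length, [])
            return None
        kept = [w for w in (walk(c) for c in tree.children[node]) if w is not None]
        if not kept:
            return None
        if len(kept) == 1:  # unary: splice, summing lengths
            lab, sub_len, kids = kept[0]
            total = None
            if sub_len is not None or length is not None:
                total = (sub_len or 0.0) + (length or 0.0)
            return (lab, total, kids)
        return (None, length, kept)

    nested = walk(tree.root)
    assert nested is not None
    return _build_canonical(nested)


def validate_congruence(
    gene: PhyloTree, master: PhyloTree
) -> tuple[bool, list[frozenset[str]]]:
    """Check that *gene*'s topology equals *master* restricted to its leaves.

    Returns ``(ok, mismatched_clades)`` where the report lists leaf sets
    (rooted bipartitions) present in exactly one of the two topologies.

    Raises
    ------
    TreeValidationError
        If the gene tree contains a leaf absent from the master tree.
    """
    extra = gene.leaf_labels - master.leaf_labels
    if extra:
        raise TreeValidationError(f"gene leaves not in master: {sorted(extra)}")
    if len(gene.leaf_labels) < 2:
        return True, []
    ref = restrict(master, gene.leaf_labels)
    a, b = gene.clades(), ref.clades()
    mismatch = sorted(a ^ b, key=lambda s: (len(s), sorted(s)))
    return not mismatch, mismatch


# ---------------------------------------------------------------------------
# gene tree sets
# ---------------------------------------------------------------------------

@dataclass
class GeneTreeSet:
    """A master species tree plus congruent per-gene trees."""

    master: PhyloTree
    genes: dict[str, PhyloTree] = field(default_factory=dict)

    @property
    def species(self) -> set[str]:
        """Union of all gene leaf sets (the species universe)."""
        out: set[str] = set()
        for t in self.genes.values():
            out |= t.leaf_labels
        return out

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.genes)

    def validate(self, drop_incongruent: bool = False) -> dict[str, list]:
        """Validate every gene tree against the master.

        Returns a report mapping gene id -> mismatched clades for offending
        genes.  With ``drop_incongruent`` they are removed, otherwise a
        :class:`CongruenceError` is raised on the first conflict.
        """
        report: dict[str, list] = {}
        for gid in list(self.genes):
            ok, mism = validate_congruence(self.genes[gid], self.master)
            if not ok:
                report[gid] = mism
                if drop_incongruent:
                    del self.genes[gid]
                else:
                    raise CongruenceError(
                        f"gene {gid!r} conflicts with master on {len(mism)} clade(s)"
                    )
        return report


def read_gene_trees(path: str | os.PathLike) -> dict[str, PhyloTree]:
    """Read gene trees from a multi-tree file.

    Each non-empty line is either ``gene_id<TAB>newick`` or a bare Newick
    string (genes are then named ``gene_0001`` ... in file order).
    """
    genes: dict[str, PhyloTree] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if "\t" in line:
                gid, nwk = line.split("\t", 1)
                gid = gid.strip()
            else:
                gid, nwk = f"gene_{i:04d}", line
            if gid in genes:
                raise TreeValidationError(f"duplicate gene id {gid!r} at line {i}")
            try:
                genes[gid] = read_newick(nwk, require_lengths=True)
            except (NewickError, TreeValidationError) as exc:
                raise type(exc)(f"gene {gid!r} (line {i}): {exc}") from exc
    return genes


def load_gene_tree_set(
    master_path: str | os.PathLike,
    trees_path: str | os.PathLike,
    drop_incongruent: bool = False,
) -> tuple[GeneTreeSet, dict[str, list]]:
    """Load master + gene trees from disk and validate congruence.

    Returns the validated :class:`GeneTreeSet` and the incongruence report
    (empty when all genes pass).
    """
    with open(master_path) as fh:
        master = read_newick(fh.read(), require_lengths=False)
    gts = GeneTreeSet(master=master, genes=read_gene_trees(trees_path))
    not_in_master = gts.species - master.leaf_labels
    if not_in_master:
        raise TreeValidationError(
            f"gene tree species absent from master: {sorted(not_in_master)[:10]}"
        )
    report = gts.validate(drop_incongruent=drop_incongruent)
    return gts, report
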