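"""Precomputed pruning paths: the feature-by-path matrix and its index.

Pruning a tree to a species subset turns ancestor-descendant *paths* of the
full topology into *edges* of the pruned topology.  We therefore precompute,
for every gene, the length of every path it can ever contribute (one entry
per (node, proper-ancestor) pair realizable on that gene's restricted
topology), and store them in a single genes x paths matrix.  Retrieving the
branch-length vector of a gene pruned to any species set then reduces to a
cached topology lookup plus one row/column indexing operation — no tree
surgery in the inner loop.

Path ids are ordered pairs ``(descendant, ancestor)`` of *master-topology*
node ids, so all genes share one coordinate system and per-pair work is a
set operation.

Rooting convention: trees are rooted as written; when pruning leaves the
root unary it is suppressed and the two root-adjacent paths merge, so a
pruned tree on S species has 2|S|-2 edges (binary master).  This is also
the branch count ``n`` used downstream in the Fisher transform.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np

from ercov.tree_io import GeneTreeSet, PhyloTree, read_newick, write_newick

__all__ = ["PathIndex", "PathLookupError"]

PathId = tuple[int, int]  # (descendant master node, ancestor master node)


class PathLookupError(KeyError):
    """A requested path is not realizable on a gene's restricted topology."""


def _master_node_map(gene: PhyloTree, master: PhyloTree) -> list[int]:
    """Map each gene-tree node to its master-topology node id.

    Leaves map by label; internal nodes map to the master MRCA of their
    descendant leaves.  Raises if the mapping is not ancestor-consistent,
    which happens exactly when the gene tree is incongruent.
    """
    mapping = [0] * gene.n_nodes
    for v in range(gene.n_nodes):
        if gene.is_leaf(v):
            mapping[v] = master.leaf_id(gene.labels[v])
        else:
            mapping[v] = master.mrca(gene.leafset(v))
    return mapping


class PathIndex:
    """All-gene path table plus species-set -> pruned-edge cache.

    Parameters
    ----------
    gene_set : GeneTreeSet
        Master tree and congruent gene trees (validate before building).

    Attributes
    ----------
    matrix : numpy.ndarray
        Dense genes x paths array of path lengths; NaN where a path is not
        realizable on a gene's leaf set (the feature-by-path matrix).
    path_ids : list[PathId]
        Column order of ``matrix``; pairs of master node ids.
    """

    def __init__(self, gene_set: GeneTreeSet):
        self.master = gene_set.master
        self.gene_ids: list[str] = gene_set.gene_ids
        self._gene_pos = {g: i for i, g in enumerate(self.gene_ids)}
        self.gene_leaves: dict[str, frozenset[str]] = {
            g: frozenset(gene_set.genes[g].leaf_labels) for g in self.gene_ids
        }

        # registry of all (node, proper ancestor) pairs on the master
        master = self.master
        self.path_ids: list[PathId] = []
        self._col: dict[PathId, int] = {}
        for d in master.preorder():
            if d == master.root:
                continue
            for a in master.ancestors(d):
                self._col[(d, a)] = len(self.path_ids)
                self.path_ids.append((d, a))

        self.matrix = np.full((len(self.gene_ids), len(self.path_ids)), np.nan)
        for g in self.gene_ids:
            self._fill_gene_row(gene_set.genes[g], self._gene_pos[g])

        self._prune_cache: dict[frozenset[str], tuple[tuple[PathId, ...], np.ndarray]] = {}

    def _fill_gene_row(self, gene: PhyloTree, row: int) -> None:
        mmap = _master_node_map(gene, self.master)
        master_anc = {
            v: set(self.master.ancestors(v)) for v in set(mmap)
        }
        for v in range(gene.n_nodes):
            if v == gene.root:
                continue
            acc = 0.0
            u = v
            while u != gene.root:
                acc += float(gene.lengths[u])
                p = gene.parent[u]
                key = (mmap[v], mmap[p])
                if mmap[p] not in master_anc[mmap[v]]:
                    raise ValueError(
                        "gene tree incongruent with master (validate first)"
                    )
                self.matrix[row, self._col[key]] = acc
                u = p

    # -- pruning ---------------------------------------------------------
    def prune_edges(self, species: Iterable[str]) -> list[PathId]:
        """Path ids that are exactly the edges of the master pruned to *species*.

        Deterministic order (master preorder of the descendant endpoint);
        results are cached by species set, and repeated calls return
        identical lists.
        """
        return list(self._prune(frozenset(species))[0])

    def _prune(self, key: frozenset[str]) -> tuple[tuple[PathId, ...], np.ndarray]:
        hit = self._prune_cache.get(key)
        if hit is not None:
            return hit
        master = self.master
        if len(key) < 2:
            raise ValueError("pruning needs at least 2 species")
        missing = key - master.leaf_labels
        if missing:
            raise ValueError(f"species not in master: {sorted(missing)}")

        n = master.n_nodes
        kept_leaves = np.zeros(n, dtype=np.int64)
        for lab in key:
            kept_leaves[master.leaf_id(lab)] = 1
        # postorder accumulation of kept-leaf counts and retained flags
        counts = kept_leaves.copy()
        retained = kept_leaves.astype(bool)
        for v in master.postorder():
            kids = master.children[v]
            if kids:
                sub = [counts[c] for c in kids]
                counts[v] = sum(sub)
                nonzero = sum(1 for s in sub if s > 0)
                retained[v] = nonzero >= 2
        root_of_pruned = master.mrca(key)
        retained[root_of_pruned] = True

        edges: list[PathId] = []
        for d in master.preorder():
            if not retained[d] or d == root_of_pruned or counts[d] == 0:
                continue
            # skip retained nodes outside the pruned subtree
            a = master.parent[d]
            inside = False
            u = d
            while u != -1:
                if u == root_of_pruned:
                    inside = True
                    break
                u = master.parent[u]
            if not inside:
                continue
            while not retained[a] or counts[a] == 0:
                a = master.parent[a]
            edges.append((d, a))
        cols = np.array([self._col[e] for e in edges], dtype=np.intp)
        out = (tuple(edges), cols)
        self._prune_cache[key] = out
        return out

    # -- vector retrieval ------------------------------------------------
    def branch_vector(
        self, gene_id: str, edges: Sequence[PathId], strict: bool = True
    ) -> np.ndarray:
        """Branch lengths of *gene_id* on the pruned topology given by *edges*.

        The result is aligned to the edge list order and equals the naive
        "prune this gene tree, then read off branch lengths" computation.
        With ``strict`` (default), an edge not realizable on the gene's leaf
        set raises :class:`PathLookupError`; otherwise it yields NaN.
        """
        row = self.matrix[self._gene_pos[gene_id]]
        cols = np.array([self._col[tuple(e)] for e in edges], dtype=np.intp)
        vec = row[cols]
        if strict and np.isnan(vec).any():
            bad = [e for e, v in zip(edges, vec) if np.isnan(v)]
            raise PathLookupError(
                f"gene {gene_id!r} does not realize path(s) {bad[:5]}"
            )
        return vec

    def submatrix(self, species: frozenset[str]) -> tuple[tuple[PathId, ...], np.ndarray]:
        """Edges of the master pruned to *species* and the genes x edges slice
        of the path matrix (NaN where a gene does not realize an edge)."""
        edges, cols = self._prune(species)
        return edges, self.matrix[:, cols]

    def path_length_naive(self, gene: PhyloTree, d: int, a: int) -> float:
        """On-demand path length by walking the gene tree (lazy evaluation).

        Independent of the precomputed row fill except for the node mapping;
        used for the lazy/full agreement contract and memory-capped builds.
        """
        mmap = _master_node_map(gene, self.master)
        inv = {m: g for g, m in enumerate(mmap)}
        if d not in inv or a not in inv:
            raise PathLookupError(f"path ({d},{a}) not on gene topology")
        acc = 0.0
        u = inv[d]
        while u != gene.root and mmap[u] != a:
            acc += float(gene.lengths[u])
            u = gene.parent[u]
        if mmap[u] != a:
            raise PathLookupError(f"{a} is not an ancestor of {d} on the gene tree")
        return acc

    # -- serialization ---------------------------------------------------
    def save(self, path: str | os.PathLike) -> None:
        """Serialize the table + registry to a single ``.npz`` container."""
        np.savez_compressed(
            path,
            matrix=self.matrix,
            path_desc=np.array([p[0] for p in self.path_ids], dtype=np.int64),
            path_anc=np.array([p[1] for p in self.path_ids], dtype=np.int64),
            gene_ids=np.array(self.gene_ids, dtype=object),
            gene_leaves=np.array(
                ["\x1f".join(sorted(self.gene_leaves[g])) for g in self.gene_ids],
                dtype=object,
            ),
            master_newick=np.array([write_newick(self.master)], dtype=object),
        )

    @classmethod
    def load(cls, path: str | os.PathLike) -> "PathIndex":
        with np.load(path, allow_pickle=True) as z:
            obj = cls.__new__(cls)
            obj.master = read_newick(str(z["master_newick"][0]), require_lengths=False)
            obj.gene_ids = [str(g) for g in z["gene_ids"]]
            obj._gene_pos = {g: i for i, g in enumerate(obj.gene_ids)}
            obj.gene_leaves = {
                g: frozenset(s.split("\x1f"))
                for g, s in zip(obj.gene_ids, z["gene_leaves"])
            }
            obj.path_ids = [
                (int(d), int(a)) for d, a in zip(z["path_desc"], z["path_anc"])
            ]
            obj._col = {p: i for i, p in enumerate(obj.path_ids)}
            obj.matrix = np.asarray(z["matrix"], dtype=float)
            obj._prune_cache = {}
        return obj

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<PathIndex {len(self.gene_ids)} genes x {len(self.path_ids)} paths, "
            f"{len(self._prune_cache)} cached prunings>"
        )
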