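"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ercov.simulate import SimConfig, simulate
from ercov.tree_io import PhyloTree, read_newick

TOY_NEWICK = "((A:1,B:2):1,(C:3,D:1):2);"


@pytest.fixture
def toy_master() -> PhyloTree:
    """4-leaf balanced rooted tree used across the examples."""
    return read_newick(TOY_NEWICK)


@pytest.fixture(scope="session")
def small_dataset():
    """Modest simulated dataset shared by read-only tests."""
    cfg = SimConfig(
        n_species=20, n_genes=40, module_sizes=(8, 8), missingness=0.1, seed=11
    )
    return simulate(cfg)


# ---------------------------------------------------------------------------
# naive pruning oracle (independent of ercov.path_index and ercov.tree_io's
# restrict): recursive collapse over the stored parent/child structure.
# ---------------------------------------------------------------------------

def naive_pruned_lengths(tree: PhyloTree, keep: set[str]) -> dict[frozenset, float]:
    """Brute-force prune-and-read: map each pruned-tree edge (identified by
    the set of kept leaves below it) to its branch length."""

    def walk(v):
        # returns (leafset, pending_length, children_list) or None
        length = float(tree.lengths[v]) if not np.isnan(tree.lengths[v]) else 0.0
        if not tree.children[v]:
            if tree.labels[v] in keep:
                return (frozenset([tree.labels[v]]), length, [])
            return None
        kids = [w for w in (walk(c) for c in tree.children[v]) if w is not None]
        if not kids:
            return None
        if len(kids) == 1:
            ls, klen, kkids = kids[0]
            return (ls, klen + length, kkids)
        leafset = frozenset().union(*(k[0] for k in kids))
        return (leafset, length, kids)

    top = walk(tree.root)
    assert top is not None, "no kept leaves"
    out: dict[frozenset, float] = {}

    def emit(node):
        for ls, length, kids in node[2]:
            out[ls] = length
            emit((ls, length, kids))

    emit(top)
    return out


def random_tree_set(seed: int, n_leaves: int, n_genes: int = 1):
    """Random master + congruent gene trees with independently jittered
    branch lengths (for oracle-equivalence checks)."""
    from ercov.simulate import _birth_death_master
    from ercov.tree_io import GeneTreeSet, restrict

    rng = np.random.default_rng(seed)
    master = _birth_death_master(n_leaves, seed, total_length=float(n_leaves) / 4)
    genes = {}
    species = sorted(master.leaf_labels)
    for g in range(n_genes):
        lengths = master.lengths * np.exp(rng.normal(0, 0.4, master.n_nodes))
        full = master.with_lengths(lengths)
        n_keep = int(rng.integers(4, len(species) + 1))
        keep = list(rng.choice(species, size=n_keep, replace=False))
        genes[f"g{g:03d}"] = restrict(full, keep) if n_keep < len(species) else full
    return GeneTreeSet(master=master, genes=genes)
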