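"""All-pairs evolutionary rate covariation (ERC).

For every gene pair, the shared species set defines a pruned topology; the
two genes' RER vectors on that topology are Pearson-correlated and the
correlation is variance-stabilized with the Fisher transform

    FtERC = arctanh(r) * sqrt(n - 3),

where ``n`` is the number of branches of the shared pruned topology (2|S|-2
under the rooting convention of :mod:`ercov.path_index`).  The null
expectation of no covariation stays at zero, and FtERC values are
approximately standard normal under the null regardless of ``n``, so scores
are comparable across gene pairs and across taxa.

Pairs are grouped by shared-species key so the pruned topology, the
expected tree, and each member gene's RER vector are computed once per
distinct intersection — the main source of the speedup alongside the path
index.  Groups are processed in deterministic key order and merged by
gene-id order, so results are independent of thread count.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from ercov.path_index import PathIndex
from ercov.rer import RERError, compute_rer, fit_expected_tree

__all__ = ["pearson", "fisher_transform", "all_pairs_erc", "ERCResult", "ERCConfig"]

_CLAMP = 1.0 - 1e-12


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two equal-length vectors.

    Raises ``ValueError`` on length < 3 or zero variance in either vector
    (downstream, such pairs are skipped and logged rather than fatal).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson needs two equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("pearson needs at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance: correlation undefined")
    r = float(xc @ yc) / math.sqrt(sx * sy)
    return max(-1.0, min(1.0, r))


def fisher_transform(r: float, n: int) -> float:
    """Fisher-transformed ERC: ``arctanh(r) * sqrt(n - 3)``.

    ``r`` is the correlation coefficient and ``n`` the number of branches
    that produced it.  ``r = 0`` maps to exactly 0 for any ``n``.  Values
    with |r| within 1e-12 of 1 are clamped to keep the result finite
    (degenerate pairs; callers flag the clamp).
    """
    if n < 4:
        raise ValueError(f"fisher transform needs n >= 4 branches, got {n}")
    if abs(r) > 1.0:
        raise ValueError(f"|r| > 1: {r}")
    if r == 0.0:
        return 0.0
    r = max(-_CLAMP, min(_CLAMP, float(r)))
    return math.atanh(r) * math.sqrt(n - 3)


@dataclass
class ERCConfig:
    """Knobs for the all-pairs computation (defaults match the CLI)."""

    corrected: bool = True
    min_species: int = 10
    min_genes: int = 5
    min_edges: int = 5
    n_bins: int = 10
    reweight_iters: int = 2
    threads: int = 1


@dataclass
class ERCResult:
    """Symmetric gene x gene FtERC matrix with branch counts.

    ``fterc`` and ``r`` are float32 with NaN for missing/skipped pairs and
    on the diagonal (self-pairs are not applicable, never zero-filled);
    ``n`` holds the branch count per pair (0 where missing).
    """

    gene_ids: list[str]
    fterc: np.ndarray
    r: np.ndarray
    n: np.ndarray
    skips: Counter = field(default_factory=Counter)
    n_clamped: int = 0
    config: ERCConfig = field(default_factory=ERCConfig)

    def __post_init__(self):
        self._pos = {g: i for i, g in enumerate(self.gene_ids)}

    def index_of(self, gene: str) -> int:
        return self._pos[gene]

    def pair_values(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Upper-triangle (fterc, r, n) arrays over all gene pairs."""
        iu = np.triu_indices(len(self.gene_ids), k=1)
        return self.fterc[iu], self.r[iu], self.n[iu]

    # -- I/O -------------------------------------------------------------
    def save(self, prefix: str) -> None:
        """Write ``<prefix>.npz`` (matrices) plus TSV matrices and the
        pair-skip report ``<prefix>.skips.tsv``."""
        np.savez_compressed(
            prefix + ".npz",
            gene_ids=np.array(self.gene_ids, dtype=object),
            fterc=self.fterc,
            r=self.r,
            n=self.n,
            n_clamped=np.array([self.n_clamped]),
            skips=np.array(sorted(self.skips.items()), dtype=object),
        )
        pd.DataFrame(self.fterc, index=self.gene_ids, columns=self.gene_ids).to_csv(
            prefix + ".fterc.tsv", sep="\t", float_format="%.6g"
        )
        pd.DataFrame(self.n, index=self.gene_ids, columns=self.gene_ids).to_csv(
            prefix + ".n.tsv", sep="\t"
        )
        with open(prefix + ".skips.tsv", "w") as fh:
            fh.write("reason\tn_pairs\n")
            for reason, count in sorted(self.skips.items()):
                fh.write(f"{reason}\t{count}\n")

    @classmethod
    def load(cls, prefix: str) -> "ERCResult":
        with np.load(prefix + ".npz", allow_pickle=True) as z:
            skips = Counter({str(k): int(v) for k, v in z["skips"]})
            return cls(
                gene_ids=[str(g) for g in z["gene_ids"]],
                fterc=np.asarray(z["fterc"]),
                r=np.asarray(z["r"]),
                n=np.asarray(z["n"]),
                skips=skips,
                n_clamped=int(z["n_clamped"][0]),
            )


def _process_group(
    index: PathIndex,
    key: frozenset,
    pairs: list[tuple[int, int]],
    cfg: ERCConfig,
) -> tuple[list[tuple[int, int, float, float, int, bool]], Counter]:
    """Compute ERC for all pairs sharing one species intersection."""
    out: list[tuple[int, int, float, float, int, bool]] = []
    skips: Counter = Counter()
    edges, L = index.submatrix(key)
    try:
        expected = fit_expected_tree(L, min_genes=cfg.min_genes)
    except RERError:
        skips["expected_tree_unfit"] += len(pairs)
        return out, skips
    n_edges = int(expected.edge_mask.sum())
    if n_edges < max(cfg.min_edges, 4):
        skips["too_few_edges"] += len(pairs)
        return out, skips
    Lu = L[:, expected.edge_mask]
    mu = expected.mu

    rers: dict[int, np.ndarray | None] = {}

    def rer_of(g: int):
        if g not in rers:
            try:
                rers[g] = compute_rer(
                    Lu[g],
                    mu,
                    corrected=cfg.corrected,
                    n_bins=cfg.n_bins,
                    reweight_iters=cfg.reweight_iters,
                    min_edges=cfg.min_edges,
                )
            except RERError:
                rers[g] = None
        return rers[g]

    for i, j in pairs:
        ri, rj = rer_of(i), rer_of(j)
        if ri is None or rj is None:
            skips["rer_failed"] += 1
            continue
        try:
            r = pearson(ri, rj)
        except ValueError:
            skips["zero_variance"] += 1
            continue
        clamped = abs(r) >= _CLAMP
        ft = fisher_transform(r, n_edges)
        out.append((i, j, ft, r, n_edges, clamped))
    return out, skips


def all_pairs_erc(
    index: PathIndex,
    config: ERCConfig | None = None,
    genes: Iterable[str] | None = None,
    **kwargs,
) -> ERCResult:
    """Compute the symmetric FtERC matrix over all gene pairs.

    Parameters
    ----------
    index : PathIndex
        Prebuilt path index over a validated gene tree set.
    config : ERCConfig, optional
        Computation knobs; keyword overrides (e.g. ``corrected=False``,
        ``min_species=10``, ``threads=4``) are applied on top.
    genes : iterable of str, optional
        Restrict to a subset of gene ids (default: all genes in the index).

    Pairs failing a precondition are left missing with a coded reason in
    ``result.skips``; nothing is fatal at the pair level.
    """
    cfg = config or ERCConfig()
    for k, v in kwargs.items():
        if not hasattr(cfg, k):
            raise TypeError(f"unknown config field {k!r}")
        setattr(cfg, k, v)

    gene_ids = sorted(genes) if genes is not None else list(index.gene_ids)
    pos = {g: i for i, g in enumerate(gene_ids)}
    G = len(gene_ids)
    fterc = np.full((G, G), np.nan, dtype=np.float32)
    rmat = np.full((G, G), np.nan, dtype=np.float32)
    nmat = np.zeros((G, G), dtype=np.int32)
    skips: Counter = Counter()
    n_clamped = 0

    # group pairs by shared-species intersection
    groups: dict[frozenset, list[tuple[int, int]]] = defaultdict(list)
    leaves = {g: index.gene_leaves[g] for g in gene_ids}
    for a_i in range(G):
        for a_j in range(a_i + 1, G):
            key = leaves[gene_ids[a_i]] & leaves[gene_ids[a_j]]
            if len(key) < cfg.min_species:
                skips["too_few_shared_species"] += 1
                continue
            groups[key].append((a_i, a_j))

    ordered_keys = sorted(groups, key=lambda s: tuple(sorted(s)))

    def row_index_pairs(key):
        # map result positions back to path-index rows once per group
        return [
            (index._gene_pos[gene_ids[i]], index._gene_pos[gene_ids[j]])
            for (i, j) in groups[key]
        ]

    def run(key):
        idx_pairs = row_index_pairs(key)
        res, sk = _process_group(index, key, idx_pairs, cfg)
        return key, res, sk

    if cfg.threads > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=cfg.threads, backend="threading")(
            delayed(run)(k) for k in ordered_keys
        )
    else:
        results = [run(k) for k in ordered_keys]

    back = {index._gene_pos[g]: pos[g] for g in gene_ids}
    for key, res, sk in results:  # deterministic merge in key order
        skips.update(sk)
        for gi, gj, ft, r, n, clamped in res:
            i, j = back[gi], back[gj]
            fterc[i, j] = fterc[j, i] = ft
            rmat[i, j] = rmat[j, i] = r
            nmat[i, j] = nmat[j, i] = n
            if clamped:
                n_clamped += 1

    return ERCResult(
        gene_ids=gene_ids,
        fterc=fterc,
        r=rmat,
        n=nmat,
        skips=skips,
        n_clamped=n_clamped,
        config=cfg,
    )
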