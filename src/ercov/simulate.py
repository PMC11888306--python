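"""Synthetic gene-tree datasets with known co-functional structure.

The generator emulates the features of real comparative-genomics tree sets
that matter to the pipeline: per-gene species missingness (each gene's tree
covers a random subset of the species), gene-specific average rates,
branch-specific rate shifts shared within co-functional gene modules, and
multiplicative noise.  Branch lengths for gene ``g`` on master branch ``b``
are

    l_{g,b} = t_b * r_g * exp(sigma_shared * f_{m(g),b} + sigma_noise * eps_{g,b})

with ``t_b`` the master branch lengths, ``r_g`` log-normal per-gene rates,
``f`` a per-(module, branch) latent factor shared by all module members
(absent for null genes), and ``eps`` independent standard normal.  The
log-normal noise is deliberately multiplicative so raw branch lengths are
heteroskedastic — variance grows with the mean — giving the RER correction
something real to remove.  Species are then dropped independently per gene
and the tree restricted (path lengths summed), so every simulated gene tree
is congruent with the master by construction.
"""

from __future__ import annotations

import json
import os
import random as _random
from dataclasses import asdict, dataclass, field

import dendropy
import numpy as np

from ercov.tree_io import GeneTreeSet, PhyloTree, read_newick, restrict, write_newick

__all__ = ["SimConfig", "SimTruth", "simulate", "write_dataset", "benchmark",
           "calibration_config"]


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults are the package's reference conditions: a 50-species
    birth-death master tree rescaled to total length 10 substitutions/site
    (a yeast-like divergence scale), 200 genes of which 4 modules of 10 are
    co-functional, module factor sd 0.5, multiplicative noise sd 0.3, and
    10% per-gene per-species missingness.
    """

    n_species: int = 50
    master_newick: str | None = None  # overrides the birth-death master
    n_genes: int = 200
    module_sizes: tuple[int, ...] = (10, 10, 10, 10)
    sigma_shared: float = 0.5
    sigma_noise: float = 0.3
    rate_meanlog: float = 0.0
    rate_sdlog: float = 0.5
    missingness: float | tuple[float, float] = 0.1  # scalar, or per-gene U(lo, hi)
    total_tree_length: float = 10.0
    min_species_per_gene: int = 4
    seed: int = 0

    def validate(self) -> None:
        if self.sigma_shared < 0 or self.sigma_noise < 0 or self.rate_sdlog < 0:
            raise ValueError("all sds must be >= 0")
        lo, hi = self.missingness_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("missingness must lie in [0, 1)")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")

    @property
    def missingness_range(self) -> tuple[float, float]:
        if isinstance(self.missingness, (tuple, list)):
            lo, hi = self.missingness
            return float(lo), float(hi)
        return float(self.missingness), float(self.missingness)


def calibration_config(seed: int = 0, n_genes: int = 200) -> SimConfig:
    """Null-calibration conditions with branch counts spanning ~20-200.

    All genes are null (no modules); 110 species with heterogeneous
    per-gene missingness U(0.05, 0.9) make pairwise shared-branch counts
    range from ~20 to ~200, the regime where the Fisher transform's
    variance stabilization is visible against raw Pearson correlations.
    """
    return SimConfig(
        n_species=110,
        n_genes=n_genes,
        module_sizes=(),
        sigma_shared=0.0,
        missingness=(0.05, 0.9),
        seed=seed,
    )


@dataclass
class SimTruth:
    """Ground truth serialized alongside the simulated trees."""

    module_of: dict[str, int | None]  # gene -> module id (None for null genes)
    factors: dict[int, list[float]]  # module -> per-master-edge latent factor
    dropped: dict[str, list[str]]  # gene -> species removed
    rates: dict[str, float]  # gene -> average-rate multiplier r_g
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "module_of": self.module_of,
            "factors": {str(k): v for k, v in self.factors.items()},
            "dropped": self.dropped,
            "rates": self.rates,
            "config": self.config,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        return cls(
            module_of={k: v for k, v in d["module_of"].items()},
            factors={int(k): v for k, v in d["factors"].items()},
            dropped={k: list(v) for k, v in d["dropped"].items()},
            rates=d["rates"],
            config=d.get("config", {}),
        )

    def module_pairs(self, gene_ids: list[str]) -> dict[str, list[tuple[int, int]]]:
        """Index pairs by class: 'within' (same module) and 'null' (both
        genes unassigned), over the given gene-id ordering."""
        pos = {g: i for i, g in enumerate(gene_ids)}
        within, null = [], []
        for a in range(len(gene_ids)):
            for b in range(a + 1, len(gene_ids)):
                ma = self.module_of.get(gene_ids[a])
                mb = self.module_of.get(gene_ids[b])
                if ma is not None and ma == mb:
                    within.append((pos[gene_ids[a]], pos[gene_ids[b]]))
                elif ma is None and mb is None:
                    null.append((pos[gene_ids[a]], pos[gene_ids[b]]))
        return {"within": within, "null": null}


def _birth_death_master(n_species: int, seed: int, total_length: float) -> PhyloTree:
    rng = _random.Random(seed)
    dtree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.4,
        num_extant_tips=n_species,
        rng=rng,
    )
    for i, leaf in enumerate(dtree.leaf_node_iter()):
        leaf.taxon.label = f"s{i + 1:03d}"
    text = dtree.as_string(schema="newick", suppress_rooting=True)
    tree = read_newick(text, require_lengths=True)
    scale = total_length / tree.total_length()
    lengths = tree.lengths * scale
    return tree.with_lengths(lengths)


def simulate(config: SimConfig) -> tuple[GeneTreeSet, SimTruth]:
    """Generate a gene-tree dataset plus its ground truth.

    Deterministic given ``config.seed``; every gene tree is congruent with
    the master by construction.  A gene left with fewer than
    ``min_species_per_gene`` species by missingness is resampled (up to 100
    tries) before erroring.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.master_newick is not None:
        master = read_newick(config.master_newick, require_lengths=True)
    else:
        master = _birth_death_master(
            config.n_species, config.seed, config.total_tree_length
        )
    species = sorted(master.leaf_labels)
    n_edges = master.n_nodes  # per-node vector; root entry unused
    t = master.lengths

    width = max(4, len(str(config.n_genes)))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(config.n_genes)]
    module_of: dict[str, int | None] = {}
    k = 0
    for m, size in enumerate(config.module_sizes):
        for _ in range(size):
            module_of[gene_ids[k]] = m
            k += 1
    for g in gene_ids[k:]:
        module_of[g] = None

    factors = {
        m: rng.standard_normal(n_edges) for m in range(len(config.module_sizes))
    }
    rates = np.exp(rng.normal(config.rate_meanlog, config.rate_sdlog, config.n_genes))
    lo, hi = config.missingness_range

    genes: dict[str, PhyloTree] = {}
    dropped: dict[str, list[str]] = {}
    for gi, gid in enumerate(gene_ids):
        m = module_of[gid]
        shared = config.sigma_shared * factors[m] if m is not None else 0.0
        eps = rng.standard_normal(n_edges)
        lengths = t * rates[gi] * np.exp(shared + config.sigma_noise * eps)
        full = master.with_lengths(lengths)

        p = rng.uniform(lo, hi) if hi > lo else lo
        keep: list[str] = []
        for attempt in range(100):
            drop_mask = rng.random(len(species)) < p
            keep = [s for s, d in zip(species, drop_mask) if not d]
            if len(keep) >= config.min_species_per_gene:
                break
        else:
            raise ValueError(
                f"gene {gid}: fewer than {config.min_species_per_gene} species "
                f"after 100 missingness draws (p={p})"
            )
        genes[gid] = restrict(full, keep) if len(keep) < len(species) else full
        dropped[gid] = sorted(set(species) - set(keep))

    truth = SimTruth(
        module_of=module_of,
        factors={m: f.tolist() for m, f in factors.items()},
        dropped=dropped,
        rates={g: float(r) for g, r in zip(gene_ids, rates)},
        config={**asdict(config), "missingness": list(config.missingness_range)},
    )
    return GeneTreeSet(master=master, genes=genes), truth


def write_dataset(gts: GeneTreeSet, truth: SimTruth, out_dir: str | os.PathLike) -> None:
    """Write master.nwk, genes.nwk (one ``gene<TAB>newick`` per line) and
    truth.json; byte-identical for identical configs."""
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "master.nwk"), "w") as fh:
        fh.write(write_newick(gts.master) + "\n")
    with open(os.path.join(out_dir, "genes.nwk"), "w") as fh:
        for gid in gts.gene_ids:
            fh.write(f"{gid}\t{write_newick(gts.genes[gid])}\n")
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        fh.write(truth.to_json() + "\n")


# ---------------------------------------------------------------------------
# benchmark
# ---------------------------------------------------------------------------

def benchmark(
    config: SimConfig,
    methods: tuple[str, ...] = ("pearson_raw", "fterc_uncorrected", "fterc_corrected"),
    n_bins: int = 5,
    min_species: int = 10,
) -> dict:
    """Calibration + power report for the scoring methods on one dataset.

    For each method: null-pair score mean/sd binned into ``n_bins``
    equal-count bins of branch count n, and the ROC AUC separating
    within-module pairs from null pairs.  Returns a JSON-serializable dict.
    """
    from sklearn.metrics import roc_auc_score

    from ercov.erc import all_pairs_erc
    from ercov.path_index import PathIndex

    allowed = {"pearson_raw", "fterc_uncorrected", "fterc_corrected"}
    bad = set(methods) - allowed
    if bad:
        raise ValueError(f"unknown methods: {sorted(bad)}")

    gts, truth = simulate(config)
    index = PathIndex(gts)
    results = {}
    if {"fterc_corrected", "pearson_raw"} & set(methods):
        results["corrected"] = all_pairs_erc(index, corrected=True, min_species=min_species)
    if "fterc_uncorrected" in methods:
        results["uncorrected"] = all_pairs_erc(index, corrected=False, min_species=min_species)

    base = results.get("corrected") or results["uncorrected"]
    classes = truth.module_pairs(base.gene_ids)

    def scores_for(method: str) -> tuple[np.ndarray, np.ndarray]:
        res = results["uncorrected" if method == "fterc_uncorrected" else "corrected"]
        ft, r, n = res.pair_values()
        return (r if method == "pearson_raw" else ft), n

    report: dict = {"methods": {}, "config": {**asdict(config),
                    "missingness": list(config.missingness_range)}}
    for method in methods:
        vals, ns = scores_for(method)
        G = len(base.gene_ids)
        iu = np.triu_indices(G, k=1)
        flat_pos = {(i, j): k for k, (i, j) in enumerate(zip(iu[0], iu[1]))}
        null_idx = [flat_pos[p] for p in classes["null"]]
        within_idx = [flat_pos[p] for p in classes["within"]]

        nv = vals[null_idx]
        nn = ns[null_idx]
        ok = ~np.isnan(nv)
        nv, nn = nv[ok], nn[ok]
        bins = []
        if nv.size >= n_bins:
            order = np.argsort(nn, kind="stable")
            for chunk in np.array_split(order, n_bins):
                bins.append(
                    {
                        "n_mean": float(nn[chunk].mean()),
                        "score_mean": float(nv[chunk].mean()),
                        "score_sd": float(nv[chunk].std(ddof=1)),
                        "n_pairs": int(chunk.size),
                    }
                )
        auc = None
        wv = vals[within_idx]
        wv = wv[~np.isnan(wv)]
        if wv.size and nv.size:
            y = np.r_[np.ones(wv.size), np.zeros(nv.size)]
            auc = float(roc_auc_score(y, np.r_[wv, nv]))
        sds = [b["score_sd"] for b in bins]
        report["methods"][method] = {
            "null_bins": bins,
            "null_mean": float(nv.mean()) if nv.size else None,
            "null_sd": float(nv.std(ddof=1)) if nv.size > 1 else None,
            "sd_ratio": (max(sds) / min(sds)) if sds and min(sds) > 0 else None,
            "auc_within_vs_null": auc,
        }
    return report
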