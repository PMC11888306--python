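"""Downstream consumption of an ERC matrix.

Three consumers are implemented:

* **Z-score query networks.**  Each gene's FtERC values form their own
  distribution, so scores are standardized per row; an edge connects two
  genes when their pairwise Z-score (max over the two row distributions)
  reaches the cutoff, default 3.  Network cohesion is tested against a
  random-graph null on the global clustering coefficient.
* **Thresholded edge export** for external Markov clustering tools — either
  the top fraction of pairs or all pairs with FtERC at or above a floor.
* **Elastic-net annotation models**: penalized logistic regression
  (mixing 0.5) over a descending regularization path with stratified
  cross-validation, reporting the best mean CV AUC and the 1-SE-rule value,
  plus class-probability predictions for unannotated genes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.special import expit
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from ercov.erc import ERCResult

__all__ = [
    "zscores_for_gene",
    "build_query_network",
    "clustering_null",
    "export_top_edges",
    "AnnotationSet",
    "read_gmt",
    "read_term_tsv",
    "feature_matrix",
    "TermModel",
    "TermSkip",
    "fit_annotation_model",
    "predict_unannotated",
]


# ---------------------------------------------------------------------------
# Z-scores and networks
# ---------------------------------------------------------------------------

def zscores_for_gene(
    result: ERCResult, gene: str, min_partners: int = 30
) -> np.ndarray:
    """Standardize one gene's FtERC row against its own distribution.

    Returns a vector aligned to ``result.gene_ids`` with
    ``Z = (FtERC - row mean) / row sd`` (sample sd, ddof=1); missing
    partners (and the self entry) stay NaN.
    """
    i = result.index_of(gene)
    row = np.asarray(result.fterc[i], dtype=float).copy()
    row[i] = np.nan
    vals = row[~np.isnan(row)]
    if vals.size < min_partners:
        raise ValueError(
            f"gene {gene!r} has only {vals.size} scored partners (< {min_partners})"
        )
    return (row - vals.mean()) / vals.std(ddof=1)


def build_query_network(
    result: ERCResult,
    queries: list[str],
    z_cutoff: float = 3.0,
    min_partners: int = 30,
) -> nx.Graph:
    """Z-score network around a set of query genes.

    Nodes are the queries plus every gene reaching ``Z >= z_cutoff``
    against at least one query; edges connect node pairs whose pairwise Z
    (the max over the two endpoints' own row distributions) reaches the
    cutoff.  Node attribute ``query`` flags the seeds; edges carry ``fterc``
    and ``z``.
    """
    unknown = [q for q in queries if q not in result._pos]
    if unknown:
        raise KeyError(f"query gene(s) not in matrix: {unknown}")
    genes = result.gene_ids
    zrows = {q: zscores_for_gene(result, q, min_partners=min_partners) for q in queries}

    hits: set[str] = set()
    for q in queries:
        z = zrows[q]
        for j in np.flatnonzero(~np.isnan(z) & (z >= z_cutoff)):
            hits.add(genes[j])
    nodes = sorted(set(queries) | hits)

    G = nx.Graph()
    for v in nodes:
        G.add_node(v, query=v in set(queries))

    def pair_z(a: str, b: str) -> float:
        best = -math.inf
        for u, v in ((a, b), (b, a)):
            if u in zrows:
                z = zrows[u][result.index_of(v)]
            else:
                row = np.asarray(result.fterc[result.index_of(u)], dtype=float).copy()
                row[result.index_of(u)] = np.nan
                vals = row[~np.isnan(row)]
                if vals.size < 2:
                    continue
                z = (row[result.index_of(v)] - vals.mean()) / vals.std(ddof=1)
            if not np.isnan(z):
                best = max(best, float(z))
        return best

    for ai in range(len(nodes)):
        for bi in range(ai + 1, len(nodes)):
            a, b = nodes[ai], nodes[bi]
            z = pair_z(a, b)
            if z >= z_cutoff:
                ft = float(result.fterc[result.index_of(a), result.index_of(b)])
                G.add_edge(a, b, fterc=ft, z=z)
    return G


def clustering_null(
    network: nx.Graph, n_random: int = 10000, seed: int = 0, degree_preserving: bool = False
) -> tuple[float, float, np.ndarray]:
    """Empirical p-value for the network's global clustering coefficient.

    The observed coefficient (3 x triangles / connected triples) is compared
    to ``n_random`` uniform random graphs with the same node and edge counts
    (Erdos-Renyi G(n, m); set ``degree_preserving`` for double-edge-swap
    rewiring instead).  Returns ``(coefficient, p, null_values)`` with
    ``p = (1 + #{null >= observed}) / (1 + n_random)``.
    """
    n, m = network.number_of_nodes(), network.number_of_edges()
    if n < 3 or m < 2:
        raise ValueError("degenerate network: need >= 3 nodes and >= 2 edges")
    observed = nx.transitivity(network)
    rng = np.random.default_rng(seed)
    null = np.empty(n_random)
    for i in range(n_random):
        s = int(rng.integers(0, 2**31 - 1))
        if degree_preserving:
            g = network.copy()
            nx.double_edge_swap(g, nswap=2 * m, max_tries=20 * m, seed=s)
        else:
            g = nx.gnm_random_graph(n, m, seed=s)
        null[i] = nx.transitivity(g)
    p = (1 + int(np.sum(null >= observed))) / (1 + n_random)
    return observed, p, null


def export_top_edges(
    result: ERCResult,
    path: str,
    top_fraction: float | None = None,
    fterc_min: float | None = None,
) -> int:
    """Write an undirected weighted edge list for external clustering.

    Exactly one of ``top_fraction`` (keep the floor(fraction x n_pairs)
    highest-FtERC pairs) or ``fterc_min`` (keep pairs with FtERC >= the
    floor, inclusive) must be given.  Each pair appears once, sorted by
    descending FtERC; returns the number of edges written (an empty
    selection yields a header-only file).
    """
    if (top_fraction is None) == (fterc_min is None):
        raise ValueError("give exactly one of top_fraction or fterc_min")
    G = len(result.gene_ids)
    iu = np.triu_indices(G, k=1)
    vals = np.asarray(result.fterc[iu], dtype=float)
    ok = ~np.isnan(vals)
    ii, jj, vals = iu[0][ok], iu[1][ok], vals[ok]
    order = np.argsort(-vals, kind="stable")
    if top_fraction is not None:
        n_keep = int(math.floor(top_fraction * (G * (G - 1) // 2)))
        order = order[:n_keep]
    else:
        order = order[vals[order] >= fterc_min]
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tfterc\n")
        for k in order:
            fh.write(
                f"{result.gene_ids[ii[k]]}\t{result.gene_ids[jj[k]]}\t{vals[k]:.6g}\n"
            )
    return order.size


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

@dataclass
class AnnotationSet:
    """Term -> gene-set map with a record of genes missing from a universe."""

    terms: dict[str, set[str]]
    unmapped: dict[str, set[str]] = field(default_factory=dict)

    def restrict_to(self, universe: list[str]) -> "AnnotationSet":
        """Map every annotated gene into *universe*; the rest are reported."""
        uni = set(universe)
        mapped = {t: g & uni for t, g in self.terms.items()}
        missing = {t: g - uni for t, g in self.terms.items() if g - uni}
        return AnnotationSet(terms=mapped, unmapped=missing)


def read_gmt(path: str) -> AnnotationSet:
    """Read GMT (``term<TAB>description<TAB>gene...`` per line)."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            terms[parts[0]] = {g for g in parts[2:] if g}
    return AnnotationSet(terms=terms)


def read_term_tsv(path: str) -> AnnotationSet:
    """Read two-column TSV (``term<TAB>gene`` per line, header optional)."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                continue
            if i == 0 and parts[0].lower() in {"term", "term_id"}:
                continue
            terms.setdefault(parts[0], set()).add(parts[1])
    return AnnotationSet(terms=terms)


# ---------------------------------------------------------------------------
# elastic-net annotation models
# ---------------------------------------------------------------------------

def feature_matrix(result: ERCResult) -> np.ndarray:
    """Genes x genes FtERC feature matrix for model fitting.

    Missing values (including each gene's self entry) are imputed at 0,
    the null expectation of the Fisher-transformed statistic.
    """
    X = np.asarray(result.fterc, dtype=float).copy()
    X[np.isnan(X)] = 0.0
    np.fill_diagonal(X, 0.0)
    return X


@dataclass
class TermSkip:
    term: str
    reason: str


@dataclass
class TermModel:
    """Cross-validated elastic-net model for one annotation term.

    ``coef``/``intercept`` are on the raw FtERC feature scale (the internal
    standardization is folded back in), refit on the full data at the
    1-SE-rule regularization.
    """

    term: str
    feature_genes: list[str]
    n_pos: int
    lambdas: np.ndarray
    mean_auc: np.ndarray
    se_auc: np.ndarray
    idx_best: int
    idx_1se: int
    coef: np.ndarray
    intercept: float

    @property
    def auc_best(self) -> float:
        return float(self.mean_auc[self.idx_best])

    @property
    def auc_1se(self) -> float:
        return float(self.mean_auc[self.idx_1se])

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(self.coef != 0.0))


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population sd, matching the cited tool's convention
    sd[sd == 0.0] = 1.0
    return (X - mean) / sd, mean, sd


def _lambda_path(
    Xs: np.ndarray, y: np.ndarray, alpha: float, n_lambda: int, min_ratio: float
) -> np.ndarray:
    """Descending log-spaced path from the smallest all-zero-coefficient
    penalty down by ``min_ratio``."""
    n = y.size
    lam_max = float(np.abs(Xs.T @ (y - y.mean())).max()) / (n * max(alpha, 1e-3))
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _fit_at(Xs, y, lam: float, alpha: float, clf: LogisticRegression | None):
    if clf is None:
        clf = LogisticRegression(
            solver="saga",
            l1_ratio=alpha,
            warm_start=True,
            max_iter=100,
            tol=1e-3,
        )
    clf.C = 1.0 / (Xs.shape[0] * lam)
    with warnings.catch_warnings():
        # deep path points may stop at the iteration cap; AUC ranking is
        # insensitive to the residual coefficient slack
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(Xs, y)
    return clf


def fit_annotation_model(
    result: ERCResult,
    annotations: AnnotationSet,
    term: str,
    folds: int = 10,
    alpha: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
    seed: int = 0,
    min_members: int = 10,
) -> TermModel | TermSkip:
    """Cross-validated elastic-net membership model for one term.

    Logistic regression with elastic-net mixing ``alpha`` over a descending
    100-point regularization path; stratified ``folds``-fold CV scored by
    ROC AUC averaged across folds (not pooled).  The report carries the
    best-AUC path point and the 1-SE-rule point (strongest regularization
    whose mean AUC is within one standard error of the best); the returned
    coefficients are refit on the full data at the 1-SE point.

    Terms with fewer than ``min_members`` member or non-member genes in the
    matrix are skipped with a reason.
    """
    mapped = annotations.restrict_to(result.gene_ids)
    members = mapped.terms.get(term)
    if members is None:
        return TermSkip(term, "unknown term")
    y = np.array([g in members for g in result.gene_ids], dtype=float)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos < min_members:
        return TermSkip(term, f"only {n_pos} member genes in matrix (< {min_members})")
    if n_neg < min_members:
        return TermSkip(term, f"only {n_neg} non-member genes (< {min_members})")

    X = feature_matrix(result)
    Xs, mean, sd = _standardize(X)
    lambdas = _lambda_path(Xs, y, alpha, n_lambda, lambda_min_ratio)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = np.empty((folds, n_lambda))
    for k, (tr, te) in enumerate(skf.split(Xs, y)):
        clf = None
        for li, lam in enumerate(lambdas):
            clf = _fit_at(Xs[tr], y[tr], lam, alpha, clf)
            score = Xs[te] @ clf.coef_[0] + clf.intercept_[0]
            aucs[k, li] = roc_auc_score(y[te], score)
    mean_auc = aucs.mean(axis=0)
    se_auc = aucs.std(axis=0, ddof=1) / math.sqrt(folds)
    idx_best = int(np.argmax(mean_auc))
    threshold = mean_auc[idx_best] - se_auc[idx_best]
    idx_1se = int(np.flatnonzero(mean_auc >= threshold)[0])  # strongest penalty

    clf = _fit_at(Xs, y, float(lambdas[idx_1se]), alpha, None)
    coef_std = clf.coef_[0]
    coef = coef_std / sd
    intercept = float(clf.intercept_[0] - np.sum(coef_std * mean / sd))
    return TermModel(
        term=term,
        feature_genes=list(result.gene_ids),
        n_pos=n_pos,
        lambdas=lambdas,
        mean_auc=mean_auc,
        se_auc=se_auc,
        idx_best=idx_best,
        idx_1se=idx_1se,
        coef=coef,
        intercept=intercept,
    )


def predict_unannotated(model: TermModel, rows: np.ndarray) -> np.ndarray:
    """Membership probabilities for FtERC feature rows at the 1-SE penalty.

    ``rows`` must be aligned to ``model.feature_genes`` (missing values may
    be NaN and are imputed at 0, the null expectation).
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if rows.shape[1] != len(model.feature_genes):
        raise ValueError(
            f"feature mismatch: got {rows.shape[1]} columns, "
            f"model has {len(model.feature_genes)}"
        )
    rows = np.where(np.isnan(rows), 0.0, rows)
    return expit(rows @ model.coef + model.intercept)
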