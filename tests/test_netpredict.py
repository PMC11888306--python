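"""Z-score networks, clustering null, edge export and annotation models."""

import subprocess
import textwrap

import networkx as nx
import numpy as np
import pytest
from scipy.special import expit

from ercov.erc import ERCResult
from ercov.netpredict import (
    AnnotationSet,
    TermModel,
    TermSkip,
    _lambda_path,
    build_query_network,
    clustering_null,
    export_top_edges,
    feature_matrix,
    fit_annotation_model,
    predict_unannotated,
    read_gmt,
    read_term_tsv,
    zscores_for_gene,
)


def _result_from_matrix(M, gene_ids=None):
    M = np.asarray(M, dtype=np.float32)
    G = M.shape[0]
    gene_ids = gene_ids or [f"g{i:02d}" for i in range(G)]
    np.fill_diagonal(M, np.nan)
    n = np.full((G, G), 50, dtype=np.int32)
    np.fill_diagonal(n, 0)
    return ERCResult(gene_ids=gene_ids, fterc=M, r=np.tanh(M), n=n)


@pytest.fixture
def toy_result():
    """6-gene matrix whose first row holds the worked example (1,2,3,4,10)."""
    M = np.zeros((6, 6))
    M[0, 1:] = [1.0, 2.0, 3.0, 4.0, 10.0]
    M[1:, 0] = M[0, 1:]
    rng = np.random.default_rng(0)
    for i in range(1, 6):
        for j in range(i + 1, 6):
            M[i, j] = M[j, i] = rng.normal()
    return _result_from_matrix(M)


class TestZScores:
    def test_worked_example_row(self, toy_result):
        z = zscores_for_gene(toy_result, "g00", min_partners=5)
        # row (1,2,3,4,10): mean 4, sample sd sqrt(12.5)
        assert z[toy_result.index_of("g05")] == pytest.approx(6 / np.sqrt(12.5))
        assert z[toy_result.index_of("g05")] == pytest.approx(1.697056, abs=1e-6)
        assert np.isnan(z[toy_result.index_of("g00")])

    def test_partner_at_row_mean_is_zero(self, toy_result):
        z = zscores_for_gene(toy_result, "g00", min_partners=5)
        assert z[toy_result.index_of("g04")] == pytest.approx(0.0)  # value 4 = mean

    def test_rows_standardize_to_unit_moments(self):
        rng = np.random.default_rng(12)
        M = rng.normal(size=(40, 40))
        M = (M + M.T) / 2
        res = _result_from_matrix(M)
        for g in res.gene_ids[:5]:
            z = zscores_for_gene(res, g)
            vals = z[~np.isnan(z)]
            assert vals.mean() == pytest.approx(0.0, abs=1e-9)
            assert vals.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_partners_errors(self, toy_result):
        with pytest.raises(ValueError, match="partners"):
            zscores_for_gene(toy_result, "g00", min_partners=30)


class TestQueryNetwork:
    def test_infinite_cutoff_leaves_isolated_queries(self, toy_result):
        G = build_query_network(
            toy_result, ["g00", "g01"], z_cutoff=np.inf, min_partners=5
        )
        assert set(G.nodes) == {"g00", "g01"}
        assert G.number_of_edges() == 0

    def test_single_query_edge_count_matches_hits(self):
        rng = np.random.default_rng(3)
        M = rng.normal(size=(45, 45)) * 0.5
        M = (M + M.T) / 2
        # plant 3 strong partners for gene 0
        for j in (5, 11, 17):
            M[0, j] = M[j, 0] = 8.0
        res = _result_from_matrix(M)
        z = zscores_for_gene(res, res.gene_ids[0])
        k = int(np.sum(z[~np.isnan(z)] >= 3.0))
        G = build_query_network(res, [res.gene_ids[0]], z_cutoff=3.0)
        query_edges = [e for e in G.edges if res.gene_ids[0] in e]
        assert len(query_edges) == k == 3

    def test_unknown_query_rejected(self, toy_result):
        with pytest.raises(KeyError, match="nope"):
            build_query_network(toy_result, ["nope"], min_partners=5)

    def test_edges_meet_cutoff(self):
        rng = np.random.default_rng(9)
        M = rng.normal(size=(40, 40))
        M = (M + M.T) / 2
        res = _result_from_matrix(M)
        G = build_query_network(res, res.gene_ids[:3], z_cutoff=2.0)
        assert all(d["z"] >= 2.0 for _, _, d in G.edges(data=True))


class TestClusteringNull:
    def test_triangle_coefficient_is_one(self):
        tri = nx.complete_graph(3)
        coef, p, null = clustering_null(tri, n_random=50, seed=1)
        assert coef == pytest.approx(1.0)

    def test_star_coefficient_is_zero(self):
        star = nx.star_graph(4)
        coef, _, _ = clustering_null(star, n_random=50, seed=1)
        assert coef == pytest.approx(0.0)

    def test_empirical_p_formula(self):
        g = nx.random_geometric_graph(25, 0.4, seed=5)
        coef, p, null = clustering_null(g, n_random=200, seed=2)
        assert p == pytest.approx((1 + np.sum(null >= coef)) / 201)
        assert 1 / 201 <= p <= 1.0

    def test_relabeling_invariance(self):
        g = nx.random_geometric_graph(20, 0.4, seed=7)
        relabeled = nx.relabel_nodes(g, {v: f"x{v}" for v in g})
        a = clustering_null(g, n_random=100, seed=3)
        b = clustering_null(relabeled, n_random=100, seed=3)
        assert a[0] == pytest.approx(b[0])
        assert a[1] == b[1]

    def test_degenerate_network_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            clustering_null(nx.path_graph(2), n_random=10, seed=0)


class TestExportTopEdges:
    @pytest.fixture
    def dense_result(self):
        rng = np.random.default_rng(8)
        M = rng.normal(size=(100, 100))
        M = (M + M.T) / 2
        return _result_from_matrix(M)

    def test_top_fraction_count(self, dense_result, tmp_path):
        out = tmp_path / "edges.tsv"
        n = export_top_edges(dense_result, str(out), top_fraction=0.01)
        assert n == 49  # floor(0.01 * 4950)
        lines = out.read_text().strip().split("\n")
        assert len(lines) == 50  # header + 49
        vals = [float(l.split("\t")[2]) for l in lines[1:]]
        assert vals == sorted(vals, reverse=True)

    def test_threshold_above_max_is_empty(self, dense_result, tmp_path):
        out = tmp_path / "edges.tsv"
        n = export_top_edges(dense_result, str(out), fterc_min=1e6)
        assert n == 0
        assert out.read_text() == "gene_a\tgene_b\tfterc\n"

    def test_threshold_is_inclusive(self, dense_result, tmp_path):
        vals = dense_result.pair_values()[0]
        exact = float(np.nanmax(vals))
        out = tmp_path / "edges.tsv"
        n = export_top_edges(dense_result, str(out), fterc_min=exact)
        assert n >= 1

    def test_exactly_one_mode_required(self, dense_result, tmp_path):
        with pytest.raises(ValueError):
            export_top_edges(dense_result, str(tmp_path / "x"), 0.01, 5.0)


class TestAnnotationIO:
    def test_gmt_round_trip(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("termA\tdesc\tg1\tg2\tg3\ntermB\t-\tg2\tg4\n")
        ann = read_gmt(p)
        assert ann.terms == {"termA": {"g1", "g2", "g3"}, "termB": {"g2", "g4"}}

    def test_two_column_tsv(self, tmp_path):
        p = tmp_path / "sets.tsv"
        p.write_text("term\tgene\nT1\tg1\nT1\tg2\nT2\tg9\n")
        ann = read_term_tsv(p)
        assert ann.terms == {"T1": {"g1", "g2"}, "T2": {"g9"}}

    def test_unmapped_genes_reported(self):
        ann = AnnotationSet(terms={"T": {"a", "b", "zz"}})
        restricted = ann.restrict_to(["a", "b", "c"])
        assert restricted.terms["T"] == {"a", "b"}
        assert restricted.unmapped["T"] == {"zz"}


def _block_result(G=60, block=12, strength=6.0, seed=5):
    """Synthetic matrix with one coherent high-FtERC block."""
    rng = np.random.default_rng(seed)
    M = rng.normal(size=(G, G))
    M = (M + M.T) / 2
    M[:block, :block] += strength
    return _result_from_matrix(M)


class TestAnnotationModels:
    def test_block_term_is_learnable(self):
        res = _block_result()
        ann = AnnotationSet(terms={"block": set(res.gene_ids[:12])})
        fit = fit_annotation_model(res, ann, "block", seed=1)
        assert isinstance(fit, TermModel)
        assert fit.auc_1se >= 0.9
        assert fit.n_pos == 12
        assert 0 < fit.n_nonzero <= len(res.gene_ids)

    def test_one_se_rule_prefers_stronger_penalty(self):
        res = _block_result()
        ann = AnnotationSet(terms={"block": set(res.gene_ids[:12])})
        fit = fit_annotation_model(res, ann, "block", seed=1)
        assert fit.idx_1se <= fit.idx_best  # lambdas are descending
        assert fit.mean_auc[fit.idx_1se] >= fit.auc_best - fit.se_auc[fit.idx_best]

    def test_tiny_term_skipped(self):
        res = _block_result()
        ann = AnnotationSet(terms={"small": set(res.gene_ids[:3])})
        fit = fit_annotation_model(res, ann, "small")
        assert isinstance(fit, TermSkip)
        assert "3 member" in fit.reason

    def test_unknown_term_skipped(self):
        res = _block_result()
        fit = fit_annotation_model(res, AnnotationSet(terms={}), "ghost")
        assert isinstance(fit, TermSkip)

    def test_zero_feature_row_predicts_logistic_intercept(self):
        res = _block_result()
        ann = AnnotationSet(terms={"block": set(res.gene_ids[:12])})
        fit = fit_annotation_model(res, ann, "block", seed=1)
        prob = predict_unannotated(fit, np.zeros(len(res.gene_ids)))
        assert prob[0] == pytest.approx(float(expit(fit.intercept)), abs=1e-12)

    def test_training_positive_scores_high(self):
        res = _block_result()
        ann = AnnotationSet(terms={"block": set(res.gene_ids[:12])})
        fit = fit_annotation_model(res, ann, "block", seed=1)
        X = feature_matrix(res)
        probs = predict_unannotated(fit, X)
        assert probs[:12].mean() > probs[12:].mean()
        # a strong training positive outscores essentially all non-members
        assert probs[0] > np.percentile(probs[12:], 95)

    def test_wrong_feature_count_rejected(self):
        res = _block_result()
        ann = AnnotationSet(terms={"block": set(res.gene_ids[:12])})
        fit = fit_annotation_model(res, ann, "block", seed=1)
        with pytest.raises(ValueError, match="feature mismatch"):
            predict_unannotated(fit, np.zeros(7))


class TestGlmnetOracle:
    """Cross-check the regularization path against R glmnet on a fixture."""

    def test_lambda_path_start_matches_glmnet(self, tmp_path):
        rng = np.random.default_rng(7)
        n, p = 120, 25
        X = rng.standard_normal((n, p))
        beta = np.zeros(p)
        beta[:4] = [2.0, -1.5, 1.0, 0.8]
        y = (X @ beta + rng.standard_normal(n) > 0).astype(float)
        Xs = (X - X.mean(0)) / X.std(0)
        ours = _lambda_path(Xs, y, alpha=0.5, n_lambda=100, min_ratio=1e-4)[0]

        np.savetxt(tmp_path / "X.csv", X, delimiter=",")
        np.savetxt(tmp_path / "y.csv", y, fmt="%d")
        script = textwrap.dedent(
            f"""
            suppressMessages(library(glmnet))
            X <- as.matrix(read.csv('{tmp_path}/X.csv', header=FALSE))
            y <- scan('{tmp_path}/y.csv', quiet=TRUE)
            fit <- glmnet(X, y, family='binomial', alpha=0.5)
            cat(sprintf('%.10f', fit$lambda[1]))
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        theirs = float(out.stdout.strip().split()[-1])
        assert ours == pytest.approx(theirs, rel=1e-6)
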