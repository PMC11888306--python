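"""Relative evolutionary rates (RERs) on a shared pruned topology.

A gene's branch lengths confound the genome-wide divergence of each branch
with the gene's own average rate and with branch-specific rate shifts.  The
RER isolates the last component: fit an expected tree (per-branch expected
length ``mu_e`` and per-gene scale ``c_g``) across all genes observing the
topology, then take per-gene regression residuals.

Two residual modes are provided:

``uncorrected``
    Ordinary least squares of branch lengths on ``mu`` without intercept.
    Raw branch-length residuals are heteroskedastic — their variance grows
    with the branch's expected length — which degrades downstream linear
    correlations.

``corrected`` (default)
    Square-root transform both sides, then an iteratively reweighted
    no-intercept regression whose weights come from a mean-variance trend
    estimated by binning fitted values into equal-count bins; the final
    weighted residuals are standardized to unit variance per gene.  This
    removes the variance-vs-magnitude trend so residuals are suitable for
    Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ExpectedTree", "RERError", "fit_expected_tree", "compute_rer"]


class RERError(ValueError):
    """RER cannot be computed for this gene/topology combination."""


@dataclass
class ExpectedTree:
    """Expected branch lengths on one pruned topology.

    Attributes
    ----------
    mu : numpy.ndarray
        Expected length per usable edge (aligned to ``edge_mask``'s True
        positions of the input edge list).
    scale : numpy.ndarray
        Per-gene rate scale ``c_g`` (normalized so mean over fitted genes
        is 1); NaN for genes observing none of the edges.
    edge_mask : numpy.ndarray
        Boolean mask over the input edge list; False marks edges dropped
        for having fewer than ``min_genes`` observations.
    """

    mu: np.ndarray
    scale: np.ndarray
    edge_mask: np.ndarray


def fit_expected_tree(
    lengths: np.ndarray,
    min_genes: int = 5,
    n_iter: int = 2,
    min_length: float = 1e-3,
) -> ExpectedTree:
    """Fit per-edge expected lengths and per-gene scales.

    Parameters
    ----------
    lengths : numpy.ndarray
        genes x edges branch-length matrix; NaN marks an edge a gene does
        not observe.
    min_genes : int
        Edges observed by fewer genes are dropped (flagged in
        ``edge_mask``); dropping all edges raises :class:`RERError`.
    n_iter : int
        Fixed number of alternating-averaging refinements (deterministic).
    min_length : float
        Low-rate filter, in substitutions/site: edges whose fitted expected
        length falls below this are flagged unusable.  Essentially
        unresolved branches carry no rate information but would otherwise
        distort the mean-variance trend at the short end.

    Notes
    -----
    The scheme initializes ``mu_e`` as the mean observed length of edge e,
    then alternates ``c_g <- mean_e l_ge/mu_e`` and
    ``mu_e <- mean_g l_ge/c_g`` (NaN-aware means) for ``n_iter`` rounds,
    finally normalizing so ``mean(c) = 1``.
    """
    L = np.asarray(lengths, dtype=float)
    if L.ndim != 2:
        raise ValueError("lengths must be a genes x edges matrix")
    obs = ~np.isnan(L)
    edge_mask = obs.sum(axis=0) >= min_genes
    if not edge_mask.any():
        raise RERError(
            f"all {L.shape[1]} edges observed by fewer than {min_genes} genes"
        )
    Lu = L[:, edge_mask]
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN gene rows
        mu = np.nanmean(Lu, axis=0)
        c = np.full(L.shape[0], np.nan)
        for _ in range(n_iter):
            c = np.nanmean(Lu / mu, axis=1)
            mu = np.nanmean(Lu / c[:, None], axis=0)
        s = np.nanmean(c)
    if not np.isfinite(s) or s <= 0:
        raise RERError("expected-tree fit degenerate (no positive signal)")
    mu = mu * s
    keep = mu >= min_length
    if not keep.any():
        raise RERError("all edges below the low-rate filter")
    if not keep.all():
        sub = np.flatnonzero(edge_mask)
        edge_mask = edge_mask.copy()
        edge_mask[sub[~keep]] = False
        mu = mu[keep]
    return ExpectedTree(mu=mu, scale=c / s, edge_mask=edge_mask)


def _variance_trend_weights(fitted: np.ndarray, resid: np.ndarray, n_bins: int) -> np.ndarray:
    """1/variance weights from a binned mean-variance trend.

    Fitted values are sorted into equal-count bins; each bin contributes
    (mean fitted, mean squared residual), and per-point variances are
    linearly interpolated between bin centers.
    """
    m = fitted.size
    nb = int(min(n_bins, max(1, m // 2)))
    order = np.argsort(fitted, kind="stable")
    centers = np.empty(nb)
    variances = np.empty(nb)
    for i, idx in enumerate(np.array_split(order, nb)):
        centers[i] = fitted[idx].mean()
        variances[i] = np.mean(resid[idx] ** 2)
    vbar = variances.mean()
    if vbar <= 0.0:
        return None  # exact fit: caller returns zeros
    v = np.interp(fitted, centers, variances)
    v = np.maximum(v, 1e-8 * vbar)
    return 1.0 / v


def compute_rer(
    gene_vector: np.ndarray,
    mu: np.ndarray,
    corrected: bool = True,
    n_bins: int = 10,
    reweight_iters: int = 2,
    min_edges: int = 5,
    return_fitted: bool = False,
):
    """Per-branch RER residuals for one gene on one pruned topology.

    Parameters
    ----------
    gene_vector : numpy.ndarray
        The gene's branch lengths on the topology's usable edges (all
        finite, >= 0; near-zero lengths are observed zeros, not missing).
    mu : numpy.ndarray
        Expected lengths from :func:`fit_expected_tree` (same alignment).
    corrected : bool
        Heteroskedasticity-corrected residuals (default) vs plain OLS.
    n_bins, reweight_iters : int
        Mean-variance trend bin count and number of reweighting rounds.
    min_edges : int
        Fewer usable edges than this raises :class:`RERError` (the pair is
        then skipped downstream).
    return_fitted : bool
        Also return the fitted values the residuals are taken around
        (on the square-root scale in corrected mode), for diagnostics.
    """
    l = np.asarray(gene_vector, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if l.shape != mu.shape:
        raise ValueError("gene vector not aligned to expected tree")
    if l.size < min_edges:
        raise RERError(f"only {l.size} usable edges (< {min_edges})")
    if not np.all(np.isfinite(l)) or np.any(l < 0):
        raise RERError("gene vector must be finite and non-negative")
    if np.ptp(l) == 0.0:
        raise RERError("zero-variance gene vector")

    if not corrected:
        c = float(l @ mu) / float(mu @ mu)
        fitted = c * mu
        resid = l - fitted
        return (resid, fitted) if return_fitted else resid

    x = np.sqrt(mu)
    y = np.sqrt(l)
    w = np.ones_like(x)
    exact_tol = 1e-12 * max(1.0, float(np.max(y)))
    for _ in range(reweight_iters):
        b = float(np.sum(w * x * y)) / float(np.sum(w * x * x))
        fitted = b * x
        resid = y - fitted
        if np.max(np.abs(resid)) <= exact_tol:
            # exact proportionality up to float epsilon: residuals are zero,
            # and must not be amplified by the 1/variance weights
            zeros = np.zeros_like(x)
            return (zeros, fitted) if return_fitted else zeros
        w = _variance_trend_weights(fitted, resid, n_bins)
        if w is None:
            zeros = np.zeros_like(x)
            return (zeros, fitted) if return_fitted else zeros
    out = resid * np.sqrt(w)
    sd = out.std(ddof=1)
    out = out / sd if sd > 0 else np.zeros_like(out)
    return (out, fitted) if return_fitted else out
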