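"""A compact multivariate adaptive regression splines (MARS) basis learner.

MARS builds a piecewise-linear model from hinge functions
``max(0, x - t)`` / ``max(0, t - x)``.  The forward pass greedily adds the
reflected hinge pair (variable, knot) that most reduces weighted residual
sum of squares; the backward pass prunes basis functions by generalized
cross-validation (GCV).  The learner here is additive (degree 1): each basis
function involves a single variable, which is the standard parsimonious
setting for niche-model ensembles where smooth unimodal responses dominate.

Only the basis construction lives here; the classification heads (logistic
regression for the MARS method, optimal-scoring least squares for FDA) are
assembled in :mod:`enmrisk.sdm_models`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = ["MarsBasis", "fit_mars_basis"]


@dataclass
class MarsBasis:
    """Fitted hinge basis: list of (var_index, knot, direction) triples.

    ``direction`` +1 encodes ``max(0, x - t)``, -1 encodes ``max(0, t - x)``.
    The transform always prepends an intercept column of ones.
    """

    terms: list  # (var_idx, knot, direction)
    n_vars: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_vars:
            raise DomainError(f"expected {self.n_vars} columns, got {X.shape}")
        cols = [np.ones(len(X))]
        for j, t, s in self.terms:
            cols.append(np.maximum(0.0, s * (X[:, j] - t)))
        return np.column_stack(cols)


def _wls_rss(B: np.ndarray, y: np.ndarray, w: np.ndarray, ridge: float = 1e-9):
    """Weighted least squares via normal equations; returns (rss, beta)."""
    Bw = B * w[:, None]
    G = B.T @ Bw
    G[np.diag_indices_from(G)] += ridge
    b = Bw.T @ y
    try:
        beta = np.linalg.solve(G, b)
    except np.linalg.LinAlgError:
        beta, *_ = np.linalg.lstsq(Bw, y * np.sqrt(w), rcond=None)
    resid = y - B @ beta
    return float(np.sum(w * resid * resid)), beta


def _gcv(rss: float, n: int, n_terms: int, penalty: float = 2.0) -> float:
    cost = n_terms + penalty * max(n_terms - 1, 0) / 2.0
    denom = (1.0 - min(cost, n - 1) / n) ** 2
    return rss / n / denom


def fit_mars_basis(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    *,
    max_terms: int = 15,
    n_knots: int = 10,
    penalty: float = 2.0,
) -> MarsBasis:
    """Forward selection of hinge pairs followed by GCV backward pruning.

    Candidate knots per variable are interior quantiles of the observed
    values.  ``max_terms`` counts hinge columns (excluding the intercept).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 10:
        raise DomainError("too few rows for MARS basis selection")
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    w = w * (n / w.sum())

    # candidate (var, knot) pairs on interior quantiles, skipping degenerate knots
    qs = np.linspace(0.05, 0.95, n_knots)
    candidates: list[tuple[int, float]] = []
    for j in range(p):
        knots = np.unique(np.quantile(X[:, j], qs))
        lo, hi = X[:, j].min(), X[:, j].max()
        for t in knots:
            if lo < t < hi:
                candidates.append((j, float(t)))

    terms: list[tuple[int, float, int]] = []
    B = np.ones((n, 1))
    rss, _ = _wls_rss(B, y, w)
    used: set[tuple[int, float]] = set()
    while len(terms) + 2 <= max_terms:
        best = None
        for cand in candidates:
            if cand in used:
                continue
            j, t = cand
            pair = np.column_stack(
                [np.maximum(0.0, X[:, j] - t), np.maximum(0.0, t - X[:, j])]
            )
            trial = np.column_stack([B, pair])
            trial_rss, _ = _wls_rss(trial, y, w)
            if best is None or trial_rss < best[0]:
                best = (trial_rss, cand, pair)
        if best is None or best[0] >= rss * (1 - 1e-10):
            break
        rss, (j, t), pair = best[0], best[1], best[2]
        used.add((j, t))
        terms.extend([(j, t, 1), (j, t, -1)])
        B = np.column_stack([B, pair])

    # backward pruning: drop hinge columns while GCV improves
    keep = list(range(len(terms)))
    best_keep = list(keep)
    rss_cur, _ = _wls_rss(B[:, [0] + [k + 1 for k in keep]], y, w)
    best_gcv = _gcv(rss_cur, n, len(keep) + 1, penalty)
    improved = True
    while improved and keep:
        improved = False
        for k in list(keep):
            trial = [q for q in keep if q != k]
            t_rss, _ = _wls_rss(B[:, [0] + [q + 1 for q in trial]], y, w)
            g = _gcv(t_rss, n, len(trial) + 1, penalty)
            if g < best_gcv - 1e-12:
                best_gcv, best_keep = g, list(trial)
                keep = trial
                improved = True
                break
    return MarsBasis(terms=[terms[k] for k in best_keep], n_vars=p)
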