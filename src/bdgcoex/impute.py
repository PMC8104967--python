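"""Dropout detection and imputation for single-cell matrices.

Single-cell counts contain technical zeros ("dropouts") where an expressed
transcript failed to be captured.  Following the mixture-model strategy of
scImpute-style methods, each gene's log-normalized values across cells are
modeled as a two-component density

    lambda * Gamma(x; alpha, beta) + (1 - lambda) * Normal(x; mu, sigma)

where the gamma component absorbs dropout-depressed values near zero and
the normal component the gene's genuine expression mode.  The posterior
weight of the gamma component at an observed entry is its dropout
probability.  Entries deemed dropouts are then replaced by a
similarity-weighted average of the same gene in the cell's nearest
neighbors, computed only over confidently expressed entries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import digamma, gammaln, polygamma
from scipy.stats import norm

from .exprio import ExpressionMatrix

logger = logging.getLogger(__name__)

_X_EPS = 1e-6      # clamp for gamma-density evaluation at exact zeros
_ALPHA_MAX = 200.0  # gamma shape cap (a near-point-mass dropout component)
_ALPHA_MIN = 1e-3
_SIGMA_MIN = 1e-3
_LAM_EPS = 1e-8

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class DropoutModel:
    """Per-gene gamma-normal mixture fit plus per-entry dropout probabilities.

    ``lam`` is the gamma (dropout) mixture weight; ``alpha``/``beta`` the
    gamma shape and rate; ``mu``/``sigma`` the normal mean and sd.
    Constant genes are flagged and carry dropout probability 0.
    """

    gene_ids: list[str]
    lam: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    converged: np.ndarray
    constant: np.ndarray
    dropout_prob: np.ndarray
    layer_tag: str = "cp10k_log"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "lambda": self.lam,
                "alpha": self.alpha,
                "beta": self.beta,
                "mu": self.mu,
                "sigma": self.sigma,
                "converged": self.converged,
                "constant": self.constant,
            }
        )


def _gamma_logpdf(x: np.ndarray, alpha: np.ndarray, beta: np.ndarray, lnx: np.ndarray) -> np.ndarray:
    a = alpha[:, None]
    b = beta[:, None]
    return a * np.log(b) - gammaln(a) + (a - 1.0) * lnx - b * x


def _solve_gamma_shape(s: np.ndarray) -> np.ndarray:
    """Solve log(alpha) - digamma(alpha) = s for alpha (weighted gamma MLE).

    Uses Minka's closed-form initialization followed by Newton steps; ``s``
    must be positive.  Vectorized over genes.
    """
    s = np.maximum(s, 1e-8)
    alpha = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    alpha = np.clip(alpha, _ALPHA_MIN, _ALPHA_MAX)
    for _ in range(3):
        f = np.log(alpha) - digamma(alpha) - s
        fp = 1.0 / alpha - polygamma(1, alpha)
        step = np.where(np.abs(fp) > 1e-300, f / fp, 0.0)
        alpha = np.clip(alpha - step, _ALPHA_MIN, _ALPHA_MAX)
    return alpha


def fit_gamma_normal(
    x: np.ndarray, max_iter: int = 100, tol: float = 1e-6
) -> tuple[float, float, float, float, float, bool]:
    """Fit the two-component mixture to one sample vector.

    Returns ``(lam, alpha, beta, mu, sigma, converged)``.  Convenience
    wrapper over the vectorized fit used by :func:`fit_dropout_model`.
    """
    x = np.asarray(x, dtype=np.float64)[None, :]
    lam, alpha, beta, mu, sigma, conv, const = _fit_genes(x, max_iter, tol)
    return float(lam[0]), float(alpha[0]), float(beta[0]), float(mu[0]), float(sigma[0]), bool(conv[0])


def _fit_genes(Y: np.ndarray, max_iter: int, tol: float):
    """Vectorized EM over genes (rows).  Returns per-gene parameter arrays."""
    G, C = Y.shape
    X = np.maximum(Y, _X_EPS)
    lnX = np.log(X)

    var = Y.var(axis=1)
    constant = var == 0.0

    # --- initialization: split at the gene median ---------------------------
    med = np.median(Y, axis=1, keepdims=True)
    low = Y < med
    none_low = ~low.any(axis=1)          # median equals the minimum
    low[none_low] = Y[none_low] <= med[none_low]
    high = ~low

    n_low = low.sum(axis=1).astype(float)
    n_high = np.maximum(high.sum(axis=1).astype(float), 1.0)
    n_low_safe = np.maximum(n_low, 1.0)

    lam = np.clip((Y < med).sum(axis=1) / C, 0.01, 0.99)
    m_low = (X * low).sum(axis=1) / n_low_safe
    v_low = ((X - m_low[:, None]) ** 2 * low).sum(axis=1) / n_low_safe
    m_low = np.maximum(m_low, _X_EPS)
    v_low = np.maximum(v_low, 1e-8)
    alpha = np.clip(m_low**2 / v_low, _ALPHA_MIN, _ALPHA_MAX)
    beta = alpha / m_low
    mu = (Y * high).sum(axis=1) / n_high
    sigma = np.sqrt(np.maximum(((Y - mu[:, None]) ** 2 * high).sum(axis=1) / n_high, 0.0))
    sigma = np.maximum(sigma, _SIGMA_MIN)

    converged = np.zeros(G, dtype=bool)
    active = ~constant
    prev_ll = np.full(G, -np.inf)

    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        Ya, Xa, lnXa = Y[idx], X[idx], lnX[idx]
        lam_a = np.clip(lam[idx], _LAM_EPS, 1.0 - _LAM_EPS)
        lg = _gamma_logpdf(Xa, alpha[idx], beta[idx], lnXa) + np.log(lam_a)[:, None]
        ln = (
            -0.5 * ((Ya - mu[idx][:, None]) / sigma[idx][:, None]) ** 2
            - np.log(sigma[idx])[:, None]
            - _LOG_SQRT_2PI
            + np.log1p(-lam_a)[:, None]
        )
        ll = np.logaddexp(lg, ln).sum(axis=1)
        with np.errstate(over="ignore"):
            gam = 1.0 / (1.0 + np.exp(ln - lg))  # responsibility of the gamma part

        # M-step
        sg = gam.sum(axis=1)
        sn = C - sg
        lam_new = np.clip(sg / C, _LAM_EPS, 1.0 - _LAM_EPS)
        ok_g = sg > 1e-6
        ok_n = sn > 1e-6

        mean_w = np.where(ok_g, (gam * Xa).sum(axis=1) / np.maximum(sg, 1e-12), 1.0)
        mean_w = np.maximum(mean_w, _X_EPS)
        meanlog_w = np.where(ok_g, (gam * lnXa).sum(axis=1) / np.maximum(sg, 1e-12), 0.0)
        s = np.log(mean_w) - meanlog_w
        alpha_new = np.where(ok_g, _solve_gamma_shape(s), alpha[idx])
        beta_new = np.where(ok_g, alpha_new / mean_w, beta[idx])

        wn = 1.0 - gam
        mu_new = np.where(ok_n, (wn * Ya).sum(axis=1) / np.maximum(sn, 1e-12), mu[idx])
        sig_new = np.sqrt(
            np.maximum((wn * (Ya - mu_new[:, None]) ** 2).sum(axis=1) / np.maximum(sn, 1e-12), 0.0)
        )
        sig_new = np.where(ok_n, np.maximum(sig_new, _SIGMA_MIN), sigma[idx])

        lam[idx], alpha[idx], beta[idx] = lam_new, alpha_new, beta_new
        mu[idx], sigma[idx] = mu_new, sig_new

        gain = ll - prev_ll[idx]
        prev_ll[idx] = ll
        done = gain < tol
        converged[idx[done]] = True
        active[idx[done]] = False

    n_unconverged = int((~converged & ~constant).sum())
    if n_unconverged:
        logger.warning("EM did not converge for %d gene(s); last iterate kept", n_unconverged)

    # Collapse unidentifiable fits: a "dropout" component sitting at or above
    # the expressed mean carries no dropout information (e.g. a gene with all
    # values tightly near one positive mode).
    collapse = ~constant & (alpha / beta >= mu)
    lam[collapse] = 0.0
    lam[constant] = 0.0
    converged[constant] = True
    return lam, alpha, beta, mu, sigma, converged, constant


def fit_dropout_model(
    m: ExpressionMatrix,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int | None = None,
) -> DropoutModel:
    """Fit the per-gene gamma-normal mixture and score every entry.

    The matrix must be on the ``cp10k_log`` working scale with at least 10
    cells.  Initialization splits each gene at its median: the gamma
    moments come from the lower half, the normal moments from the upper
    half, and lambda starts at the fraction of entries below the median.
    EM stops when the per-gene log-likelihood gain drops below ``tol`` or
    after ``max_iter`` iterations (non-convergence keeps the last iterate
    with a warning).  The computation is exact and deterministic; ``seed``
    is accepted for API uniformity.
    """
    if m.layer_tag != "cp10k_log":
        raise ValueError(f"expected layer 'cp10k_log', got {m.layer_tag!r}")
    if m.n_cells < 10:
        raise ValueError(f"need at least 10 cells to fit the dropout model, got {m.n_cells}")

    Y = m.values
    lam, alpha, beta, mu, sigma, converged, constant = _fit_genes(Y, max_iter, tol)

    dropout_prob = np.zeros_like(Y)
    scored = ~constant & (lam > 0.0)
    if scored.any():
        idx = np.flatnonzero(scored)
        X = np.maximum(Y[idx], _X_EPS)
        lg = _gamma_logpdf(X, alpha[idx], beta[idx], np.log(X)) + np.log(lam[idx])[:, None]
        ln = (
            norm.logpdf(Y[idx], loc=mu[idx][:, None], scale=sigma[idx][:, None])
            + np.log1p(-lam[idx])[:, None]
        )
        with np.errstate(over="ignore"):
            dropout_prob[idx] = 1.0 / (1.0 + np.exp(ln - lg))

    return DropoutModel(
        gene_ids=list(m.gene_ids),
        lam=lam,
        alpha=alpha,
        beta=beta,
        mu=mu,
        sigma=sigma,
        converged=converged,
        constant=constant,
        dropout_prob=dropout_prob,
        layer_tag=m.layer_tag,
    )


def impute_matrix(
    m: ExpressionMatrix,
    model: DropoutModel,
    threshold: float = 0.5,
    k_neighbors: int = 20,
) -> ExpressionMatrix:
    """Replace likely-dropout entries by neighbor-weighted averages.

    Entries with dropout probability above ``threshold`` are replaced by
    the similarity-weighted mean of the same gene across the cell's
    ``k_neighbors`` most similar cells.  Cell-cell similarity is the
    Pearson correlation computed only over genes confidently expressed
    (dropout probability <= threshold) in both cells; neighbor weights are
    ``max(similarity, 0)`` renormalized, and neighbor entries that are
    themselves dropouts do not contribute.  Entries with no usable
    neighbor are left unchanged (logged); confident entries are never
    modified.  Imputed values are clamped to 1.5x the gene's largest
    confident value.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    if k_neighbors >= m.n_cells:
        raise ValueError(
            f"k_neighbors ({k_neighbors}) must be smaller than the number of cells ({m.n_cells})"
        )
    if model.dropout_prob.shape != m.values.shape or list(model.gene_ids) != list(m.gene_ids):
        raise ValueError("model does not match the matrix (genes or shape differ)")

    V = m.values
    D = model.dropout_prob > threshold          # entries to impute
    conf = ~D                                    # confident entries
    if not D.any():
        return replace(m, values=V.copy(), layer_tag="imputed")

    Mf = conf.astype(np.float64)
    Xm = V * Mf
    # masked pairwise Pearson between cells over jointly confident genes
    n = Mf.T @ Mf
    sx = Xm.T @ Mf
    sxx = (Xm * Xm).T @ Mf
    sxy = Xm.T @ Xm
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        varx = sxx - sx**2 / n
        sim = cov / np.sqrt(varx * varx.T)
    sim[~np.isfinite(sim)] = -np.inf
    sim[n < 3] = -np.inf
    np.fill_diagonal(sim, -np.inf)

    # deterministic top-k neighbors (stable sort; ties resolved by index)
    order = np.argsort(-sim, axis=1, kind="stable")[:, :k_neighbors]
    W = np.zeros_like(sim)
    rows = np.repeat(np.arange(m.n_cells), k_neighbors)
    nbr = order.ravel()
    w = np.maximum(sim[rows, nbr], 0.0)
    w[~np.isfinite(w)] = 0.0
    W[nbr, rows] = w  # column j holds cell j's neighbor weights

    numer = Xm @ W
    denom = Mf @ W
    out = V.copy()
    fill = D & (denom > 0.0)
    n_skipped = int(D.sum() - fill.sum())
    if n_skipped:
        logger.info("%d dropout entries had no usable neighbor; left unchanged", n_skipped)
    if fill.any():
        gmax = np.where(conf, V, -np.inf).max(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cand = numer / denom
        cand = np.minimum(cand, 1.5 * gmax[:, None])
        out[fill] = np.maximum(cand[fill], 0.0)
    return replace(m, values=out, layer_tag="imputed")
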