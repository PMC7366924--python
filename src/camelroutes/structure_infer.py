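"""Population structure: PCA, model-based ancestry clustering, distances.

The clustering maximizes the ADMIXTURE-style binomial likelihood

    L(Q, F) = sum_ij [ g_ij log(sum_k q_ik f_kj)
                       + (2 - g_ij) log(sum_k q_ik (1 - f_kj)) ]

over non-missing calls, where Q holds per-individual ancestry fractions
(rows on the simplex) and F per-cluster allele frequencies, via EM
updates (monotone in the log-likelihood).  Model choice uses fivefold
cross-validation: non-missing genotype entries are partitioned into
folds, each fold is masked and predicted by the refitted model, and the
CV error is the root-mean-squared deviation between the masked genotypes
and their expectation ``2 sum_k q_ik f_kj``; the best K minimizes the
mean error over folds.

PCA mean-imputes missing calls per SNP, centers columns without variance
scaling, and reports percent variance per axis; the sign convention makes
the largest-magnitude loading of each axis positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from camelroutes.genotype_io import MISSING, GenotypeMatrix
from camelroutes.qc_filter import ibs_distance_matrix

_EPS = 1e-9


@dataclass
class PcaResult:
    scores: np.ndarray  # (n, n_axes)
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    samples: list[str]


@dataclass
class AdmixtureResult:
    K: int
    Q: np.ndarray  # (n, K) ancestry fractions
    F: np.ndarray  # (K, m) allele frequencies
    log_likelihood: float
    n_iter: int
    converged: bool
    samples: list[str]


def _impute_centered(G: GenotypeMatrix) -> np.ndarray:
    X = G.calls.astype(float)
    X[G.calls == MISSING] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    nan = np.isnan(X)
    X[nan] = np.broadcast_to(col_mean, X.shape)[nan]
    return X - col_mean


def pca(G: GenotypeMatrix, n_axes: int = 10) -> PcaResult:
    """Principal component analysis of the genotype matrix.

    Missing calls are mean-imputed per SNP; columns are centered but not
    scaled.  Percent variance is the eigenvalue share of the total.
    """
    if G.n_samples < 2:
        raise ValueError("PCA needs at least 2 individuals")
    X = _impute_centered(G)
    n_axes = min(n_axes, G.n_samples - 1, G.n_snps)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    eig = s**2 / (G.n_samples - 1)
    total = eig.sum()
    if total == 0:
        warnings.warn("constant genotype matrix: all eigenvalues are zero")
        pct = np.zeros_like(eig)
    else:
        pct = 100.0 * eig / total
    scores = u * s
    # sign convention: largest-|loading| positive per axis
    for a in range(n_axes):
        lead = np.argmax(np.abs(vt[a]))
        if vt[a, lead] < 0:
            scores[:, a] *= -1
            vt[a] *= -1
    return PcaResult(
        scores=scores[:, :n_axes],
        eigenvalues=eig[:n_axes],
        percent_variance=pct[:n_axes],
        samples=list(G.samples),
    )


# ---------------------------------------------------------------------------
# Admixture model
# ---------------------------------------------------------------------------

def _log_likelihood(g, obs, Q, F):
    P = np.clip(Q @ F, _EPS, 1 - _EPS)
    with np.errstate(invalid="ignore"):
        ll = np.where(obs, g * np.log(P) + (2 - g) * np.log(1 - P), 0.0)
    return float(ll.sum())


def _em_step(g, obs, Q, F):
    P = np.clip(Q @ F, _EPS, 1 - _EPS)
    # responsibilities, summed over SNPs/individuals without materializing
    # the (n, m, K) tensor: A = g/P, B = (2-g)/(1-P), masked where missing
    A = np.where(obs, g / P, 0.0)
    B = np.where(obs, (2 - g) / (1 - P), 0.0)
    #   a_ijk = A_ij q_ik f_kj ; b_ijk = B_ij q_ik (1 - f_kj)
    F_new_num = Q.T @ A * F  # (K, m): sum_i a_ijk
    F_new_den = F_new_num + Q.T @ B * (1 - F)
    Q_new = Q * (A @ F.T + B @ (1 - F).T)  # (n, K): sum_j (a + b)
    denom = 2.0 * obs.sum(axis=1, keepdims=True)
    Q_new = Q_new / np.maximum(denom, 1.0)
    Q_new = np.clip(Q_new, _EPS, None)
    Q_new /= Q_new.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        F_new = np.where(F_new_den > 0, F_new_num / F_new_den, F)
    F_new = np.clip(F_new, _EPS, 1 - _EPS)
    return Q_new, F_new


def admixture_fit(
    G: GenotypeMatrix,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_starts: int = 3,
    mask: np.ndarray | None = None,
) -> AdmixtureResult:
    """Fit the K-cluster ancestry model by EM with multi-start.

    ``mask`` marks additional entries to exclude from the likelihood
    (used by cross-validation).  Convergence: relative log-likelihood
    change below ``tol``.  The best of ``n_starts`` random initializations
    is returned; K = 1 reduces to the closed form (q = 1, f = observed
    frequencies).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    g = G.calls.astype(float)
    obs = G.calls != MISSING
    if mask is not None:
        obs = obs & ~mask
    g = np.where(obs, g, 0.0)

    if K == 1:
        denom = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(denom > 0, g.sum(axis=0) / denom, 0.5)
        F = np.clip(f[None, :], _EPS, 1 - _EPS)
        Q = np.ones((G.n_samples, 1))
        ll = _log_likelihood(g, obs, Q, F)
        return AdmixtureResult(1, Q, F, ll, 0, True, list(G.samples))

    best: AdmixtureResult | None = None
    for start in range(n_starts):
        rng = np.random.default_rng(seed * 1000 + start)
        Q = rng.dirichlet(np.ones(K), size=G.n_samples)
        F = np.clip(rng.uniform(0.05, 0.95, size=(K, G.n_snps)), _EPS, 1 - _EPS)
        ll = _log_likelihood(g, obs, Q, F)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            Q, F = _em_step(g, obs, Q, F)
            new_ll = _log_likelihood(g, obs, Q, F)
            if abs(new_ll - ll) <= tol * abs(ll):
                ll = new_ll
                converged = True
                break
            ll = new_ll
        if not converged:
            warnings.warn(f"admixture K={K} start {start}: no convergence "
                          f"in {max_iter} iterations")
        cand = AdmixtureResult(K, Q, F, ll, it, converged, list(G.samples))
        if best is None or cand.log_likelihood > best.log_likelihood:
            best = cand
    return best


def admixture_cv(
    G: GenotypeMatrix,
    K_values=range(1, 11),
    folds: int = 5,
    seed: int = 0,
    **fit_kwargs,
):
    """Choose K by masked-genotype cross-validation.

    Non-missing entries are partitioned into ``folds`` folds; each fold
    is masked, the model refit on the rest, and the fold error is the
    RMSE between the masked genotypes and their model expectation
    ``2 Q F``.  Returns ``(errors, best_K)`` where ``errors`` maps K to
    the per-fold error list.
    """
    rng = np.random.default_rng(seed)
    obs_idx = np.argwhere(G.calls != MISSING)
    if len(obs_idx) < folds:
        raise ValueError("not enough non-missing entries to form folds")
    fold_of = rng.permuted(np.arange(len(obs_idx)) % folds)
    errors: dict[int, list[float]] = {}
    for K in K_values:
        errs = []
        for f in range(folds):
            sel = obs_idx[fold_of == f]
            if len(sel) == 0:
                raise ValueError(f"fold {f} has zero entries")
            mask = np.zeros_like(G.calls, dtype=bool)
            mask[sel[:, 0], sel[:, 1]] = True
            fit = admixture_fit(G, K, seed=seed + 7 * f, mask=mask, **fit_kwargs)
            pred = 2.0 * (fit.Q @ fit.F)
            truth = G.calls[sel[:, 0], sel[:, 1]].astype(float)
            errs.append(float(np.sqrt(np.mean((truth - pred[sel[:, 0], sel[:, 1]]) ** 2))))
        errors[K] = errs
    best_K = min(errors, key=lambda k: np.mean(errors[k]))
    return errors, best_K


# ---------------------------------------------------------------------------
# Allele-sharing distance
# ---------------------------------------------------------------------------

def allele_sharing_distance(G: GenotypeMatrix) -> np.ndarray:
    """Allele-sharing distance matrix (same kernel as the QC stage's
    identity-by-state distance), for external network construction."""
    return ibs_distance_matrix(G)


def write_phylip_square(D: np.ndarray, samples: list[str], path) -> None:
    """Write a distance matrix in square PHYLIP format."""
    with open(path, "w") as fh:
        fh.write(f"{len(samples)}\n")
        for i, s in enumerate(samples):
            row = " ".join(f"{x:.6f}" for x in D[i])
            fh.write(f"{s[:10]:<10} {row}\n")


def align_q_to_reference(Q: np.ndarray, Q_ref: np.ndarray) -> np.ndarray:
    """Resolve label switching: permute Q's columns to best match a
    reference (greedy on column correlations)."""
    K = Q.shape[1]
    remaining = list(range(K))
    order = []
    for k in range(K):
        best_j = max(
            remaining,
            key=lambda j: float(np.dot(Q[:, j], Q_ref[:, k])),
        )
        order.append(best_j)
        remaining.remove(best_j)
    return Q[:, order]
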