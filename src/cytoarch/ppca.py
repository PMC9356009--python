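"""Probabilistic PCA with missing data: EM fitting, evidence-based
dimensionality selection, conditional-mean imputation, and the
simulated-missingness validation against per-feature mean imputation.

Model: x = W z + mu + eps with z ~ N(0, I_k) and isotropic noise
eps ~ N(0, sigma^2 I_d).  With missing entries, the E-step computes the
posterior of z (and implicitly of the missing coordinates) from each row's
observed coordinates; the M-step jointly re-estimates (W, mu) by a
per-feature regression on the augmented latent [z, 1] and then sigma^2 —
an ECM scheme whose observed-data log-likelihood is non-decreasing.
Missing cells are imputed by their conditional expectation
mu_M + W_M <z | x_O>.

Latent dimensionality is chosen by maximizing the Laplace approximation of
the model evidence for PCA (Minka's automatic choice), evaluated on the
eigenspectrum of the mean-filled sample covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class PPCAModel:
    W: np.ndarray  # (d, k) loadings
    mu: np.ndarray  # (d,)
    sigma2: float
    k: int
    log_likelihood: list[float] = field(default_factory=list)
    converged: bool = False
    evidence: dict[int, float] = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.W.shape[0]


def _estep(X0, obs, W, mu, sigma2):
    """Posterior latent moments and observed-data log-likelihood.

    ``X0`` holds the data with missing cells set to 0 and ``obs`` is the
    boolean observed mask.  All rows are handled at once through batched
    k x k linear algebra (per-row B_i = sigma2 I + W_O^T W_O assembled by
    masked tensor contractions), so cost is O(n d k^2) per call regardless
    of how many distinct missingness patterns exist.
    """
    n, d = X0.shape
    k = W.shape[1]
    R = (X0 - mu) * obs  # residuals, zero where missing
    T = W[:, :, None] * W[:, None, :]  # (d, k, k) per-feature outer products
    M = np.tensordot(obs.astype(float), T, axes=(1, 0))  # (n, k, k)
    B = M + sigma2 * np.eye(k)
    A = np.linalg.inv(B)
    b = R @ W  # (n, k)
    Z = np.einsum("nij,nj->ni", A, b)
    covs = sigma2 * A  # (n, k, k) posterior covariance of z per row
    _, logdetB = np.linalg.slogdet(B)
    n_obs_row = obs.sum(axis=1)
    logdetC = (n_obs_row - k) * np.log(sigma2) + logdetB
    quad = (np.einsum("ij,ij->i", R, R) - np.einsum("ni,ni->n", b, Z)) / sigma2
    ll = -0.5 * float(np.sum(n_obs_row * _LOG2PI + logdetC + quad))
    return Z, covs, ll


def fit_ppca(
    matrix,
    k: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_restarts: int = 3,
) -> PPCAModel:
    """Fit PPCA to a (rows x features) array with NaN marking missing cells.

    Every row and column must have at least one observed value and
    1 <= k < min(n_rows, n_features).  Runs ``n_restarts`` EM fits from an
    SVD-based initialization (subsequent restarts perturbed, seeded) and
    keeps the best final log-likelihood.
    """
    X = np.asarray(matrix, dtype=float)
    n, d = X.shape
    obs = ~np.isnan(X)
    if not obs.any(axis=1).all():
        raise ValueError("every row needs at least one observed value")
    if not obs.any(axis=0).all():
        raise ValueError("every column needs at least one observed value")
    if not 1 <= k < min(n, d):
        raise ValueError(f"k must satisfy 1 <= k < {min(n, d)}")
    obs_f = obs.astype(float)
    X0 = np.where(obs, X, 0.0)
    n_obs = int(obs.sum())

    mu0 = np.nanmean(X, axis=0)
    Xf = np.where(obs, X, mu0)
    Xc = Xf - Xf.mean(axis=0)
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    lam = s**2 / n
    sigma2_0 = float(np.mean(lam[k:])) if lam.size > k else float(lam[-1]) * 0.1
    sigma2_0 = max(sigma2_0, 1e-8)
    W0 = Vt[:k].T * np.sqrt(np.maximum(lam[:k] - sigma2_0, 1e-8))

    rng = np.random.default_rng(seed)
    best: PPCAModel | None = None
    for restart in range(max(n_restarts, 1)):
        W = W0.copy()
        if restart > 0:
            W = W + rng.normal(scale=0.1 * (np.abs(W0).mean() + 1e-8), size=W.shape)
        mu = mu0.copy()
        sigma2 = sigma2_0
        trace: list[float] = []
        converged = False
        for _ in range(max_iter):
            Z, covs, ll = _estep(X0, obs, W, mu, sigma2)
            if trace:
                if ll < trace[-1] - 1e-8 * (1.0 + abs(trace[-1])):
                    raise RuntimeError("EM log-likelihood decreased")
                if abs(ll - trace[-1]) <= tol * (1.0 + abs(trace[-1])):
                    trace.append(ll)
                    converged = True
                    break
            trace.append(ll)
            # M-step: joint (W, mu) per-feature regression on [z, 1]
            Zt = np.hstack([Z, np.ones((n, 1))])  # (n, k+1)
            S1 = (X0 * obs_f).T @ Zt  # (d, k+1)
            G = Zt[:, :, None] * Zt[:, None, :]  # (n, k+1, k+1)
            G[:, :k, :k] += covs
            S2 = np.tensordot(obs_f.T, G, axes=(1, 0))  # (d, k+1, k+1)
            S2 += 1e-9 * np.eye(k + 1)[None]  # guard near-singular sparse features
            theta = np.linalg.solve(S2, S1[:, :, None])[:, :, 0]
            W_new, mu_new = theta[:, :k], theta[:, k]
            # sigma^2 with new (W, mu), posterior moments from the E-step
            resid = (X0 - mu_new - Z @ W_new.T) * obs_f
            T_new = W_new[:, :, None] * W_new[:, None, :]
            M_new = np.tensordot(obs_f, T_new, axes=(1, 0))  # (n, k, k)
            total = float(np.einsum("ij,ij->", resid, resid)) + float(
                np.einsum("nab,nab->", covs, M_new)
            )
            W, mu, sigma2 = W_new, mu_new, max(total / n_obs, 1e-12)
        model = PPCAModel(W, mu, float(sigma2), k, trace, converged)
        if best is None or trace[-1] > best.log_likelihood[-1]:
            best = model
    return best


def impute(matrix, model: PPCAModel) -> np.ndarray:
    """Replace missing cells by conditional expectations; keep observed cells."""
    X = np.asarray(matrix, dtype=float)
    if X.shape[1] != model.n_features:
        raise ValueError("feature count does not match the fitted model")
    obs = ~np.isnan(X)
    X0 = np.where(obs, X, 0.0)
    Z, _, _ = _estep(X0, obs, model.W, model.mu, model.sigma2)
    pred = model.mu + Z @ model.W.T
    return np.where(obs, X, pred)


def minka_log_evidence(eigenvalues: np.ndarray, n_rows: int, k: int) -> float:
    """Laplace-approximation log evidence for a k-dimensional PCA model."""
    lam = np.maximum(np.sort(np.asarray(eigenvalues))[::-1], 1e-12)
    d = lam.size
    if not 1 <= k < d:
        raise ValueError("k must satisfy 1 <= k < n_features")
    N = n_rows
    sigma2 = float(np.mean(lam[k:]))
    m = d * k - k * (k + 1) // 2
    i = np.arange(1, k + 1)
    log_pu = -k * np.log(2.0) + float(
        np.sum(gammaln((d - i + 1) / 2.0) - ((d - i + 1) / 2.0) * np.log(np.pi))
    )
    log_lik = -N / 2.0 * float(np.sum(np.log(lam[:k]))) - N * (d - k) / 2.0 * np.log(
        sigma2
    )
    lam_hat = np.where(np.arange(d) < k, lam, sigma2)
    log_az = 0.0
    for a in range(k):
        j = np.arange(a + 1, d)
        terms = (1.0 / lam_hat[j] - 1.0 / lam_hat[a]) * (lam[a] - lam[j]) * N
        log_az += float(np.sum(np.log(np.maximum(terms, 1e-300))))
    return (
        log_pu
        + log_lik
        + (m + k) / 2.0 * _LOG2PI
        - 0.5 * log_az
        - k / 2.0 * np.log(N)
    )


def select_dimensionality(
    matrix, k_candidates=None
) -> tuple[int, dict[int, float]]:
    """Pick the latent dimension maximizing the Laplace log evidence.

    The eigenspectrum is taken from the mean-filled, column-centered sample
    covariance (MLE normalization), so selection needs no EM runs; the full
    evidence curve is returned for audit.
    """
    X = np.asarray(matrix, dtype=float)
    n, d = X.shape
    mu = np.nanmean(X, axis=0)
    Xf = np.where(np.isnan(X), mu, X)
    Xc = Xf - Xf.mean(axis=0)
    lam = np.sort(np.linalg.eigvalsh(Xc.T @ Xc / n))[::-1]
    kmax = min(n, d) - 1
    candidates = list(k_candidates) if k_candidates is not None else list(range(1, kmax))
    candidates = [k for k in candidates if 1 <= k <= kmax - 0]
    candidates = [k for k in candidates if k < d]
    if not candidates:
        raise ValueError("no valid dimensionality candidate")
    evidence = {k: minka_log_evidence(lam, n, k) for k in candidates}
    k_star = max(evidence, key=lambda k: (evidence[k], -k))
    return k_star, evidence


@dataclass
class ImputationValidation:
    errors: pd.DataFrame  # columns: replicate, method, rmse
    missing_rate: float
    n_replicates: int
    seed: int

    def rmse(self, method: str) -> np.ndarray:
        sel = self.errors[self.errors["method"] == method]
        return sel.sort_values("replicate")["rmse"].to_numpy()

    def ppca_win_fraction(self) -> float:
        return float(np.mean(self.rmse("ppca") < self.rmse("mean")))


def validate_imputation(
    matrix,
    missing_rate: float,
    n_replicates: int,
    seed: int = 0,
    k: int | None = None,
    k_candidates=None,
) -> ImputationValidation:
    """Mask known cells at the study missing rate and score both imputers.

    Per replicate a fresh random subset of observed cells is hidden, the
    matrix is completed by PPCA (dimension fixed or evidence-selected on the
    masked data) and by per-feature observed means, and the root-mean-square
    error is computed on the hidden cells only — the same cells for both
    methods.
    """
    if not 0.0 < missing_rate < 1.0:
        raise ValueError("missing_rate must be in (0, 1)")
    X = np.asarray(matrix, dtype=float)
    obs_cells = np.argwhere(~np.isnan(X))
    n_mask = max(int(round(missing_rate * obs_cells.shape[0])), 1)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        chosen = obs_cells[rng.choice(obs_cells.shape[0], n_mask, replace=False)]
        Xm = X.copy()
        Xm[chosen[:, 0], chosen[:, 1]] = np.nan
        # keep every row/column identifiable: restore cells where masking
        # emptied a line
        keep = np.ones(len(chosen), dtype=bool)
        obs_m = ~np.isnan(Xm)
        for axis in (0, 1):
            empty = np.flatnonzero(~obs_m.any(axis=1 - axis))
            for e in empty:
                cand = np.flatnonzero(keep & (chosen[:, axis] == e))
                i = cand[0]
                keep[i] = False
                Xm[chosen[i, 0], chosen[i, 1]] = X[chosen[i, 0], chosen[i, 1]]
        chosen = chosen[keep]
        kk = k
        if kk is None:
            kk, _ = select_dimensionality(Xm, k_candidates)
        model = fit_ppca(Xm, kk, seed=rng.integers(2**31))
        completed = impute(Xm, model)
        truth = X[chosen[:, 0], chosen[:, 1]]
        ppca_err = float(
            np.sqrt(np.mean((completed[chosen[:, 0], chosen[:, 1]] - truth) ** 2))
        )
        col_means = np.nanmean(Xm, axis=0)
        mean_err = float(np.sqrt(np.mean((col_means[chosen[:, 1]] - truth) ** 2)))
        rows.append({"replicate": rep, "method": "ppca", "rmse": ppca_err})
        rows.append({"replicate": rep, "method": "mean", "rmse": mean_err})
    return ImputationValidation(pd.DataFrame(rows), missing_rate, n_replicates, seed)
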