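"""Maximum-likelihood admixture estimation by EM, K selection, replicate alignment.

Model: individual i's genotype at biallelic site j is Binomial(2, π_ij) with
π_ij = Σ_k q_ik f_kj, where q_ik are ancestry proportions (rows of Q on the
simplex) and f_kj cluster allele frequencies.  Q and F are estimated by the
classic block EM for this likelihood; the number of clusters K is chosen by
masked-entry cross-validation, and replicate runs (whose cluster labels are
arbitrary) are aligned by Hungarian matching before averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .genio import MISSING, GenotypeMatrix

__all__ = [
    "AdmixtureFit",
    "CVResult",
    "admixture_loglik",
    "fit_admixture",
    "cross_validate_K",
    "align_replicates",
]

logger = logging.getLogger(__name__)

EPS = 1e-6  # cluster frequencies are clamped to [EPS, 1-EPS]


def _geno_array(G) -> np.ndarray:
    """Accept a GenotypeMatrix or a raw N×L int array with -1 for missing."""
    if isinstance(G, GenotypeMatrix):
        return G.genotypes
    return np.asarray(G)


@dataclass
class AdmixtureFit:
    """Result of one EM run."""

    Q: np.ndarray
    F: np.ndarray
    loglik_trace: np.ndarray
    K: int
    n_iter: int
    converged: bool
    seed: int | None

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


@dataclass
class CVResult:
    """Cross-validation errors per K; lower is better."""

    K_values: list[int]
    errors: np.ndarray  # (n_K, folds) mean squared prediction error
    recommended_K: int

    def mean_errors(self) -> np.ndarray:
        return self.errors.mean(axis=1)

    def sd_errors(self) -> np.ndarray:
        return self.errors.std(axis=1, ddof=1) if self.errors.shape[1] > 1 else (
            np.zeros(len(self.K_values))
        )


def admixture_loglik(G, Q: np.ndarray, F: np.ndarray) -> float:
    """Binomial log-likelihood ℓ = Σ_obs [g ln π + (2−g) ln(1−π)].

    The binomial coefficient is omitted (constant in the parameters);
    missing genotypes contribute nothing.
    """
    g = _geno_array(G)
    Q = np.asarray(Q, dtype=float)
    F = np.asarray(F, dtype=float)
    if g.shape != (Q.shape[0], F.shape[1]) or Q.shape[1] != F.shape[0]:
        raise ValueError("inconsistent dimensions for G, Q, F")
    W = g != MISSING
    g0 = np.where(W, g, 0).astype(float)
    P = np.clip(Q @ F, 1e-12, 1.0 - 1e-12)
    ll = W * (g0 * np.log(P) + (2.0 - g0) * np.log1p(-P))
    return float(ll.sum())


def _em_step(
    g0: np.ndarray, W: np.ndarray, Q: np.ndarray, F: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    P = np.clip(Q @ F, 1e-12, 1.0 - 1e-12)
    R1 = np.where(W, g0 / P, 0.0)
    R0 = np.where(W, (2.0 - g0) / (1.0 - P), 0.0)
    K = Q.shape[1]
    Qn = np.empty_like(Q)
    Fn = np.empty_like(F)
    for k in range(K):
        t1 = (Q[:, k : k + 1] * F[k]) * R1
        t0 = (Q[:, k : k + 1] * (1.0 - F[k])) * R0
        Qn[:, k] = t1.sum(axis=1) + t0.sum(axis=1)
        s1 = t1.sum(axis=0)
        s0 = t0.sum(axis=0)
        Fn[k] = s1 / np.maximum(s1 + s0, 1e-300)
    n_obs = W.sum(axis=1)
    Qn /= np.maximum(2.0 * n_obs, 1)[:, None]
    Qn /= Qn.sum(axis=1, keepdims=True)
    return Qn, np.clip(Fn, EPS, 1.0 - EPS)


def fit_admixture(
    G,
    K: int,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
    init_Q: np.ndarray | None = None,
    init_F: np.ndarray | None = None,
) -> AdmixtureFit:
    """Fit Q and F for a given K by EM.

    Q rows are initialized from a seeded flat Dirichlet; F from the global
    observed allele frequencies with multiplicative jitter to break cluster
    symmetry.  Convergence is declared when the log-likelihood improves by
    less than ``tol``; the trace is monotone non-decreasing (an EM
    guarantee, up to the frequency clamp).
    """
    g = _geno_array(G)
    N, L = g.shape
    if K > N:
        raise ValueError(f"K={K} exceeds the number of samples ({N})")
    if K < 1:
        raise ValueError("K must be positive")
    W = g != MISSING
    if not W.any():
        raise ValueError("no observed genotypes")
    g0 = np.where(W, g, 0).astype(float)

    rng = np.random.default_rng(seed)
    Q = rng.dirichlet(np.ones(K), size=N) if init_Q is None else np.array(
        init_Q, dtype=float)
    with np.errstate(invalid="ignore"):
        pbar = np.where(W.sum(axis=0) > 0, g0.sum(axis=0) / np.maximum(
            2.0 * W.sum(axis=0), 1), 0.5)
    if init_F is None:
        F = np.clip(
            pbar[None, :] * np.exp(rng.normal(0.0, 0.3, size=(K, L))),
            EPS, 1.0 - EPS,
        )
    else:
        F = np.clip(np.array(init_F, dtype=float), EPS, 1.0 - EPS)

    trace = [admixture_loglik(g, Q, F)]
    converged = False
    for it in range(1, max_iter + 1):
        Q, F = _em_step(g0, W, Q, F)
        ll = admixture_loglik(g, Q, F)
        trace.append(ll)
        if ll - trace[-2] < tol and ll >= trace[-2] - 1e-8:
            converged = True
            break
    if not converged:
        logger.warning("fit_admixture: no convergence in %d iterations", max_iter)
    return AdmixtureFit(Q, F, np.array(trace), K, len(trace) - 1, converged, seed)


def cross_validate_K(
    G,
    K_range=range(1, 7),
    folds: int = 5,
    holdout_frac: float = 0.1,
    seed: int | None = None,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> CVResult:
    """Choose K by hiding genotype entries and scoring their prediction.

    Per fold, a seeded mask hides ``holdout_frac`` of the non-missing
    entries (redrawn, with a log message, if a sample would lose all of its
    data); the model is fit on the remainder and the hidden genotypes are
    predicted as ĝ = 2π.  The per-fold error is the mean squared
    difference; the recommended K minimizes the across-fold mean.
    """
    g = _geno_array(G)
    W = g != MISSING
    obs_idx = np.argwhere(W)
    n_hold = max(1, int(round(holdout_frac * len(obs_idx))))
    rng = np.random.default_rng(seed)
    K_values = list(K_range)
    errors = np.empty((len(K_values), folds))
    for fold in range(folds):
        for attempt in range(20):
            sel = rng.choice(len(obs_idx), size=n_hold, replace=False)
            rows = obs_idx[sel, 0]
            per_row = np.bincount(rows, minlength=g.shape[0])
            if np.all(W.sum(axis=1) - per_row > 0):
                break
            logger.info("cross_validate_K: redrawing mask (a sample lost all data)")
        mask_rows, mask_cols = obs_idx[sel, 0], obs_idx[sel, 1]
        g_train = g.copy()
        g_train[mask_rows, mask_cols] = MISSING
        for ki, K in enumerate(K_values):
            fit = fit_admixture(
                g_train, K, seed=rng.integers(2**31), tol=tol, max_iter=max_iter
            )
            pred = 2.0 * np.clip(fit.Q @ fit.F, 0.0, 1.0)
            resid = g[mask_rows, mask_cols] - pred[mask_rows, mask_cols]
            errors[ki, fold] = float(np.mean(resid**2))
    recommended = K_values[int(np.argmin(errors.mean(axis=1)))]
    return CVResult(K_values, errors, recommended)


def align_replicates(
    q_list: list[np.ndarray],
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Align replicate Q matrices (label-switching) and average them.

    Each replicate's columns are permuted to best match the first replicate
    (Hungarian assignment maximizing the total column-wise Pearson
    correlation); the consensus is the element-wise mean of aligned
    replicates, re-normalized to the simplex.  Returns (consensus, list of
    permutations), where ``perm[r][k]`` is the source column in replicate r
    for consensus column k.
    """
    if not q_list:
        raise ValueError("no replicates given")
    ref = np.asarray(q_list[0], dtype=float)
    N, K = ref.shape
    aligned = [ref]
    perms = [np.arange(K)]
    for q in q_list[1:]:
        q = np.asarray(q, dtype=float)
        if q.shape != (N, K):
            raise ValueError("replicates must share N and K")
        corr = np.zeros((K, K))
        for a in range(K):
            for b in range(K):
                sa = ref[:, a] - ref[:, a].mean()
                sb = q[:, b] - q[:, b].mean()
                denom = np.sqrt((sa**2).sum() * (sb**2).sum())
                corr[a, b] = (sa @ sb) / denom if denom > 0 else 0.0
        rows, cols = linear_sum_assignment(-corr)
        perm = cols[np.argsort(rows)]
        aligned.append(q[:, perm])
        perms.append(perm)
    consensus = np.mean(aligned, axis=0)
    consensus = np.clip(consensus, 0.0, None)
    consensus /= consensus.sum(axis=1, keepdims=True)
    return consensus, perms
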