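"""Independent brute-force oracles used to check the package's fast paths.

Everything here is deliberately naive (double loops, dense solves) and
shares no code with the implementation it verifies.
"""

from __future__ import annotations

import math

import numpy as np


def naive_admixture_loglik(g: np.ndarray, Q: np.ndarray, F: np.ndarray) -> float:
    """Binomial admixture log-likelihood by explicit double loop."""
    N, L = g.shape
    K = Q.shape[1]
    total = 0.0
    for i in range(N):
        for j in range(L):
            if g[i, j] < 0:
                continue
            pij = 0.0
            for k in range(K):
                pij += Q[i, k] * F[k, j]
            pij = min(max(pij, 1e-12), 1 - 1e-12)
            total += g[i, j] * math.log(pij) + (2 - g[i, j]) * math.log(1 - pij)
    return total


def dense_ok_predict(
    points: np.ndarray, values: np.ndarray, gamma, targets: np.ndarray
) -> np.ndarray:
    """Ordinary kriging using every observation (no neighborhood truncation)."""
    n = len(points)
    A = np.zeros((n + 1, n + 1))
    for a in range(n):
        for b in range(n):
            d = math.dist(points[a], points[b])
            A[a, b] = gamma(d) if d > 0 else 0.0
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    out = np.empty(len(targets))
    for t, target in enumerate(np.atleast_2d(targets)):
        rhs = np.empty(n + 1)
        for a in range(n):
            d = math.dist(points[a], target)
            rhs[a] = gamma(d) if d > 0 else 0.0
        rhs[n] = 1.0
        w = np.linalg.solve(A, rhs)[:n]
        out[t] = float(w @ values)
    return out


def brute_site_filter(
    g: np.ndarray, min_mac: int, max_site_missing: float, max_het: float
) -> tuple[list[int], dict[str, int]]:
    """Per-site recount of the filter cascade, one site at a time."""
    N, L = g.shape
    keep = []
    removed = {"site_missingness": 0, "mac": 0, "excess_het": 0}
    for j in range(L):
        col = g[:, j]
        obs = col[col >= 0]
        miss = 1 - len(obs) / N
        if miss > max_site_missing:
            removed["site_missingness"] += 1
            continue
        alt = int(obs.sum())
        mac = min(alt, 2 * len(obs) - alt)
        if mac < min_mac:
            removed["mac"] += 1
            continue
        if mac > 0 and len(obs) > 0 and (obs == 1).sum() / len(obs) > max_het:
            removed["excess_het"] += 1
            continue
        keep.append(j)
    return keep, removed


def brute_sample_filter(g: np.ndarray, min_completeness: float) -> list[int]:
    keep = []
    for i in range(g.shape[0]):
        row = g[i]
        if (row >= 0).sum() / len(row) >= min_completeness:
            keep.append(i)
    return keep


def brute_prevosti(ga: np.ndarray, gb: np.ndarray) -> float:
    num = 0.0
    cnt = 0
    for a, b in zip(ga, gb):
        if a >= 0 and b >= 0:
            num += abs(int(a) - int(b)) / 2.0
            cnt += 1
    return num / cnt


def wc_fst(genotypes: np.ndarray, pops: np.ndarray) -> float:
    """Weir–Cockerham (1984) multilocus FST (ratio of averages) for biallelic codes.

    ``genotypes`` is N×L in {0,1,2,-1}; ``pops`` assigns each sample to a
    population.  Returns Σa / Σ(a+b+c) over loci with valid components.
    """
    labels = np.unique(pops)
    r = len(labels)
    num = 0.0
    den = 0.0
    for j in range(genotypes.shape[1]):
        ns, ps, hs = [], [], []
        for lab in labels:
            col = genotypes[pops == lab, j]
            col = col[col >= 0]
            if len(col) == 0:
                break
            ns.append(len(col))
            ps.append(col.sum() / (2 * len(col)))
            hs.append((col == 1).sum() / len(col))
        else:
            n = np.array(ns, float)
            p = np.array(ps)
            h = np.array(hs)
            nbar = n.mean()
            if nbar <= 1:
                continue
            nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
            pbar = (n * p).sum() / (r * nbar)
            s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n * h).sum() / (r * nbar)
            a = (nbar / nc) * (
                s2
                - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            num += a
            den += a + b + c
    return num / den
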