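"""Entropy and fractal-dimension estimators for short iEEG segments.

Standard literature definitions, tuned for the short coefficient vectors
produced by wavelet decomposition of event segments.  All estimators
return finite values on finite non-constant input; degenerate inputs
(constant, too short) fall back to documented conventions instead of
NaN/inf so that downstream feature tables stay numeric.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

__all__ = [
    "shannon_entropy",
    "renyi_entropy",
    "permutation_entropy",
    "sample_entropy",
    "kraskov_entropy",
    "svd_entropy",
    "petrosian_fd",
    "katz_fd",
    "higuchi_fd",
]


def _power_dist(x: np.ndarray) -> np.ndarray | None:
    p = np.asarray(x, dtype=float) ** 2
    total = p.sum()
    if total <= 0:
        return None
    return p / total


def shannon_entropy(coeffs: np.ndarray) -> float:
    """Shannon entropy (nats) of the normalized squared coefficients.

    All-zero input returns the maximum entropy ``log(n)`` by convention.
    """
    p = _power_dist(coeffs)
    if p is None:
        return math.log(max(len(coeffs), 1)) if len(coeffs) > 1 else 0.0
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def renyi_entropy(coeffs: np.ndarray, order: float = 2.0) -> float:
    """Renyi entropy (nats) of the normalized squared coefficients."""
    p = _power_dist(coeffs)
    if p is None:
        return math.log(max(len(coeffs), 1)) if len(coeffs) > 1 else 0.0
    return float(np.log((p**order).sum()) / (1.0 - order))


def permutation_entropy(x: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Entropy (nats) of the ordinal-pattern distribution (ties broken by
    position, the usual argsort convention)."""
    x = np.asarray(x, dtype=float)
    n = x.size - (order - 1) * delay
    if n < 1:
        return 0.0
    patterns = np.empty(n, dtype=np.int64)
    idx = np.arange(order) * delay
    base = np.array([math.factorial(order - 1 - i) for i in range(order)])
    for i in range(n):
        patterns[i] = int((np.argsort(x[i + idx], kind="stable") * base).sum())
    _, counts = np.unique(patterns, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy with Chebyshev distance; ``r`` defaults to 0.2*SD.

    Computed as ``-log((A+1)/(B+1))`` where A/B are the m+1 / m template
    match counts; the +1 regularization keeps the value finite when no
    template matches on short segments.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        return 0.0
    if r is None:
        r = 0.2 * x.std()
    if r <= 0:
        return 0.0

    def _count(mm: int) -> int:
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)
        # pairwise Chebyshev matches, excluding self-pairs
        total = 0
        for i in range(templ.shape[0] - 1):
            d = np.abs(templ[i + 1 :] - templ[i]).max(axis=1)
            total += int((d <= r).sum())
        return total

    b = _count(m)
    a = _count(m + 1)
    return float(-np.log((a + 1.0) / (b + 1.0)))


def kraskov_entropy(x: np.ndarray, k: int = 4) -> float:
    """Kozachenko-Leonenko (KSG) differential-entropy estimate, nats.

    1-D k-nearest-neighbour estimator:
    ``H = psi(N) - psi(k) + mean(log(2 * eps_k))`` with ``eps_k`` the
    distance to the k-th neighbour.  Duplicate samples are supported by
    flooring distances at machine tiny.
    """
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    n = x.shape[0]
    if n < 3:
        return 0.0
    k = min(k, n - 1)
    tree = cKDTree(x)
    dist, _ = tree.query(x, k=k + 1)
    eps = np.maximum(dist[:, -1], np.finfo(float).tiny)
    return float(digamma(n) - digamma(k) + np.mean(np.log(2.0 * eps)))


def svd_entropy(x: np.ndarray, embedding: int = 10, delay: int = 1) -> float:
    """Shannon entropy (nats) of the normalized singular-value spectrum of
    the delay-embedded trajectory matrix."""
    x = np.asarray(x, dtype=float)
    emb = min(embedding, max(x.size // 2, 2))
    n = x.size - (emb - 1) * delay
    if n < 2:
        return 0.0
    mat = np.lib.stride_tricks.sliding_window_view(x, emb)[::delay][:n]
    s = np.linalg.svd(mat, compute_uv=False)
    total = s.sum()
    if total <= 0:
        return 0.0
    p = s / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def petrosian_fd(x: np.ndarray) -> float:
    """Petrosian fractal dimension from sign changes of the derivative."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        return 1.0
    diff = np.diff(x)
    n_delta = int(np.count_nonzero(diff[:-1] * diff[1:] < 0))
    if n_delta == 0:
        return 1.0
    return float(
        math.log10(n) / (math.log10(n) + math.log10(n / (n + 0.4 * n_delta)))
    )


def katz_fd(x: np.ndarray) -> float:
    """Katz fractal dimension; degenerate (flat) input returns 1."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return 1.0
    dists = np.sqrt(1.0 + np.diff(x) ** 2)
    L = dists.sum()
    a = L / (n - 1)
    d = np.sqrt(np.arange(n) ** 2 + (x - x[0]) ** 2).max()
    if L <= 0 or d <= 0:
        return 1.0
    denom = math.log10(d / L) + math.log10(n - 1)
    if denom == 0:
        return 1.0
    return float(math.log10(n - 1) / denom)


def higuchi_fd(x: np.ndarray, k_max: int = 10) -> float:
    """Higuchi fractal dimension (least-squares slope of log curve length
    versus log 1/k); constant input returns 1."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        return 1.0
    k_max = max(min(k_max, n // 2), 2)
    lk = []
    ks = []
    for k in range(1, k_max + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            lm = np.abs(np.diff(x[idx])).sum() * (n - 1) / (((idx.size - 1) * k) * k)
            lengths.append(lm)
        if lengths:
            mean_l = np.mean(lengths)
            if mean_l > 0:
                lk.append(math.log(mean_l))
                ks.append(math.log(1.0 / k))
    if len(lk) < 2:
        return 1.0
    slope = np.polyfit(ks, lk, 1)[0]
    return float(slope)
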