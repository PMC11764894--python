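"""Six entropy estimators for one rhythm sequence.

All estimators use the natural logarithm and return nonnegative values (up
to a tiny slack introduced by the ``eps`` guard against ``log(0)``).
Degenerate constant inputs yield 0 by convention, so downstream feature
matrices never contain NaN.

Conventions follow the dominant usage in the nonlinear time-series
literature: Chebyshev distance with tolerance ``r = r_frac * SD(x)`` for the
template entropies, self-matches excluded for sample entropy and included
for approximate entropy, mean-centred templates with an exponential
membership function for fuzzy entropy, stable argsort tie-breaking for
ordinal patterns, and a Hann-windowed Welch periodogram for the spectral
entropy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import welch
from scipy.spatial.distance import cdist

__all__ = [
    "EntropyConfig",
    "shannon_entropy",
    "spectral_entropy",
    "singular_spectrum_entropy",
    "sample_entropy",
    "fuzzy_entropy",
    "approximate_entropy",
    "permutation_entropy",
    "FEATURES",
    "all_entropies",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EntropyConfig:
    """Parameters shared by the entropy estimators.

    ``m`` is the embedding dimension, ``r_frac`` the tolerance expressed as
    a fraction of the sequence's standard deviation, ``n_fuzzy`` the fuzzy
    membership exponent, ``pe_order``/``pe_delay`` the ordinal pattern order
    and delay, ``eps`` the guard added inside logarithms, ``welch_nperseg``
    and ``welch_overlap_frac`` the Welch segmentation, and ``sse_window``
    the trajectory-matrix window length.
    """

    m: int = 2
    r_frac: float = 0.2
    n_fuzzy: float = 2.0
    pe_order: int = 3
    pe_delay: int = 1
    eps: float = 1e-12
    welch_nperseg: int = 256
    welch_overlap_frac: float = 0.5
    sse_window: int = 10

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_frac <= 0:
            raise ValueError("r_frac must be > 0")
        if self.n_fuzzy <= 0:
            raise ValueError("n_fuzzy must be > 0")
        if self.pe_order < 2:
            raise ValueError("pe_order must be >= 2")
        if self.pe_delay < 1:
            raise ValueError("pe_delay must be >= 1")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.sse_window < 2:
            raise ValueError("sse_window must be >= 2")
        if not 0 <= self.welch_overlap_frac < 1:
            raise ValueError("welch_overlap_frac must be in [0, 1)")


def _validate(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("input sequence must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("input sequence contains non-finite values")
    return x


def shannon_entropy(p: np.ndarray, eps: float = 1e-12) -> float:
    """``-sum(p * log(p + eps))`` for a normalized distribution ``p``."""
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < 0):
        raise ValueError("probabilities must be nonnegative")
    return float(-np.sum(p * np.log(p + eps)))


def spectral_entropy(x, fs: float,
                     cfg: EntropyConfig = EntropyConfig()) -> float:
    """Shannon entropy of the Welch PSD normalized to sum 1 (PSDE)."""
    x = _validate(x)
    if len(x) < 2:
        raise ValueError("sequence too short for a spectrum")
    if not np.any(x):
        logger.debug("spectral_entropy: all-zero signal, returning 0")
        return 0.0
    nperseg = min(cfg.welch_nperseg, len(x))
    noverlap = int(nperseg * cfg.welch_overlap_frac)
    _, pxx = welch(x, fs=fs, window="hann", nperseg=nperseg,
                   noverlap=noverlap)
    total = pxx.sum()
    if total == 0:
        return 0.0
    return shannon_entropy(pxx / total, cfg.eps)


def singular_spectrum_entropy(x, cfg: EntropyConfig = EntropyConfig()) -> float:
    """Shannon entropy of the normalized singular values of the
    time-delay trajectory matrix (SSE).

    The trajectory matrix has shape ``L x (N - L + 1)`` with window
    ``L = cfg.sse_window``; its singular values are normalized to sum 1.
    """
    x = _validate(x)
    L = cfg.sse_window
    if len(x) <= L:
        raise ValueError(f"sequence too short: need N > sse_window={L}")
    traj = sliding_window_view(x, len(x) - L + 1)  # rows x[i:i+N-L+1]
    sv = np.linalg.svd(traj, compute_uv=False)
    total = sv.sum()
    if total == 0:
        return 0.0
    return shannon_entropy(sv / total, cfg.eps)


def _embed(x: np.ndarray, m: int, count: int) -> np.ndarray:
    return sliding_window_view(x, m)[:count]


def sample_entropy(x, cfg: EntropyConfig = EntropyConfig()) -> float:
    """Sample entropy ``-ln(phi(m+1) / phi(m))``.

    ``phi(m)`` counts pairs of distinct length-``m`` templates whose
    Chebyshev distance is within ``r``; both template sets use the first
    ``N - m`` windows so the pair counts are comparable.  A constant
    sequence returns 0; if no ``m+1`` pair matches, the bounded sentinel
    ``ln(phi(m) * (N - m))`` is returned instead of infinity.
    """
    x = _validate(x)
    N = len(x)
    m = cfg.m
    if N <= m + 1:
        raise ValueError(f"sequence too short: need N > m+1={m + 1}")
    sd = x.std()
    if sd == 0:
        return 0.0
    r = cfg.r_frac * sd

    def pairs(mm: int) -> int:
        t = _embed(x, mm, N - m)
        d = cdist(t, t, metric="chebyshev")
        return int(np.count_nonzero(d[np.triu_indices(len(t), k=1)] <= r))

    b = pairs(m)
    a = pairs(m + 1)
    if b == 0:
        return float(np.log((N - m) * (N - m - 1)))
    if a == 0:
        return float(np.log(b * (N - m)))
    return float(-np.log(a / b))


def fuzzy_entropy(x, cfg: EntropyConfig = EntropyConfig()) -> float:
    """Fuzzy entropy ``ln(phi^m) - ln(phi^(m+1))``.

    Templates are mean-centred and pair similarity is the exponential
    membership ``exp(-(d/r)^n)`` of their Chebyshev distance.
    """
    x = _validate(x)
    N = len(x)
    m = cfg.m
    if N <= m + 1:
        raise ValueError(f"sequence too short: need N > m+1={m + 1}")
    sd = x.std()
    if sd == 0:
        return 0.0
    r = cfg.r_frac * sd

    def phi(mm: int) -> float:
        t = _embed(x, mm, N - m)
        t = t - t.mean(axis=1, keepdims=True)
        d = cdist(t, t, metric="chebyshev")
        mu = np.exp(-((d / r) ** cfg.n_fuzzy))
        np.fill_diagonal(mu, 0.0)
        return float(mu.sum(axis=1).mean() / (len(t) - 1))

    return float(np.log(phi(m)) - np.log(phi(m + 1)))


def approximate_entropy(x, cfg: EntropyConfig = EntropyConfig()) -> float:
    """Approximate entropy ``Phi^m(r) - Phi^(m+1)(r)``.

    ``Phi^m`` is the mean over all ``N - m + 1`` templates of the log of the
    fraction of templates (self-match included) within Chebyshev distance
    ``r``.
    """
    x = _validate(x)
    N = len(x)
    m = cfg.m
    if N <= m + 1:
        raise ValueError(f"sequence too short: need N > m+1={m + 1}")
    sd = x.std()
    if sd == 0:
        return 0.0
    r = cfg.r_frac * sd

    def phi(mm: int) -> float:
        t = sliding_window_view(x, mm)
        d = cdist(t, t, metric="chebyshev")
        frac = np.count_nonzero(d <= r, axis=1) / len(t)
        return float(np.mean(np.log(frac)))

    return phi(m) - phi(m + 1)


def permutation_entropy(x, cfg: EntropyConfig = EntropyConfig()) -> float:
    """Shannon entropy of the ordinal-pattern distribution (PE).

    Ties are broken by earlier index (stable argsort).  The value lies in
    ``[0, ln(order!)]``.
    """
    x = _validate(x)
    order, delay = cfg.pe_order, cfg.pe_delay
    if len(x) < order * delay + 1:
        raise ValueError(
            f"sequence too short: need N >= pe_order*pe_delay+1="
            f"{order * delay + 1}")
    n_pat = len(x) - (order - 1) * delay
    idx = np.arange(n_pat)[:, None] + delay * np.arange(order)[None, :]
    patterns = np.argsort(x[idx], axis=1, kind="stable")
    # injective encoding: digits of the permutation in base `order`
    codes = patterns @ (order ** np.arange(order))
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(max(-np.sum(p * np.log(p)), 0.0))


#: Feature registry in BREM column order (AE, FE, SE, PE, SSE, PSDE).
FEATURES = ("ae", "fe", "se", "pe", "sse", "psde")


def all_entropies(x, fs: float,
                  cfg: EntropyConfig = EntropyConfig()) -> dict[str, float]:
    """Compute all six entropies of one sequence, keyed by feature code."""
    return {
        "ae": approximate_entropy(x, cfg),
        "fe": fuzzy_entropy(x, cfg),
        "se": sample_entropy(x, cfg),
        "pe": permutation_entropy(x, cfg),
        "sse": singular_spectrum_entropy(x, cfg),
        "psde": spectral_entropy(x, fs, cfg),
    }
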