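"""Independent brute-force reference implementations used only by tests.

Deliberately naive (explicit Python loops, exhaustive enumeration) so they
share no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np


def chebyshev(u, v) -> float:
    return max(abs(a - b) for a, b in zip(u, v))


def sampen_bruteforce(x, m: int, r: float) -> float:
    """Sample entropy by exhaustive pair counting over N-m templates."""
    x = list(map(float, x))
    N = len(x)

    def count(mm: int) -> int:
        t = [x[i:i + mm] for i in range(N - m)]
        c = 0
        for i in range(len(t)):
            for j in range(i + 1, len(t)):
                if chebyshev(t[i], t[j]) <= r:
                    c += 1
        return c

    b, a = count(m), count(m + 1)
    if b == 0:
        return math.log((N - m) * (N - m - 1))
    if a == 0:
        return math.log(b * (N - m))
    return -math.log(a / b)


def apen_bruteforce(x, m: int, r: float) -> float:
    """Approximate entropy, self-matches included."""
    x = list(map(float, x))
    N = len(x)

    def phi(mm: int) -> float:
        t = [x[i:i + mm] for i in range(N - mm + 1)]
        total = 0.0
        for ti in t:
            c = sum(1 for tj in t if chebyshev(ti, tj) <= r)
            total += math.log(c / len(t))
        return total / len(t)

    return phi(m) - phi(m + 1)


def fuzzyen_bruteforce(x, m: int, n: float, r: float) -> float:
    """Fuzzy entropy with mean-centred templates, exhaustive sums."""
    x = list(map(float, x))
    N = len(x)

    def phi(mm: int) -> float:
        t = []
        for i in range(N - m):
            w = x[i:i + mm]
            mu = sum(w) / mm
            t.append([v - mu for v in w])
        total = 0.0
        for i in range(len(t)):
            s = 0.0
            for j in range(len(t)):
                if i == j:
                    continue
                d = chebyshev(t[i], t[j])
                s += math.exp(-((d / r) ** n))
            total += s / (len(t) - 1)
        return total / len(t)

    return math.log(phi(m)) - math.log(phi(m + 1))


def pe_bruteforce(x, order: int, delay: int) -> float:
    """Permutation entropy by explicit pattern histogram; ties broken by
    earlier index."""
    x = list(map(float, x))
    counts: dict[tuple, int] = {}
    n_win = len(x) - (order - 1) * delay
    for i in range(n_win):
        window = [x[i + k * delay] for k in range(order)]
        pattern = tuple(sorted(range(order), key=lambda k: (window[k], k)))
        counts[pattern] = counts.get(pattern, 0) + 1
    total = sum(counts.values())
    return -sum((c / total) * math.log(c / total) for c in counts.values())


def dtw_bruteforce(a, b) -> float:
    """DTW distance by exhaustive enumeration of all monotone warping
    paths from (0, 0) to (n-1, m-1).  Exponential; lengths <= ~6 only."""
    a = list(map(float, a))
    b = list(map(float, b))
    n, m = len(a), len(b)
    best = [math.inf]

    def walk(i: int, j: int, cost: float) -> None:
        cost += abs(a[i] - b[j])
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        if i + 1 < n:
            walk(i + 1, j, cost)
        if j + 1 < m:
            walk(i, j + 1, cost)
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cost)

    walk(0, 0, 0.0)
    return best[0]


def fft_band_energy(x, fs: float, lo: float, hi: float) -> float:
    """Energy of x in the (lo, hi] Hz band via a plain periodogram."""
    x = np.asarray(x, dtype=float)
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    return float(spec[(freqs > lo) & (freqs <= hi)].sum())


def psde_bruteforce(p, eps: float = 1e-12) -> float:
    """Shannon entropy of an explicit distribution."""
    return -sum(pi * math.log(pi + eps) for pi in p)


def sse_bruteforce(x, L: int, eps: float = 1e-12) -> float:
    """Singular spectrum entropy from an explicitly built trajectory
    matrix."""
    x = np.asarray(x, dtype=float)
    N = len(x)
    traj = np.array([x[i:i + N - L + 1] for i in range(L)])
    sv = np.linalg.svd(traj, compute_uv=False)
    sv = sv / sv.sum()
    return float(-(sv * np.log(sv + eps)).sum())
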