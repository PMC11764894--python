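"""Orthogonal discrete wavelet transform with symmetric signal extension.

Implements the classical decimated DWT filter bank (Mallat algorithm) for
the Daubechies family, plus per-group band reconstruction: zero every
coefficient group except one and invert.  The filter coefficients below were
obtained by spectral factorization of the Daubechies polynomial at 30-digit
precision and rounded to double.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Wavelet", "dwt", "idwt", "wavedec", "reconstruct_band"]

# Scaling (lowpass reconstruction) filters, sum = sqrt(2).
_DB_FILTERS: dict[str, tuple[float, ...]] = {
    "db1": (0.7071067811865476, 0.7071067811865476),
    "db2": (0.48296291314453416, 0.8365163037378079, 0.2241438680420134,
            -0.12940952255126037),
    "db3": (0.33267055295008263, 0.8068915093110925, 0.45987750211849154,
            -0.13501102001025458, -0.08544127388202666, 0.03522629188570953),
    "db4": (0.2303778133088965, 0.7148465705529157, 0.6308807679298589,
            -0.027983769416859854, -0.18703481171909309, 0.030841381835560764,
            0.0328830116668852, -0.010597401785069032),
    "db5": (0.16010239797419293, 0.6038292697971896, 0.7243085284377729,
            0.13842814590132074, -0.24229488706638203, -0.032244869584638375,
            0.07757149384004572, -0.006241490212798274, -0.012580751999081999,
            0.0033357252854737712),
    "db6": (0.11154074335010947, 0.49462389039845306, 0.7511339080210954,
            0.31525035170919763, -0.22626469396543983, -0.12976686756726194,
            0.09750160558732304, 0.027522865530305727, -0.03158203931748603,
            0.0005538422011614961, 0.004777257510945511,
            -0.0010773010853084796),
    "db7": (0.07785205408500918, 0.3965393194819173, 0.7291320908462351,
            0.4697822874051931, -0.14390600392856498, -0.22403618499387498,
            0.07130921926683026, 0.08061260915108308, -0.03802993693501441,
            -0.01657454163066688, 0.01255099855609984, 0.0004295779729213665,
            -0.0018016407040474908, 0.00035371379997452024),
    "db8": (0.05441584224310401, 0.31287159091429995, 0.6756307362972898,
            0.5853546836542067, -0.015829105256349306, -0.2840155429615469,
            0.0004724845739132828, 0.12874742662047847, -0.017369301001807547,
            -0.044088253930794755, 0.013981027917398282, 0.008746094047405777,
            -0.004870352993451574, -0.00039174037337694705,
            0.0006754494064505693, -0.00011747678412476953),
}


@dataclass(frozen=True)
class Wavelet:
    """Quadrature-mirror filter bank of an orthogonal wavelet."""

    name: str
    dec_lo: np.ndarray
    dec_hi: np.ndarray
    rec_lo: np.ndarray
    rec_hi: np.ndarray

    @property
    def filter_length(self) -> int:
        return len(self.rec_lo)

    @classmethod
    def from_name(cls, name: str) -> "Wavelet":
        try:
            h = np.asarray(_DB_FILTERS[name.lower()], dtype=np.float64)
        except KeyError:
            raise ValueError(
                f"unsupported wavelet {name!r}; supported: "
                f"{sorted(_DB_FILTERS)}"
            ) from None
        L = len(h)
        rec_lo = h
        rec_hi = np.array([(-1.0) ** k * h[L - 1 - k] for k in range(L)])
        return cls(name=name.lower(), dec_lo=rec_lo[::-1].copy(),
                   dec_hi=rec_hi[::-1].copy(), rec_lo=rec_lo, rec_hi=rec_hi)


def _symmetric_pad(x: np.ndarray, pad: int) -> np.ndarray:
    # half-sample symmetric extension: ... x1 x0 | x0 x1 ... xN-1 | xN-1 ...
    if pad > len(x):
        reps = int(np.ceil(pad / len(x)))
        return _symmetric_pad(np.tile(np.concatenate([x, x[::-1]]), reps), pad)
    return np.concatenate([x[:pad][::-1], x, x[-pad:][::-1]])


def dwt(x: np.ndarray, wavelet: Wavelet) -> tuple[np.ndarray, np.ndarray]:
    """One analysis step: approximation and detail coefficients."""
    L = wavelet.filter_length
    xe = _symmetric_pad(np.asarray(x, dtype=np.float64), L - 1)
    a = np.convolve(xe, wavelet.dec_lo, mode="valid")[1::2]
    d = np.convolve(xe, wavelet.dec_hi, mode="valid")[1::2]
    return a, d


def idwt(a: np.ndarray, d: np.ndarray, wavelet: Wavelet,
         out_len: int) -> np.ndarray:
    """One synthesis step, cropped to ``out_len`` samples."""
    if len(a) != len(d):
        raise ValueError("coefficient arrays must have equal length")
    L = wavelet.filter_length
    up_a = np.zeros(2 * len(a))
    up_d = np.zeros(2 * len(d))
    up_a[::2] = a
    up_d[::2] = d
    y = (np.convolve(up_a, wavelet.rec_lo, mode="full")
         + np.convolve(up_d, wavelet.rec_hi, mode="full"))
    lo = L - 2
    if lo + out_len > len(y):
        raise ValueError("requested output length exceeds reconstruction")
    return y[lo:lo + out_len]


def wavedec(x: np.ndarray, wavelet: Wavelet,
            levels: int) -> tuple[list[np.ndarray], list[int]]:
    """Multi-level analysis.

    Returns ``([a_L, d_L, d_{L-1}, ..., d_1], lengths)`` where ``lengths``
    holds the signal length entering each level (needed to crop the inverse
    transform), coarsest first.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    details: list[np.ndarray] = []
    lengths: list[int] = []
    a = x
    for _ in range(levels):
        lengths.append(len(a))
        a, d = dwt(a, wavelet)
        details.append(d)
    coeffs = [a] + details[::-1]
    return coeffs, lengths[::-1]


def reconstruct_band(coeffs: list[np.ndarray], lengths: list[int],
                     wavelet: Wavelet, keep: int) -> np.ndarray:
    """Invert keeping only coefficient group ``keep`` (0 = approximation,
    1 = coarsest detail, ..., levels = finest detail); all others zeroed."""
    if not 0 <= keep < len(coeffs):
        raise ValueError(f"keep index {keep} out of range")
    levels = len(coeffs) - 1
    a = coeffs[0] if keep == 0 else np.zeros_like(coeffs[0])
    for lev in range(levels):
        d = coeffs[lev + 1]
        if keep != lev + 1:
            d = np.zeros_like(d)
        a = idwt(a, d, wavelet, lengths[lev])
    return a
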