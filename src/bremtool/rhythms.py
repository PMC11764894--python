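"""Brain-rhythm extraction by multi-level DWT band reconstruction.

A four-level decomposition of a signal sampled at ``fs`` splits the spectrum
into five dyadic bands that are mapped coarse-to-fine onto the canonical
rhythms: approximation -> delta, then theta, alpha, beta, and the finest
detail -> gamma.  At 128 Hz the resulting edges are 0-4, 4-8, 8-16, 16-32
and 32-64 Hz.  These are dyadic approximations of the nominal rhythm ranges
(alpha is nominally 8-13 Hz, beta 13-30 Hz); the edges actually realized are
reported in :attr:`RhythmSet.band_edges` and a warning is logged when they
drift far from the nominal ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._wavelets import Wavelet, reconstruct_band, wavedec

__all__ = ["EEGSignal", "RhythmSet", "RHYTHM_NAMES", "decompose_rhythms"]

logger = logging.getLogger(__name__)

#: Rhythm names ordered coarse (low frequency) to fine.
RHYTHM_NAMES: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")

# Nominal rhythm band edges in Hz (gamma top is capped at Nyquist).
_NOMINAL_EDGES = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, None),
}


@dataclass
class EEGSignal:
    """One channel's sampled voltage trace.

    Parameters
    ----------
    samples
        Voltage samples in microvolts.
    fs
        Sampling rate in Hz, strictly positive.
    channel
        Montage label of the recording electrode.
    trial_id
        Identifier of the trial the segment belongs to.
    t0
        Start offset of the segment within its trial, in seconds.
    """

    samples: np.ndarray
    fs: float
    channel: str = ""
    trial_id: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class RhythmSet:
    """The five band-limited reconstructions of one signal."""

    delta: np.ndarray
    theta: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    fs: float
    band_edges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(getattr(self, name)) for name in RHYTHM_NAMES}
        if len(lengths) != 1:
            raise ValueError("all rhythm reconstructions must share a length")

    def band(self, name: str) -> np.ndarray:
        if name not in RHYTHM_NAMES:
            raise KeyError(f"unknown rhythm {name!r}")
        return getattr(self, name)

    def __iter__(self):
        return (getattr(self, name) for name in RHYTHM_NAMES)


def dyadic_band_edges(fs: float, levels: int = 4) -> dict[str, tuple[float, float]]:
    """Band edges (Hz) realized by a ``levels``-level dyadic split of [0, fs/2]."""
    nyq = fs / 2.0
    edges = {}
    hi = nyq
    for k, name in enumerate(reversed(RHYTHM_NAMES[1:])):  # gamma..theta
        lo = nyq / 2 ** (k + 1)
        edges[name] = (lo, hi)
        hi = lo
    edges["delta"] = (0.0, hi)
    return edges


def _warn_if_off_nominal(edges: dict[str, tuple[float, float]]) -> None:
    for name, (lo, hi) in edges.items():
        nlo, nhi = _NOMINAL_EDGES[name]
        ref = nhi if nhi is not None else nlo
        got = hi if nhi is not None else lo
        if ref and abs(got - ref) / ref > 0.25:
            logger.warning(
                "rhythm %s realized as %.3g-%.3g Hz deviates >25%% from the "
                "nominal %s-%s Hz range", name, lo, hi, nlo,
                nhi if nhi is not None else "Nyquist")


def decompose_rhythms(signal: EEGSignal, wavelet_name: str = "db4",
                      levels: int = 4) -> RhythmSet:
    """Split a signal into the five brain rhythms.

    The signal is decomposed with a ``levels``-level DWT and each rhythm is
    obtained by inverting the transform with all but one coefficient group
    zeroed, so the five outputs sum back to the input exactly (orthogonal
    perfect-reconstruction identity) and each has the input's length.

    Raises
    ------
    ValueError
        If the signal is shorter than ``2**levels * filter_length`` samples
        ("insufficient length"), or if ``levels`` does not yield five bands.
    """
    if levels != 4:
        raise ValueError(
            "five rhythms require exactly four decomposition levels "
            f"(got levels={levels})")
    wav = Wavelet.from_name(wavelet_name)
    min_len = 2 ** levels * wav.filter_length
    if len(signal) < min_len:
        raise ValueError(
            f"insufficient length: need >= {min_len} samples for a "
            f"{levels}-level {wav.name} decomposition, got {len(signal)}")

    coeffs, lengths = wavedec(signal.samples, wav, levels)
    # group 0 = approximation -> delta; groups 1..levels coarsest..finest
    bands = {
        name: reconstruct_band(coeffs, lengths, wav, keep=k)
        for k, name in enumerate(RHYTHM_NAMES)
    }
    edges = dyadic_band_edges(signal.fs, levels)
    _warn_if_off_nominal(edges)
    return RhythmSet(fs=signal.fs, band_edges=edges, **bands)
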