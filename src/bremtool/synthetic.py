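"""Two-class synthetic EEG generator.

Each trial is a sum over the five dyadic rhythm bands of a mixture of a
band-centre sinusoid (the "regular" part) and band-limited Gaussian noise,
plus broadband noise.  The two classes differ in band amplitudes and in the
sinusoidal energy fraction: the positive class boosts beta/gamma power and
is less regular, the negative class boosts delta/alpha power and is more
regular, both scaled by a single ``effect`` knob so ``effect = 0`` makes the
classes exchangeable.  Band-limited noise is shaped with an FFT mask over
the same dyadic edges that the rhythm decomposition extracts, so planted
structure lands in the intended BREM rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import NEGATIVE, POSITIVE, Trial, TrialSet
from .rhythms import EEGSignal, RHYTHM_NAMES, dyadic_band_edges

__all__ = ["SyntheticConfig", "generate_trial", "generate_subject", "preset"]

# Per-band amplitude boost directions (delta, theta, alpha, beta, gamma).
_BOOST_POS = np.array([0.0, 0.0, 0.0, 1.0, 1.0])   # beta/gamma up
_BOOST_NEG = np.array([1.0, 0.0, 1.0, 0.0, 0.0])   # delta/alpha up


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; ``effect = 0`` removes all class contrast.

    ``regularity_contrast`` is the baseline sinusoidal energy fraction per
    band; the classes move away from it by ``0.3 * effect`` in opposite
    directions (positive less regular, negative more regular).  Amplitudes
    scale as ``band_amp * (1 + effect)`` on each class's boosted bands.
    Only ``signal_channel`` carries the class contrast; other channels are
    generated at ``effect = 0``.
    """

    fs: float = 128.0
    trial_s: float = 60.0
    n_pos: int = 24
    n_neg: int = 16
    effect: float = 0.0
    band_amp_pos: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    band_amp_neg: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    noise_sd: float = 0.5
    regularity_contrast: float = 0.3
    channels: tuple[str, ...] = ("O2",)
    signal_channel: str = "O2"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.trial_s <= 0:
            raise ValueError("fs and trial_s must be positive")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("trial counts must be positive")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if len(self.band_amp_pos) != 5 or len(self.band_amp_neg) != 5:
            raise ValueError("band amplitude vectors must have 5 entries")
        if min(self.band_amp_pos) < 0 or min(self.band_amp_neg) < 0:
            raise ValueError("band amplitudes must be >= 0")
        if not 0 <= self.regularity_contrast <= 1:
            raise ValueError("regularity_contrast must be in [0, 1]")
        if self.signal_channel not in self.channels:
            raise ValueError("signal_channel must be one of channels")


def _class_params(label: str, cfg: SyntheticConfig,
                  effect: float) -> tuple[np.ndarray, float]:
    if label == POSITIVE:
        amps = np.asarray(cfg.band_amp_pos) * (1.0 + effect * _BOOST_POS)
        rho = cfg.regularity_contrast - 0.3 * effect
    elif label == NEGATIVE:
        amps = np.asarray(cfg.band_amp_neg) * (1.0 + effect * _BOOST_NEG)
        rho = cfg.regularity_contrast + 0.3 * effect
    else:
        raise ValueError(f"unknown class label {label!r}")
    return amps, float(np.clip(rho, 0.0, 0.95))


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                lo: float, hi: float) -> np.ndarray:
    """Unit-SD Gaussian noise band-limited to (lo, hi] Hz via FFT masking."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs <= lo) | (freqs > hi)] = 0.0
    shaped = np.fft.irfft(spec, n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _synth_samples(label: str, cfg: SyntheticConfig, effect: float,
                   rng: np.random.Generator) -> np.ndarray:
    n = int(round(cfg.trial_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    amps, rho = _class_params(label, cfg, effect)
    edges = dyadic_band_edges(cfg.fs)
    x = np.zeros(n)
    for amp, name in zip(amps, RHYTHM_NAMES):
        lo, hi = edges[name]
        centre = (lo + hi) / 2.0
        phase = rng.uniform(0.0, 2.0 * np.pi)
        sinus = np.sqrt(2.0) * np.sin(2.0 * np.pi * centre * t + phase)
        noise = _band_noise(rng, n, cfg.fs, lo, hi)
        x += amp * (np.sqrt(rho) * sinus + np.sqrt(1.0 - rho) * noise)
    x += cfg.noise_sd * rng.standard_normal(n)
    return x


def generate_trial(class_label: str, cfg: SyntheticConfig,
                   rng: np.random.Generator,
                   channel: str | None = None,
                   trial_id: str = "") -> EEGSignal:
    """One synthetic single-channel trial; deterministic given ``rng``."""
    channel = channel or cfg.signal_channel
    effect = cfg.effect if channel == cfg.signal_channel else 0.0
    samples = _synth_samples(class_label, cfg, effect, rng)
    return EEGSignal(samples=samples, fs=cfg.fs, channel=channel,
                     trial_id=trial_id)


def generate_subject(cfg: SyntheticConfig,
                     dimension: str = "arousal") -> TrialSet:
    """A full labeled subject: ``n_pos`` positive then ``n_neg`` negative
    trials across ``cfg.channels``, class contrast only in
    ``cfg.signal_channel``."""
    rng = np.random.default_rng(cfg.seed)
    trials: list[Trial] = []
    labels = [POSITIVE] * cfg.n_pos + [NEGATIVE] * cfg.n_neg
    for k, label in enumerate(labels):
        tid = f"t{k:03d}"
        chans = {ch: generate_trial(label, cfg, rng, channel=ch, trial_id=tid)
                 for ch in cfg.channels}
        rating = 7.0 if label == POSITIVE else 3.0
        trials.append(Trial(trial_id=tid, channels=chans, label=label,
                            rating=rating))
    return TrialSet(subject=f"synth-{cfg.seed}", trials=trials,
                    dimension=dimension)


_PRESETS = {
    # strong: 2x amplitude on the boosted bands and a 0.6 gap in the
    # sinusoidal energy fraction (0.2 vs 0.8)
    "strong": dict(effect=1.0, regularity_contrast=0.5),
    "null": dict(effect=0.0),
}


def preset(name: str, seed: int = 0, **overrides) -> SyntheticConfig:
    """Named generator presets: ``strong`` (well-separated classes) and
    ``null`` (identically distributed classes)."""
    try:
        base = dict(_PRESETS[name])
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from None
    base.update(overrides)
    return SyntheticConfig(seed=seed, **base)
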