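"""Brain Rhythm Entropy Matrix (BREM) construction and region fusion.

A single-channel BREM is a fixed-order 5x6 matrix: rows are the rhythms
gamma, beta, alpha, theta, delta (top to bottom) and columns the entropies
AE, FE, SE, PE, SSE, PSDE (left to right).  Region fusion concatenates the
BREMs of a region's channels horizontally, so five occipital channels yield
a 5x30 matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .entropies import EntropyConfig, all_entropies
from .rhythms import EEGSignal, decompose_rhythms

__all__ = [
    "ROW_ORDER", "COL_ORDER", "MONTAGE_32", "DEFAULT_REGION_MAP",
    "BREM", "RegionBREM", "RegionMap", "build_brem", "fuse_region",
]

#: Fixed BREM row order, top to bottom.
ROW_ORDER: tuple[str, ...] = ("gamma", "beta", "alpha", "theta", "delta")
#: Fixed BREM column order, left to right.
COL_ORDER: tuple[str, ...] = ("AE", "FE", "SE", "PE", "SSE", "PSDE")

_REGION_CHANNELS = {
    "Frontal": ("FP1", "FP2", "AF3", "AF4", "F3", "FZ", "F4"),
    "Central": ("FC5", "FC1", "FC2", "FC6", "C3", "CZ", "C4"),
    "Parietal": ("CP5", "CP1", "CP2", "CP6", "P3", "PZ", "P4"),
    "Temporal": ("F7", "F8", "T7", "T8", "P7", "P8"),
    "Occipital": ("PO3", "PO4", "O1", "OZ", "O2"),
}

#: The 32-channel montage in region listing order.
MONTAGE_32: tuple[str, ...] = tuple(
    ch for chans in _REGION_CHANNELS.values() for ch in chans)


@dataclass(frozen=True)
class RegionMap:
    """Ordered region -> channel-label mapping."""

    mapping: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for region, channels in self.mapping.items():
            for ch in channels:
                if ch in seen:
                    raise ValueError(
                        f"channel {ch!r} listed in more than one region")
                seen.add(ch)
        if not seen:
            raise ValueError("region map is empty")

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.mapping)

    def channels(self, region: str) -> tuple[str, ...]:
        try:
            return self.mapping[region]
        except KeyError:
            raise KeyError(
                f"unknown region {region!r}; known: {self.regions}") from None

    def region_of(self, channel: str) -> str | None:
        for region, channels in self.mapping.items():
            if channel in channels:
                return region
        return None


DEFAULT_REGION_MAP = RegionMap(dict(_REGION_CHANNELS))


@dataclass
class BREM:
    """Single-channel 5x6 Brain Rhythm Entropy Matrix."""

    values: np.ndarray
    channel: str = ""
    window: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (5, 6):
            raise ValueError(
                f"BREM must be 5x6, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("BREM contains non-finite entries")

    def cell(self, rhythm: str, entropy: str) -> float:
        return float(self.values[ROW_ORDER.index(rhythm),
                                 COL_ORDER.index(entropy)])

    @property
    def size(self) -> int:
        return int(self.values.size)


@dataclass
class RegionBREM:
    """Horizontal concatenation of one region's single-channel BREMs."""

    values: np.ndarray
    region: str
    channel_order: tuple[str, ...]
    window: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n_ch = len(self.channel_order)
        if self.values.shape != (5, 6 * n_ch):
            raise ValueError(
                f"RegionBREM for {n_ch} channels must be 5x{6 * n_ch}, "
                f"got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("RegionBREM contains non-finite entries")


def build_brem(signal: EEGSignal, cfg: EntropyConfig = EntropyConfig(),
               wavelet_name: str = "db4", levels: int = 4,
               standardize: bool = False) -> BREM:
    """Decompose a signal into rhythms and fill the 5x6 entropy matrix.

    With ``standardize=True`` the 30 entries are z-scored over the matrix
    after construction (off by default; the canonical BREM is raw).
    """
    rhythms = decompose_rhythms(signal, wavelet_name=wavelet_name,
                                levels=levels)
    values = np.empty((5, 6))
    for i, rhythm in enumerate(ROW_ORDER):
        band = rhythms.band(rhythm)
        try:
            feats = all_entropies(band, signal.fs, cfg)
        except Exception as exc:
            raise RuntimeError(
                f"entropy extraction failed on rhythm {rhythm!r} of channel "
                f"{signal.channel!r}: {exc}") from exc
        for j, col in enumerate(COL_ORDER):
            values[i, j] = feats[col.lower()]
    if standardize:
        sd = values.std()
        values = (values - values.mean()) / (sd if sd > 0 else 1.0)
    t0 = signal.t0
    return BREM(values=values, channel=signal.channel,
                window=(t0, t0 + signal.duration))


def fuse_region(brems: list[BREM], region: str,
                region_map: RegionMap = DEFAULT_REGION_MAP) -> RegionBREM:
    """Concatenate single-channel BREMs of one region, in map order."""
    if not brems:
        raise ValueError("need at least one BREM to fuse")
    channels = region_map.channels(region)
    offenders = [b.channel for b in brems if b.channel not in channels]
    if offenders:
        raise ValueError(
            f"channels {offenders} do not belong to region {region!r} "
            f"(expected among {channels})")
    labels = [b.channel for b in brems]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate channels in fusion input: {labels}")
    windows = {b.window for b in brems}
    if len(windows) != 1:
        raise ValueError(f"BREMs span different windows: {sorted(windows)}")
    ordered = sorted(brems, key=lambda b: channels.index(b.channel))
    values = np.hstack([b.values for b in ordered])
    return RegionBREM(values=values, region=region,
                      channel_order=tuple(b.channel for b in ordered),
                      window=ordered[0].window)
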