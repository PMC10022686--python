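"""40-bin filopodia localization maps and tip-enrichment statistics.

To homogenize filopodia of different lengths, each tip-to-base profile
is reduced to exactly 40 bins: sample ``i`` of ``n`` falls in bin
``floor(40·i/n) + 1`` (bins 1..40, tip first) and each bin takes the
median of its samples.  A localization map for a condition is the
per-bin arithmetic mean of hundreds of binned profiles.  Preferential
tip recruitment is quantified by the enrichment ratio: mean intensity
over the tip bins (1-6) divided by mean intensity over the shaft bins
(7-40).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from filotip.profiles import LineProfile

__all__ = [
    "N_BINS",
    "TIP_BINS",
    "SHAFT_BINS",
    "BinnedProfile",
    "FilopodiaMap",
    "TipEnrichment",
    "bin_profile",
    "average_map",
    "tip_enrichment_ratio",
    "tip_intensity",
    "write_binned_profiles",
    "write_map",
]

N_BINS = 40
#: tip window: bins 1-6 (1-based, tip first)
TIP_BINS = (1, 6)
#: shaft window: bins 7-40
SHAFT_BINS = (7, 40)


@dataclass(frozen=True)
class BinnedProfile:
    """One profile reduced to 40 bins per channel, bin index 0 = tip end."""

    filopodium_id: str
    bins: dict[str, np.ndarray]
    n_source_samples: int

    def __post_init__(self) -> None:
        clean = {k: np.asarray(v, dtype=float) for k, v in self.bins.items()}
        for ch, v in clean.items():
            if v.shape != (N_BINS,):
                raise ValueError(f"channel {ch!r} must have exactly {N_BINS} bins")
        object.__setattr__(self, "bins", clean)

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.bins)


@dataclass(frozen=True)
class FilopodiaMap:
    """Per-bin mean (and sd) over many binned profiles, per channel."""

    condition_id: str
    means: dict[str, np.ndarray]
    n_profiles: int
    sds: dict[str, np.ndarray] | None = None

    def rescaled(self) -> "FilopodiaMap":
        """Per-channel [0, 1] rescale for heatmap display (display only:
        statistics are always computed on unrescaled values)."""
        out = {}
        for ch, m in self.means.items():
            lo, hi = m.min(), m.max()
            out[ch] = np.zeros_like(m) if hi == lo else (m - lo) / (hi - lo)
        return FilopodiaMap(self.condition_id, out, self.n_profiles, self.sds)


@dataclass(frozen=True)
class TipEnrichment:
    """Tip/shaft intensity ratio for one filopodium and channel.

    ``ratio`` is NaN and ``defined`` False when the shaft mean is not
    positive.
    """

    filopodium_id: str
    channel: str
    tip_mean: float
    shaft_mean: float
    ratio: float
    defined: bool


def _bin_assignment(n: int, n_bins: int = N_BINS) -> np.ndarray:
    """0-based bin of each sample: floor(n_bins * i / n)."""
    return (n_bins * np.arange(n)) // n


def bin_profile(p: LineProfile, short_policy: str = "strict") -> BinnedProfile:
    """Reduce one line profile to 40 per-channel bin medians.

    Sample ``i`` of ``n`` is assigned to bin ``floor(40·i/n)`` (0-based;
    contiguous, near-equal occupancy); the bin value is the median of
    its samples (midpoint of the two central values for even counts).

    Profiles with fewer than 40 samples raise by default
    (``short_policy="strict"``); with ``short_policy="resample"`` they
    are first linearly upsampled to 40 samples so every bin gets one.
    """
    n = p.n_samples
    samples = p.samples
    if n < N_BINS:
        if short_policy == "strict":
            raise ValueError(
                f"profile {p.filopodium_id!r} has {n} < {N_BINS} samples; "
                "use short_policy='resample' to upsample"
            )
        if short_policy != "resample":
            raise ValueError(f"unknown short_policy {short_policy!r}")
        old = np.linspace(0.0, 1.0, n)
        new = np.linspace(0.0, 1.0, N_BINS)
        samples = {ch: np.interp(new, old, v) for ch, v in samples.items()}
        n = N_BINS

    assign = _bin_assignment(n)
    bins = {
        ch: np.array([np.median(v[assign == b]) for b in range(N_BINS)])
        for ch, v in samples.items()
    }
    return BinnedProfile(p.filopodium_id, bins, p.n_samples)


def average_map(bps: list[BinnedProfile], condition_id: str) -> FilopodiaMap:
    """Average binned profiles into one localization map per channel."""
    if not bps:
        raise ValueError("average_map needs at least one binned profile")
    channels = bps[0].channels
    for bp in bps:
        if bp.channels != channels:
            raise ValueError("all binned profiles must share the same channels")
    means, sds = {}, {}
    for ch in channels:
        stack = np.stack([bp.bins[ch] for bp in bps])
        means[ch] = stack.mean(axis=0)
        sds[ch] = stack.std(axis=0, ddof=1) if len(bps) > 1 else np.zeros(N_BINS)
    return FilopodiaMap(condition_id, means, len(bps), sds)


def tip_enrichment_ratio(
    bp: BinnedProfile,
    channel: str,
    tip_bins: tuple[int, int] = TIP_BINS,
    shaft_bins: tuple[int, int] = SHAFT_BINS,
) -> TipEnrichment:
    """Tip/shaft enrichment ratio for one binned profile and channel.

    ``tip_bins`` and ``shaft_bins`` are inclusive 1-based windows,
    defaulting to tip = bins 1-6 and shaft = bins 7-40.
    """
    v = bp.bins[channel]
    tip = float(v[tip_bins[0] - 1 : tip_bins[1]].mean())
    shaft = float(v[shaft_bins[0] - 1 : shaft_bins[1]].mean())
    defined = shaft > 0
    return TipEnrichment(
        filopodium_id=bp.filopodium_id,
        channel=channel,
        tip_mean=tip,
        shaft_mean=shaft,
        ratio=tip / shaft if defined else float("nan"),
        defined=defined,
    )


def tip_intensity(
    bp: BinnedProfile, channel: str, tip_bins: tuple[int, int] = TIP_BINS
) -> float:
    """Raw mean intensity over the tip bins (1-6 by default)."""
    v = bp.bins[channel]
    return float(v[tip_bins[0] - 1 : tip_bins[1]].mean())


def write_binned_profiles(path: str | Path, bps: list[BinnedProfile]) -> None:
    rows = []
    for bp in bps:
        for ch, v in bp.bins.items():
            rows.append({"filopodium_id": bp.filopodium_id, "channel": ch,
                         **{f"bin{b + 1}": v[b] for b in range(N_BINS)}})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_map(path: str | Path, fmap: FilopodiaMap) -> None:
    rows = []
    for ch, m in fmap.means.items():
        sd = fmap.sds[ch] if fmap.sds else np.full(N_BINS, np.nan)
        for b in range(N_BINS):
            rows.append((fmap.condition_id, ch, b + 1, m[b], sd[b], fmap.n_profiles))
    pd.DataFrame(rows, columns=["condition", "channel", "bin", "mean", "sd", "n"]).to_csv(
        path, index=False
    )
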