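"""Synthetic data with planted ground truth for every pipeline stage.

Filopodia are thin (<200 nm wide) finger-like protrusions a few µm long
whose distal tip hosts a protein complex.  The generators here emulate
the three data modalities the analysis consumes:

* multi-channel fluorescence images of filopodia (bright thin lines with
  channel-specific tip puncta over a noisy background),
* tip-to-base line intensity profiles,
* spectral-count tables from bait-vs-control mass spectrometry, and
* filopodia tip-spot trajectories sampled at a fixed frame interval.

Every generator is a pure function of its arguments (including the
seed), so fixed-seed runs are bit-identical and analytic expectations
hold exactly at zero noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilopodiumGroundTruth",
    "CountTableGroundTruth",
    "TrackGroundTruth",
    "generate_image",
    "generate_profiles",
    "generate_count_table",
    "generate_tracks",
    "straight_filopodium",
]

#: default tip window: first 6 of 40 bins of the arclength
DEFAULT_TIP_FRACTION = 6 / 40

#: default pixel size, µm (SIM-scale: a 2-µm filopodium spans 50 px)
DEFAULT_PIXEL_SIZE_UM = 0.04


def _polyline_arclength(path: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1)))


@dataclass(frozen=True)
class FilopodiumGroundTruth:
    """One planted filopodium: geometry plus per-channel amplitudes.

    ``path`` is an (n, 2) array of (x, y) points in µm, tip first.  The
    tip punctum carries ``tip_amplitude_per_channel`` on top of the
    shaft amplitude over the first ``tip_fraction`` of the arclength.
    """

    filopodium_id: str
    path: np.ndarray
    tip_amplitude_per_channel: tuple[float, ...]
    shaft_amplitude_per_channel: tuple[float, ...]
    tip_fraction: float = DEFAULT_TIP_FRACTION

    def __post_init__(self) -> None:
        path = np.asarray(self.path, dtype=float)
        if path.ndim != 2 or path.shape[0] < 2 or path.shape[1] != 2:
            raise ValueError("path must be an (n>=2, 2) array of µm coordinates")
        object.__setattr__(self, "path", path)
        if not 0 < self.tip_fraction < 1:
            raise ValueError("tip_fraction must lie in (0, 1)")
        if len(self.tip_amplitude_per_channel) != len(self.shaft_amplitude_per_channel):
            raise ValueError("tip and shaft amplitude tuples must have equal length")
        if any(a < 0 for a in self.tip_amplitude_per_channel + self.shaft_amplitude_per_channel):
            raise ValueError("amplitudes must be nonnegative")

    @property
    def length_um(self) -> float:
        """Polyline arclength in µm."""
        return _polyline_arclength(self.path)

    @property
    def n_channels(self) -> int:
        return len(self.tip_amplitude_per_channel)


def straight_filopodium(
    filopodium_id: str,
    tip_xy_um: tuple[float, float],
    base_xy_um: tuple[float, float],
    tip_amplitude_per_channel: tuple[float, ...],
    shaft_amplitude_per_channel: tuple[float, ...],
    tip_fraction: float = DEFAULT_TIP_FRACTION,
) -> FilopodiumGroundTruth:
    """Convenience constructor for a straight two-vertex filopodium."""
    return FilopodiumGroundTruth(
        filopodium_id=filopodium_id,
        path=np.array([tip_xy_um, base_xy_um], dtype=float),
        tip_amplitude_per_channel=tuple(tip_amplitude_per_channel),
        shaft_amplitude_per_channel=tuple(shaft_amplitude_per_channel),
        tip_fraction=tip_fraction,
    )


@dataclass(frozen=True)
class CountTableGroundTruth:
    """Planted design of a bait-vs-control spectral-count experiment."""

    n_proteins: int
    enriched_ids: frozenset[str]
    baseline_mean: float
    enrichment_factor: float
    n_replicates_bait: int = 2
    n_replicates_control: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be nonnegative")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if self.n_replicates_bait < 1 or self.n_replicates_control < 1:
            raise ValueError("replicate counts must be positive")
        object.__setattr__(self, "enriched_ids", frozenset(self.enriched_ids))
        bad = self.enriched_ids - set(self.protein_ids)
        if bad:
            raise ValueError(f"enriched_ids not among generated proteins: {sorted(bad)}")

    @property
    def protein_ids(self) -> list[str]:
        return [f"P{i:04d}" for i in range(self.n_proteins)]


@dataclass(frozen=True)
class TrackGroundTruth:
    """One planted tip-spot trajectory, defined on [spawn_frame, death_frame]."""

    cell_id: str
    spawn_frame: int
    death_frame: int
    positions: np.ndarray  # (n_frames, 2) µm, one row per frame
    frame_interval_s: float = 5.0

    def __post_init__(self) -> None:
        if self.death_frame < self.spawn_frame:
            raise ValueError("death_frame must be >= spawn_frame")
        positions = np.asarray(self.positions, dtype=float)
        n = self.death_frame - self.spawn_frame + 1
        if positions.shape != (n, 2):
            raise ValueError(
                f"positions must have shape ({n}, 2) covering every frame of "
                f"[{self.spawn_frame}, {self.death_frame}]"
            )
        object.__setattr__(self, "positions", positions)
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.spawn_frame, self.death_frame + 1)


# ---------------------------------------------------------------------------
# image generator


def _segment_distance(px: np.ndarray, py: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean distance from grid points (px, py) to segment a->b."""
    d = b - a
    seg2 = float(d @ d)
    if seg2 == 0.0:
        return np.hypot(px - a[0], py - a[1])
    t = ((px - a[0]) * d[0] + (py - a[1]) * d[1]) / seg2
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(px - (a[0] + t * d[0]), py - (a[1] + t * d[1]))


def generate_image(
    specs: list[FilopodiumGroundTruth],
    image_shape: tuple[int, int],
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    noise_sd: float = 0.0,
    background: float = 0.0,
    seed: int = 0,
    line_sigma_px: float = 0.5,
    tip_sigma_px: float = 2.0,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Render planted filopodia into a multi-channel image.

    Each filopodium is drawn as an anti-aliased line (Gaussian transverse
    profile of sd ``line_sigma_px``, peak = shaft amplitude) plus a tip
    punctum: a 2D Gaussian of sd ``tip_sigma_px`` centred on the first
    path vertex, peak = tip amplitude.  Additive Gaussian noise of the
    given sd and a constant background complete the image.

    Returns ``(image, paths_px)`` where ``image`` has shape
    ``(n_channels, ny, nx)`` and ``paths_px`` gives each ground-truth
    path in continuous pixel coordinates (x, y), pixel-centre origin.

    Raises ``ValueError`` naming the filopodium if its path leaves the
    image.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    ny, nx = image_shape
    n_channels = specs[0].n_channels if specs else 2

    paths_px: list[np.ndarray] = []
    for gt in specs:
        if gt.n_channels != n_channels:
            raise ValueError("all filopodia must share the channel count")
        p = gt.path / pixel_size_um  # (x, y) px
        if (p[:, 0].min() < 0 or p[:, 0].max() > nx - 1
                or p[:, 1].min() < 0 or p[:, 1].max() > ny - 1):
            raise ValueError(f"path of filopodium {gt.filopodium_id!r} lies outside the image")
        paths_px.append(p)

    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    image = np.full((n_channels, ny, nx), float(background))

    for gt, p in zip(specs, paths_px):
        dist = np.full((ny, nx), np.inf)
        for a, b in zip(p[:-1], p[1:]):
            dist = np.minimum(dist, _segment_distance(xx, yy, a, b))
        line_profile = np.exp(-0.5 * (dist / line_sigma_px) ** 2)
        tip = p[0]
        tip_blob = np.exp(
            -((xx - tip[0]) ** 2 + (yy - tip[1]) ** 2) / (2.0 * tip_sigma_px**2)
        )
        for c in range(n_channels):
            image[c] += gt.shaft_amplitude_per_channel[c] * line_profile
            if gt.tip_amplitude_per_channel[c] > 0:
                image[c] += gt.tip_amplitude_per_channel[c] * tip_blob

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    return image, paths_px


# ---------------------------------------------------------------------------
# profile generator


def generate_profiles(
    specs: list[FilopodiumGroundTruth],
    samples_per_profile: int = 120,
    noise_sd: float = 0.0,
    seed: int = 0,
    spacing_um: float | None = None,
) -> list["LineProfile"]:
    """Generate noisy tip-to-base line profiles directly (no image).

    Sample ``i`` of ``n`` sits at arclength fraction ``i/(n-1)`` from the
    tip; its expected value is ``shaft + tip`` inside the tip window
    (fraction < ``tip_fraction``) and ``shaft`` outside, plus N(0, sd)
    noise.  Spacing defaults to ``length_um / (n-1)``.
    """
    from filotip.profiles import LineProfile

    if samples_per_profile < 40:
        raise ValueError(
            "samples_per_profile must be >= 40 (binning needs at least one sample per bin)"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    out: list[LineProfile] = []
    n = samples_per_profile
    frac = np.arange(n) / (n - 1)
    for gt in specs:
        in_tip = frac < gt.tip_fraction
        samples: dict[str, np.ndarray] = {}
        for c in range(gt.n_channels):
            expected = np.where(
                in_tip,
                gt.shaft_amplitude_per_channel[c] + gt.tip_amplitude_per_channel[c],
                gt.shaft_amplitude_per_channel[c],
            ).astype(float)
            if noise_sd > 0:
                expected = expected + rng.normal(0.0, noise_sd, size=n)
            samples[f"ch{c}"] = expected
        sp = spacing_um if spacing_um is not None else gt.length_um / (n - 1)
        out.append(LineProfile(filopodium_id=gt.filopodium_id, spacing_um=sp, samples=samples))
    return out


# ---------------------------------------------------------------------------
# spectral-count generator


def generate_count_table(gt: CountTableGroundTruth) -> pd.DataFrame:
    """Poisson spectral-count table for one bait/control experiment.

    ``baseline_mean`` is the expected *total* spectral count of a
    protein across a sample's replicates (spectral counts are summed
    across repeats, which is also what the enrichment filter consumes),
    so each replicate draws Poisson(``baseline_mean / n_replicates``).
    Planted proteins carry ``baseline_mean × enrichment_factor`` in the
    bait; everything else is background in both samples.  Columns are a
    MultiIndex of (sample_label, replicate): ``bait`` and ``control``.
    """
    rng = np.random.default_rng(gt.seed)
    ids = gt.protein_ids
    enriched = np.array([pid in gt.enriched_ids for pid in ids])
    bait_total = np.where(enriched, gt.baseline_mean * gt.enrichment_factor, gt.baseline_mean)

    cols: dict[tuple[str, int], np.ndarray] = {}
    for r in range(1, gt.n_replicates_bait + 1):
        cols[("bait", r)] = rng.poisson(bait_total / gt.n_replicates_bait,
                                        size=gt.n_proteins)
    for r in range(1, gt.n_replicates_control + 1):
        cols[("control", r)] = rng.poisson(gt.baseline_mean / gt.n_replicates_control,
                                           size=gt.n_proteins)

    table = pd.DataFrame(cols, index=pd.Index(ids, name="protein_id"))
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["sample", "replicate"])
    return table


# ---------------------------------------------------------------------------
# track generator


def generate_tracks(
    gts: list[TrackGroundTruth],
    detection_noise_um: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Spot table from planted trajectories: one detection per position.

    Adds isotropic Gaussian jitter of sd ``detection_noise_um``.  No
    spurious or missing detections.  Columns: cell_id, frame, x_um,
    y_um, truth_track (ground-truth track index, for validation only).
    """
    if detection_noise_um < 0:
        raise ValueError("detection_noise_um must be nonnegative")
    rng = np.random.default_rng(seed)
    rows = []
    for k, gt in enumerate(gts):
        pos = gt.positions.copy()
        if detection_noise_um > 0:
            pos = pos + rng.normal(0.0, detection_noise_um, size=pos.shape)
        for f, (x, y) in zip(gt.frames, pos):
            rows.append((gt.cell_id, int(f), float(x), float(y), k))
    spots = pd.DataFrame(rows, columns=["cell_id", "frame", "x_um", "y_um", "truth_track"])
    return spots.sort_values(["cell_id", "frame"], kind="stable").reset_index(drop=True)


def random_walk_tracks(
    n_tracks: int,
    cell_id: str = "cell0",
    n_frames: int = 20,
    step_sd_um: float = 0.1,
    spacing_um: float = 5.0,
    frame_interval_s: float = 5.0,
    seed: int = 0,
) -> list[TrackGroundTruth]:
    """Well-separated Gaussian random-walk trajectories on a grid.

    Starting points sit on a grid with pitch ``spacing_um`` so that, for
    small step sizes, distinct tracks never approach within the linking
    radius and identity recovery is unambiguous.
    """
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_tracks)))
    tracks = []
    for k in range(n_tracks):
        start = np.array([(k % side) * spacing_um, (k // side) * spacing_um], dtype=float)
        steps = rng.normal(0.0, step_sd_um, size=(n_frames - 1, 2))
        positions = np.vstack([start, start + np.cumsum(steps, axis=0)])
        tracks.append(
            TrackGroundTruth(
                cell_id=cell_id,
                spawn_frame=0,
                death_frame=n_frames - 1,
                positions=positions,
                frame_interval_s=frame_interval_s,
            )
        )
    return tracks
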