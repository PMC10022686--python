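"""Image normalization and tip-to-base line-profile extraction.

Intensity profiles are sampled along user-supplied polyline paths drawn
from the filopodium tip to its base (the intersection with the
lamellipodium).  Coordinates are continuous, 0-based pixel coordinates
with the origin at the centre of pixel (0, 0); profiles are sampled by
bilinear interpolation at (near) 1-pixel arclength spacing, matching a
1-pixel-wide line profile with no transverse averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "MultiChannelImage",
    "PolylinePath",
    "LineProfile",
    "normalize_image",
    "sample_line_profile",
    "profile_length",
    "read_image",
    "write_image",
    "read_paths",
    "write_paths",
    "read_profiles",
    "write_profiles",
]


@dataclass(frozen=True)
class MultiChannelImage:
    """Pixel data per channel plus physical pixel size.

    ``pixels`` has shape (n_channels, ny, nx); ``channel_names`` label
    the planes in order.
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels, dtype=float)
        if pixels.ndim == 2:
            pixels = pixels[None]
        if pixels.ndim != 3:
            raise ValueError("pixels must be a (channels, ny, nx) array")
        if pixels.size == 0:
            raise ValueError("image is empty")
        object.__setattr__(self, "pixels", pixels)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        names = self.channel_names or tuple(f"ch{i}" for i in range(pixels.shape[0]))
        if len(names) != pixels.shape[0]:
            raise ValueError("channel_names length must match channel count")
        object.__setattr__(self, "channel_names", tuple(names))

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]


@dataclass(frozen=True)
class PolylinePath:
    """Tip-first polyline in continuous pixel coordinates (x, y)."""

    filopodium_id: str
    vertices: np.ndarray
    tip_first: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (n>=2, 2) array")
        object.__setattr__(self, "vertices", v)
        if not self.tip_first:
            raise ValueError("paths must be oriented tip-first")
        if self.arclength_px <= 0:
            raise ValueError("path must have positive arclength")

    @property
    def arclength_px(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)))


@dataclass(frozen=True)
class LineProfile:
    """Per-channel intensity samples along one filopodium, tip first.

    ``samples`` maps channel name to a 1D array; all channels share the
    sample positions, so their lengths are equal.  ``spacing_um`` is the
    physical distance between consecutive samples.
    """

    filopodium_id: str
    spacing_um: float
    samples: dict[str, np.ndarray]
    source_image_id: str | None = None

    def __post_init__(self) -> None:
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be positive")
        if not self.samples:
            raise ValueError("profile needs at least one channel")
        clean = {k: np.asarray(v, dtype=float) for k, v in self.samples.items()}
        lengths = {v.size for v in clean.values()}
        if len(lengths) != 1:
            raise ValueError("all channels must have equal sample counts")
        if lengths.pop() < 2:
            raise ValueError("profiles need at least 2 samples")
        object.__setattr__(self, "samples", clean)

    @property
    def n_samples(self) -> int:
        return next(iter(self.samples.values())).size

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.samples)


def normalize_image(img: MultiChannelImage) -> MultiChannelImage:
    """Per-channel affine rescale to [0, 1].

    The upper bound is the channel maximum (the brightest structure in
    the field of view), the lower bound the channel minimum.  Constant
    channels map to all zeros.  Idempotent.
    """
    out = np.empty_like(img.pixels)
    for c in range(img.n_channels):
        plane = img.pixels[c]
        finite = plane[np.isfinite(plane)]
        if finite.size == 0:
            raise ValueError(f"channel {img.channel_names[c]!r} has no finite pixels")
        lo, hi = finite.min(), finite.max()
        out[c] = np.zeros_like(plane) if hi == lo else (plane - lo) / (hi - lo)
    return MultiChannelImage(out, img.pixel_size_um, img.channel_names)


def _bilinear(plane: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Bilinear interpolation at continuous (x, y), pixel-centre origin."""
    ny, nx = plane.shape
    x0 = np.clip(np.floor(x).astype(int), 0, nx - 2) if nx > 1 else np.zeros_like(x, int)
    y0 = np.clip(np.floor(y).astype(int), 0, ny - 2) if ny > 1 else np.zeros_like(y, int)
    fx, fy = x - x0, y - y0
    p00 = plane[y0, x0]
    p01 = plane[y0, np.minimum(x0 + 1, nx - 1)]
    p10 = plane[np.minimum(y0 + 1, ny - 1), x0]
    p11 = plane[np.minimum(y0 + 1, ny - 1), np.minimum(x0 + 1, nx - 1)]
    return (p00 * (1 - fx) * (1 - fy) + p01 * fx * (1 - fy)
            + p10 * (1 - fx) * fy + p11 * fx * fy)


def _points_at_arclengths(vertices: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Points along a polyline at the requested arclengths."""
    seg = np.diff(vertices, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    s = np.clip(s, 0.0, cum[-1])
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seglen) - 1)
    t = np.where(seglen[idx] > 0, (s - cum[idx]) / np.where(seglen[idx] > 0, seglen[idx], 1.0), 0.0)
    return vertices[idx] + seg[idx] * t[:, None]


def sample_line_profile(img: MultiChannelImage, path: PolylinePath) -> LineProfile:
    """Sample all channels along one path at ~1-pixel arclength spacing.

    The number of samples is ``round(arclength) + 1`` and samples are
    uniformly spaced over the full arclength, so both endpoints (tip and
    base) are included and the spacing is exactly one pixel whenever the
    arclength is a whole number of pixels.  Bilinear interpolation; all
    channels are sampled at identical positions.
    """
    ny, nx = img.shape
    for k, (x, y) in enumerate(path.vertices):
        if not (0 <= x <= nx - 1 and 0 <= y <= ny - 1):
            raise ValueError(
                f"path {path.filopodium_id!r} exits the image at vertex {k} "
                f"(x={x:.2f}, y={y:.2f})"
            )
    length = path.arclength_px
    n = max(2, int(round(length)) + 1)
    s = np.linspace(0.0, length, n)
    pts = _points_at_arclengths(path.vertices, s)
    samples = {
        name: _bilinear(img.pixels[c], pts[:, 0], pts[:, 1])
        for c, name in enumerate(img.channel_names)
    }
    return LineProfile(
        filopodium_id=path.filopodium_id,
        spacing_um=(length / (n - 1)) * img.pixel_size_um,
        samples=samples,
    )


def profile_length(p: LineProfile) -> float:
    """Filopodium length in µm: (n_samples - 1) × spacing."""
    return (p.n_samples - 1) * p.spacing_um


# ---------------------------------------------------------------------------
# I/O


def write_image(path: str | Path, img: MultiChannelImage) -> None:
    """Channel-first multi-page TIFF; pixel size stored as resolution metadata."""
    tifffile.imwrite(
        path,
        img.pixels.astype(np.float32),
        metadata={"axes": "CYX", "pixel_size_um": img.pixel_size_um,
                  "channel_names": list(img.channel_names)},
    )


def read_image(path: str | Path, pixel_size_um: float | None = None) -> MultiChannelImage:
    """Read a channel-first TIFF written by :func:`write_image`.

    ``pixel_size_um`` overrides (or supplies, for foreign TIFFs) the
    stored pixel size.
    """
    with tifffile.TiffFile(path) as tif:
        pixels = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    size = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    if size is None:
        raise ValueError(f"{path}: no pixel size in metadata; pass pixel_size_um")
    names = tuple(meta.get("channel_names", ()))
    return MultiChannelImage(pixels, float(size), names)


def write_paths(path: str | Path, paths: list[PolylinePath]) -> None:
    rows = [
        (p.filopodium_id, k, x, y)
        for p in paths
        for k, (x, y) in enumerate(p.vertices)
    ]
    pd.DataFrame(rows, columns=["filopodium_id", "vertex_index", "x_px", "y_px"]).to_csv(
        path, index=False
    )


def read_paths(path: str | Path) -> list[PolylinePath]:
    df = pd.read_csv(path)
    out = []
    for fid, g in df.groupby("filopodium_id", sort=False):
        g = g.sort_values("vertex_index")
        out.append(PolylinePath(str(fid), g[["x_px", "y_px"]].to_numpy(float)))
    return out


def write_profiles(path: str | Path, profiles: list[LineProfile]) -> None:
    """Long-format CSV: filopodium_id, sample_index, channel, intensity, spacing_um."""
    frames = []
    for p in profiles:
        for ch, vals in p.samples.items():
            frames.append(
                pd.DataFrame(
                    {
                        "filopodium_id": p.filopodium_id,
                        "sample_index": np.arange(vals.size),
                        "channel": ch,
                        "intensity": vals,
                        "spacing_um": p.spacing_um,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_profiles(path: str | Path) -> list[LineProfile]:
    df = pd.read_csv(path)
    out = []
    for fid, g in df.groupby("filopodium_id", sort=False):
        samples = {
            str(ch): gc.sort_values("sample_index")["intensity"].to_numpy(float)
            for ch, gc in g.groupby("channel", sort=False)
        }
        out.append(LineProfile(str(fid), float(g["spacing_um"].iloc[0]), samples))
    return out
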