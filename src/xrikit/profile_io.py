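"""Image and centerline I/O plus intensity-profile measurement.

The readout of a recording filament starts from a curved centerline drawn
along its long axis in the constitutive (HA) channel.  Intensity profiles
along that centerline — one per channel, on a shared uniform arc grid — are
the decoder's input.  This module reads multichannel TIFF stacks and
centerline CSVs, applies the filament selection rule (keep the longest
filament per soma plus any filament longer than half of it), measures the
filament width (median FWHM of perpendicular cuts), and samples profiles by
averaging bilinear interpolations across a perpendicular breadth of half the
measured width.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import skeletonize

__all__ = [
    "ImageStack",
    "Centerline",
    "LineProfile",
    "read_image",
    "write_image",
    "select_xris",
    "measure_width",
    "extract_profile",
    "trace_centerline",
    "read_centerlines",
    "write_centerlines",
    "profiles_to_frame",
    "write_profiles",
    "read_profiles",
]


@dataclass
class ImageStack:
    """Multichannel 2D image with channels indexed by role name."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 0.1

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class Centerline:
    """Polyline along a filament, in 0-based pixel-center coordinates."""

    vertices: np.ndarray  # (n, 2) columns x, y
    width_um: float = np.nan
    cell_id: str = "cell0"
    xri_id: str = "xri0"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be (n, 2)")
        if len(self.vertices) < 2:
            raise ValueError("centerline needs at least 2 vertices")
        seg = np.diff(self.vertices, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0):
            raise ValueError("consecutive vertices must be distinct")

    @property
    def length_px(self) -> float:
        seg = np.diff(self.vertices, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    def length_um(self, pixel_size_um: float) -> float:
        return self.length_px * pixel_size_um


@dataclass
class LineProfile:
    """Per-channel intensity versus arc distance along a centerline.

    All channels share the uniform arc grid ``d_um`` (step ``delta_d_um``,
    starting at 0).  ``intensities`` maps channel role to a 1D array.
    """

    d_um: np.ndarray
    intensities: dict[str, np.ndarray]
    delta_d_um: float
    cell_id: str = "cell0"
    xri_id: str = "xri0"
    meta: dict = field(default_factory=dict)

    @property
    def length_um(self) -> float:
        return float(self.d_um[-1])

    @property
    def n_samples(self) -> int:
        return len(self.d_um)

    def channel(self, role: str) -> np.ndarray:
        return self.intensities[role]


# ---------------------------------------------------------------------------
# image I/O

def write_image(stack: ImageStack, path, channel_order: Sequence[str] | None = None):
    """Write a stack as a multipage TIFF (one page per channel)."""
    order = list(channel_order) if channel_order else list(stack.channels)
    data = np.stack([np.asarray(stack.channels[c], dtype=np.float32) for c in order])
    desc = json.dumps(
        {"pixel_size_um": stack.pixel_size_um, "channels": order}
    )
    tifffile.imwrite(path, data, description=desc, photometric="minisblack")


def read_image(
    path,
    channel_map: Mapping[str, int] | None = None,
    pixel_size_um: float | None = None,
) -> ImageStack:
    """Read a multipage TIFF into an :class:`ImageStack`.

    ``channel_map`` maps role names to 0-based page indices.  When the file
    was written by :func:`write_image`, the channel names and pixel size are
    recovered from the embedded description unless overridden.
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    if data.ndim == 2:
        data = data[None]
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if channel_map is None:
        names = meta.get("channels")
        if names is None:
            raise ValueError("channel_map required: file carries no channel names")
        channel_map = {name: i for i, name in enumerate(names)}
    for role, page in channel_map.items():
        if not 0 <= page < data.shape[0]:
            raise ValueError(
                f"channel {role!r} maps to page {page} of a {data.shape[0]}-page file"
            )
    px = pixel_size_um or meta.get("pixel_size_um") or 0.1
    return ImageStack(
        channels={role: data[page] for role, page in channel_map.items()},
        pixel_size_um=float(px),
    )


# ---------------------------------------------------------------------------
# selection rule

def select_xris(lengths: Sequence[float]) -> list[int]:
    """Indices of filaments kept for analysis within one soma.

    Keeps the longest filament plus every filament whose length is strictly
    greater than half the longest.  Always contains the argmax; invariant to
    input order up to index relabeling.
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0:
        raise ValueError("need at least one length")
    longest = lengths.max()
    keep = np.nonzero(lengths > longest / 2.0)[0]
    best = int(lengths.argmax())
    if best not in keep:  # pragma: no cover - argmax always > max/2 for max > 0
        keep = np.append(keep, best)
    return sorted(int(i) for i in keep)


# ---------------------------------------------------------------------------
# geometry helpers

def _resample_polyline(
    vertices: np.ndarray, step_px: float
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform-arc resampling.  Returns (points (n,2), unit normals (n,2))."""
    v = np.asarray(vertices, dtype=float)
    seg = np.diff(v, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    n = max(int(np.floor(total / step_px)) + 1, 2)
    arcs = step_px * np.arange(n)
    arcs = arcs[arcs <= total + 1e-9]
    x = np.interp(arcs, cum, v[:, 0])
    y = np.interp(arcs, cum, v[:, 1])
    pts = np.column_stack([x, y])
    tang = np.gradient(pts, axis=0)
    norm = np.hypot(tang[:, 0], tang[:, 1])
    norm[norm == 0] = 1.0
    tang = tang / norm[:, None]
    normals = np.column_stack([-tang[:, 1], tang[:, 0]])
    return pts, normals


def _bilinear(image: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(
        np.asarray(image, dtype=float), [ys, xs], order=1, mode="nearest"
    )


def _background_level(image: np.ndarray, background, bg_percentile: float) -> float:
    if background is None:
        return 0.0
    if isinstance(background, (int, float)) and not isinstance(background, bool):
        return float(background)
    if background == "percentile":
        return float(np.percentile(image, bg_percentile))
    if background == "median":
        return float(np.median(image))
    raise ValueError(f"unknown background mode {background!r}")


# ---------------------------------------------------------------------------
# width measurement

def measure_width(
    image: np.ndarray,
    centerline: Centerline,
    pixel_size_um: float,
    cut_halfwidth_um: float = 1.5,
    background: str | float | None = "percentile",
    bg_percentile: float = 1.0,
    max_cuts: int = 100,
) -> float:
    """Filament width as the median FWHM of perpendicular intensity cuts.

    At up to ``max_cuts`` evenly spaced arc positions, the background-
    subtracted constitutive-channel intensity is sampled along a
    perpendicular segment; the full width at half maximum of each cut is
    found by linear interpolation around the cut maximum, and the median
    over cuts is returned in micrometers.  Raises if no cut has positive
    contrast (degenerate ridge).
    """
    pts, normals = _resample_polyline(centerline.vertices, 1.0)
    if len(pts) > max_cuts:
        idx = np.linspace(0, len(pts) - 1, max_cuts).astype(int)
        pts, normals = pts[idx], normals[idx]
    bg = _background_level(image, background, bg_percentile)
    half_px = cut_halfwidth_um / pixel_size_um
    offsets = np.arange(-half_px, half_px + 1e-9, 0.25)
    widths = []
    for p, nvec in zip(pts, normals):
        xs = p[0] + offsets * nvec[0]
        ys = p[1] + offsets * nvec[1]
        cut = _bilinear(image, xs, ys) - bg
        imax = int(np.argmax(cut))
        peak = cut[imax]
        if peak <= 0:
            continue
        half = peak / 2.0
        left = right = None
        for i in range(imax, 0, -1):
            if cut[i - 1] <= half <= cut[i]:
                frac = (half - cut[i - 1]) / (cut[i] - cut[i - 1])
                left = offsets[i - 1] + frac * (offsets[i] - offsets[i - 1])
                break
        for i in range(imax, len(cut) - 1):
            if cut[i + 1] <= half <= cut[i]:
                frac = (cut[i] - half) / (cut[i] - cut[i + 1])
                right = offsets[i] + frac * (offsets[i + 1] - offsets[i])
                break
        if left is None or right is None:
            continue
        widths.append((right - left) * pixel_size_um)
    if not widths:
        raise ValueError("degenerate ridge: no cut with positive contrast")
    return float(np.median(widths))


# ---------------------------------------------------------------------------
# profile extraction

def extract_profile(
    stack: ImageStack,
    centerline: Centerline,
    width_um: float | None = None,
    channels: Sequence[str] | None = None,
    background: str | float | None = "percentile",
    bg_percentile: float = 1.0,
) -> LineProfile:
    """Measure per-channel intensity profiles along a centerline.

    The centerline is resampled to a uniform arc step equal to the pixel
    size.  At each arc sample, the profile value is the mean of bilinear
    interpolations along the perpendicular segment of total length
    ``width/2`` (the profile breadth is half the measured filament width).
    A constant background (image percentile by default) is subtracted per
    channel and the result clipped at zero; pass ``background=None`` to
    keep raw intensities.
    """
    if width_um is None:
        width_um = centerline.width_um
    if not np.isfinite(width_um) or width_um <= 0:
        raise ValueError("width_um must be positive")
    if channels is None:
        channels = list(stack.channels)
    px = stack.pixel_size_um
    ny, nx = stack.shape
    pts, normals = _resample_polyline(centerline.vertices, 1.0)
    if (
        pts[:, 0].min() < -0.5
        or pts[:, 1].min() < -0.5
        or pts[:, 0].max() > nx - 0.5
        or pts[:, 1].max() > ny - 0.5
    ):
        raise ValueError("centerline exits image bounds")
    breadth_px = (width_um / 2.0) / px
    offsets = np.arange(-breadth_px / 2.0, breadth_px / 2.0 + 1e-9, 0.5)
    if offsets.size == 0:
        offsets = np.array([0.0])
    xs = pts[:, 0, None] + offsets[None, :] * normals[:, 0, None]
    ys = pts[:, 1, None] + offsets[None, :] * normals[:, 1, None]
    d_um = px * np.arange(len(pts))
    intensities: dict[str, np.ndarray] = {}
    for role in channels:
        image = stack.channels[role]
        bg = _background_level(image, background, bg_percentile)
        vals = _bilinear(image, xs.ravel(), ys.ravel()).reshape(xs.shape)
        prof = vals.mean(axis=1) - bg
        if background is not None:
            prof = np.clip(prof, 0.0, None)
        intensities[role] = prof
    return LineProfile(
        d_um=d_um,
        intensities=intensities,
        delta_d_um=px,
        cell_id=centerline.cell_id,
        xri_id=centerline.xri_id,
        meta={"width_um": width_um},
    )


# ---------------------------------------------------------------------------
# automatic centerline tracing (convenience for synthetic fixtures)

def trace_centerline(
    image: np.ndarray,
    seed_point: tuple[float, float],
    smooth_window: int = 5,
) -> Centerline:
    """Trace a filament centerline from the constitutive channel.

    Otsu threshold -> connected component containing ``seed_point`` ->
    morphological skeleton -> longest geodesic path (double breadth-first
    search over the 8-connected skeleton graph) -> moving-average smoothed
    polyline.  ``seed_point`` is (x, y) in pixels; raises if it does not
    land on a supra-threshold component.
    """
    img = np.asarray(image, dtype=float)
    thr = threshold_otsu(img)
    mask = img > thr
    labels = cc_label(mask, connectivity=2)
    sx, sy = int(round(seed_point[0])), int(round(seed_point[1]))
    if not (0 <= sy < img.shape[0] and 0 <= sx < img.shape[1]):
        raise ValueError("seed point outside image")
    lab = labels[sy, sx]
    if lab == 0:
        raise ValueError("seed point is not on a supra-threshold component")
    skel = skeletonize(labels == lab)
    pix = {(int(y), int(x)) for y, x in zip(*np.nonzero(skel))}
    if len(pix) < 2:
        raise ValueError("skeleton too small to trace")

    def bfs(start):
        from collections import deque

        prev = {start: None}
        dist = {start: 0.0}
        queue = deque([start])
        far, far_d = start, 0.0
        while queue:
            y, x = queue.popleft()
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dy == 0 and dx == 0:
                        continue
                    nb = (y + dy, x + dx)
                    if nb in pix and nb not in prev:
                        prev[nb] = (y, x)
                        dist[nb] = dist[(y, x)] + np.hypot(dy, dx)
                        if dist[nb] > far_d:
                            far, far_d = nb, dist[nb]
                        queue.append(nb)
        return far, prev

    start = min(pix, key=lambda p: (p[0] - sy) ** 2 + (p[1] - sx) ** 2)
    end_a, _ = bfs(start)
    end_b, prev = bfs(end_a)
    path = []
    node = end_b
    while node is not None:
        path.append(node)
        node = prev[node]
    coords = np.array([(x, y) for y, x in path], dtype=float)
    if smooth_window > 1 and len(coords) > smooth_window:
        kernel = np.ones(smooth_window) / smooth_window
        sm = np.column_stack(
            [
                np.convolve(coords[:, 0], kernel, mode="valid"),
                np.convolve(coords[:, 1], kernel, mode="valid"),
            ]
        )
        coords = np.vstack([coords[:1], sm, coords[-1:]])
    # drop duplicate consecutive vertices introduced by smoothing
    keep = np.ones(len(coords), dtype=bool)
    keep[1:] = np.hypot(*(np.diff(coords, axis=0).T)) > 1e-9
    return Centerline(vertices=coords[keep])


# ---------------------------------------------------------------------------
# centerline and profile CSV I/O

def write_centerlines(centerlines: Iterable[Centerline], path) -> None:
    rows = []
    for cl in centerlines:
        for i, (x, y) in enumerate(cl.vertices):
            rows.append(
                {
                    "cell_id": cl.cell_id,
                    "xri_id": cl.xri_id,
                    "vertex_index": i,
                    "x_px": x,
                    "y_px": y,
                    "width_um": cl.width_um,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_centerlines(path) -> list[Centerline]:
    df = pd.read_csv(path)
    out = []
    for (cell, xri), grp in df.groupby(["cell_id", "xri_id"], sort=False):
        grp = grp.sort_values("vertex_index")
        out.append(
            Centerline(
                vertices=grp[["x_px", "y_px"]].to_numpy(float),
                width_um=float(grp["width_um"].iloc[0]),
                cell_id=str(cell),
                xri_id=str(xri),
            )
        )
    return out


def profiles_to_frame(profiles: Iterable[LineProfile]) -> pd.DataFrame:
    """Long-format table: cell_id, xri_id, d_um, channel, intensity."""
    rows = []
    for prof in profiles:
        for ch, vals in prof.intensities.items():
            rows.append(
                pd.DataFrame(
                    {
                        "cell_id": prof.cell_id,
                        "xri_id": prof.xri_id,
                        "d_um": prof.d_um,
                        "channel": ch,
                        "intensity": vals,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def write_profiles(profiles: Iterable[LineProfile], path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)


def read_profiles(path) -> list[LineProfile]:
    df = pd.read_csv(path)
    out = []
    for (cell, xri), grp in df.groupby(["cell_id", "xri_id"], sort=False):
        channels = {}
        d = None
        for ch, sub in grp.groupby("channel", sort=False):
            sub = sub.sort_values("d_um")
            channels[ch] = sub["intensity"].to_numpy(float)
            d = sub["d_um"].to_numpy(float)
        delta = float(d[1] - d[0]) if len(d) > 1 else 1.0
        out.append(
            LineProfile(
                d_um=d,
                intensities=channels,
                delta_d_um=delta,
                cell_id=str(cell),
                xri_id=str(xri),
            )
        )
    return out
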