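"""Membrane fluorescence quantification and blot densitometry.

Mirrors a manual ImageJ workflow: maximum-project a small confocal sub-stack
(2-4 slices), measure the mean intensity along a fixed-length polyline laid
on a nurse cell membrane, measure the mean over a cytoplasm region of the
same cell, and report the difference (membrane minus cytoplasm) so that
stain-intensity variation between samples cancels.  Probes are inputs, as in
the manual workflow — there is no automated segmentation here.

Intensities are arbitrary units (AU).  Coordinates are pixel-based with the
origin at the top-left, x rightward, y downward; image bounds are half-open.
Line probes are sampled at sub-pixel spacing (<= 0.5 px) with bilinear
interpolation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

logger = logging.getLogger(__name__)

#: maximum arc-length spacing between interpolation samples on a line probe
PROBE_SPACING = 0.5


class ProbeError(ValueError):
    """A probe leaves the image or conflicts with another probe."""


@dataclass
class ImageStack:
    """An ordered stack of same-shaped 2D intensity rasters."""

    slices: np.ndarray  #: (n_slices, H, W), intensities >= 0
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=float)
        if self.slices.ndim == 2:
            self.slices = self.slices[None, :, :]
        if self.slices.ndim != 3:
            raise ValueError(f"expected a (n, H, W) stack, got shape {self.slices.shape}")
        if (self.slices < 0).any():
            raise ValueError("stack intensities must be non-negative")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @classmethod
    def from_tiff(cls, path: str | Path, pixel_size: float | None = None) -> "ImageStack":
        return cls(tifffile.imread(str(path)), pixel_size=pixel_size)

    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(str(path), self.slices.astype(np.float32))


@dataclass(frozen=True)
class LineProbe:
    """Polyline membrane probe with a sampling width (pixels)."""

    vertices: tuple[tuple[float, float], ...]  #: ordered (x, y) points
    width: float = 1.0

    def __post_init__(self) -> None:
        if len(self.vertices) < 2:
            raise ValueError("a line probe needs at least 2 vertices")
        if self.length <= 0:
            raise ValueError("line probe has zero length")
        if self.width < 1:
            raise ValueError("probe width must be >= 1 pixel")

    @property
    def length(self) -> float:
        v = np.asarray(self.vertices, dtype=float)
        return float(np.sum(np.hypot(*(np.diff(v, axis=0).T))))

    @classmethod
    def from_json(cls, path: str | Path, width: float = 1.0) -> "LineProbe":
        pts = json.loads(Path(path).read_text())
        return cls(tuple((float(p["x"]), float(p["y"])) for p in pts), width=width)


@dataclass(frozen=True)
class RegionProbe:
    """Cytoplasm region of the same cell: polygon vertices or an explicit mask."""

    vertices: tuple[tuple[float, float], ...] | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.vertices is None) == (self.mask is None):
            raise ValueError("give exactly one of polygon vertices or a mask")
        if self.vertices is not None and len(self.vertices) < 3:
            raise ValueError("a polygon region needs at least 3 vertices")

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        if self.mask is not None:
            if self.mask.shape != shape:
                raise ProbeError(f"mask shape {self.mask.shape} != image shape {shape}")
            m = self.mask.astype(bool)
        else:
            xs = np.array([v[0] for v in self.vertices])
            ys = np.array([v[1] for v in self.vertices])
            rr, cc = draw_polygon(ys, xs, shape=shape)
            m = np.zeros(shape, dtype=bool)
            m[rr, cc] = True
        if not m.any():
            raise ProbeError("region probe rasterizes to an empty mask")
        return m

    @classmethod
    def from_json(cls, path: str | Path) -> "RegionProbe":
        pts = json.loads(Path(path).read_text())
        return cls(vertices=tuple((float(p["x"]), float(p["y"])) for p in pts))


@dataclass(frozen=True)
class CorrectedIntensity:
    membrane_mean: float
    cytoplasm_mean: float

    @property
    def corrected(self) -> float:
        return self.membrane_mean - self.cytoplasm_mean

    @property
    def negative(self) -> bool:
        """Corrected values below zero are retained but flagged."""
        return self.corrected < 0


def max_project(stack: ImageStack, slice_range: tuple[int, int] | None = None) -> np.ndarray:
    """Elementwise maximum over a contiguous range of slices.

    ``slice_range`` is a half-open (start, stop) index interval; the
    quantification protocol projects 2 slices and acquisition uses 2-4, so a
    count outside 2-4 only warns (a single slice is returned unchanged).
    """
    if slice_range is None:
        slice_range = (0, stack.n_slices)
    start, stop = slice_range
    sub = stack.slices[start:stop]
    if sub.shape[0] == 0:
        raise ValueError(f"empty slice range {slice_range} for a {stack.n_slices}-slice stack")
    if not (2 <= sub.shape[0] <= 4):
        logger.warning("projecting %d slice(s); the protocol uses 2-4", sub.shape[0])
    return sub.max(axis=0)


def _sample_points(probe: LineProbe) -> np.ndarray:
    """(M, 2) array of (x, y) samples along the polyline, spacing <= 0.5 px."""
    v = np.asarray(probe.vertices, dtype=float)
    seg = np.diff(v, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    m = max(int(math.ceil(total / PROBE_SPACING)), 1)
    s = np.linspace(0.0, total, m + 1)
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    frac = (s - cum[idx]) / np.where(seg_len[idx] > 0, seg_len[idx], 1.0)
    return v[idx] + seg[idx] * frac[:, None]


def _offset_lines(points: np.ndarray, width: float) -> list[np.ndarray]:
    """Parallel sample lines across the probe width (1 px apart, centered)."""
    n_off = max(int(round(width)), 1)
    if n_off == 1:
        return [points]
    tang = np.gradient(points, axis=0)
    norm = np.hypot(tang[:, 0], tang[:, 1])
    normal = np.column_stack([-tang[:, 1], tang[:, 0]]) / np.where(norm > 0, norm, 1.0)[:, None]
    offsets = np.arange(n_off) - (n_off - 1) / 2.0
    return [points + o * normal for o in offsets]


def probe_mean(image: np.ndarray, probe: LineProbe) -> float:
    """Mean bilinear-interpolated intensity along the probe path.

    Raises :class:`ProbeError` naming the first offending vertex if any part
    of the sampled band leaves the image.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("probe_mean expects a single 2D raster (project the stack first)")
    h, w = image.shape
    for i, (x, y) in enumerate(probe.vertices):
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            raise ProbeError(f"probe vertex {i} at ({x}, {y}) is outside the {w}x{h} image")
    vals = []
    for line in _offset_lines(_sample_points(probe), probe.width):
        if (
            (line[:, 0] < 0).any()
            or (line[:, 0] > w - 1).any()
            or (line[:, 1] < 0).any()
            or (line[:, 1] > h - 1).any()
        ):
            raise ProbeError("probe sampling band leaves the image bounds")
        # map_coordinates takes (row, col) = (y, x)
        vals.append(ndimage.map_coordinates(image, [line[:, 1], line[:, 0]], order=1))
    return float(np.mean(np.concatenate(vals)))


def region_mean(image: np.ndarray, region: RegionProbe) -> float:
    image = np.asarray(image, dtype=float)
    return float(image[region.to_mask(image.shape)].mean())


def corrected_membrane_intensity(
    image: np.ndarray, membrane: LineProbe, cytoplasm: RegionProbe
) -> CorrectedIntensity:
    """Membrane probe mean minus same-cell cytoplasm mean.

    The subtraction corrects for overall stain-intensity variation; negative
    values are retained (and flagged on the result), never clipped, so
    downstream t-tests stay valid.  Probes must be disjoint.
    """
    image = np.asarray(image, dtype=float)
    mask = cytoplasm.to_mask(image.shape)
    pts = _sample_points(membrane)
    band = max(int(round(membrane.width)), 1) / 2.0
    ix = np.clip(np.round(pts[:, 0]).astype(int), 0, image.shape[1] - 1)
    iy = np.clip(np.round(pts[:, 1]).astype(int), 0, image.shape[0] - 1)
    if mask[iy, ix].any():
        raise ProbeError("membrane probe overlaps the cytoplasm region")
    mem = probe_mean(image, membrane)
    cyt = float(image[mask].mean())
    result = CorrectedIntensity(membrane_mean=mem, cytoplasm_mean=cyt)
    if result.negative:
        logger.warning("corrected intensity is negative (%.3f AU); retained", result.corrected)
    return result


# -- synthetic fixture generator --------------------------------------------


@dataclass(frozen=True)
class SyntheticFollicle:
    stack: ImageStack
    membrane_probe: LineProbe
    cytoplasm_probe: RegionProbe
    truth: CorrectedIntensity


def synth_follicle_image(
    membrane_intensity: float,
    cytoplasm_intensity: float,
    seed: int = 0,
    noise_sd: float = 0.0,
    n_slices: int = 2,
    shape: tuple[int, int] = (96, 96),
    ridge_sigma: float = 1.5,
) -> SyntheticFollicle:
    """Synthetic nurse-cell image with an analytically known ground truth.

    A polygonal "cell" boundary is rendered as a Gaussian ridge of peak
    ``membrane_intensity`` over a uniform ``cytoplasm_intensity`` interior:
    the pixel value is cyt + (mem - cyt) * exp(-d^2 / (2 sigma^2)) with d the
    exact distance to the boundary polyline, so the crest equals the membrane
    intensity and the ground-truth corrected value is mem - cyt exactly.  The
    bottom edge is axis-aligned at an integer row so the reference membrane
    probe sits on the analytic crest.  Per-slice Gaussian noise (clipped at
    zero) is added when ``noise_sd > 0``; its maximum-projection bias is
    common to membrane and cytoplasm and cancels in the corrected value.
    """
    if membrane_intensity < 0 or cytoplasm_intensity < 0:
        raise ValueError("intensities must be non-negative")
    rng = np.random.default_rng(seed)
    h, w = shape
    cx, cy, r = w / 2.0, h / 2.0, min(h, w) * 0.32
    # hexagon with a horizontal bottom edge on an integer row; the other
    # vertices get a small seeded jitter
    base_angles = np.deg2rad([240, 300, 0, 60, 120, 180])
    radii = r * (1.0 + 0.08 * rng.uniform(-1, 1, size=6))
    radii[0] = radii[1] = r  # keep the bottom edge symmetric and horizontal
    vx = cx + radii * np.cos(base_angles)
    vy = cy + radii * np.sin(base_angles)
    y_bottom = float(np.round(cy + r * math.sin(math.radians(300))))
    vy[0] = vy[1] = y_bottom
    verts = np.column_stack([vx, vy])

    yy, xx = np.mgrid[0:h, 0:w]
    d2 = np.full(shape, np.inf)
    closed = np.vstack([verts, verts[:1]])
    for (x0, y0), (x1, y1) in zip(closed[:-1], closed[1:]):
        ex, ey = x1 - x0, y1 - y0
        ln2 = ex * ex + ey * ey
        t = np.clip(((xx - x0) * ex + (yy - y0) * ey) / ln2, 0.0, 1.0)
        dx, dy = xx - (x0 + t * ex), yy - (y0 + t * ey)
        d2 = np.minimum(d2, dx * dx + dy * dy)
    clean = cytoplasm_intensity + (membrane_intensity - cytoplasm_intensity) * np.exp(
        -d2 / (2.0 * ridge_sigma**2)
    )
    slices = np.stack([clean] * n_slices)
    if noise_sd > 0:
        slices = np.clip(slices + rng.normal(0.0, noise_sd, size=slices.shape), 0.0, None)
    stack = ImageStack(slices)

    # membrane probe: central 60% of the bottom edge, exactly on the crest row
    x0, x1 = sorted([vx[0], vx[1]])
    span = x1 - x0
    membrane_probe = LineProbe(
        (((x0 + 0.2 * span), y_bottom), ((x0 + 0.8 * span), y_bottom))
    )
    # cytoplasm region: small square at the centroid, far from the ridge
    half = max(3.0, 0.12 * min(h, w) / 2)
    cyto_probe = RegionProbe(
        vertices=(
            (cx - half, cy - half),
            (cx + half, cy - half),
            (cx + half, cy + half),
            (cx - half, cy + half),
        )
    )
    truth = CorrectedIntensity(
        membrane_mean=membrane_intensity, cytoplasm_mean=cytoplasm_intensity
    )
    return SyntheticFollicle(stack, membrane_probe, cyto_probe, truth)


# -- densitometry ------------------------------------------------------------


@dataclass
class DensitometryRecord:
    """One gel lane: target band and loading-control band intensities."""

    lane: str
    band_intensity: float
    loading_intensity: float
    normalized: float | None = None
    relative_to_control: float | None = None


def densitometry_normalize(
    records: Sequence[DensitometryRecord], control_lanes: Sequence[str]
) -> list[DensitometryRecord]:
    """Normalize each band to its loading control, then to the control-lane mean.

    normalized = band / loading; relative_to_control = normalized divided by
    the mean normalized value over the named control lanes.
    """
    control_lanes = list(control_lanes)
    if not control_lanes:
        raise ValueError("need at least one control lane")
    out = []
    for r in records:
        if r.loading_intensity <= 0:
            raise ValueError(f"lane {r.lane!r}: loading intensity must be > 0")
        out.append(
            DensitometryRecord(
                lane=r.lane,
                band_intensity=r.band_intensity,
                loading_intensity=r.loading_intensity,
                normalized=r.band_intensity / r.loading_intensity,
            )
        )
    by_lane = {r.lane: r for r in out}
    missing = [l for l in control_lanes if l not in by_lane]
    if missing:
        raise ValueError(f"control lane(s) not found: {missing}")
    ref = float(np.mean([by_lane[l].normalized for l in control_lanes]))
    for r in out:
        r.relative_to_control = r.normalized / ref
    return out


def write_intensity_table(rows: Sequence[tuple[str, CorrectedIntensity]], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "image": name,
                "membrane_mean": ci.membrane_mean,
                "cytoplasm_mean": ci.cytoplasm_mean,
                "corrected": ci.corrected,
                "negative_flag": ci.negative,
            }
            for name, ci in rows
        ]
    ).to_csv(path, sep="\t", index=False)
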