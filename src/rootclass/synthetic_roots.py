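"""Procedural generation of labeled binary root-crown images.

Emulates excavated alfalfa root crowns of three architecture phenotypes:

* **B** (branch type): 4-6 thick lateral roots along the taproot at
  1-2 cm intervals, with a comparatively thin taproot.
* **T** (taproot type): fewer than four thin laterals spaced 3-4 cm
  apart on a dominant, thick taproot.
* **TB** (intermediate): four or more laterals of intermediate thickness
  spaced more than 2 cm apart.

Images are black-background rasters (foreground = root = True) with a known
pixel scale, so downstream trait extraction can run without any external
image archive.  Everything is deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

CLASS_LABELS = ("B", "T", "TB")

#: Margin (mm) kept above the crown and below the taproot tip.
_TOP_MARGIN_MM = 2.0
_BOTTOM_MARGIN_MM = 8.0
#: Laterals originate between these arc positions (mm from the crown).
_FIRST_LATERAL_MM = (5.0, 10.0)
#: Keep lateral origins this far (mm) above the taproot tip.
_TIP_EXCLUSION_MM = 8.0
_LATERAL_LENGTH_MM = (15.0, 35.0)
_LATERAL_ANGLE_DEG = (20.0, 70.0)


@dataclass(frozen=True)
class PhenotypeSpec:
    """Stochastic geometry rules for one root-architecture class.

    Lengths are in mm; ``fine_root_density`` is rootlets per mm of taproot.
    """

    label: str
    lateral_count_range: tuple[int, int]
    lateral_spacing_range_mm: tuple[float, float]
    lateral_thickness_mm: tuple[float, float]
    taproot_diameter_mm: tuple[float, float]
    taproot_length_mm: float = 105.0
    fine_root_density: float = 0.1

    def __post_init__(self):
        lo, hi = self.lateral_count_range
        if lo > hi or hi < 0:
            raise ValueError("lateral_count_range must be a nonempty interval")
        for name in ("lateral_spacing_range_mm", "lateral_thickness_mm",
                     "taproot_diameter_mm"):
            a, b = getattr(self, name)
            if a > b or a <= 0:
                raise ValueError(f"{name} must be a nonempty positive interval")
        if self.fine_root_density < 0:
            raise ValueError("fine_root_density must be >= 0")


# Branch type: many thick laterals, close spacing, thin taproot.
# Taproot type: few thin laterals, wide spacing, dominant taproot.
# Intermediate: >=4 laterals of in-between thickness, spacing just over 2 cm.
DEFAULT_SPECS: dict[str, PhenotypeSpec] = {
    "B": PhenotypeSpec("B", (4, 6), (10.0, 20.0), (1.1, 1.9), (3.5, 5.5),
                       fine_root_density=0.12),
    "T": PhenotypeSpec("T", (0, 3), (30.0, 40.0), (0.5, 0.9), (5.5, 8.5),
                       fine_root_density=0.06),
    "TB": PhenotypeSpec("TB", (4, 5), (20.5, 30.0), (0.7, 1.5), (4.5, 7.0),
                        fine_root_density=0.09),
}


@dataclass
class BinaryRootImage:
    """A binary root-crown raster plus its pixel scale.

    ``pixels`` is a 2-D boolean array, foreground (root) = True, row 0 at
    the top.  ``px_per_mm`` converts pixel measurements to mm.
    """

    pixels: np.ndarray
    px_per_mm: float
    image_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D raster")
        if not (np.isfinite(self.px_per_mm) and self.px_per_mm > 0):
            raise ValueError("px_per_mm must be finite and positive")


@dataclass
class GroundTruth:
    """Realized geometry of one generated image (for oracle-style tests)."""

    label: str
    lateral_count: int
    lateral_spacing_mm: list[float] = field(default_factory=list)
    rng_seed: int = 0


def _stamp_disk(canvas: np.ndarray, cy: float, cx: float, r: float) -> None:
    """Set pixels within radius ``r`` of (cy, cx) to True, clipped to canvas."""
    r = max(r, 0.6)  # sub-pixel strokes still leave a 1-px trace
    y0 = max(int(math.floor(cy - r)), 0)
    y1 = min(int(math.ceil(cy + r)) + 1, canvas.shape[0])
    x0 = max(int(math.floor(cx - r)), 0)
    x1 = min(int(math.ceil(cx + r)) + 1, canvas.shape[1])
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.ogrid[y0:y1, x0:x1]
    canvas[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _draw_stroke(canvas: np.ndarray, pts: np.ndarray, radii: np.ndarray) -> None:
    """Rasterize a polyline ``pts`` (N x 2, row/col px) with per-point radii."""
    for (cy, cx), r in zip(pts, radii):
        _stamp_disk(canvas, cy, cx, r)


def _polyline(points: np.ndarray, step_px: float = 0.6) -> np.ndarray:
    """Resample a coarse polyline at roughly ``step_px`` spacing."""
    segs = np.diff(points, axis=0)
    lens = np.hypot(segs[:, 0], segs[:, 1])
    total = lens.sum()
    n = max(int(total / step_px), 2)
    t = np.linspace(0.0, 1.0, n)
    cum = np.concatenate([[0.0], np.cumsum(lens)]) / max(total, 1e-9)
    out = np.empty((n, 2))
    for d in (0, 1):
        out[:, d] = np.interp(t, cum, points[:, d])
    return out


def _sample_lateral_origins(rng: np.random.Generator, spec: PhenotypeSpec,
                            count: int) -> tuple[list[float], list[float]]:
    """Arc positions (mm from crown) of lateral origins, plus the gaps.

    Consecutive gaps are drawn from the class spacing interval; the upper
    bound of each draw is clamped so the remaining gaps still fit on the
    taproot, keeping every realized gap inside the class bounds.
    """
    if count == 0:
        return [], []
    lo, hi = spec.lateral_spacing_range_mm
    usable = spec.taproot_length_mm - _TIP_EXCLUSION_MM
    start = rng.uniform(*_FIRST_LATERAL_MM)
    need = start + lo * (count - 1)
    if need > usable:
        raise ValueError(
            f"taproot of {spec.taproot_length_mm} mm cannot hold {count} "
            f"laterals spaced >= {lo} mm (needs {need + _TIP_EXCLUSION_MM:.0f} mm)")
    origins = [start]
    gaps: list[float] = []
    for i in range(1, count):
        gaps_left_after = count - 1 - i
        hi_i = min(hi, usable - origins[-1] - lo * gaps_left_after)
        gap = rng.uniform(lo, hi_i) if hi_i > lo else lo
        gaps.append(gap)
        origins.append(origins[-1] + gap)
    return origins, gaps


def required_canvas(spec: PhenotypeSpec, px_per_mm: float) -> tuple[int, int]:
    """Smallest (rows, cols) canvas that holds this phenotype at this scale."""
    reach = _LATERAL_LENGTH_MM[1] + 5.0  # lateral reach + wobble allowance
    rows = math.ceil((spec.taproot_length_mm + _TOP_MARGIN_MM
                      + _BOTTOM_MARGIN_MM) * px_per_mm)
    cols = math.ceil(2 * reach * px_per_mm + spec.taproot_diameter_mm[1] * px_per_mm)
    return rows, cols


def generate_root_image(spec: PhenotypeSpec,
                        canvas: tuple[int, int] | None = None,
                        px_per_mm: float = 10.0,
                        seed: int = 0,
                        image_id: str | None = None,
                        ) -> tuple[BinaryRootImage, GroundTruth]:
    """Render one root crown of the given phenotype.

    The taproot is a vertically descending, quadratically tapering stroke;
    laterals emerge at class-rule spacing with class-rule thickness at
    oblique downward angles; fine 1-px rootlets and occasional small holes
    add realistic texture.  Deterministic given ``(spec, canvas, px_per_mm,
    seed)``.

    Parameters
    ----------
    canvas : (rows, cols) in px, or None to auto-size to the phenotype.
    """
    rng = np.random.default_rng(seed)
    need = required_canvas(spec, px_per_mm)
    if canvas is None:
        canvas = need
    if canvas[0] < need[0] or canvas[1] < need[1]:
        raise ValueError(
            f"canvas {canvas} too small for {spec.label} phenotype at "
            f"{px_per_mm} px/mm; requires at least {need} (rows, cols)")

    img = np.zeros(canvas, dtype=bool)
    ppm = px_per_mm
    cx0 = canvas[1] / 2.0
    top = _TOP_MARGIN_MM * ppm
    length_px = spec.taproot_length_mm * ppm

    # Taproot centerline: vertical descent with gentle sinusoidal wobble.
    n_ctrl = 9
    ys = np.linspace(top, top + length_px, n_ctrl)
    phase = rng.uniform(0, 2 * math.pi)
    amp = rng.uniform(0.5, 2.0) * ppm
    xs = cx0 + amp * np.sin(np.linspace(0, rng.uniform(1.5, 3.0) * math.pi,
                                        n_ctrl) + phase)
    ctrl = np.column_stack([ys, xs])
    path = _polyline(ctrl)
    t = np.linspace(0.0, 1.0, len(path))
    d_crown = rng.uniform(*spec.taproot_diameter_mm)
    d_tip = 0.5
    diam = d_tip + (d_crown - d_tip) * (1.0 - t) ** 2  # quadratic taper
    _draw_stroke(img, path, diam * ppm / 2.0)

    # Arc-length lookup: mm position along the taproot -> pixel coordinate.
    steps = np.hypot(*np.diff(path, axis=0).T)
    arc_px = np.concatenate([[0.0], np.cumsum(steps)])

    def at_arc(mm: float) -> np.ndarray:
        i = int(np.searchsorted(arc_px, mm * ppm))
        return path[min(i, len(path) - 1)]

    count = int(rng.integers(spec.lateral_count_range[0],
                             spec.lateral_count_range[1] + 1))
    origins, gaps = _sample_lateral_origins(rng, spec, count)

    side = 1 if rng.random() < 0.5 else -1
    for o_mm in origins:
        origin = at_arc(o_mm)
        ang = math.radians(rng.uniform(*_LATERAL_ANGLE_DEG))
        llen = rng.uniform(*_LATERAL_LENGTH_MM) * ppm
        thick = rng.uniform(*spec.lateral_thickness_mm)
        # straight stroke with a slight downward droop at the far end
        droop = rng.uniform(0.0, 0.15)
        end = origin + np.array([math.sin(ang), side * math.cos(ang)]) * llen
        mid = 0.5 * (origin + end) + np.array([droop * llen, 0.0])
        lpath = _polyline(np.array([origin, mid, end]))
        lt = np.linspace(0.0, 1.0, len(lpath))
        ldiam = 0.3 + (thick - 0.3) * (1.0 - lt)
        _draw_stroke(img, lpath, ldiam * ppm / 2.0)
        side = -side if rng.random() < 0.8 else side

    # Fine rootlets: short, hair-thin, scattered along the taproot.
    n_fine = rng.poisson(spec.fine_root_density * spec.taproot_length_mm)
    for _ in range(n_fine):
        o_mm = rng.uniform(2.0, spec.taproot_length_mm - 2.0)
        origin = at_arc(o_mm)
        ang = math.radians(rng.uniform(10.0, 85.0))
        s = 1 if rng.random() < 0.5 else -1
        flen = rng.uniform(3.0, 8.0) * ppm
        end = origin + np.array([math.sin(ang), s * math.cos(ang)]) * flen
        fpath = _polyline(np.array([origin, end]))
        _draw_stroke(img, fpath, np.full(len(fpath), max(0.6, 0.08 * ppm)))

    # Punch small holes into thick interior regions (imaging artifacts /
    # root crossings); rate tied to the fine-root density so a zero-noise
    # spec renders a clean stroke.  Placement keeps the mask connected.
    n_holes = rng.poisson(12.0 * spec.fine_root_density)
    if n_holes:
        edt = ndimage.distance_transform_edt(img)
        for _ in range(n_holes):
            r = rng.uniform(1.0, 2.5)
            cand = np.argwhere(edt > r + 2.5)
            if len(cand) == 0:
                continue
            cy, cx = cand[rng.integers(len(cand))]
            yy, xx = np.ogrid[:img.shape[0], :img.shape[1]]
            img &= (yy - cy) ** 2 + (xx - cx) ** 2 > r * r

    # Keep only the component attached to the crown (defensive: sub-pixel
    # rootlet rasterization could in principle detach a speck).
    lab, n = ndimage.label(img, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        crown = lab[int(path[0, 0]), int(path[0, 1])]
        if crown == 0:  # fall back to the largest component
            crown = np.argmax(np.bincount(lab[lab > 0]))
        img = lab == crown

    iid = image_id if image_id is not None else f"{spec.label}_seed{seed}"
    return (BinaryRootImage(img, px_per_mm, iid),
            GroundTruth(spec.label, count, list(gaps), seed))


def generate_dataset(n_per_class: dict[str, int],
                     px_per_mm_range: tuple[float, float] = (8.0, 12.0),
                     seed: int = 0,
                     specs: dict[str, PhenotypeSpec] | None = None,
                     ) -> tuple[list[BinaryRootImage], list[GroundTruth]]:
    """Generate a labeled image set with per-image pixel-scale variation.

    The per-image scale is drawn uniformly from ``px_per_mm_range``,
    emulating a camera whose working distance was not constant across
    shots.  The class sequence is shuffled deterministically by ``seed``.
    """
    specs = specs or DEFAULT_SPECS
    for lbl, n in n_per_class.items():
        if lbl not in specs:
            raise ValueError(f"unknown class label {lbl!r}")
        if n < 0:
            raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    labels = [lbl for lbl in sorted(n_per_class) for _ in range(n_per_class[lbl])]
    rng.shuffle(labels)
    images, truths = [], []
    for i, lbl in enumerate(labels):
        ppm = rng.uniform(*px_per_mm_range)
        sub = int(rng.integers(0, 2**31 - 1))
        im, gt = generate_root_image(specs[lbl], canvas=None, px_per_mm=ppm,
                                     seed=sub, image_id=f"root{i:04d}_{lbl}")
        images.append(im)
        truths.append(gt)
    return images, truths


def save_dataset(images: list[BinaryRootImage], truths: list[GroundTruth],
                 out_dir) -> None:
    """Write 8-bit PNGs (foreground 255) plus a CSV manifest."""
    import pandas as pd
    from PIL import Image
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for im, gt in zip(images, truths):
        arr = (im.pixels.astype(np.uint8)) * 255
        Image.fromarray(arr, mode="L").save(out / f"{im.image_id}.png")
        rows.append({"image_id": im.image_id, "label": gt.label,
                     "px_per_mm": im.px_per_mm, "seed": gt.rng_seed,
                     "lateral_count": gt.lateral_count})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
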