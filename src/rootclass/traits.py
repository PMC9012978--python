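"""Extraction of the 38-trait morphological feature vector from a binary
root-crown image.

The trait set mirrors the standard root-crown phenotyping repertoire:
counts (tips, branch points, roots per row), skeleton-based lengths and
diameters via the Euclidean distance transform, areas (network, convex
hull, holes), angle-frequency bins, and per-diameter-range length /
projected area / surface area / volume.  Pixel measurements are converted
to mm, mm^2 and mm^3 with the per-image pixel scale; the diameter-range
bounds are applied in PIXELS before unit conversion, because the ranges
are configured on pixel images whose scale varies image to image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure
from skimage.morphology import convex_hull_image, skeletonize

from rootclass.synthetic_roots import BinaryRootImage

#: Canonical 38-trait column order: 26 whole-root traits followed by
#: length / projected area / surface area / volume within each of the
#: three diameter ranges.
TRAIT_NAMES: tuple[str, ...] = (
    "median_root_count", "max_root_count", "tip_count", "branch_point_count",
    "branching_density", "total_length_mm", "depth_mm", "max_width_mm",
    "width_depth_ratio", "network_area_mm2", "convex_hull_area_mm2",
    "solidity", "lower_root_area_mm2", "perimeter_mm", "surface_area_mm2",
    "volume_mm3", "hole_count", "total_hole_area_mm2", "avg_hole_size_mm2",
    "avg_orientation_deg", "shallow_angle_freq", "medium_angle_freq",
    "steep_angle_freq", "avg_diameter_mm", "median_diameter_mm",
    "max_diameter_mm",
    "length_1_mm", "projected_area_1_mm2", "surface_area_1_mm2", "volume_1_mm3",
    "length_2_mm", "projected_area_2_mm2", "surface_area_2_mm2", "volume_2_mm3",
    "length_3_mm", "projected_area_3_mm2", "surface_area_3_mm2", "volume_3_mm3",
)


@dataclass(frozen=True)
class ScaleMarker:
    """Circular scale marker of known physical size imaged alongside a root."""

    pixel_width: float
    known_diameter_mm: float


def px_per_mm_from_marker(marker: ScaleMarker) -> float:
    """Pixel scale from a measured scale marker: pixel_width / diameter."""
    if marker.pixel_width <= 0 or marker.known_diameter_mm <= 0:
        raise ValueError("marker pixel_width and known_diameter_mm must be > 0")
    return marker.pixel_width / marker.known_diameter_mm


@dataclass(frozen=True)
class ExtractionSettings:
    """Feature-extraction configuration (whole-root mode).

    ``diameter_range_bounds_px`` are the two breakpoints splitting skeleton
    diameters (in px) into three ranges: (0, b0], (b0, b1], (b1, inf).
    """

    binarize_threshold: int = 200
    pruning_threshold_px: int = 2
    diameter_range_bounds_px: tuple[float, float] = (10.0, 20.0)
    orientation_window_px: int = 7
    lower_area_fraction: float = 1.0 / 3.0

    def __post_init__(self):
        b = self.diameter_range_bounds_px
        if not (0 < b[0] < b[1]):
            raise ValueError("diameter range breakpoints must be increasing and positive")


@dataclass
class TraitVector:
    """Ordered, named 38-trait vector for one root crown."""

    values: dict[str, float]
    image_id: str = ""
    degenerate: bool = False

    def __post_init__(self):
        missing = set(TRAIT_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"missing traits: {sorted(missing)}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_series(self) -> pd.Series:
        return pd.Series({k: self.values[k] for k in TRAIT_NAMES},
                         name=self.image_id)


def binarize(raster: np.ndarray, threshold: int = 200) -> np.ndarray:
    """Threshold a grayscale raster into a boolean root mask.

    Polarity is auto-detected: of the two sides of the threshold, the side
    with FEWER pixels is taken as foreground (the root occupies a minority
    of a crown photograph); ties go to the bright side.  Idempotent on
    already-binary input of either polarity.
    """
    raster = np.asarray(raster)
    if raster.min() < 0 or raster.max() > 255:
        raise ValueError("raster values must lie in [0, 255]")
    high = raster > threshold
    low = ~high
    fg = high if high.sum() <= low.sum() else low
    if not fg.any():
        raise ValueError(f"no foreground at threshold {threshold}")
    return fg


def _neighbor_count(skel: np.ndarray) -> np.ndarray:
    k = np.ones((3, 3), dtype=int)
    k[1, 1] = 0
    return ndimage.convolve(skel.astype(int), k, mode="constant")


_OFFSETS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _prune_spurs(skel: np.ndarray, threshold: int) -> np.ndarray:
    """Remove terminal spur branches of skeleton length <= threshold px.

    A spur is traced from an endpoint to the first junction pixel
    (>= 3 neighbors); open curves with no junction are never removed.
    Repeats until stable, since removing one spur can expose another.
    """
    if threshold <= 0:
        return skel
    skel = skel.copy()
    while True:
        nc = _neighbor_count(skel) * skel
        endpoints = np.argwhere((nc == 1))
        removed_any = False
        for ep in endpoints:
            path = [tuple(ep)]
            prev = None
            cur = tuple(ep)
            while len(path) <= threshold + 1:
                nbrs = [(cur[0] + dy, cur[1] + dx) for dy, dx in _OFFSETS8
                        if 0 <= cur[0] + dy < skel.shape[0]
                        and 0 <= cur[1] + dx < skel.shape[1]
                        and skel[cur[0] + dy, cur[1] + dx]
                        and (cur[0] + dy, cur[1] + dx) != prev]
                if not nbrs:
                    break  # isolated curve, keep
                if len(nbrs) > 1 or nc[cur] >= 3:
                    # cur is a junction: spur is path[:-1]
                    spur = path[:-1]
                    if 0 < len(spur) <= threshold:
                        for p in spur:
                            skel[p] = False
                        removed_any = True
                    break
                prev, cur = cur, nbrs[0]
                path.append(cur)
                if nc[cur] >= 3:
                    spur = path[:-1]
                    if 0 < len(spur) <= threshold:
                        for p in spur:
                            skel[p] = False
                        removed_any = True
                    break
        if not removed_any:
            return skel


def skeletonize_and_prune(img: BinaryRootImage, pruning_threshold_px: int = 2
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Medial-axis skeleton plus per-skeleton-pixel radius map.

    The radius at each skeleton pixel is the Euclidean distance-transform
    value of the original mask; 2x radius is the local root diameter.
    """
    fg = np.asarray(img.pixels, dtype=bool)
    if not fg.any():
        raise ValueError("empty foreground")
    skel = skeletonize(fg)
    skel = _prune_spurs(skel, pruning_threshold_px)
    edt = ndimage.distance_transform_edt(fg)
    radius = np.where(skel, edt, 0.0)
    return skel, radius


def _skeleton_edges(skel: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique adjacency edges of the skeleton graph.

    Returns (points_a, points_b, step_lengths) where each 8-connected pixel
    pair appears once; diagonal steps count sqrt(2) px.
    """
    coords = np.argwhere(skel)
    index = -np.ones(skel.shape, dtype=int)
    index[tuple(coords.T)] = np.arange(len(coords))
    a_list, b_list, w_list = [], [], []
    h, w = skel.shape
    for dy, dx in ((0, 1), (1, -1), (1, 0), (1, 1)):  # forward neighbors only
        ys, xs = coords[:, 0], coords[:, 1]
        ny, nx = ys + dy, xs + dx
        ok = (ny >= 0) & (ny < h) & (nx >= 0) & (nx < w)
        ok[ok] &= skel[ny[ok], nx[ok]]
        a_list.append(np.flatnonzero(ok))
        b_list.append(index[ny[ok], nx[ok]])
        w_list.append(np.full(ok.sum(), np.hypot(dy, dx)))
    if not a_list or sum(len(a) for a in a_list) == 0:
        return (np.empty(0, int), np.empty(0, int), np.empty(0))
    return (np.concatenate(a_list), np.concatenate(b_list),
            np.concatenate(w_list))


def _orientation_angles(skel: np.ndarray, window_px: int) -> np.ndarray:
    """Per-skeleton-pixel tangent angle from horizontal, in [0, 90] degrees.

    The tangent is the principal axis of the skeleton pixels within a
    window of ``window_px`` extent around each pixel; short isolated
    fragments fall back to the window's span.  Absolute components make
    the angle invariant under horizontal/vertical mirroring.
    """
    coords = np.argwhere(skel).astype(float)
    if len(coords) < 2:
        return np.empty(0)
    tree = cKDTree(coords)
    r = max(window_px / 2.0, 1.5)
    angles = np.empty(len(coords))
    neighborhoods = tree.query_ball_point(coords, r)
    for i, idx in enumerate(neighborhoods):
        pts = coords[idx]
        if len(pts) < 2:
            angles[i] = 0.0
            continue
        c = pts - pts.mean(axis=0)
        cov = c.T @ c
        evals, evecs = np.linalg.eigh(cov)
        v = evecs[:, -1]  # (dy, dx) principal direction
        angles[i] = np.degrees(np.arctan2(abs(v[0]), abs(v[1])))
    return angles


def extract_traits(img: BinaryRootImage,
                   settings: ExtractionSettings = ExtractionSettings()
                   ) -> TraitVector:
    """Compute the 38-trait vector for one binary root-crown image.

    Raises on empty foreground.  A degenerate skeleton (fewer than two
    pixels) yields zero lengths and frequencies with ``degenerate=True``.
    """
    fg = np.asarray(img.pixels, dtype=bool)
    if not fg.any():
        raise ValueError("empty foreground")
    ppm = float(img.px_per_mm)

    skel, radius = skeletonize_and_prune(img, settings.pruning_threshold_px)
    coords = np.argwhere(skel)
    t: dict[str, float] = {}

    # --- bounding box, row-wise root counts, areas (mask-level traits) ---
    rows = np.any(fg, axis=1)
    cols = np.any(fg, axis=0)
    rmin, rmax = np.flatnonzero(rows)[[0, -1]]
    cmin, cmax = np.flatnonzero(cols)[[0, -1]]
    depth_px = rmax - rmin + 1
    width_px = cmax - cmin + 1
    t["depth_mm"] = depth_px / ppm
    t["max_width_mm"] = width_px / ppm
    t["width_depth_ratio"] = width_px / depth_px

    box = fg[rmin:rmax + 1]
    run_starts = np.hstack([box[:, :1], box[:, 1:] & ~box[:, :-1]])
    run_counts = run_starts.sum(axis=1)
    occupied = run_counts[run_counts > 0]
    t["median_root_count"] = float(np.median(occupied)) if len(occupied) else 0.0
    t["max_root_count"] = float(run_counts.max()) if len(run_counts) else 0.0

    area_px = int(fg.sum())
    t["network_area_mm2"] = area_px / ppm**2
    hull = convex_hull_image(fg)
    hull_px = int(hull.sum())
    t["convex_hull_area_mm2"] = hull_px / ppm**2
    t["solidity"] = area_px / hull_px if hull_px else 0.0
    lower_cut = rmin + settings.lower_area_fraction * depth_px
    t["lower_root_area_mm2"] = int(fg[int(np.ceil(lower_cut)):].sum()) / ppm**2
    t["perimeter_mm"] = float(measure.perimeter(fg)) / ppm

    # --- holes: background 4-components not touching the image border ---
    bg_lab, n_bg = ndimage.label(~fg, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    border = np.unique(np.concatenate([
        bg_lab[0], bg_lab[-1], bg_lab[:, 0], bg_lab[:, -1]]))
    sizes = np.bincount(bg_lab.ravel(), minlength=n_bg + 1)
    hole_ids = [i for i in range(1, n_bg + 1) if i not in set(border)]
    t["hole_count"] = float(len(hole_ids))
    hole_area_px = float(sizes[hole_ids].sum()) if hole_ids else 0.0
    t["total_hole_area_mm2"] = hole_area_px / ppm**2
    t["avg_hole_size_mm2"] = (hole_area_px / len(hole_ids) / ppm**2
                              if hole_ids else 0.0)

    degenerate = len(coords) < 2

    # --- skeleton topology: tips and merged branch-point clusters ---
    if degenerate:
        t["tip_count"] = float(len(coords))
        t["branch_point_count"] = 0.0
    else:
        nc = _neighbor_count(skel) * skel
        t["tip_count"] = float(np.sum(nc == 1))
        branch_mask = (nc >= 3) & skel
        _, n_clusters = ndimage.label(branch_mask,
                                      structure=np.ones((3, 3), dtype=int))
        t["branch_point_count"] = float(n_clusters)

    # --- skeleton edges: length, surface, volume, per-diameter-range ---
    ia, ib, steps = _skeleton_edges(skel)
    pix_rad = radius[tuple(coords.T)] if len(coords) else np.empty(0)
    if len(steps):
        d_edge = pix_rad[ia] + pix_rad[ib]  # mean diameter = (2ra+2rb)/2
        length_px_total = steps.sum()
        surf_px = np.pi * d_edge * steps
        vol_px = np.pi * (d_edge / 2.0) ** 2 * steps
        proj_px = d_edge * steps
        b0, b1 = settings.diameter_range_bounds_px
        bins = np.digitize(d_edge, [b0, b1], right=True)  # 0,1,2
        for r in range(3):
            sel = bins == r
            t[f"length_{r+1}_mm"] = steps[sel].sum() / ppm
            t[f"projected_area_{r+1}_mm2"] = proj_px[sel].sum() / ppm**2
            t[f"surface_area_{r+1}_mm2"] = surf_px[sel].sum() / ppm**2
            t[f"volume_{r+1}_mm3"] = vol_px[sel].sum() / ppm**3
        t["total_length_mm"] = length_px_total / ppm
        t["surface_area_mm2"] = surf_px.sum() / ppm**2
        t["volume_mm3"] = vol_px.sum() / ppm**3
    else:
        for r in range(3):
            t[f"length_{r+1}_mm"] = 0.0
            t[f"projected_area_{r+1}_mm2"] = 0.0
            t[f"surface_area_{r+1}_mm2"] = 0.0
            t[f"volume_{r+1}_mm3"] = 0.0
        t["total_length_mm"] = 0.0
        t["surface_area_mm2"] = 0.0
        t["volume_mm3"] = 0.0
        degenerate = True

    t["branching_density"] = (t["branch_point_count"] / t["total_length_mm"]
                              if t["total_length_mm"] > 0 else 0.0)

    # --- diameters over skeleton pixels ---
    if len(pix_rad):
        diam_mm = 2.0 * pix_rad / ppm
        t["avg_diameter_mm"] = float(diam_mm.mean())
        t["median_diameter_mm"] = float(np.median(diam_mm))
        t["max_diameter_mm"] = float(diam_mm.max())
    else:
        t["avg_diameter_mm"] = t["median_diameter_mm"] = t["max_diameter_mm"] = 0.0

    # --- angle frequencies: [0,30), [30,60), [60,90] from horizontal ---
    if not degenerate:
        ang = _orientation_angles(skel, settings.orientation_window_px)
        t["avg_orientation_deg"] = float(ang.mean())
        n = len(ang)
        t["shallow_angle_freq"] = float(np.sum(ang < 30.0)) / n
        t["medium_angle_freq"] = float(np.sum((ang >= 30.0) & (ang < 60.0))) / n
        t["steep_angle_freq"] = float(np.sum(ang >= 60.0)) / n
    else:
        t["avg_orientation_deg"] = 0.0
        t["shallow_angle_freq"] = t["medium_angle_freq"] = 0.0
        t["steep_angle_freq"] = 0.0

    if degenerate:
        warnings.warn(f"degenerate skeleton in image {img.image_id!r}; "
                      "length-based traits set to 0", stacklevel=2)
    return TraitVector(t, image_id=img.image_id, degenerate=degenerate)


def batch_extract(images: list[BinaryRootImage],
                  settings: ExtractionSettings = ExtractionSettings(),
                  out_csv=None) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Extract traits for a list of images into one table.

    Returns (table, failures); failures are (image_id, message) pairs and
    the corresponding rows are absent from the table, never silently
    zero-filled.  Row order follows input order.
    """
    rows, failures = [], []
    for im in images:
        try:
            tv = extract_traits(im, settings)
        except Exception as exc:  # collect, keep going
            failures.append((im.image_id, str(exc)))
            continue
        row = {"image_id": im.image_id}
        row.update({k: tv.values[k] for k in TRAIT_NAMES})
        rows.append(row)
    table = pd.DataFrame(rows, columns=["image_id", *TRAIT_NAMES])
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table, failures
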