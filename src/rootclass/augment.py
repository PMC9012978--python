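"""Constrained image augmentation: random rotation and isotropic scaling.

Each source image receives ``n_aug`` label-preserving transforms with
rotation drawn uniformly from [-20, 20] degrees and scale from [0.8, 1.2],
simulating arbitrary placement of the root crown under the camera and the
varying working distance.  The output canvas is padded so no foreground is
ever clipped, interpolation is nearest-neighbor (the mask stays binary),
and every transform is logged so a run is fully reproducible.

The pixel scale of an augmented image is inherited unchanged from its
source, so a scale factor deliberately changes the measured mm sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from rootclass.synthetic_roots import BinaryRootImage

ROTATION_BOUNDS_DEG = (-20.0, 20.0)
SCALE_BOUNDS = (0.8, 1.2)


@dataclass(frozen=True)
class AugmentationRecord:
    """One logged transform: which source, which replicate, which params."""

    source_image_id: str
    replicate_index: int
    rotation_deg: float
    scale_factor: float
    seed: int

    def __post_init__(self):
        if not ROTATION_BOUNDS_DEG[0] <= self.rotation_deg <= ROTATION_BOUNDS_DEG[1]:
            raise ValueError(
                f"rotation {self.rotation_deg} outside {ROTATION_BOUNDS_DEG}")
        if not SCALE_BOUNDS[0] <= self.scale_factor <= SCALE_BOUNDS[1]:
            raise ValueError(f"scale {self.scale_factor} outside {SCALE_BOUNDS}")


def _apply_transform(pixels: np.ndarray, rotation_deg: float,
                     scale: float) -> np.ndarray:
    """Rotate about the image center and scale isotropically, padding the
    output so the whole (transformed) input canvas fits."""
    h, w = pixels.shape
    th = math.radians(rotation_deg)
    c, s = math.cos(th), math.sin(th)
    # forward map: p_out = scale * R @ (p_in - center_in) + center_out
    out_h = int(math.ceil(scale * (h * abs(c) + w * abs(s)))) + 2
    out_w = int(math.ceil(scale * (h * abs(s) + w * abs(c)))) + 2
    if rotation_deg == 0.0 and scale == 1.0:
        return pixels.copy()
    center_in = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    center_out = np.array([(out_h - 1) / 2.0, (out_w - 1) / 2.0])
    rot = np.array([[c, -s], [s, c]])
    # affine_transform needs the INVERSE map: p_in = M @ p_out + offset
    minv = rot.T / scale
    offset = center_in - minv @ center_out
    out = ndimage.affine_transform(pixels.astype(np.uint8), minv,
                                   offset=offset, output_shape=(out_h, out_w),
                                   order=0, cval=0)
    return out.astype(bool)


def random_transform(img: BinaryRootImage, rng: np.random.Generator,
                     replicate_index: int = 1, seed: int = 0,
                     rotation_deg: float | None = None,
                     scale_factor: float | None = None,
                     ) -> tuple[BinaryRootImage, AugmentationRecord]:
    """Apply one random (or forced) rotation+scale transform.

    Forced parameters outside the constrained bounds are rejected.
    """
    if rotation_deg is None:
        rotation_deg = float(rng.uniform(*ROTATION_BOUNDS_DEG))
    if scale_factor is None:
        scale_factor = float(rng.uniform(*SCALE_BOUNDS))
    rec = AugmentationRecord(img.image_id, replicate_index,
                             rotation_deg, scale_factor, seed)
    out = _apply_transform(img.pixels, rotation_deg, scale_factor)
    aug = BinaryRootImage(out, img.px_per_mm,
                          f"{img.image_id}_aug{replicate_index}")
    return aug, rec


def augment_dataset(images: list[BinaryRootImage], n_aug: int = 10,
                    seed: int = 0
                    ) -> tuple[list[BinaryRootImage], pd.DataFrame]:
    """Produce ``n_aug`` transformed copies of every image plus a log table.

    The log has one row per augmented image with the exact transform
    parameters; replicate indices run 1..n_aug per source.
    """
    if n_aug < 1:
        raise ValueError("n_aug must be >= 1")
    rng = np.random.default_rng(seed)
    out_images, records = [], []
    for im in images:
        for rep in range(1, n_aug + 1):
            aug, rec = random_transform(im, rng, replicate_index=rep, seed=seed)
            out_images.append(aug)
            records.append(asdict(rec))
    log = pd.DataFrame(records, columns=["source_image_id", "replicate_index",
                                         "rotation_deg", "scale_factor", "seed"])
    return out_images, log
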