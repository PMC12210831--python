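"""Nuclear label masks and spot-to-nucleus assignment.

Masks are 2D integer label images (0 = background, k >= 1 = nucleus k).
Provided masks (from the generator, or hand-drawn boundaries rasterized
upstream) are the primary path; ``segment_nuclei_auto`` is a deterministic
threshold-based fallback for DAPI images with well-separated nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

from .spots import Spot


@dataclass(frozen=True)
class LabelMask:
    labels: np.ndarray  # (y, x) int array
    provenance: str = "provided"  # provided | auto

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError(f"label mask must be 2D; got shape {lab.shape}")
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.all(lab == lab.astype(int)):
                raise ValueError("label mask must contain integers")
            lab = lab.astype(int)
        if lab.min() < 0:
            raise ValueError("labels must be nonnegative")
        object.__setattr__(self, "labels", lab)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def segment_nuclei_auto(image: np.ndarray, min_area: int = 50) -> LabelMask:
    """Threshold-based nuclear segmentation of a 2D DAPI plane or projection.

    Otsu global threshold, hole filling, small-object removal, connected-
    component labelling.  A foreground-free image yields an empty (all-zero)
    mask rather than an error.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    if img.max() == img.min():
        return LabelMask(np.zeros(img.shape, dtype=np.int32), provenance="auto")
    thr = filters.threshold_otsu(img)
    fg = img > thr
    fg = ndimage.binary_fill_holes(fg)
    fg = morphology.remove_small_objects(fg, max_size=min_area - 1)
    labels = measure.label(fg, connectivity=1)
    return LabelMask(labels.astype(np.int32), provenance="auto")


def assign_spots_to_nuclei(
    spots: Sequence[Spot], mask: LabelMask, frame_shape: tuple[int, int] | None = None
) -> list[Spot]:
    """Annotate each spot with the nucleus label under its fitted center.

    The subpixel center is rounded to the nearest pixel with round-half-to-even
    (numpy's default), then clipped to the mask; the spot's ``nucleus_id`` is
    the mask value there (0 when outside every nucleus).
    """
    if frame_shape is not None and tuple(frame_shape) != mask.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image frame {tuple(frame_shape)}"
        )
    ny, nx = mask.shape
    out = []
    for s in spots:
        iy = int(np.clip(np.round(s.y), 0, ny - 1))
        ix = int(np.clip(np.round(s.x), 0, nx - 1))
        out.append(replace(s, nucleus_id=int(mask.labels[iy, ix])))
    return out
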