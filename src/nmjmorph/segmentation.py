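"""Channel binarization and 3D mask hygiene.

Thresholding is Otsu on the full 3D histogram (256 bins) by default —
an automatic, reproducible stand-in for interactive manual thresholding
— or a fixed intensity.  Cleaning removes sub-resolution speckle and,
when a reference mask is supplied, connected components that do not
approach the reference (used to strip axonal label from the
pre-synaptic channel).  Every threshold applied is logged.
"""

from __future__ import annotations

import logging
from typing import Optional, Union

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .datamodel import BinaryVolume, ImageStack, MAX_INTENSITY

logger = logging.getLogger(__name__)

#: 26-connectivity in 3D
STRUCTURE_3D = np.ones((3, 3, 3), dtype=bool)


def resolve_threshold(image: np.ndarray, method: Union[str, float, int] = "otsu") -> float:
    """Turn a threshold spec (``"otsu"``, ``"fixed:N"``, or a number)
    into an intensity value for this image."""
    if isinstance(method, (int, float)):
        t = float(method)
    elif method == "otsu":
        lo, hi = float(image.min()), float(image.max())
        if lo == hi:
            # degenerate: constant stack; >= lo marks everything foreground
            logger.warning("constant-intensity stack; Otsu degenerate, threshold=%g", lo)
            return lo
        # skimage's Otsu marks strictly-greater pixels foreground; our
        # contract is >=, so step to the next representable value
        t = float(np.nextafter(threshold_otsu(image, nbins=256), np.inf))
    elif isinstance(method, str) and method.startswith("fixed:"):
        t = float(method.split(":", 1)[1])
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    if not 0 <= t <= MAX_INTENSITY:
        raise ValueError(f"fixed threshold must lie in [0, {MAX_INTENSITY}], got {t}")
    return t


def binarize_channel(
    stack: ImageStack, channel: str, method: Union[str, float, int] = "otsu"
) -> BinaryVolume:
    """Binarize one channel: voxels with intensity >= threshold are
    foreground.  The threshold actually used is logged."""
    image = stack.channel(channel)
    t = resolve_threshold(image, method)
    mask = image >= t
    logger.info("channel %s: threshold %s -> %g (%d foreground voxels)",
                channel, method, t, int(mask.sum()))
    if not mask.any():
        logger.warning("channel %s segmented empty at threshold %g", channel, t)
    return BinaryVolume(mask=mask, voxel_size=stack.voxel_size, channel_role=channel)


def clean_mask(
    vol: BinaryVolume,
    min_object_volume: float = 5.0,
    link_distance: float = 2.0,
    reference: Optional[BinaryVolume] = None,
) -> BinaryVolume:
    """Remove small 26-connected components and, given a reference mask,
    components farther than ``link_distance`` µm from it.

    The reference path is how axonal label is excluded from pre-synaptic
    volume: the terminal component abuts the end-plate, stray axon
    segments do not.  Idempotent.
    """
    labels, n = ndimage.label(vol.mask, structure=STRUCTURE_3D)
    if n == 0:
        return vol.with_mask(vol.mask.copy())
    counts = np.bincount(labels.ravel())
    keep = counts * vol.voxel_volume >= min_object_volume
    keep[0] = False

    if reference is not None and reference.mask.any():
        # distance from every voxel to the reference; a component is linked
        # if it comes within link_distance of the reference
        d_ref = ndimage.distance_transform_edt(~reference.mask, sampling=vol.voxel_size)
        linked = np.zeros_like(keep)
        candidates = np.flatnonzero(keep)
        if candidates.size:
            mins = ndimage.minimum(d_ref, labels=labels, index=candidates)
            linked[candidates] = np.atleast_1d(mins) <= link_distance
        keep &= linked

    return vol.with_mask(keep[labels])


def mask_volume(vol: BinaryVolume) -> float:
    """Foreground voxel count × voxel volume, in µm³."""
    return float(np.count_nonzero(vol.mask)) * vol.voxel_volume
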