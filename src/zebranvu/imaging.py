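"""Stack quantifications: projections, vessel masks, vascular length,
vessel-normalised intensity, tissue-ROI means and mural-nuclei counts.

Vessel segmentation runs on the 2-D maximum-intensity projection; vascular
length is the physical length of the topological skeleton of the mask
(unit steps for 4-neighbours, √2 steps for diagonals, times the pixel size).
Reporter intensity is the total masked signal divided by that length
(a.u./µm).  Mural nuclei are 3-D connected components (26-connectivity) of a
thresholded channel within a fixed ROI box, discarding components below a
minimum physical volume.  Thresholds default to Otsu and are always logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects, skeletonize

from .io import ImageStack

__all__ = [
    "VesselQuant",
    "max_intensity_projection",
    "segment_vessels",
    "vessel_length",
    "normalized_vascular_intensity",
    "quantify_vessels",
    "roi_mean_intensity",
    "count_mural_nuclei",
]

log = logging.getLogger(__name__)


@dataclass
class VesselQuant:
    """Vessel-mask quantification of one stack."""

    mask: np.ndarray
    skeleton_length: float  # µm
    total_masked_intensity: float  # a.u.
    normalized_intensity: float  # a.u./µm


def max_intensity_projection(stack: ImageStack, channel: str) -> np.ndarray:
    """Per-pixel maximum over z of one channel."""
    if channel not in stack.channels:
        raise KeyError(f"unknown channel {channel!r}; have {list(stack.channels)}")
    return stack.channels[channel].max(axis=0)


def segment_vessels(
    image: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    min_object_px: int = 50,
) -> np.ndarray:
    """Threshold a 2-D image into a vessel mask, dropping specks.

    ``method='otsu'`` derives the threshold from the histogram;
    ``method='fixed'`` uses ``threshold``.  The realised threshold is logged.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("segment_vessels expects a 2-D image")
    if method == "otsu":
        if np.ptp(image) == 0:
            raise ValueError("no foreground: image is constant")
        thr = float(threshold_otsu(image))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown method {method!r}")
    mask = image > thr
    if not mask.any():
        raise ValueError("no foreground above threshold")
    # drop specks strictly smaller than min_object_px
    mask = remove_small_objects(mask, max_size=min_object_px - 1)
    if not mask.any():
        raise ValueError("no foreground after small-object removal")
    log.info("vessel segmentation: threshold=%.6g, %d foreground px", thr, int(mask.sum()))
    return mask


def vessel_length(mask: np.ndarray, pixel_size_um: float) -> float:
    """Physical length (µm) of the skeleton of a vessel mask.

    Length sums centre-to-centre distances over adjacent skeleton-pixel pairs:
    1 pixel for axial neighbours, √2 for diagonals, scaled by the pixel size.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    skel = skeletonize(mask)
    length_px = 0.0
    for (dy, dx), w in (((0, 1), 1.0), ((1, 0), 1.0), ((1, 1), math.sqrt(2)), ((1, -1), math.sqrt(2))):
        ys = slice(0, skel.shape[0] - dy)
        yt = slice(dy, skel.shape[0])
        if dx >= 0:
            xs = slice(0, skel.shape[1] - dx)
            xt = slice(dx, skel.shape[1])
        else:
            xs = slice(-dx, skel.shape[1])
            xt = slice(0, skel.shape[1] + dx)
        pairs = np.logical_and(skel[ys, xs], skel[yt, xt]).sum()
        length_px += w * float(pairs)
    return length_px * pixel_size_um


def normalized_vascular_intensity(
    signal_image: np.ndarray, mask: np.ndarray, length_um: float
) -> float:
    """Total signal within the vessel mask per unit vascular length (a.u./µm)."""
    signal_image = np.asarray(signal_image)
    mask = np.asarray(mask, dtype=bool)
    if signal_image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if length_um <= 0:
        raise ValueError("vascular length must be positive")
    return float(signal_image[mask].sum() / length_um)


def quantify_vessels(
    stack: ImageStack,
    vessel_channel: str = "red",
    signal_channel: str = "green",
    method: str = "otsu",
    threshold: float | None = None,
    min_object_px: int = 50,
) -> VesselQuant:
    """Full vessel-normalised intensity pipeline on one stack.

    MIP of the vessel channel -> mask -> skeleton length -> total signal-
    channel intensity inside the mask per µm of vasculature.
    """
    mip_vessel = max_intensity_projection(stack, vessel_channel)
    mip_signal = max_intensity_projection(stack, signal_channel)
    mask = segment_vessels(mip_vessel, method=method, threshold=threshold, min_object_px=min_object_px)
    if not math.isclose(stack.voxel_size[1], stack.voxel_size[2], rel_tol=1e-6):
        raise ValueError("anisotropic in-plane pixels are not supported")
    length = vessel_length(mask, stack.voxel_size[1])
    total = float(mip_signal[mask].sum())
    return VesselQuant(
        mask=mask,
        skeleton_length=length,
        total_masked_intensity=total,
        normalized_intensity=total / length,
    )


def _roi_slices(roi_box: tuple, shape: tuple[int, int, int]) -> tuple[slice, slice, slice]:
    """Validate an ROI box ((z0, z1), (y0, y1), (x0, x1)), half-open, voxels."""
    if len(roi_box) != 3:
        raise ValueError("roi_box must give (z, y, x) ranges")
    slices = []
    for (lo, hi), n in zip(roi_box, shape):
        if not (0 <= lo < hi <= n):
            raise ValueError(f"ROI range ({lo}, {hi}) out of bounds for axis of size {n}")
        slices.append(slice(int(lo), int(hi)))
    return tuple(slices)


def roi_mean_intensity(stack: ImageStack, channel: str, roi_box: tuple) -> float:
    """Mean voxel intensity of one channel over a fixed 3-D ROI box."""
    if channel not in stack.channels:
        raise KeyError(f"unknown channel {channel!r}")
    sl = _roi_slices(roi_box, stack.shape)
    return float(stack.channels[channel][sl].mean())


def count_mural_nuclei(
    stack: ImageStack,
    channel: str = "red",
    roi_box: tuple | None = None,
    min_blob_um3: float = 4.0,
    threshold_method: str = "otsu",
    threshold: float | None = None,
) -> int:
    """Count labelled nuclei in a fixed vascular volume.

    3-D threshold of the channel inside the ROI, 26-connected components,
    discard components below ``min_blob_um3``, count the rest.
    """
    if channel not in stack.channels:
        raise KeyError(f"unknown channel {channel!r}")
    data = stack.channels[channel]
    if roi_box is not None:
        data = data[_roi_slices(roi_box, stack.shape)]
    if threshold_method == "otsu":
        if np.ptp(data) == 0:
            return 0
        thr = float(threshold_otsu(np.asarray(data)))
    elif threshold_method == "fixed":
        if threshold is None:
            raise ValueError("threshold_method='fixed' requires a threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    fg = data > thr
    labels, n = ndimage.label(fg, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        return 0
    voxel_vol = float(np.prod(stack.voxel_size))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    count = int(np.sum(sizes * voxel_vol >= min_blob_um3))
    log.info("nuclei count: threshold=%.6g, %d components, %d kept", thr, n, count)
    return count
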