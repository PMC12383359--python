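"""Quantification of multi-channel confocal z-stacks of whole embryos.

Stacks are acquired in 1.675 µm steps with an ROI outlining the embryo.
After thresholding (a single threshold per channel, shared across every
stack in a batch so groups stay comparable), the total fluorescence of a
channel is

    total intensity / µm^3 = sum(integrated density) / (sum(area) x 1.675)

where per slice the integrated density is the sum of voxel intensities in
the mask and the area is the mask voxel count.  Per-slice intensity is the
same quotient for a single slice without the slice-height factor.  Nuclei
are counted as 3-D connected components of the thresholded nuclear channel
(so a nucleus spanning several slices counts once), and lipid peroxidation
is reported as the oxidized:reduced (green:red) intensity ratio on the
analyzed (by default middle) slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import filters, measure

__all__ = [
    "ZStack",
    "IntensityResult",
    "LipidRatio",
    "DEFAULT_SLICE_HEIGHT_UM",
    "threshold_channel",
    "batch_threshold",
    "total_intensity",
    "slice_intensity",
    "count_nuclei",
    "lipid_ratio",
]

DEFAULT_SLICE_HEIGHT_UM = 1.675
DEFAULT_MIN_NUCLEUS_VOLUME = 27  # voxels


@dataclass
class ZStack:
    """Named 3-D channels (slices x rows x cols) with slice height in µm.

    ``roi`` is a per-voxel boolean region-of-interest mask (default: the
    full frame on every slice).
    """

    channels: dict
    slice_height_um: float = DEFAULT_SLICE_HEIGHT_UM
    roi: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("a ZStack needs at least one channel")
        shapes = {np.asarray(v).shape for v in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels disagree on shape: {shapes}")
        (self.shape,) = shapes
        if len(self.shape) != 3:
            raise ValueError(f"channels must be 3-D, got shape {self.shape}")
        if self.slice_height_um <= 0:
            raise ValueError("slice_height_um must be positive")
        if self.roi is None:
            self.roi = np.ones(self.shape, dtype=bool)
        else:
            self.roi = np.asarray(self.roi, dtype=bool)
            if self.roi.shape != self.shape:
                raise ValueError("ROI shape must match channel shape")
        for name, arr in self.channels.items():
            if np.any(np.asarray(arr) < 0):
                raise ValueError(f"channel {name!r} has negative intensities")

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(
                f"unknown channel {name!r}; have {sorted(self.channels)}"
            )
        return np.asarray(self.channels[name], dtype=float)

    @property
    def n_slices(self) -> int:
        return self.shape[0]


@dataclass(frozen=True)
class IntensityResult:
    channel: str
    threshold: float
    total_intensity_per_um3: float
    per_slice: tuple  # per-slice intensity (integrated density / area)


@dataclass(frozen=True)
class LipidRatio:
    green_intensity: float
    red_intensity: float
    ratio: float
    slice_index: int


def threshold_channel(stack: ZStack, channel: str, method="otsu") -> tuple[np.ndarray, float]:
    """Binary mask of a channel, restricted to the ROI.

    ``method`` is either a fixed numeric threshold t (mask = voxel >= t)
    or ``"otsu"`` for Otsu's threshold on the ROI voxel histogram.  Returns
    ``(mask, threshold)``; the threshold should be recorded and reused for
    every stack in a batch (see :func:`batch_threshold`).
    """
    data = stack.channel(channel)
    if isinstance(method, (int, float)) and not isinstance(method, bool):
        t = float(method)
    elif method == "otsu":
        voxels = data[stack.roi]
        if np.ptp(voxels) == 0:
            # constant channel: threshold above the single value -> empty mask
            t = float(voxels.flat[0]) + 1.0 if voxels.size else np.inf
        else:
            t = float(filters.threshold_otsu(voxels))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return (data >= t) & stack.roi, t


def batch_threshold(stacks, channel: str) -> float:
    """One Otsu threshold from the pooled ROI histogram of several stacks.

    Using a single threshold for all samples and groups keeps intensity
    comparisons unbiased across a batch.
    """
    voxels = np.concatenate([s.channel(channel)[s.roi].ravel() for s in stacks])
    if voxels.size == 0 or np.ptp(voxels) == 0:
        raise ValueError("cannot derive a threshold from a constant batch")
    return float(filters.threshold_otsu(voxels))


def _slice_density_area(data: np.ndarray, mask: np.ndarray):
    density = np.array([data[i][mask[i]].sum() for i in range(data.shape[0])])
    area = np.array([int(mask[i].sum()) for i in range(mask.shape[0])])
    return density, area


def total_intensity(stack: ZStack, channel: str, mask: np.ndarray, threshold: float = np.nan) -> IntensityResult:
    """Total fluorescence per µm^3 over the whole stack.

    Sum of per-slice integrated densities divided by (sum of per-slice mask
    areas x slice height).  Per-slice intensities (density/area, no height
    factor) are reported alongside; slices with an empty mask get NaN.

    Raises
    ------
    ValueError
        If the mask is empty (no signal above threshold).
    """
    data = stack.channel(channel)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.shape:
        raise ValueError("mask shape must match stack shape")
    if not mask.any():
        raise ValueError(f"empty mask for channel {channel!r}: no signal above threshold")
    density, area = _slice_density_area(data, mask)
    total = float(density.sum()) / (float(area.sum()) * stack.slice_height_um)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_slice = np.where(area > 0, density / np.where(area > 0, area, 1), np.nan)
    return IntensityResult(
        channel=channel,
        threshold=float(threshold),
        total_intensity_per_um3=total,
        per_slice=tuple(float(v) for v in per_slice),
    )


def slice_intensity(stack: ZStack, channel: str, mask: np.ndarray, slice_index: int) -> float:
    """Integrated density / area for one slice (no slice-height factor)."""
    data = stack.channel(channel)
    mask = np.asarray(mask, dtype=bool)
    if not 0 <= slice_index < stack.n_slices:
        raise IndexError(
            f"slice {slice_index} out of range for {stack.n_slices}-slice stack"
        )
    m = mask[slice_index]
    if not m.any():
        raise ValueError(f"empty mask on slice {slice_index}")
    return float(data[slice_index][m].sum()) / float(m.sum())


def count_nuclei(
    stack: ZStack,
    channel: str = "nuclei",
    method="otsu",
    min_volume: int = DEFAULT_MIN_NUCLEUS_VOLUME,
) -> int:
    """Number of nuclei in the nuclear channel.

    The thresholded mask is labeled by 3-D connected components, so a
    nucleus spanning several z slices is counted once, and components
    smaller than ``min_volume`` voxels are discarded as speckle.  Zero is a
    valid result.
    """
    mask, _ = threshold_channel(stack, channel, method)
    if not mask.any():
        return 0
    labels = measure.label(mask, connectivity=3)
    sizes = np.bincount(labels.ravel())[1:]  # skip background
    return int((sizes >= min_volume).sum())


def lipid_ratio(
    stack: ZStack,
    green_channel: str,
    red_channel: str,
    mask: np.ndarray,
    slice_index: int | None = None,
) -> LipidRatio:
    """Oxidized:reduced (green:red) intensity ratio on one analyzed slice.

    Defaults to the middle slice of the stack; both channels use the same
    mask and slice.  A zero red intensity leaves the ratio undefined and is
    an error.
    """
    if slice_index is None:
        slice_index = stack.n_slices // 2
    green = slice_intensity(stack, green_channel, mask, slice_index)
    red = slice_intensity(stack, red_channel, mask, slice_index)
    if red == 0:
        raise ValueError("red (reduced) intensity is zero; ratio undefined")
    return LipidRatio(
        green_intensity=green,
        red_intensity=red,
        ratio=green / red,
        slice_index=slice_index,
    )
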