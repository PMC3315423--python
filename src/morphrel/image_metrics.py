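"""Bias-correction quality metrics on grey-level volumes.

After bias-field correction, voxels of one tissue type should have
near-uniform grey levels.  Two summary metrics quantify this on a
T1-weighted volume with WM/GM/CSF masks:

* the coefficient of variation (SD / mean of grey levels) within each
  tissue mask — lower is better;
* the WM/GM contrast, the ratio of the modal (peak) grey level within
  the WM mask to that within the GM mask — higher separation of the two
  tissue peaks aids segmentation.

To avoid favouring either of two segmentation programs being compared,
metrics are typically computed within the voxelwise intersection of
their tissue masks.  Peaks are estimated by histogramming the within-
mask grey levels over a percentile-clipped range with optional
moving-average smoothing; all knobs are exposed in
:class:`PeakConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InsufficientMaskError, ValidationError

try:  # nibabel is only needed for file I/O
    import nibabel as nib
except ImportError:  # pragma: no cover
    nib = None


@dataclass
class ImageVolume:
    """A 3-D scalar grey-level volume with voxel size in mm."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValidationError("volume must be 3-D with positive extents")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("volume contains non-finite values")


@dataclass
class Mask:
    """A boolean 3-D mask; shape is checked against its companion volume."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValidationError("mask must be 3-D")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class PeakConfig:
    """Histogram-mode estimator settings.

    The grey levels within the mask are histogrammed between their 1st and
    99th percentiles (``clip_percentiles``) into ``bins`` bins, optionally
    smoothed with a centred moving average of ``smooth_window`` bins, and
    the centre of the maximal bin is returned; ties break toward the lower
    grey level.
    """

    bins: int = 128
    smooth_window: int = 3
    clip_percentiles: tuple[float, float] = (1.0, 99.0)


def _check_shapes(volume: ImageVolume, *masks: Mask) -> None:
    for m in masks:
        if m.data.shape != volume.data.shape:
            raise ValidationError(
                f"mask shape {m.data.shape} != volume shape {volume.data.shape}"
            )


def intersect_masks(a: Mask, b: Mask) -> Mask:
    """Voxelwise logical AND of two same-shape masks."""
    if a.data.shape != b.data.shape:
        raise ValidationError(f"mask shapes differ: {a.data.shape} vs {b.data.shape}")
    return Mask(a.data & b.data)


def coefficient_of_variation(
    volume: ImageVolume, mask: Mask, *, min_voxels: int = 10, ddof: int = 0
) -> float:
    """SD / mean of grey levels within the mask (population SD by default)."""
    _check_shapes(volume, mask)
    if mask.n_voxels < min_voxels:
        raise InsufficientMaskError(
            f"mask has {mask.n_voxels} voxels (< {min_voxels})"
        )
    vals = volume.data[mask.data]
    mean = float(vals.mean())
    if mean <= 0:
        raise ValueError("mean grey level within mask must be > 0")
    return float(vals.std(ddof=ddof)) / mean


def detect_peak(
    volume: ImageVolume, mask: Mask, config: PeakConfig = PeakConfig()
) -> float:
    """Modal grey level within the mask, by percentile-clipped histogram."""
    _check_shapes(volume, mask)
    if mask.n_voxels < 1:
        raise InsufficientMaskError("mask is empty")
    vals = volume.data[mask.data]
    lo, hi = np.percentile(vals, config.clip_percentiles)
    if hi <= lo:  # constant (or near-constant) grey levels
        return float(vals[0]) if vals.min() == vals.max() else float((lo + hi) / 2)
    hist, edges = np.histogram(vals, bins=config.bins, range=(lo, hi))
    hist = hist.astype(float)
    w = config.smooth_window
    if w and w > 1:
        kernel = np.ones(w) / w
        hist = np.convolve(hist, kernel, mode="same")
    peak_bin = int(np.argmax(hist))  # argmax takes the first maximum: lower tie wins
    return float((edges[peak_bin] + edges[peak_bin + 1]) / 2)


def wm_gm_contrast(
    volume: ImageVolume,
    wm_mask: Mask,
    gm_mask: Mask,
    config: PeakConfig = PeakConfig(),
) -> float:
    """Ratio of the WM peak grey level to the GM peak grey level."""
    wm_peak = detect_peak(volume, wm_mask, config)
    gm_peak = detect_peak(volume, gm_mask, config)
    if gm_peak <= 0:
        raise ValueError(f"GM peak must be > 0, got {gm_peak}")
    return wm_peak / gm_peak


def load_volume(path: str | Path) -> ImageVolume:
    """Read a NIfTI grey-level volume."""
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(np.asarray(img.get_fdata(), dtype=float), voxel_size=zooms)


def load_mask(path: str | Path) -> Mask:
    """Read a NIfTI mask (nonzero = true)."""
    img = nib.load(str(path))
    return Mask(np.asarray(img.get_fdata()) != 0)


def save_volume(volume: ImageVolume, path: str | Path) -> None:
    affine = np.diag(list(volume.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), affine), str(path))


def save_mask(mask: Mask, path: str | Path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), str(path))
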