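"""Extraction of the adhesive-layer mask from a grayscale volume.

The interface is three-material by construction (tooth, adhesive,
composite), so the default automatic mode is 3-class multi-Otsu
thresholding with the middle intensity class taken as the adhesive; an
explicit intensity band [lo, hi] can be given instead. Cleanup is a
morphological opening of radius 1 voxel followed by retention of the
largest 26-connected component, which removes noise speckle without
bridging the layer to other structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu

from .volume import AdhesiveMask, Volume3D


class SegmentationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SegmentationConfig:
    """Either an explicit intensity band or automatic 3-class thresholding."""

    intensity_band: tuple[float, float] | None = None  # (lo, hi), inclusive
    opening_radius: int = 1
    connectivity: int = 26
    #: fill enclosed background cavities; isolated misclassified voxels inside
    #: the film would otherwise cap the inscribed-sphere thickness at the
    #: typical hole spacing instead of the film width
    fill_holes: bool = True

    def validate(self) -> None:
        if self.intensity_band is not None:
            lo, hi = self.intensity_band
            if not lo < hi:
                raise ValueError(f"intensity band must satisfy lo < hi, got ({lo}, {hi})")
        if self.opening_radius < 0:
            raise ValueError("opening_radius must be >= 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


def segment_adhesive(
    volume: Volume3D, config: SegmentationConfig | None = None
) -> tuple[AdhesiveMask, dict]:
    """Binary adhesive mask plus a report of the thresholds used."""
    config = config or SegmentationConfig()
    config.validate()
    vox = np.asarray(volume.voxels)

    if config.intensity_band is not None:
        lo, hi = config.intensity_band
        mode = "band"
    else:
        values = vox.ravel()
        if np.ptp(values) == 0:
            raise SegmentationError(
                "volume has constant intensity; no adhesive class separable"
            )
        try:
            t1, t2 = threshold_multiotsu(values, classes=3)
        except ValueError as err:  # fewer than 3 distinguishable levels
            raise SegmentationError(f"3-class thresholding failed: {err}") from err
        lo, hi = float(t1), float(t2)
        mode = "multiotsu"
    raw = (vox >= lo) & (vox <= hi)

    cleaned = _cleanup(raw, config)
    if not cleaned.any():
        raise SegmentationError(
            f"empty adhesive mask after cleanup (mode={mode}, band=[{lo:g}, {hi:g}])"
        )
    report = {
        "mode": mode,
        "threshold_lo": float(lo),
        "threshold_hi": float(hi),
        "raw_voxels": int(raw.sum()),
        "final_voxels": int(cleaned.sum()),
        "opening_radius": config.opening_radius,
        "connectivity": config.connectivity,
    }
    return AdhesiveMask(cleaned, volume.voxel_size), report


def _cleanup(mask: np.ndarray, config: SegmentationConfig) -> np.ndarray:
    if config.opening_radius > 0:
        ball = _ball(config.opening_radius)
        # outside the grid counts as foreground during erosion (the layer
        # continues past the field of view), as background during dilation
        eroded = ndimage.binary_erosion(mask, structure=ball, border_value=1)
        mask = ndimage.binary_dilation(eroded, structure=ball, border_value=0)
    if not mask.any():
        return mask
    structure = _connectivity_structure(config.connectivity)
    labels, n = ndimage.label(mask, structure=structure)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == counts.argmax()
    if config.fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    return mask


def _ball(radius: int) -> np.ndarray:
    grid = np.indices((2 * radius + 1,) * 3) - radius
    return (grid**2).sum(axis=0) <= radius**2


def _connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, order)
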