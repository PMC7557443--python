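"""The surface-area-versus-width distribution S(w) and its anchor points.

S(w) is the curve a volumetric wall-thickness analysis yields for an
adhesive film: how much interface surface area (mm^2) belongs to layer
width w (mm). The area accounting is voxel-face counting: every
tooth-side interface face (a mask voxel whose 6-neighbour on the tooth
side is outside the mask) contributes voxel_size^2 to the bin holding the
local thickness of its adjacent layer voxel. Face counting conserves the
total interface area exactly under re-binning, which makes the
distribution a trivial oracle for the model-fitting stage.

The anchor points (w0, S0) onset, (wM, SM) peak, (wI, SI) tail knot and
(wmax, Sm) terminal summarize one curve and parameterize the piecewise
model of :mod:`adhesivect.swmodel`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import AdhesiveMask, ThicknessMap


class DistributionError(ValueError):
    pass


@dataclass
class AreaWidthDistribution:
    """Binned surface area per layer width; uniform half-open bins [e_i, e_i+1)."""

    bin_edges: np.ndarray  # mm, strictly increasing, len = n_bins + 1
    areas: np.ndarray  # mm^2 per bin, >= 0
    provenance: dict

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.bin_edges.ndim != 1 or self.bin_edges.size != self.areas.size + 1:
            raise DistributionError("bin_edges must have len(areas) + 1 entries")
        if not np.all(np.diff(self.bin_edges) > 0):
            raise DistributionError("bin_edges must be strictly increasing")
        if np.any(self.areas < 0):
            raise DistributionError("areas must be >= 0")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def occupied(self) -> np.ndarray:
        return self.areas > 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "w_bin_left": self.bin_edges[:-1],
                "w_bin_right": self.bin_edges[1:],
                "area_mm2": self.areas,
            }
        )


@dataclass(frozen=True)
class AnchorPoints:
    """Onset, peak, tail knot and terminal of one S(w) curve (mm, mm^2)."""

    w0: float
    S0: float
    wM: float
    SM: float
    wI: float
    SI: float
    wmax: float
    Sm: float

    def __post_init__(self):
        if not (self.w0 <= self.wM < self.wI < self.wmax):
            raise DistributionError(
                f"anchor widths must satisfy w0 <= wM < wI < wmax, got "
                f"{self.w0:g}, {self.wM:g}, {self.wI:g}, {self.wmax:g}"
            )
        if self.SI > self.SM or self.Sm < 0 or self.S0 < 0:
            raise DistributionError("anchor areas must satisfy 0 <= SI <= SM, Sm >= 0")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("w0", "S0", "wM", "SM", "wI", "SI", "wmax", "Sm")}


def area_width_distribution(
    mask: AdhesiveMask,
    tmap: ThicknessMap,
    bin_width: float = 0.01,
    tooth_axis: int = 0,
    tooth_side: int = -1,
) -> AreaWidthDistribution:
    """Bin tooth-side interface face areas by adjacent layer thickness.

    The tooth side is the ``tooth_side`` (default: low-index) end of
    ``tooth_axis`` (default: the depth axis); a face is a mask voxel whose
    6-neighbour in that direction is outside the mask.
    """
    if bin_width < tmap.voxel_size / 4:
        raise DistributionError(
            f"bin_width {bin_width:g} mm below voxel_size/4 = {tmap.voxel_size / 4:g} mm"
        )
    m = mask.mask
    if m.shape != tmap.values.shape:
        raise DistributionError("mask and thickness map shapes differ")
    faces = _tooth_side_faces(m, tooth_axis, tooth_side)
    widths = tmap.values[faces]
    if np.isnan(widths).any():
        raise DistributionError("thickness map undefined on some interface voxels")
    face_area = mask.voxel_size**2
    n_bins = max(1, int(np.ceil((widths.max() + 1e-12) / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.minimum((widths // bin_width).astype(int), n_bins - 1)
    areas = np.bincount(idx, minlength=n_bins).astype(float) * face_area
    return AreaWidthDistribution(
        edges,
        areas,
        provenance={
            "bin_width": bin_width,
            "face_convention": "tooth-side 6-neighbour voxel faces",
            "tooth_axis": tooth_axis,
            "tooth_side": tooth_side,
            "n_faces": int(faces.sum()),
        },
    )


def _tooth_side_faces(m: np.ndarray, axis: int, side: int) -> np.ndarray:
    shifted = np.zeros_like(m)
    sl_src = [slice(None)] * 3
    sl_dst = [slice(None)] * 3
    if side < 0:  # neighbour at index - 1; boundary voxels count as faces
        sl_src[axis] = slice(None, -1)
        sl_dst[axis] = slice(1, None)
    else:
        sl_src[axis] = slice(1, None)
        sl_dst[axis] = slice(None, -1)
    shifted[tuple(sl_dst)] = m[tuple(sl_src)]
    return m & ~shifted


def thickness_weighted_volume(dist: AreaWidthDistribution) -> float:
    """Physical film volume (mm^3): sum of bin area x bin-centre width.

    This is the layer-cake volume of a film whose area-at-thickness
    histogram is ``dist``; it serves as the physical counterpart of the
    fitted-model volume statistic.
    """
    return float((dist.areas * dist.bin_centers).sum())


def extract_anchors(
    dist: AreaWidthDistribution, smoothing_window: int = 3
) -> AnchorPoints:
    """Read the four anchor points off a (smoothed) distribution.

    All S values are read from the centred moving average of the
    distribution (``smoothing_window=1`` disables smoothing, appropriate
    for exactly synthesized curves). The tail knot wI is the post-peak bin
    centre where the discrete gradient magnitude of the smoothed curve is
    smallest (the hand-over from a descending parabola to a shallow linear
    tail), excluding the terminal bins contaminated by the smoother's edge
    padding.
    """
    occ = dist.occupied()
    if occ.sum() < 6:
        raise DistributionError(
            f"need >= 6 occupied bins to extract anchors, got {int(occ.sum())}"
        )
    smooth = _moving_average(dist.areas, smoothing_window)
    centers = dist.bin_centers

    first = int(np.argmax(occ))
    last = int(occ.size - 1 - np.argmax(occ[::-1]))
    w0 = float(dist.bin_edges[first])
    S0 = float(smooth[first])
    wmax = float(dist.bin_edges[last + 1])
    Sm = float(smooth[last])

    half = smoothing_window // 2
    k_peak = int(np.argmax(smooth))
    wM = float(centers[k_peak])
    SM = float(smooth[k_peak])

    # tail knot: where a descending parabola hands over to the linear tail,
    # i.e. the post-peak minimum of the gradient magnitude. The trailing
    # `half + 1` bins are excluded because the moving average's edge padding
    # artificially flattens them.
    grad = np.gradient(smooth, centers)
    post = np.abs(grad[k_peak:])
    if post.size < 2:
        raise DistributionError("peak at the distribution tail; no post-peak branch")
    stop = max(2, post.size - (half + 1))
    interior = post[1:stop]
    k_tail = k_peak + 1 + int(np.argmin(interior))
    # keep the knot strictly between the peak and the terminal bin
    k_tail = int(np.clip(k_tail, k_peak + 1, max(k_peak + 1, last - 1)))
    wI = float(centers[k_tail])
    SI = float(min(smooth[k_tail], SM))
    return AnchorPoints(w0=w0, S0=S0, wM=wM, SM=SM, wI=wI, SI=SI, wmax=wmax, Sm=Sm)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window < 1 or window % 2 == 0:
        raise DistributionError("smoothing_window must be a positive odd integer")
    if window == 1:
        return x.astype(float)
    pad = window // 2
    padded = np.pad(x.astype(float), pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")
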