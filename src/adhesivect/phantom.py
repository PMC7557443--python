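"""Synthetic three-material interface phantoms with known thickness fields.

A phantom emulates the reconstructed micro-CT volume of a restored cavity
wall: a tooth half-space, an adhesive film of spatially varying thickness,
and a composite filling on top, with additive Gaussian intensity noise.
Because the film thickness field is known exactly (and the adhesive voxel
count gives the exact film volume), every downstream stage — segmentation,
local thickness, the S(w) area-width distribution, the piecewise volume
model — can be validated against ground truth without any scan data.

Geometry is a slab cavity: the tooth occupies the low-depth side, the
adhesive band covers a lateral region of interest (ROI) of the interface
plane, and the interface plane is split into three equal column bands
standing in for the vestibular / oral / pulpal walls.

The thickness field is a smoothed Gaussian random field pushed through a
Beta(2, b) quantile map so that its mode sits at a chosen peak width, then
scaled to the configured [base - amplitude, base + amplitude] range; two
small smooth extremal patches (one thinnest, one thickest spot, placed at
fixed opposite corners of the ROI) guarantee that each realization attains
the range endpoints, the way reported per-group ranges are the observed
min/max of real samples.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import ndtr
from scipy.stats import beta as beta_dist

from .stats import WidthRecord
from .volume import AdhesiveMask, Volume3D

AREAS = ("vestibular", "oral", "pulpal")

#: depth margin (voxels) of tooth material below the interface plane
TOOTH_MARGIN_VOX = 6


class PhantomConfigError(ValueError):
    """A PhantomSpec invariant is violated."""


@dataclass(frozen=True)
class PhantomSpec:
    """Configuration of one synthetic interface volume.

    Parameters
    ----------
    grid_shape:
        voxels, axis order (depth, row, col); every dimension >= 16.
    voxel_size:
        isotropic voxel edge, mm.
    base_thickness:
        mean film thickness per interface area (vestibular, oral, pulpal),
        mm; a scalar applies to all three areas.
    variation_amplitude:
        half-range of the thickness field, mm; the realized field spans
        [base - amplitude, base + amplitude].
    correlation_length:
        lateral smoothness scale of the thickness field, mm.
    peak_thickness:
        location of the mode of the thickness distribution, mm (None =
        symmetric field, mode at the base thickness).
    lateral_fraction:
        fraction (0, 1] of the interface plane covered by the adhesive ROI
        (centred square); outside it the composite rests on the tooth.
    intensity_levels:
        grayscale means of (tooth, adhesive, composite).
    noise_sigma:
        grayscale noise SD; levels must be pairwise > 4 sigma apart.
    seed:
        RNG seed; identical specs produce bit-identical phantoms.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size: float = 0.005
    base_thickness: float | tuple[float, float, float] = 0.1
    variation_amplitude: float = 0.0
    correlation_length: float = 0.05
    peak_thickness: float | None = None
    lateral_fraction: float = 1.0
    intensity_levels: tuple[float, float, float] = (90.0, 140.0, 200.0)
    noise_sigma: float = 8.0
    seed: int = 0

    def base_triple(self) -> tuple[float, float, float]:
        b = self.base_thickness
        return tuple(b) if isinstance(b, (tuple, list)) else (b, b, b)

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) < 16 for s in self.grid_shape):
            raise PhantomConfigError(
                f"all grid dimensions must be >= 16, got {self.grid_shape}"
            )
        if not self.voxel_size > 0:
            raise PhantomConfigError(f"voxel_size must be > 0, got {self.voxel_size}")
        if self.variation_amplitude < 0:
            raise PhantomConfigError("variation_amplitude must be >= 0")
        for b in self.base_triple():
            if b - self.variation_amplitude < 2 * self.voxel_size:
                raise PhantomConfigError(
                    "layer not resolvable: base_thickness - variation_amplitude = "
                    f"{b - self.variation_amplitude:g} mm < 2 x voxel_size = "
                    f"{2 * self.voxel_size:g} mm"
                )
        depth_mm = self.grid_shape[0] * self.voxel_size
        max_t = max(self.base_triple()) + self.variation_amplitude
        if TOOTH_MARGIN_VOX * self.voxel_size + max_t >= depth_mm:
            raise PhantomConfigError(
                f"grid too shallow: need > {max_t:g} mm of film plus margins in "
                f"{depth_mm:g} mm of depth"
            )
        if not 0 < self.lateral_fraction <= 1:
            raise PhantomConfigError("lateral_fraction must be in (0, 1]")
        if self.correlation_length <= 0:
            raise PhantomConfigError("correlation_length must be > 0")
        levels = sorted(self.intensity_levels)
        if self.noise_sigma > 0:
            gap = min(levels[1] - levels[0], levels[2] - levels[1])
            if gap <= 4 * self.noise_sigma:
                raise PhantomConfigError(
                    f"intensity levels separated by {gap:g} <= 4 x noise_sigma "
                    f"= {4 * self.noise_sigma:g}; phantom not segmentable"
                )
        if self.peak_thickness is not None:
            lo = min(self.base_triple()) - self.variation_amplitude
            hi = max(self.base_triple()) + self.variation_amplitude
            if not lo < self.peak_thickness < hi:
                raise PhantomConfigError(
                    f"peak_thickness {self.peak_thickness:g} outside the realized "
                    f"range ({lo:g}, {hi:g})"
                )


@dataclass
class PhantomTruth:
    """Ground truth attached to a generated phantom."""

    mask: AdhesiveMask
    thickness_truth: np.ndarray  # (row, col) realized film height, mm; NaN off-ROI
    area_labels: np.ndarray  # (row, col) int: 0/1/2 = AREAS index, -1 off-ROI
    true_volume: float  # mm^3, exactly mask count x voxel_size^3

    def area_thickness(self, area: str) -> np.ndarray:
        idx = AREAS.index(area)
        vals = self.thickness_truth[self.area_labels == idx]
        return vals[~np.isnan(vals)]


def generate_phantom(spec: PhantomSpec) -> tuple[Volume3D, PhantomTruth]:
    """Generate one voxel volume plus its ground truth.

    Deterministic in the spec (including the seed): identical specs give
    byte-identical volumes and truths.
    """
    spec.validate()
    nd, nr, nc = (int(s) for s in spec.grid_shape)
    vs = spec.voxel_size
    rng = np.random.default_rng(spec.seed)

    roi, labels = _roi_and_labels(nr, nc, spec.lateral_fraction)
    tfield = _thickness_field(spec, rng, roi)  # (nr, nc), NaN off-ROI

    # film occupancy: voxel i is adhesive iff z0 <= (i + 0.5) vs < z0 + t
    z0 = TOOTH_MARGIN_VOX * vs
    centers = (np.arange(nd) + 0.5) * vs
    t_col = np.where(np.isnan(tfield), 0.0, tfield)
    film = (centers[:, None, None] >= z0) & (centers[:, None, None] < z0 + t_col)

    # realized film height per column (what the voxel grid actually holds)
    heights = film.sum(axis=0) * vs
    thickness_truth = np.where(roi, heights, np.nan)

    tooth_lvl, adh_lvl, comp_lvl = spec.intensity_levels
    tooth = centers[:, None, None] < z0
    vol = np.where(film, adh_lvl, np.where(tooth, tooth_lvl, comp_lvl))
    if spec.noise_sigma > 0:
        vol = vol + rng.normal(0.0, spec.noise_sigma, size=vol.shape)
    volume = Volume3D(vol.astype(np.float32), vs)

    mask = AdhesiveMask(film, vs)
    truth = PhantomTruth(
        mask=mask,
        thickness_truth=thickness_truth,
        area_labels=labels,
        true_volume=mask.volume_mm3,
    )
    return volume, truth


def _roi_and_labels(nr: int, nc: int, fraction: float):
    """Centred square ROI covering ``fraction`` of the plane; column thirds
    of the ROI stand in for the vestibular/oral/pulpal walls."""
    side = np.sqrt(fraction)
    hr = max(8, int(round(nr * side / 2)))
    hc = max(8, int(round(nc * side / 2)))
    r0, r1 = max(0, nr // 2 - hr), min(nr, nr // 2 + hr)
    c0, c1 = max(0, nc // 2 - hc), min(nc, nc // 2 + hc)
    roi = np.zeros((nr, nc), dtype=bool)
    roi[r0:r1, c0:c1] = True
    labels = np.full((nr, nc), -1, dtype=np.int8)
    width = c1 - c0
    for k in range(3):
        a = c0 + (k * width) // 3
        b = c0 + ((k + 1) * width) // 3
        labels[r0:r1, a:b] = k
    return roi, labels


def _thickness_field(spec: PhantomSpec, rng: np.random.Generator, roi: np.ndarray):
    nr, nc = roi.shape
    bases = spec.base_triple()
    amp = spec.variation_amplitude
    if amp == 0.0:
        # constant per area; use the column-third area layout
        _, labels = _roi_and_labels(nr, nc, spec.lateral_fraction)
        t = np.full((nr, nc), np.nan)
        for k in range(3):
            t[(labels == k) & roi] = bases[k]
        t[roi & np.isnan(t)] = bases[0]
        return t

    lo = np.asarray(bases) - amp
    hi = np.asarray(bases) + amp
    sigma_vox = spec.correlation_length / spec.voxel_size
    g = gaussian_filter(rng.standard_normal((nr, nc)), sigma_vox, mode="wrap")
    g = (g - g.mean()) / g.std()
    u = np.clip(ndtr(g), 1e-9, 1 - 1e-9)

    # Beta(2, b) quantile map puts the marginal mode at the peak width
    lo_s, hi_s = float(lo.min()), float(hi.max())
    if spec.peak_thickness is None:
        mode_rel = 0.5
    else:
        mode_rel = (spec.peak_thickness - lo_s) / (hi_s - lo_s)
    mode_rel = float(np.clip(mode_rel, 0.02, 0.98))
    b_par = 1.0 / mode_rel  # mode of Beta(2, b) is 1 / b
    y = beta_dist.ppf(u, 2.0, b_par)

    t = lo_s + y * (hi_s - lo_s)
    t = _imprint_extremes(t, roi, lo_s, hi_s, sigma_vox, spec.voxel_size)
    return np.where(roi, t, np.nan)


def _imprint_extremes(t, roi, lo, hi, sigma_vox, voxel_size):
    """Blend in one thinnest and one thickest spot at fixed ROI corners.

    The thick spot carries a half-voxel allowance so the discretized film
    height still reaches the configured maximum after voxel flooring."""
    rows, cols = np.where(roi)
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    off = max(2.0, 1.5 * sigma_vox)
    thin_center = (r0 + off, c0 + off)
    thick_center = (r1 - off, c1 - off)
    rr, cc = np.indices(t.shape, dtype=float)
    s = max(1.0, sigma_vox / 2.0)

    def bump(center):
        d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
        w = np.exp(-d2 / (2 * s**2))
        w[w < 1e-6] = 0.0
        return w

    hi_eff = hi + 0.5 * voxel_size
    w_thin, w_thick = bump(thin_center), bump(thick_center)
    t = t + w_thin * (lo - t) + w_thick * (hi_eff - t)
    # force exact endpoints at the bump centres (continuous peak == 1 there)
    t[int(round(thin_center[0])), int(round(thin_center[1]))] = lo
    t[int(round(thick_center[0])), int(round(thick_center[1]))] = hi_eff
    return t


# ---------------------------------------------------------------------------
# group presets
# ---------------------------------------------------------------------------

#: per-group study conditions: realized width range (mm) from the reported
#: micro-CT analysis; voxel size chosen so the thinnest film is >= ~3 voxels;
#: lateral grid extent scaled so total interface areas follow the reported
#: volume ratios. `peak` is the internal thickness-field mode, calibrated so
#: the *measured* S(w) argmax lands at the reported predominant width (the
#: inscribed-sphere reading of a rough film is shifted relative to the film
#: height marginal, see docs/methods.md).
_PRESETS = {
    1: dict(grid_shape=(128, 128, 128), voxel_size=0.005, lo=0.020, hi=0.40,
            peak=0.10, correlation_length=0.10),
    2: dict(grid_shape=(128, 104, 104), voxel_size=0.005, lo=0.017, hi=0.40,
            peak=0.06, correlation_length=0.10),
    3: dict(grid_shape=(128, 104, 104), voxel_size=0.004, lo=0.013, hi=0.31,
            peak=0.020, correlation_length=0.06),
    4: dict(grid_shape=(64, 128, 128), voxel_size=0.001, lo=0.011, hi=0.032,
            peak=0.018, correlation_length=0.020),
}


def group_preset(group_id: int, seed: int = 0) -> PhantomSpec:
    """PhantomSpec emulating the width statistics of one treatment group.

    Group 1: plain adhesive; Group 2: adhesive doped with magnetic
    nanoparticles; Groups 3 and 4: doped adhesive exposed to a magnetic
    field for 5 and 10 minutes. Realized width ranges, peak widths and
    relative interface areas follow the per-group micro-CT statistics.
    """
    if group_id not in _PRESETS:
        raise ValueError(f"unknown group id {group_id}; expected 1, 2, 3 or 4")
    p = _PRESETS[group_id]
    return PhantomSpec(
        grid_shape=p["grid_shape"],
        voxel_size=p["voxel_size"],
        base_thickness=(p["lo"] + p["hi"]) / 2.0,
        variation_amplitude=(p["hi"] - p["lo"]) / 2.0,
        correlation_length=p["correlation_length"],
        peak_thickness=p["peak"],
        seed=seed,
    )


def preset_bin_width(spec: PhantomSpec) -> float:
    """Histogram bin width (mm) matched to the spec's realized width span.

    0.01 mm (the resolution of the reported S(w) curves) unless the whole
    span is narrower than 0.05 mm, in which case 0.002 mm keeps >= 6
    occupied bins.
    """
    span = 2 * spec.variation_amplitude
    return 0.01 if span >= 0.05 else 0.002


# ---------------------------------------------------------------------------
# packaged width table
# ---------------------------------------------------------------------------

class FixtureIntegrityError(RuntimeError):
    pass


def load_table1_fixture() -> list[WidthRecord]:
    """The packaged per-sample width table (4 groups x 5 samples x 3 areas x
    2 methods), converted from the printed micrometres to mm."""
    ref = importlib.resources.files("adhesivect").joinpath("data/table1_widths.csv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    records = [
        WidthRecord(
            group=int(r.group),
            sample=int(r.sample),
            area=str(r.area),
            method=str(r.method),
            width=float(r.width_um) / 1000.0,
        )
        for r in df.itertuples()
    ]
    expected = 4 * 5 * 3 * 2
    if len(records) != expected:
        raise FixtureIntegrityError(
            f"width table corrupted: expected {expected} records, found {len(records)}"
        )
    keys = {(r.group, r.sample, r.area, r.method) for r in records}
    if len(keys) != expected:
        raise FixtureIntegrityError("width table corrupted: duplicate group/sample/area/method keys")
    return records
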