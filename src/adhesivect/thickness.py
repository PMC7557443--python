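"""Local width/thickness of the segmented adhesive layer.

The thickness definition is the standard micro-CT wall-thickness one
(largest inscribed sphere): the thickness at a voxel is the diameter of
the largest sphere that lies fully inside the structure and covers that
voxel. On the voxel grid this package uses the convention

    thickness(v) = 2 * voxel_size * max{ d(c) : c in mask, |v - c| <= d(c) }

where d(c) is the Euclidean distance (in voxels) from the centre of c to
the nearest background voxel centre, and voxels outside the grid count as
foreground (spheres may extend past the grid, so a slab spanning the full
lateral extent behaves as an infinite slab). Under this convention a slab
of k voxels reads exactly k * voxel_size for even k, and all shapes are
accurate to one voxel.

``local_thickness`` computes the field via an exact Euclidean distance
transform, distance-ridge extraction and sphere marking in decreasing
radius order; ``brute_force_thickness`` evaluates the definition by
exhaustive search and serves as the independent oracle on small masks.

``virtual_section_widths`` emulates the sectioned-sample microscopy
measurement: within one section plane it traces the layer centreline per
interface area and measures the chord through the mask along the local
in-plane normal at equally spaced centreline points.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import ndimage

from .volume import AdhesiveMask, ThicknessMap

BRUTE_FORCE_GUARD = 64**3


def local_thickness(mask: AdhesiveMask) -> ThicknessMap:
    """Largest-inscribed-sphere thickness field (mm) over the mask."""
    m = mask.mask
    if not m.any():
        raise ValueError("empty mask")
    if m.all():
        raise ValueError("mask has no background; thickness is unbounded")
    # squared EDT is an exact integer (sum of three squared offsets); all
    # coverage and domination tests below stay in integer arithmetic so the
    # field matches the brute-force definition bit for bit
    edt2 = np.rint(ndimage.distance_transform_edt(m) ** 2).astype(np.int64)
    ridge = _distance_ridge(m, edt2)
    out2 = np.zeros(m.shape, dtype=np.int64)
    pts = np.argwhere(ridge)
    radii2 = edt2[ridge]
    order = np.argsort(radii2, kind="stable")[::-1]  # decreasing radius
    _paint_spheres(out2, m, pts[order].astype(np.int64), radii2[order])
    values = np.where(m, 2.0 * np.sqrt(out2) * mask.voxel_size, np.nan)
    return ThicknessMap(values, mask.voxel_size)


def _distance_ridge(mask: np.ndarray, edt2: np.ndarray) -> np.ndarray:
    """Drop centres whose sphere lies inside a neighbour's sphere.

    c is redundant when a 26-neighbour c' satisfies d(c') >= d(c) + |c - c'|;
    painting from the surviving (ridge) centres yields the same field as
    painting from every foreground voxel. With squared integer distances the
    test is d2' >= d2 + k + 2 sqrt(d2 k), i.e. t = d2' - d2 - k >= 0 and
    t^2 >= 4 d2 k, evaluated exactly.
    """
    keep = mask.copy()
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    padded = np.pad(edt2, 1)
    core = edt2
    for dz, dy, dx in offsets:
        k = dz * dz + dy * dy + dx * dx
        shifted = padded[
            1 + dz : 1 + dz + core.shape[0],
            1 + dy : 1 + dy + core.shape[1],
            1 + dx : 1 + dx + core.shape[2],
        ]
        t = shifted - core - k
        dominated = (t >= 0) & (t * t >= 4 * core * k)
        keep &= ~dominated
    keep &= mask
    return keep


@njit(cache=True)
def _paint_spheres(out2, mask, points, radii2):  # pragma: no cover - jitted
    nd, nr, nc = out2.shape
    for idx in range(points.shape[0]):
        z0, y0, x0 = points[idx, 0], points[idx, 1], points[idx, 2]
        r2 = radii2[idx]
        ri = int(np.floor(np.sqrt(r2)))
        for z in range(max(0, z0 - ri), min(nd, z0 + ri + 1)):
            dz2 = (z - z0) * (z - z0)
            for y in range(max(0, y0 - ri), min(nr, y0 + ri + 1)):
                dy2 = (y - y0) * (y - y0)
                if dz2 + dy2 > r2:
                    continue
                for x in range(max(0, x0 - ri), min(nc, x0 + ri + 1)):
                    if dz2 + dy2 + (x - x0) * (x - x0) <= r2:
                        if mask[z, y, x] and out2[z, y, x] < r2:
                            out2[z, y, x] = r2
    return out2


def brute_force_thickness(mask: AdhesiveMask) -> ThicknessMap:
    """Definitionally exact thickness by exhaustive search (test oracle).

    For every foreground voxel the largest covering inscribed sphere is
    found by scanning all candidate centres; guarded to masks of at most
    64^3 voxels.
    """
    m = mask.mask
    if m.size > BRUTE_FORCE_GUARD:
        raise ValueError(f"mask exceeds brute-force guard of {BRUTE_FORCE_GUARD} voxels")
    if not m.any():
        raise ValueError("empty mask")
    if m.all():
        raise ValueError("mask has no background; thickness is unbounded")
    fg = np.argwhere(m).astype(np.int64)
    bg = np.argwhere(~m).astype(np.int64)
    values2 = _brute_force_kernel(fg, bg)
    out = np.full(m.shape, np.nan)
    out[m] = 2.0 * np.sqrt(values2) * mask.voxel_size
    return ThicknessMap(out, mask.voxel_size)


@njit(cache=True)
def _brute_force_kernel(fg, bg):  # pragma: no cover - jitted
    n = fg.shape[0]
    nb = bg.shape[0]
    # squared distance from each candidate centre to the nearest background
    d2 = np.empty(n, dtype=np.int64)
    for i in range(n):
        best = np.int64(1 << 60)
        for j in range(nb):
            dz = fg[i, 0] - bg[j, 0]
            dy = fg[i, 1] - bg[j, 1]
            dx = fg[i, 2] - bg[j, 2]
            dist2 = dz * dz + dy * dy + dx * dx
            if dist2 < best:
                best = dist2
        d2[i] = best
    out2 = np.zeros(n, dtype=np.int64)
    for i in range(n):
        best = np.int64(0)
        for j in range(n):
            dz = fg[i, 0] - fg[j, 0]
            dy = fg[i, 1] - fg[j, 1]
            dx = fg[i, 2] - fg[j, 2]
            dist2 = dz * dz + dy * dy + dx * dx
            if dist2 <= d2[j] and d2[j] > best:
                best = d2[j]
        out2[i] = best
    return out2


# ---------------------------------------------------------------------------
# virtual sectioning (microscopy emulation)
# ---------------------------------------------------------------------------

class SectionError(ValueError):
    pass


def virtual_section_widths(
    mask: AdhesiveMask,
    plane_axis: int = 1,
    plane_index: int | None = None,
    n_points: int = 10,
    area_labels: np.ndarray | None = None,
) -> dict[str, list[float]]:
    """Chord widths (mm) at equally spaced centreline points of one section.

    The section plane is perpendicular to ``plane_axis`` (default: a row
    plane, so the section shows depth x col and the layer appears as a
    band). Per interface area the band's centreline is traced column by
    column and the width is measured as the chord through the mask along
    the local in-plane normal at ``n_points`` equally spaced centreline
    points. ``area_labels`` assigns interface areas to the in-plane lateral
    coordinate (anything from :class:`~adhesivect.phantom.PhantomTruth`);
    without labels the occupied lateral extent is split into three equal
    bands.
    """
    if n_points < 1:
        raise SectionError("n_points must be >= 1")
    if plane_axis not in (1, 2):
        raise SectionError("plane_axis must be 1 (row plane) or 2 (col plane)")
    m = mask.mask
    if plane_index is None:
        plane_index = m.shape[plane_axis] // 2
    section = np.take(m, plane_index, axis=plane_axis)  # (depth, lateral)
    if not section.any():
        raise SectionError(f"section plane axis={plane_axis} index={plane_index} misses the mask")

    lateral_cols = np.where(section.any(axis=0))[0]
    if area_labels is not None:
        lane = np.take(area_labels, plane_index, axis=plane_axis - 1)
        area_cols = {name: np.where(lane == k)[0] for k, name in enumerate(_AREAS)}
    else:
        thirds = np.array_split(lateral_cols, 3)
        area_cols = dict(zip(_AREAS, thirds))

    out: dict[str, list[float]] = {}
    for area, cols in area_cols.items():
        cols = np.asarray([c for c in cols if section[:, c].any()])
        if cols.size == 0:
            raise SectionError(f"interface area {area!r} absent from the section")
        centers = np.array([_column_center(section[:, c]) for c in cols])
        picks = np.linspace(0, cols.size - 1, n_points).round().astype(int)
        widths = []
        for p in picks:
            normal = _inplane_normal(cols, centers, p)
            w = _chord_length(section, (centers[p], float(cols[p])), normal)
            widths.append(w * mask.voxel_size)
        out[area] = widths
    return out


_AREAS = ("vestibular", "oral", "pulpal")


def _column_center(column: np.ndarray) -> float:
    idx = np.where(column)[0]
    return float(idx.mean())


def _inplane_normal(cols, centers, p) -> tuple[float, float]:
    """Unit normal to the centreline at point p, in (depth, lateral) coords."""
    lo, hi = max(0, p - 1), min(cols.size - 1, p + 1)
    dz = centers[hi] - centers[lo]
    dx = float(cols[hi] - cols[lo])
    norm = np.hypot(dz, dx)
    if norm == 0:
        return (1.0, 0.0)
    # tangent (dz, dx) -> normal (-dx, dz) oriented toward +depth
    nz, nx = dx / norm, -dz / norm
    if nz < 0:
        nz, nx = -nz, -nx
    return (nz, nx)


def _chord_length(section: np.ndarray, start: tuple[float, float], normal) -> float:
    """March from a centreline point to the mask boundary in both directions."""
    step = 0.25
    total = 0.0
    for sign in (1.0, -1.0):
        s = 0.0
        while True:
            s += step
            z = start[0] + sign * normal[0] * s
            x = start[1] + sign * normal[1] * s
            zi, xi = int(round(z)), int(round(x))
            if not (0 <= zi < section.shape[0] and 0 <= xi < section.shape[1]):
                break
            if not section[zi, xi]:
                break
        total += s - step / 2.0
    return total
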