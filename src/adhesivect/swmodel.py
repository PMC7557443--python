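"""Piecewise linear/parabolic models of S(w) and the volume statistic V.

Each group's area-width curve is approximated by the simplest shapes on
portions: three polynomial pieces joined with C0 continuity. Two template
shapes cover the four treatment groups:

* template A (broad, late-peak curves): quadratic rise f on
  [w0, (w0+wM)/2), quadratic rise g on [(w0+wM)/2, wM), quadratic tail h
  on [wM, wmax];
* template B (early sharp peak): parabola f = a w^2 on [0, wM),
  quadratic descent g on [wM, wI), linear tail h on [wI, wmax].

The summary statistic is the closed-form integral

    V = integral of S(w) dw over [first knot, wmax]   [mm^3]

used to rank the adhesives: smaller V means a thinner, tighter film.
Models are constructed from anchor points or fitted to binned data by
equality-constrained linear least squares; pieces are never transcribed
from published coefficient tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

from .distribution import AnchorPoints, AreaWidthDistribution


class ModelError(ValueError):
    pass


#: coefficient order in every piece: constant, linear, quadratic
Piece = np.ndarray

C0_TOL = 1e-9


@dataclass
class PiecewiseSW:
    """A fitted/constructed piecewise S(w) model.

    ``knots`` are the 4 interval boundaries (mm); ``pieces[i]`` holds the
    polynomial coefficients (constant -> quadratic) active on
    [knots[i], knots[i+1]), the last interval closed at wmax.
    """

    template: str  # "A" or "B"
    knots: np.ndarray  # (4,), increasing
    pieces: list  # 3 coefficient arrays
    residual: float = 0.0
    fallback_intervals: list = field(default_factory=list)

    def __post_init__(self):
        self.knots = np.asarray(self.knots, dtype=float)
        self.pieces = [np.asarray(p, dtype=float) for p in self.pieces]
        if self.template not in ("A", "B"):
            raise ModelError(f"unknown template {self.template!r}")
        if self.knots.size != 4 or not np.all(np.diff(self.knots) > 0):
            raise ModelError(f"knots must be 4 increasing widths, got {self.knots}")
        if len(self.pieces) != 3:
            raise ModelError("expected 3 polynomial pieces")
        for k in (1, 2):  # C0 continuity at interior knots
            left = _polyval(self.pieces[k - 1], self.knots[k])
            right = _polyval(self.pieces[k], self.knots[k])
            if abs(left - right) > C0_TOL:
                raise ModelError(
                    f"pieces discontinuous at knot {self.knots[k]:g}: "
                    f"{left:.3e} vs {right:.3e}"
                )

    # -- evaluation ---------------------------------------------------------

    @property
    def wmax(self) -> float:
        return float(self.knots[-1])

    def _piece_index(self, w: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.knots, w, side="right") - 1
        return np.clip(idx, 0, 2)

    def __call__(self, w):
        return self.evaluate(w)

    def evaluate(self, w):
        """S(w) in mm^2; half-open pieces, left-continuous at wmax."""
        w_arr = np.asarray(w, dtype=float)
        if np.any(w_arr < self.knots[0] - 1e-12) or np.any(w_arr > self.wmax + 1e-12):
            raise ModelError(
                f"width outside model domain [{self.knots[0]:g}, {self.wmax:g}] mm"
            )
        idx = self._piece_index(w_arr)
        out = np.empty_like(w_arr, dtype=float)
        for k in range(3):
            sel = idx == k
            if np.any(sel):
                out[sel] = _polyval(self.pieces[k], w_arr[sel])
        return out if out.ndim else float(out)

    def gradient(self, w):
        """dS/dw in mm^2/mm, piecewise, same interval convention."""
        w_arr = np.asarray(w, dtype=float)
        if np.any(w_arr < self.knots[0] - 1e-12) or np.any(w_arr > self.wmax + 1e-12):
            raise ModelError(
                f"width outside model domain [{self.knots[0]:g}, {self.wmax:g}] mm"
            )
        idx = self._piece_index(w_arr)
        out = np.empty_like(w_arr, dtype=float)
        for k in range(3):
            sel = idx == k
            if np.any(sel):
                out[sel] = _polyval(_polyder(self.pieces[k]), w_arr[sel])
        return out if out.ndim else float(out)

    def min_value(self, samples_per_piece: int = 200) -> float:
        """Smallest S over the domain (dense sampling); model sanity check."""
        lows = []
        for k in range(3):
            grid = np.linspace(self.knots[k], self.knots[k + 1], samples_per_piece)
            lows.append(_polyval(self.pieces[k], grid).min())
        return float(min(lows))

    def to_dict(self) -> dict:
        return {
            "template": self.template,
            "knots": self.knots.tolist(),
            "pieces": [p.tolist() for p in self.pieces],
            "residual": self.residual,
            "fallback_intervals": list(self.fallback_intervals),
        }


@dataclass(frozen=True)
class VolumeStatistic:
    """Closed-form V = integral of S(w) dw with its provenance."""

    V: float  # mm^3
    group: str
    template: str
    knots: tuple

    def __post_init__(self):
        if self.V < 0:
            raise ModelError(f"volume statistic must be >= 0, got {self.V}")


def _polyval(coeffs: np.ndarray, w):
    # coefficients stored constant -> quadratic
    return np.polynomial.polynomial.polyval(w, coeffs)


def _polyder(coeffs: np.ndarray) -> np.ndarray:
    return np.polynomial.polynomial.polyder(coeffs)


def _polyint(coeffs: np.ndarray) -> np.ndarray:
    return np.polynomial.polynomial.polyint(coeffs)


# ---------------------------------------------------------------------------
# construction from anchors
# ---------------------------------------------------------------------------

def template_knots(anchors: AnchorPoints, template: str) -> np.ndarray:
    if template == "A":
        return np.array(
            [anchors.w0, 0.5 * (anchors.w0 + anchors.wM), anchors.wM, anchors.wmax]
        )
    if template == "B":
        return np.array([0.0, anchors.wM, anchors.wI, anchors.wmax])
    raise ModelError(f"unknown template {template!r}")


def select_template(anchors: AnchorPoints, peak_split: float = 0.05) -> str:
    """A for broad/late-peak curves (wM >= 0.05 mm), B for early sharp peaks."""
    return "A" if anchors.wM >= peak_split else "B"


def build_model_from_anchors(anchors: AnchorPoints, template: str) -> PiecewiseSW:
    """Interpolating piecewise model through the anchor points.

    Template A: an S-shaped rise made of two parabolas (vertex at w0 and at
    wM respectively, meeting at the midpoint at height (S0+SM)/2) followed
    by the quadratic through (wM,SM), (wI,SI), (wmax,Sm). Template B:
    f = (SM/wM^2) w^2 through the origin and the peak, a descending
    parabola with vertex at wI through (wM,SM) and (wI,SI), and the line
    through (wI,SI), (wmax,Sm). C0 continuity holds by construction.
    """
    knots = template_knots(anchors, template)
    if np.any(np.diff(knots) <= 0):
        raise ModelError(f"degenerate anchors: non-increasing knots {knots}")
    a = anchors
    if template == "A":
        mid_w = knots[1]
        mid_s = 0.5 * (a.S0 + a.SM)
        f = _parabola_with_vertex(vertex=(a.w0, a.S0), through=(mid_w, mid_s))
        g = _parabola_with_vertex(vertex=(a.wM, a.SM), through=(mid_w, mid_s))
        h = _quadratic_through((a.wM, a.SM), (a.wI, a.SI), (a.wmax, a.Sm))
        if _piece_min(h, a.wM, a.wmax) < 0:
            # an interpolating quadratic through a high peak and two near-zero
            # tail anchors has roots inside the interval; fall back to the
            # monotone parabola with vertex at the terminal point
            h = _parabola_with_vertex(vertex=(a.wmax, a.Sm), through=(a.wM, a.SM))
    else:
        f = np.array([0.0, 0.0, a.SM / a.wM**2])
        g = _parabola_with_vertex(vertex=(a.wI, a.SI), through=(a.wM, a.SM))
        h = _line_through((a.wI, a.SI), (a.wmax, a.Sm))
    model = PiecewiseSW(template=template, knots=knots, pieces=[f, g, h])
    if model.min_value() < -C0_TOL:
        raise ModelError("anchor-built model dips below zero on its domain")
    return model


def _piece_min(coeffs: np.ndarray, lo: float, hi: float) -> float:
    grid = np.linspace(lo, hi, 201)
    return float(_polyval(coeffs, grid).min())


def _parabola_with_vertex(vertex, through) -> np.ndarray:
    (wv, sv), (wt, st) = vertex, through
    if wv == wt:
        raise ModelError("degenerate anchors: coincident widths")
    aa = (st - sv) / (wt - wv) ** 2
    # a (w - wv)^2 + sv  ->  constant, linear, quadratic
    return np.array([aa * wv**2 + sv, -2.0 * aa * wv, aa])


def _quadratic_through(p1, p2, p3) -> np.ndarray:
    ws = np.array([p1[0], p2[0], p3[0]])
    ss = np.array([p1[1], p2[1], p3[1]])
    if len(np.unique(ws)) < 3:
        raise ModelError("degenerate anchors: coincident widths")
    return np.polynomial.polynomial.polyfit(ws, ss, 2)


def _line_through(p1, p2) -> np.ndarray:
    (w1, s1), (w2, s2) = p1, p2
    if w1 == w2:
        raise ModelError("degenerate anchors: coincident widths")
    slope = (s2 - s1) / (w2 - w1)
    return np.array([s1 - slope * w1, slope, 0.0])


# ---------------------------------------------------------------------------
# constrained least-squares fit
# ---------------------------------------------------------------------------

#: per-template design: number of free coefficients per piece and the basis
#: exponents (template B's f piece is the pure parabola a w^2)
_TEMPLATE_BASIS = {
    "A": [(0, 1, 2), (0, 1, 2), (0, 1, 2)],
    "B": [(2,), (0, 1, 2), (0, 1)],
}


def fit_model(
    dist: AreaWidthDistribution,
    template: str,
    anchors: AnchorPoints,
) -> PiecewiseSW:
    """Equality-constrained linear least squares fit of the template.

    Bin centres/areas are assigned to the template's intervals (knots come
    from the anchors); the total squared residual is minimized subject to
    C0 continuity at the interior knots. An interval with fewer occupied
    bins than free coefficients falls back to the anchor-built piece, which
    is recorded in ``fallback_intervals``.
    """
    if template not in _TEMPLATE_BASIS:
        raise ModelError(f"unknown template {template!r}")
    knots = template_knots(anchors, template)
    if np.any(np.diff(knots) <= 0):
        raise ModelError(f"degenerate anchors: non-increasing knots {knots}")
    basis = _TEMPLATE_BASIS[template]
    centers = dist.bin_centers
    areas = dist.areas
    occ = dist.occupied()
    in_domain = (centers >= knots[0]) & (centers <= knots[-1]) & occ
    w = centers[in_domain]
    s = areas[in_domain]
    piece_of = np.clip(np.searchsorted(knots, w, side="right") - 1, 0, 2)

    fallback = [k for k in range(3) if (piece_of == k).sum() < len(basis[k])]
    anchor_model = build_model_from_anchors(anchors, template) if fallback else None

    offsets = np.cumsum([0] + [len(b) for b in basis])
    n_par = offsets[-1]

    design = np.zeros((w.size, n_par))
    for k in range(3):
        sel = piece_of == k
        for j, exp in enumerate(basis[k]):
            design[sel, offsets[k] + j] = w[sel] ** exp

    cons_rows, cons_vals = [], []
    for k in (1, 2):  # C0 at interior knots
        row = np.zeros(n_par)
        for j, exp in enumerate(basis[k - 1]):
            row[offsets[k - 1] + j] = knots[k] ** exp
        for j, exp in enumerate(basis[k]):
            row[offsets[k] + j] -= knots[k] ** exp
        cons_rows.append(row)
        cons_vals.append(0.0)
    for k in fallback:  # pin underdetermined pieces to the anchor-built ones
        full = anchor_model.pieces[k]
        for j, exp in enumerate(basis[k]):
            row = np.zeros(n_par)
            row[offsets[k] + j] = 1.0
            cons_rows.append(row)
            cons_vals.append(full[exp])
    C = np.vstack(cons_rows)
    d = np.asarray(cons_vals)

    # solve min ||A x - s|| subject to C x = d via null-space substitution
    x_part, *_ = np.linalg.lstsq(C, d, rcond=None)
    N = null_space(C)
    if N.size:
        z, *_ = np.linalg.lstsq(design @ N, s - design @ x_part, rcond=None)
        x = x_part + N @ z
    else:
        x = x_part

    pieces = []
    for k in range(3):
        full = np.zeros(3)
        for j, exp in enumerate(basis[k]):
            full[exp] = x[offsets[k] + j]
        pieces.append(full)
    residual = float(np.sum((design @ x - s) ** 2))
    return PiecewiseSW(
        template=template,
        knots=knots,
        pieces=pieces,
        residual=residual,
        fallback_intervals=fallback,
    )


# ---------------------------------------------------------------------------
# integration and group comparison
# ---------------------------------------------------------------------------

def integrate_model(model: PiecewiseSW, group: str = "") -> VolumeStatistic:
    """Exact piecewise antiderivative of S over [first knot, wmax] (mm^3)."""
    total = 0.0
    for k in range(3):
        anti = _polyint(model.pieces[k])
        total += _polyval(anti, model.knots[k + 1]) - _polyval(anti, model.knots[k])
    return VolumeStatistic(
        V=max(float(total), 0.0),
        group=group,
        template=model.template,
        knots=tuple(model.knots.tolist()),
    )


def compare_group_volumes(models: dict) -> dict:
    """Volumes of per-group models, sorted, with a 1->N monotonicity flag."""
    if len(models) < 2:
        raise ModelError("need at least two group models to compare")
    stats = {g: integrate_model(m, group=str(g)) for g, m in models.items()}
    by_group = sorted(stats.items(), key=lambda kv: kv[0])
    vols = [kv[1].V for kv in by_group]
    strictly_decreasing = all(a > b for a, b in zip(vols, vols[1:]))
    ranked = sorted(stats.items(), key=lambda kv: -kv[1].V)
    return {
        "volumes": {str(g): v.V for g, v in by_group},
        "ranked": [(str(g), v.V) for g, v in ranked],
        "strictly_decreasing": bool(strictly_decreasing),
        "ties": len({round(v.V, 15) for _, v in stats.items()}) < len(stats),
    }
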