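import numpy as np
import pytest
from scipy.integrate import quad

from adhesivect.distribution import AnchorPoints
from adhesivect.swmodel import (
    ModelError,
    PiecewiseSW,
    build_model_from_anchors,
    compare_group_volumes,
    fit_model,
    integrate_model,
    select_template,
)

from conftest import (
    GROUP1_ANCHORS,
    GROUP4_ANCHORS,
    distribution_from_model,
    random_anchor_model,
)


def quadrature_volume(model):
    return sum(
        quad(lambda w: float(model.evaluate(w)), model.knots[k], model.knots[k + 1],
             limit=200)[0]
        for k in range(3)
    )


class TestBuildFromAnchors:
    def test_sharp_peak_parabola_coefficient(self):
        model = build_model_from_anchors(GROUP4_ANCHORS, "B")
        # SM / wM^2 = 0.015 / 0.015^2
        assert model.pieces[0][2] == pytest.approx(66.67, abs=0.01)

    def test_zero_terminal_is_interpolated_exactly(self):
        model = build_model_from_anchors(GROUP4_ANCHORS, "B")
        assert model.evaluate(model.wmax) == pytest.approx(0.0, abs=1e-15)

    def test_template_a_round_trip_at_bin_centers(self):
        model = build_model_from_anchors(GROUP1_ANCHORS, "A")
        dist = distribution_from_model(model, bin_width=0.01)
        rebuilt = build_model_from_anchors(GROUP1_ANCHORS, "A")
        assert np.allclose(
            rebuilt.evaluate(dist.bin_centers), model.evaluate(dist.bin_centers),
            atol=1e-9,
        )

    def test_continuity_at_interior_knots(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            model, _ = random_anchor_model(rng)
            for k in (1, 2):
                w = model.knots[k]
                left = np.polynomial.polynomial.polyval(w, model.pieces[k - 1])
                right = np.polynomial.polynomial.polyval(w, model.pieces[k])
                assert abs(left - right) <= 1e-9

    def test_degenerate_anchors_rejected(self):
        a = AnchorPoints(w0=0.0, S0=0.0, wM=0.05, SM=0.01, wI=0.1, SI=0.005,
                         wmax=0.2, Sm=0.001)
        bad = AnchorPoints(**{**a.to_dict(), "w0": 0.05})  # w0 == wM
        with pytest.raises(ModelError, match="knots"):
            build_model_from_anchors(bad, "A")


class TestEvaluateAndGradient:
    def test_printed_descent_piece_gradient_algebra(self):
        """d/dw of -5.714 w^2 + 0.8 w - 0.014 is -11.428 w + 0.8."""
        piece = np.array([-0.014, 0.8, -5.714])
        model = PiecewiseSW(
            template="A",
            knots=np.array([0.0, 0.035, 0.07, 0.4]),
            pieces=[
                np.array([-0.014 + 0.8 * 0.035 - 5.714 * 0.035**2, 0.0, 0.0]),
                piece,
                np.array([np.polynomial.polynomial.polyval(0.07, piece), 0.0, 0.0]),
            ],
        )
        w = np.linspace(0.035, 0.07, 100, endpoint=False)
        assert np.allclose(model.gradient(w), -11.428 * w + 0.8, atol=1e-12)

    def test_constant_piece_gradient_zero(self):
        model = PiecewiseSW(
            template="B",
            knots=np.array([0.0, 0.1, 0.2, 0.3]),
            pieces=[np.array([0.01, 0, 0])] * 3,
        )
        assert model.gradient(0.15) == 0.0

    def test_outside_domain_rejected(self):
        model = build_model_from_anchors(GROUP4_ANCHORS, "B")
        with pytest.raises(ModelError, match="domain"):
            model.evaluate(0.5)
        with pytest.raises(ModelError, match="domain"):
            model.gradient(-0.01)

    def test_left_right_agreement_at_knots(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            model, _ = random_anchor_model(rng)
            for k in (1, 2):
                w = model.knots[k]
                below = model.evaluate(np.nextafter(w, -1))
                at = model.evaluate(w)
                assert abs(below - at) < 1e-9 + 1e-6 * abs(at)


class TestIntegration:
    def test_constant_model(self):
        model = PiecewiseSW(
            template="B",
            knots=np.array([0.0, 0.1, 0.2, 0.3]),
            pieces=[np.array([0.02, 0, 0])] * 3,
        )
        assert integrate_model(model).V == pytest.approx(0.02 * 0.3, rel=1e-12)

    def test_pure_parabola_closed_form(self):
        a = 66.67
        model = PiecewiseSW(
            template="B",
            knots=np.array([0.0, 0.1, 0.2, 0.3]),
            pieces=[
                np.array([0, 0, a]),
                np.array([a * 0.01, 0, 0]),
                np.array([a * 0.01, 0, 0]),
            ],
        )
        expected = a * 0.1**3 / 3 + a * 0.01 * 0.2
        assert integrate_model(model).V == pytest.approx(expected, rel=1e-12)

    def test_matches_quadrature_on_random_models(self):
        rng = np.random.default_rng(123)
        for _ in range(25):
            model, _ = random_anchor_model(rng)
            v = integrate_model(model).V
            vq = quadrature_volume(model)
            assert abs(v - vq) <= 1e-10 * max(abs(vq), 1e-12)

    def test_linearity_under_scaling(self):
        model = build_model_from_anchors(GROUP4_ANCHORS, "B")
        doubled = PiecewiseSW(
            template=model.template,
            knots=model.knots,
            pieces=[2 * p for p in model.pieces],
        )
        assert integrate_model(doubled).V == pytest.approx(2 * integrate_model(model).V,
                                                           rel=1e-12)


class TestFitModel:
    def test_noise_free_recovery_to_1e6(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            gen, anchors = random_anchor_model(rng)
            dist = distribution_from_model(gen, bin_width=0.002)
            fit = fit_model(dist, gen.template, anchors)
            for k in range(3):
                scale = np.max(np.abs(gen.pieces[k])) or 1.0
                assert np.max(np.abs(fit.pieces[k] - gen.pieces[k])) <= 1e-6 * scale

    def test_underdetermined_interval_falls_back_and_flags(self):
        # the quadratic descent piece spans two bins only: 2 occupied bins
        # < 3 coefficients, so that interval is pinned to the anchor model
        anchors = AnchorPoints(w0=0.0, S0=0.0, wM=0.015, SM=0.015, wI=0.035,
                               SI=0.010, wmax=0.36, Sm=0.001)
        gen = build_model_from_anchors(anchors, "B")
        dist = distribution_from_model(gen, bin_width=0.01)
        fit = fit_model(dist, "B", anchors)
        assert 1 in fit.fallback_intervals
        anchor_model = build_model_from_anchors(anchors, "B")
        assert np.allclose(fit.pieces[1], anchor_model.pieces[1], atol=1e-9)

    def test_template_selection_rule(self):
        assert select_template(GROUP1_ANCHORS) == "A"
        assert select_template(GROUP4_ANCHORS) == "B"


class TestCompareGroupVolumes:
    def test_scaling_doubles_volume(self):
        m = build_model_from_anchors(GROUP4_ANCHORS, "B")
        m2 = PiecewiseSW(template=m.template, knots=m.knots,
                         pieces=[2 * p for p in m.pieces])
        report = compare_group_volumes({1: m2, 2: m})
        assert report["volumes"]["1"] == pytest.approx(2 * report["volumes"]["2"])
        assert report["strictly_decreasing"]

    def test_identical_models_tie(self):
        m = build_model_from_anchors(GROUP4_ANCHORS, "B")
        report = compare_group_volumes({1: m, 2: m})
        assert report["ties"]
        assert not report["strictly_decreasing"]
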