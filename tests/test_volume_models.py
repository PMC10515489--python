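"""Volume models: unit examples, scaling laws, the correction-factor identity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from mpvol import (
    ModelParams,
    TanoiriGroup,
    collective_volume,
    correction_factor,
    estimate_volume,
    ramanujan_perimeter,
    volume_barchiesi,
    volume_cozar,
    volume_fiber,
    volume_isobe,
    volume_medina,
    volume_simon,
    volume_tanoiri,
)


def ellipse_perimeter_quadrature(a, b):
    """Independent arc-length oracle for the Ramanujan approximation."""
    return quad(lambda t: math.hypot(a * math.sin(t), b * math.cos(t)),
                0.0, 2 * math.pi, limit=200)[0]


class TestRamanujan:
    def test_circle_is_exact(self):
        assert ramanujan_perimeter(1.0, 1.0) == pytest.approx(2 * math.pi, abs=1e-12)

    def test_two_one_matches_quadrature(self):
        exact = ellipse_perimeter_quadrature(2.0, 1.0)
        assert ramanujan_perimeter(2.0, 1.0) == pytest.approx(exact, rel=1e-5)

    def test_symmetric_in_axes(self):
        assert ramanujan_perimeter(3.2, 1.1) == ramanujan_perimeter(1.1, 3.2)

    @pytest.mark.parametrize("ar,tol", [(1.5, 1e-5), (2, 1e-5), (3, 5e-5),
                                        (4, 2e-4), (8, 1e-3), (13, 2e-3)])
    def test_error_envelope_vs_quadrature(self, ar, tol):
        # the first Ramanujan approximation degrades slowly with eccentricity
        exact = ellipse_perimeter_quadrature(ar, 1.0)
        assert ramanujan_perimeter(ar, 1.0) == pytest.approx(exact, rel=tol)

    def test_nonpositive_axis_rejected(self):
        with pytest.raises(ValueError):
            ramanujan_perimeter(0.0, 1.0)


class TestCorrectionFactor:
    def test_equal_perimeters_give_one(self):
        assert correction_factor(5.0, 5.0) == pytest.approx(1.0, abs=1e-12)

    def test_cubed_ratio(self):
        p_ell = ramanujan_perimeter(2.0, 1.0)
        assert correction_factor(p_ell, 12.0) == pytest.approx((p_ell / 12.0) ** 3,
                                                               abs=1e-14)

    def test_monotone_decreasing_in_measured_perimeter(self):
        cfs = [correction_factor(6.0, p) for p in (6.0, 8.0, 12.0, 100.0)]
        assert all(a > b for a, b in zip(cfs, cfs[1:]))
        assert cfs[-1] < 1e-3

    def test_clamp_caps_at_one(self):
        assert correction_factor(7.0, 6.0, clamp=True) == 1.0
        assert correction_factor(7.0, 6.0, clamp=False) > 1.0


class TestModelExamples:
    def test_cozar(self):
        est = volume_cozar(2.0)
        assert est.volume_mm3 == pytest.approx(0.8)
        assert est.height_mm == pytest.approx(0.2)
        assert volume_cozar(1.0).volume_mm3 == pytest.approx(0.1)

    def test_isobe(self):
        assert volume_isobe(2.0).volume_mm3 == pytest.approx(0.4 * math.pi * 8 / 4)
        assert volume_isobe(1.0).volume_mm3 == pytest.approx(0.4 * math.pi / 4)

    def test_isobe_cozar_ratio_identity(self):
        for L in (0.5, 1.0, 3.7):
            ratio = volume_isobe(L).volume_mm3 / volume_cozar(L).volume_mm3
            assert ratio == pytest.approx(math.pi / 4 * 0.4 / 0.1)

    def test_medina(self):
        est = volume_medina(math.pi)
        assert est.volume_mm3 == pytest.approx(math.pi / 6 * 8)  # sphere d=2
        assert volume_medina(math.pi / 4).volume_mm3 == pytest.approx(math.pi / 6)

    def test_medina_three_halves_scaling(self):
        assert volume_medina(4.0).volume_mm3 == pytest.approx(
            8 * volume_medina(1.0).volume_mm3)

    def test_simon(self):
        est = volume_simon(4.0, 2.0)
        assert est.height_mm == pytest.approx(1.0)
        assert est.volume_mm3 == pytest.approx(math.pi / 6 * 8)

    def test_simon_sphere_case(self):
        assert volume_simon(2.0, 2.0).volume_mm3 == pytest.approx(math.pi / 6 * 8)

    def test_simon_depends_only_on_minor_axis(self):
        a, b = volume_simon(8.0, 2.0), volume_simon(4.0, 2.0)
        assert a.volume_mm3 == pytest.approx(b.volume_mm3)
        assert a.height_mm != b.height_mm

    def test_simon_rejects_swapped_axes(self):
        with pytest.raises(ValueError):
            volume_simon(2.0, 4.0)

    def test_fiber(self):
        assert volume_fiber(2.0, 0.1).volume_mm3 == pytest.approx(
            0.6 * math.pi / 4 * 0.01 * 2)
        plain = volume_fiber(2.0, 0.1, ModelParams(fiber_void_fraction=0.0))
        assert plain.volume_mm3 == pytest.approx(math.pi / 4 * 0.01 * 2)
        assert volume_fiber(2.0, 0.1).volume_mm3 == pytest.approx(
            0.6 * plain.volume_mm3)


class TestTanoiri:
    def params(self, **groups):
        return ModelParams(tanoiri_groups={
            name: TanoiriGroup(**kw) for name, kw in groups.items()})

    def test_simon_like_group(self):
        p = self.params(g={"axis": "minor", "slope": 0.5})
        est = volume_tanoiri(4.0, 2.0, "g", p)
        assert est.height_mm == pytest.approx(1.0)
        assert est.volume_mm3 == pytest.approx(math.pi / 6 * 8)

    def test_identity_height_group(self):
        p = self.params(g={"axis": "minor", "slope": 1.0})
        assert volume_tanoiri(4.0, 2.0, "g", p).volume_mm3 == pytest.approx(
            math.pi / 6 * 4 * 2 * 2)

    def test_constant_height_passthrough(self):
        p = self.params(g={"axis": "minor", "slope": 0.0, "intercept": 1.0})
        assert volume_tanoiri(4.0, 2.0, "g", p).volume_mm3 == pytest.approx(
            math.pi / 6 * 4 * 2)

    def test_unknown_group_is_config_error(self):
        with pytest.raises(KeyError, match="unknown Tanoiri group"):
            volume_tanoiri(4.0, 2.0, "nope", self.params(g={}))

    def test_nonpositive_height_flagged_invalid(self):
        p = self.params(g={"axis": "minor", "slope": 0.0, "intercept": -1.0})
        assert not volume_tanoiri(4.0, 2.0, "g", p).valid

    def test_placeholder_defaults_warn(self):
        with pytest.warns(UserWarning, match="PLACEHOLDER"):
            volume_tanoiri(4.0, 2.0, "fragments")


class TestBarchiesi:
    def test_perfect_ellipse_outline_gives_simon(self):
        p_mp = ramanujan_perimeter(2.0, 1.0)
        est = volume_barchiesi(4.0, 2.0, p_mp)
        assert est.c_f == pytest.approx(1.0, abs=1e-6)
        assert est.volume_mm3 == pytest.approx(math.pi / 6 * 8)

    def test_product_of_components(self):
        est = volume_barchiesi(4.0, 2.0, 12.0)
        cf = correction_factor(ramanujan_perimeter(2.0, 1.0), 12.0)
        assert est.volume_mm3 == pytest.approx(cf * math.pi / 6 * 8, rel=1e-12)

    def test_circle_outline_equals_medina_and_simon(self):
        # ideal circle of diameter 2: analytic area and perimeter
        d = 2.0
        medina = volume_medina(math.pi * (d / 2) ** 2)
        simon = volume_simon(d, d)
        barch = volume_barchiesi(d, d, math.pi * d)
        assert barch.c_f == pytest.approx(1.0, abs=1e-12)
        assert medina.volume_mm3 == pytest.approx(simon.volume_mm3)
        assert barch.volume_mm3 == pytest.approx(simon.volume_mm3)

    @settings(derandomize=True, max_examples=200)
    @given(major=st.floats(0.1, 30.0), ar=st.floats(1.0, 13.0),
           rough=st.floats(1.0, 3.0))
    def test_decomposition_identity_exact(self, major, ar, rough):
        minor = major / ar
        p_mp = rough * ramanujan_perimeter(major / 2, minor / 2)
        est = volume_barchiesi(major, minor, p_mp)
        simon = volume_simon(major, minor)
        assert est.volume_mm3 == est.c_f * simon.volume_mm3  # bit-for-bit

    def test_rough_outline_below_simon(self):
        p_ell = ramanujan_perimeter(2.0, 1.0)
        assert volume_barchiesi(4, 2, 1.3 * p_ell).volume_mm3 < volume_simon(4, 2).volume_mm3
        assert volume_barchiesi(4, 2, p_ell).volume_mm3 == pytest.approx(
            volume_simon(4, 2).volume_mm3, rel=1e-9)


@pytest.mark.parametrize("s", [0.5, 2.0, 10.0])
def test_cubic_scaling_law(s):
    base = {
        "cozar": volume_cozar(2.0).volume_mm3,
        "isobe": volume_isobe(2.0).volume_mm3,
        "medina": volume_medina(3.0).volume_mm3,
        "simon": volume_simon(4.0, 2.0).volume_mm3,
        "barchiesi": volume_barchiesi(4.0, 2.0, 12.0).volume_mm3,
        "fiber": volume_fiber(2.0, 0.1).volume_mm3,
    }
    scaled = {
        "cozar": volume_cozar(2.0 * s).volume_mm3,
        "isobe": volume_isobe(2.0 * s).volume_mm3,
        "medina": volume_medina(3.0 * s * s).volume_mm3,  # area scales as s^2
        "simon": volume_simon(4.0 * s, 2.0 * s).volume_mm3,
        "barchiesi": volume_barchiesi(4.0 * s, 2.0 * s, 12.0 * s).volume_mm3,
        "fiber": volume_fiber(2.0 * s, 0.1 * s).volume_mm3,
    }
    for model in base:
        assert scaled[model] == pytest.approx(s ** 3 * base[model], rel=1e-9), model


class TestCollectiveVolume:
    def _est(self, v):
        from mpvol import VolumeEstimate
        return VolumeEstimate("simon", v)

    def test_sum(self):
        assert collective_volume([self._est(0.8), self._est(0.2)]) == pytest.approx(1.0)

    def test_permutation_invariance_and_replication(self):
        vols = [0.3, 1.2, 0.7]
        a = collective_volume([self._est(v) for v in vols])
        b = collective_volume([self._est(v) for v in reversed(vols)])
        assert a == b
        assert collective_volume([self._est(0.5)] * 7) == pytest.approx(3.5)

    def test_empty_is_zero_mixed_is_error(self):
        from mpvol import VolumeEstimate
        assert collective_volume([]) == 0.0
        with pytest.raises(ValueError, match="mixed"):
            collective_volume([VolumeEstimate("simon", 1), VolumeEstimate("cozar", 1)])


class TestParamsAndDispatch:
    def test_printed_defaults(self):
        p = ModelParams()
        assert p.k_c == 0.1 and p.k_i == 0.4 and p.fiber_void_fraction == 0.40

    def test_invalid_params_rejected(self):
        for kw in ({"k_c": 0.0}, {"k_i": 1.5}, {"fiber_void_fraction": 1.0}):
            with pytest.raises(ValueError):
                ModelParams(**kw)

    def test_dispatch_matches_direct_calls(self):
        row = {"id": "p1", "major_mm": 4.0, "minor_mm": 2.0, "area_mm2": 5.0,
               "perimeter_mm": 12.0, "fiber_length_mm": 2.0, "fiber_width_mm": 0.1}
        assert estimate_volume(row, "simon").volume_mm3 == volume_simon(4, 2).volume_mm3
        assert estimate_volume(row, "medina").volume_mm3 == volume_medina(5.0).volume_mm3
        assert estimate_volume(row, "barchiesi").volume_mm3 == pytest.approx(
            volume_barchiesi(4, 2, 12).volume_mm3)
        with pytest.raises(ValueError, match="unknown model"):
            estimate_volume(row, "sphereify")
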