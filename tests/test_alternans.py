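"""Beat-series analysis and coupled-map stability theory."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coopgate.alternans import (ALTERNANS, QUASIPERIODIC, STABLE, BeatSeries,
                                MapParams, alternans_amplitudes, classify_map,
                                coupling_slope, map_eigenvalues, measure_apd,
                                peak_per_beat, sustained_alternans_onset,
                                theoretical_boundary)
from coopgate.io import make_fixture

finite = st.floats(min_value=-3.0, max_value=3.0, allow_nan=False)


class TestMapEigenvalues:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(lv=finite, lc=finite, c=finite)
    def test_characteristic_identities(self, lv, lc, c):
        """Sum and product of the roots match the characteristic polynomial
        of the coupled two-variable map to machine precision."""
        lp, lm = map_eigenvalues(MapParams(lv, lc, c))
        assert lp + lm == pytest.approx(-(lv + lc), abs=1e-12)
        assert lp * lm == pytest.approx(lv * lc - c, abs=1e-12)

    def test_uncoupled_roots(self):
        lp, lm = map_eigenvalues(MapParams(0.8, 0.3, 0.0))
        assert sorted([lp.real, lm.real]) == pytest.approx([-0.8, -0.3])
        assert lp.imag == lm.imag == 0.0

    def test_equal_eigenvalue_case(self):
        lam, c = 0.6, 0.04
        lp, lm = map_eigenvalues(MapParams(lam, lam, c))
        assert lp == pytest.approx(-lam + np.sqrt(c))
        assert lm == pytest.approx(-lam - np.sqrt(c))

    def test_complex_pair_modulus(self):
        """For a complex pair the squared modulus equals the root product
        lambda_v*lambda_c - C."""
        p = MapParams(1.05, 1.05, -0.3)
        lp, lm = map_eigenvalues(p)
        assert lp.imag != 0.0
        assert abs(lp) ** 2 == pytest.approx(1.05 * 1.05 + 0.3, rel=1e-12)


class TestClassifyMap:
    @pytest.mark.parametrize("lv,lc,c,expected", [
        (0.5, 0.5, 0.0, STABLE),
        (1.2, 0.2, 0.0, ALTERNANS),
        (1.05, 1.05, -0.3, QUASIPERIODIC),
        (0.2, 0.3, 0.05, STABLE),
    ])
    def test_examples(self, lv, lc, c, expected):
        assert classify_map(MapParams(lv, lc, c)) == expected

    def test_boundary_square_when_uncoupled(self):
        """With C = 0 the stability boundary is the square
        |lambda_v| = 1 union |lambda_c| = 1."""
        lv = np.linspace(0.0, 1.5, 16)
        res = theoretical_boundary(0.0, lv, lv)
        for i, a in enumerate(lv):
            for j, b in enumerate(lv):
                expect_stable = (a < 1.0) and (b < 1.0)
                assert (res.labels[i, j] == STABLE) == expect_stable

    @pytest.mark.parametrize("c0,c1", [(0.10, 0.15), (-0.10, -0.05)])
    def test_stronger_coupling_shrinks_stable_area(self, c0, c1):
        """Making the Ca_i->V_m coupling more positive (or less negative)
        strictly shrinks the stable region of the map."""
        lv = np.linspace(0.0, 1.4, 41)
        r0 = theoretical_boundary(c0, lv, lv)
        r1 = theoretical_boundary(c1, lv, lv)
        assert r1.stable_cells < r0.stable_cells

    def test_boundary_points_have_unit_modulus(self):
        """Points flagged on either side of the contour bracket
        |lambda| = 1."""
        lv = np.linspace(0.5, 1.3, 81)
        c = 0.1
        for a in lv:
            mods = []
            for b in lv:
                lp, lm = map_eigenvalues(MapParams(a, b, c))
                mods.append(max(abs(lp), abs(lm)))
            mods = np.array(mods)
            cross = np.nonzero(np.diff(np.sign(mods - 1.0)))[0]
            for k in cross:
                assert min(abs(mods[k] - 1.0), abs(mods[k + 1] - 1.0)) < 0.05


class TestMeasureApd:
    def test_square_ap(self):
        data, truth = make_fixture("square_ap", {"width": 200.0})
        apd = measure_apd(data["t"], data["vm"])
        assert apd.size == 3
        assert np.allclose(apd, truth["apd"], atol=0.5)

    def test_flat_trace_empty(self):
        t = np.arange(0.0, 100.0, 0.1)
        assert measure_apd(t, np.full_like(t, -80.0)).size == 0

    def test_triangle_ap_matches_closed_form(self):
        """For a linear repolarisation ramp the APD90 crossing time has a
        closed form: fraction * ramp duration."""
        data, truth = make_fixture("triangle_ap", {"duration": 250.0})
        apd = measure_apd(data["t"], data["vm"], truth["fraction"])
        assert apd.size >= 2
        assert np.allclose(apd, truth["apd"], atol=1.0)


class TestAlternansAmplitudes:
    def test_constant_series_zero(self):
        s = BeatSeries(apd=np.full(10, 200.0), ca_peak=np.full(10, 1.0), pcl=300)
        d_apd, d_ca = alternans_amplitudes(s)
        assert np.all(d_apd == 0.0) and np.all(d_ca == 0.0)

    def test_period2_constant_amplitude(self):
        series, truth = make_fixture("period2_beats",
                                     {"apd_long": 200.0, "apd_short": 180.0})
        d_apd, d_ca = alternans_amplitudes(series)
        assert np.allclose(d_apd, truth["d_apd"])  # (-1)^n (APD_{n+1}-APD_n)
        assert np.allclose(d_ca, truth["d_ca"])

    def test_random_series_matches_independent_recomputation(self):
        rng = np.random.default_rng(7)
        apd = rng.uniform(150, 250, 30)
        ca = rng.uniform(0.5, 1.5, 30)
        s = BeatSeries(apd=apd, ca_peak=ca, pcl=300)
        d_apd, d_ca = alternans_amplitudes(s)
        expect = [(-1.0) ** n * (apd[n + 1] - apd[n]) for n in range(29)]
        assert np.allclose(d_apd, expect)
        expect_ca = [(-1.0) ** n * (ca[n + 1] - ca[n]) for n in range(29)]
        assert np.allclose(d_ca, expect_ca)

    def test_printed_sum_variant(self):
        s = BeatSeries(apd=np.array([200.0, 180.0]),
                       ca_peak=np.array([1.0, 0.8]), pcl=300)
        _, d_ca = alternans_amplitudes(s, printed_sum=True)
        assert d_ca[0] == pytest.approx(1.8)

    def test_sustained_onset(self):
        d = np.concatenate([np.random.default_rng(0).normal(0, 0.3, 20),
                            np.full(15, 8.0)])
        assert sustained_alternans_onset(d) == 20
        assert sustained_alternans_onset(np.zeros(30)) is None
        # alternating-sign dAPD is modulation, not sustained alternans
        d2 = 8.0 * (-1.0) ** np.arange(30)
        assert sustained_alternans_onset(d2) is None


class TestCouplingSlope:
    def test_exact_on_collinear_points(self):
        pts = [(x, 2.5 * x + 1.0) for x in (-0.2, -0.1, 0.0, 0.1, 0.2)]
        assert coupling_slope(pts) == pytest.approx(2.5, abs=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 2))
        s1 = coupling_slope(pts)
        s2 = coupling_slope(pts[::-1])
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            coupling_slope([(0.0, 1.0), (0.0, 2.0), (0.0, 3.0)])
        with pytest.raises(ValueError):
            coupling_slope([(0.0, 1.0), (1.0, 2.0)])


def test_peak_per_beat_windows():
    t = np.arange(0.0, 900.0, 0.5)
    ca = 0.1 + np.where((t % 300.0) < 150.0, (t % 300.0) / 150.0, 0.0)
    peaks = peak_per_beat(t, ca, 300.0)
    assert peaks.size == 3
    assert np.allclose(peaks, 0.1 + 149.5 / 150.0, atol=0.01)
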