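"""Synthetic scene generators and ground-truth encoding."""

import numpy as np
import pytest

from tdspec.calibration import fit_calibration, CalibrationPoint
from tdspec.synthetic import (
    BandSpec,
    SceneSpec,
    calibrant_scene,
    gen_2d_from_truth,
    gen_linear_od,
    gen_pump,
    generate_measurement,
    random_scene,
    scene_from_dict,
    scene_to_dict,
    truth_tds_profile,
)
from tdspec.tds import compute_tds, peak_tds

FWHM = 2 * np.sqrt(2 * np.log(2))


class TestGenLinearOd:
    def test_empty_scene_is_zero(self):
        s = SceneSpec(bands=())
        od = gen_linear_od(s)
        assert np.all(od.values == 0)

    def test_single_gaussian_matches_closed_form(self):
        band = BandSpec(1640.0, 24.0, 5.0, 0.2)
        od = gen_linear_od(SceneSpec(bands=(band,)))
        sigma = 24.0 / FWHM
        expected = 5.0 * np.exp(-0.5 * ((od.axis - 1640) / sigma) ** 2) \
            / (sigma * np.sqrt(2 * np.pi))
        assert np.allclose(od.values, expected)

    def test_lorentzian_and_pseudo_voigt_shapes(self):
        x = np.array([1640.0])
        lor = BandSpec(1640.0, 20.0, 1.0, 0.2, shape="lorentzian")
        assert lor.profile(x)[0] == pytest.approx(1.0 / (np.pi * 10.0))
        pv = BandSpec(1640.0, 20.0, 1.0, 0.2, shape="pseudo_voigt", mixing=1.0)
        assert pv.profile(x)[0] == pytest.approx(lor.profile(x)[0])

    def test_determinism_contract(self):
        s = SceneSpec(bands=(BandSpec(1640.0, 24.0, 5.0, 0.2),),
                      noise_sd=0.01, seed=3)
        a, b = gen_linear_od(s), gen_linear_od(s)
        assert np.array_equal(a.values, b.values)
        s2 = SceneSpec(bands=s.bands, noise_sd=0.01, seed=4)
        assert not np.array_equal(a.values, gen_linear_od(s2).values)

    def test_truth_stored_in_metadata(self):
        s = SceneSpec(bands=(BandSpec(1640.0, 24.0, 5.0, 0.2),),
                      baseline_poly=(0.1,), noise_sd=0.01, seed=1)
        od = gen_linear_od(s)
        assert np.allclose(od.meta["truth_bands"] + od.meta["truth_baseline"]
                           + (od.values - od.meta["truth_bands"]
                              - od.meta["truth_baseline"]), od.values)
        assert np.allclose(od.meta["truth_baseline"], 0.1)

    def test_axis_too_narrow_rejected(self):
        with pytest.raises(ValueError, match="narrow"):
            SceneSpec(bands=(BandSpec(1590.0, 30.0, 5.0, 0.2),))


class TestGenPump:
    def test_unit_peak_at_center(self):
        s = SceneSpec(bands=(), pump=(1640.0, 120.0))
        p = gen_pump(s)
        assert p.values[np.argmin(np.abs(p.axis - 1640))] == pytest.approx(1.0)
        assert np.all(p.values > 0)

    def test_symmetry_about_center(self):
        p = gen_pump(SceneSpec(bands=(), pump=(1650.0, 100.0)))
        left = np.interp(1650 - 30, p.axis, p.values)
        right = np.interp(1650 + 30, p.axis, p.values)
        assert left == pytest.approx(right, rel=1e-12)

    def test_generated_width_matches_spec(self):
        p = gen_pump(SceneSpec(bands=(), pump=(1640.0, 80.0)))
        above = p.axis[p.values >= 0.5]
        assert above[-1] - above[0] == pytest.approx(80.0, abs=1.0)


class TestTruthProfile:
    def test_single_band_profile_is_constant(self):
        s = SceneSpec(bands=(BandSpec(1640.0, 24.0, 5.0, 0.27),))
        d = truth_tds_profile(s, s.grid())
        assert np.allclose(d[np.isfinite(d)], 0.27)

    def test_overlap_is_od_weighted_mean(self):
        b1 = BandSpec(1630.0, 24.0, 5.0, 0.12)
        b2 = BandSpec(1650.0, 24.0, 5.0, 0.26)
        s = SceneSpec(bands=(b1, b2))
        axis = s.grid()
        d = truth_tds_profile(s, axis)
        i = np.argmin(np.abs(axis - 1640.0))  # symmetric midpoint
        assert d[i] == pytest.approx(0.19, rel=1e-6)


class TestGen2D:
    def test_diagonal_encodes_truth_exactly(self, calibrant_measurement):
        m = calibrant_measurement
        g = m["sample_2d"]
        # on matched axes the stored diagonal equals the encoded magnitude
        diag = np.array([g.delta_od[i, i] for i in range(g.pump_axis.size)])
        assert np.allclose(np.abs(diag), g.meta["truth_diag"])
        assert np.all(diag <= 0)

    def test_overtone_lobe_positive_and_red_shifted(self):
        s = SceneSpec(bands=(BandSpec(1645.0, 24.0, 5.0, 0.2),),
                      axis=(1560.0, 1740.0, 1.0))
        m = generate_measurement(s)
        g = m["sample_2d"]
        i = np.argmin(np.abs(g.pump_axis - 1645.0))
        row = g.delta_od[i]
        assert row[i] < 0
        j = np.argmax(row)
        assert g.probe_axis[j] < g.pump_axis[i]  # shifted to lower frequency

    def test_mismatched_od_axis_rejected(self):
        s = SceneSpec(bands=(BandSpec(1645.0, 24.0, 5.0, 0.2),),
                      axis=(1560.0, 1740.0, 1.0))
        od = gen_linear_od(SceneSpec(bands=(BandSpec(1645.0, 24.0, 5.0, 0.2),)))
        m = generate_measurement(s)
        with pytest.raises(ValueError, match="scene axis"):
            gen_2d_from_truth(s, od, m["pump"],
                              compute_tds(m["sample_2d"], m["sample_od"],
                                          m["cal_2d"], m["cal_od"],
                                          m["pump"]).calibrant)


class TestSceneSerialization:
    def test_round_trip(self):
        s = random_scene(11)
        assert scene_from_dict(scene_to_dict(s)) == s

    def test_defaults_fill_in(self):
        s = scene_from_dict({"bands": []})
        assert s.axis == (1580.0, 1720.0, 1.0)


class TestRecovery:
    def test_two_band_round_trip_with_overlap(self):
        """Uncoupled-amide and long-helix bands in one scene: both per-mode
        TDS values recovered within 2% (noise-free)."""
        s = SceneSpec(bands=(BandSpec(1625.0, 22.0, 4.0, 0.12),
                             BandSpec(1652.0, 24.0, 5.0, 0.26)),
                      baseline_poly=(0.05, 3e-4),
                      axis=(1560.0, 1740.0, 1.0))
        m = generate_measurement(s)
        r = compute_tds(m["sample_2d"], m["sample_od"], m["cal_2d"],
                        m["cal_od"], m["pump"])
        axis = s.grid()
        for b in s.bands:
            pk = peak_tds(r.tds, (b.center - 5, b.center + 5),
                          reference=r.sample_diagonal)
            truth = float(np.interp(pk.omega, axis, m["truth_tds"]))
            assert pk.tds == pytest.approx(truth, rel=0.02)

    def test_calibration_line_recovery_through_full_pipeline(self):
        """Scenes built with TDS on a known line in helical length yield a
        fitted slope/intercept within 5% of the generating values."""
        slope, intercept = 0.0067, 0.122
        pts = []
        for length in (0.0, 6.0, 13.0, 20.0):
            tds = intercept + slope * length
            s = SceneSpec(bands=(BandSpec(1642.0, 24.0, 5.0, tds),),
                          baseline_poly=(0.04, 2e-4),
                          axis=(1560.0, 1740.0, 1.0))
            m = generate_measurement(s)
            r = compute_tds(m["sample_2d"], m["sample_od"], m["cal_2d"],
                            m["cal_od"], m["pump"])
            pk = peak_tds(r.tds, (1637, 1647), reference=r.sample_diagonal)
            pts.append(CalibrationPoint(length, pk.tds))
        model = fit_calibration(pts)
        assert model.slope == pytest.approx(slope, rel=0.05)
        assert model.intercept == pytest.approx(intercept, rel=0.05)

    def test_pump_width_sweep_does_not_bias_recovery(self):
        """Recovery holds across pump envelopes from 60 to 200 cm^-1 FWHM."""
        for pump_fwhm in (60.0, 120.0, 200.0):
            s = SceneSpec(bands=(BandSpec(1660.0, 24.0, 5.0, 0.3),),
                          pump=(1640.0, pump_fwhm),
                          axis=(1560.0, 1740.0, 1.0))
            m = generate_measurement(s)
            r = compute_tds(m["sample_2d"], m["sample_od"], m["cal_2d"],
                            m["cal_od"], m["pump"])
            pk = peak_tds(r.tds, (1655, 1665), reference=r.sample_diagonal)
            assert pk.tds == pytest.approx(0.3, rel=0.02)


class TestRandomScene:
    def test_deterministic_in_seed(self):
        assert random_scene(5) == random_scene(5)
        assert random_scene(5) != random_scene(6)

    def test_physical_plausibility(self):
        for seed in range(20):
            s = random_scene(seed)
            assert 1 <= len(s.bands) <= 3
            for b in s.bands:
                assert 1615 <= b.center <= 1675
                assert 0.12 <= b.tds <= 0.35
            centers = sorted(b.center for b in s.bands)
            assert all(c2 - c1 >= 15 for c1, c2 in zip(centers, centers[1:]))
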