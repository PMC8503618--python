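"""Synthetic scene generator: activation-time maps and renderers."""

import numpy as np
import pytest

import afpathways as af
from afpathways import synth
from afpathways.grid import BasketLayout


def _scene(driver, **kw):
    kw.setdefault("noise_sd", 0.0)
    kw.setdefault("duration", 2.0)
    return af.SynthScene(drivers=(driver,), **kw)


class TestActivationTimes:
    def test_planar_rightward_distance_over_speed(self):
        drv = af.DriverSpec(kind="planar", direction=0.0, period=200.0)
        scene = _scene(drv, conduction_speed=1.0)
        t = af.activation_times(scene)
        assert t[0][0][0] == pytest.approx(0.0)
        assert t[0][5][0] == pytest.approx(5.0)  # 5 px at 1 px/ms
        assert t[3][5][0] == pytest.approx(5.0)  # same column, same time

    def test_focal_radial_symmetry(self):
        drv = af.DriverSpec(kind="focal", origin=(3.5, 3.5), period=200.0)
        t = af.activation_times(_scene(drv))
        # the four nodes equidistant from the centre origin
        vals = [t[3][3][0], t[3][4][0], t[4][3][0], t[4][4][0]]
        assert np.allclose(vals, vals[0])

    def test_rotor_consecutive_intervals_equal_period(self):
        drv = af.DriverSpec(kind="rotor", origin=(3.5, 3.5), period=200.0)
        t = af.activation_times(_scene(drv, duration=3.0))
        for r, c in [(0, 0), (2, 6), (7, 3)]:
            iv = np.diff(t[r][c])
            assert np.allclose(iv, 200.0)

    def test_period_recovery_all_kinds(self):
        for kind in ("planar", "focal", "rotor"):
            drv = af.DriverSpec(kind=kind, origin=(3.5, 3.5), period=170.0)
            t = af.activation_times(_scene(drv, duration=3.0))
            med = np.median(np.diff(t[2][5]))
            assert med == pytest.approx(170.0, abs=0.5)

    def test_unknown_kind_named_in_error(self):
        with pytest.raises(ValueError, match="spiral"):
            af.DriverSpec(kind="spiral")

    def test_rotor_phase_singularity_winding(self):
        """First-beat activation phase winds by one full turn (signed by
        chirality) around the rotor origin."""
        for chir in (1, -1):
            drv = af.DriverSpec(kind="rotor", origin=(3.5, 3.5), period=200.0,
                                chirality=chir)
            t = af.activation_times(_scene(drv))
            ring = [(2, 2), (2, 3), (2, 4), (2, 5), (3, 5), (4, 5), (5, 5),
                    (5, 4), (5, 3), (5, 2), (4, 2), (3, 2)]  # CCW in (row,col)
            v = 0.10
            phases = []
            for r, c in ring:
                dist = np.hypot(r - 3.5, c - 3.5)
                ph = 2 * np.pi * ((t[r][c][0] - dist / v) % 200.0) / 200.0
                phases.append(ph)
            winding = np.sum(np.angle(np.exp(1j * np.diff(phases + phases[:1]))))
            assert winding == pytest.approx(chir * 2 * np.pi, abs=1e-6)

    def test_focal_scene_has_no_singularity(self):
        drv = af.DriverSpec(kind="focal", origin=(3.5, 3.5), period=200.0)
        t = af.activation_times(_scene(drv))
        ring = [(2, 2), (2, 5), (5, 5), (5, 2)]
        v = 0.10
        phases = [2 * np.pi * ((t[r][c][0] - np.hypot(r - 3.5, c - 3.5) / v) % 200.0)
                  / 200.0 for r, c in ring]
        winding = np.sum(np.angle(np.exp(1j * np.diff(phases + phases[:1]))))
        assert winding == pytest.approx(0.0, abs=1e-6)

    def test_driver_time_window_confines_activations(self):
        drv = af.DriverSpec(kind="focal", origin=(3.5, 3.5), period=200.0,
                            t_start=1.0, t_stop=1.5)
        t = af.activation_times(_scene(drv, duration=3.0))
        allt = np.concatenate([t[r][c] for r in range(8) for c in range(8)])
        assert allt.min() >= 1000.0
        assert allt.max() <= 1500.0 + 200.0 + 8 * np.sqrt(2) / 0.10

    def test_multiwavelet_activity_and_determinism(self):
        drv = af.DriverSpec(kind="multiwavelet", wavelet_count=4, period=180.0)
        s = _scene(drv, duration=4.0, seed=5)
        t1 = af.activation_times(s)
        t2 = af.activation_times(s)
        counts = [len(t1[r][c]) for r in range(8) for c in range(8)]
        assert np.mean(counts) > 3  # sustained activity over 4 s
        for r in range(8):
            for c in range(8):
                assert np.array_equal(t1[r][c], t2[r][c])


class TestRenderMovie:
    def test_pulse_peak_is_one_at_activation(self):
        drv = af.DriverSpec(kind="focal", origin=(0.0, 0.0), period=1000.0)
        scene = _scene(drv, duration=1.0, conduction_speed=1.0)
        t = af.activation_times(scene)
        gm = af.render_movie(t, scene)
        t0 = t[4][4][0]
        idx = int(round(t0 * scene.fs / 1000.0))
        # unit amplitude up to half-sample discretization of the pulse
        assert gm.frames[idx, 4, 4] == pytest.approx(1.0, abs=1e-3)

    def test_no_drivers_all_zero(self):
        scene = af.SynthScene(drivers=(), noise_sd=0.0, duration=1.0)
        gm = af.render_movie(af.activation_times(scene), scene)
        assert not gm.frames.any()

    def test_argmax_recovers_activation_time(self):
        drv = af.DriverSpec(kind="planar", direction=0.0, period=500.0)
        scene = _scene(drv, duration=1.2)
        t = af.activation_times(scene)
        gm = af.render_movie(t, scene)
        for r, c in [(0, 0), (3, 4), (7, 7)]:
            # isolate the first pulse
            first = t[r][c][0]
            lo = int(max(0, (first - 100) * scene.fs / 1000))
            hi = int((first + 100) * scene.fs / 1000)
            am = lo + np.argmax(gm.frames[lo:hi, r, c])
            assert abs(am - first * scene.fs / 1000.0) <= 1.0

    def test_nonpositive_pulse_width_rejected(self):
        drv = af.DriverSpec(kind="focal", origin=(3.5, 3.5))
        scene = _scene(drv, pulse_width_ms=0.0)
        with pytest.raises(ValueError, match="pulse width"):
            af.render_movie(af.activation_times(scene), scene)

    def test_noise_respects_clipping(self):
        drv = af.DriverSpec(kind="planar", direction=0.0, period=200.0)
        scene = _scene(drv, noise_sd=0.1, duration=1.0)
        gm = af.render_movie(af.activation_times(scene), scene)
        assert gm.frames.min() >= 0.0 and gm.frames.max() <= 1.0


class TestRenderElectrograms:
    def test_single_activation_negative_peak_near_time(self):
        drv = af.DriverSpec(kind="focal", origin=(0.0, 0.0), period=5000.0)
        scene = _scene(drv, duration=1.0, conduction_speed=1.0)
        t = af.activation_times(scene)
        rec = af.render_electrograms(t, scene)
        ch = 3 * 8 + 4  # spline 3, electrode 4 -> pixel (3, 4)
        sig = rec.voltages[ch]
        assert len(t[3][4]) == 1
        neg_peak = np.argmin(sig)
        t_true = t[3][4][0] * scene.fs / 1000.0
        assert abs(neg_peak - t_true) <= 8.0 / 1000.0 * scene.fs  # half deflection
        assert sig[neg_peak] < 0

    def test_qrs_artifact_common_mode(self):
        scene = af.SynthScene(drivers=(), duration=2.0, noise_sd=0.0,
                              qrs_artifact=(800.0, 2.0))
        rec = af.render_electrograms(af.activation_times(scene), scene)
        mean_sig = rec.voltages.mean(axis=0)
        for q in rec.qrs_times:
            assert mean_sig[q] > 0.9 * 2.0

    def test_equal_seeds_bit_identical(self):
        drv = af.DriverSpec(kind="focal", origin=(3.5, 3.5))
        s = _scene(drv, noise_sd=0.05, seed=42, duration=1.0)
        t = af.activation_times(s)
        r1 = af.render_electrograms(t, s)
        r2 = af.render_electrograms(af.activation_times(s), s)
        assert np.array_equal(r1.voltages, r2.voltages)

    def test_electrode_outside_grid_lists_index(self):
        drv = af.DriverSpec(kind="focal", origin=(2.0, 2.0))
        scene = _scene(drv, grid_shape=(6, 8), duration=1.0)
        with pytest.raises(ValueError, match="electrodes mapped outside"):
            af.render_electrograms(af.activation_times(scene), scene,
                                   BasketLayout())


class TestSceneValidation:
    def test_invariants(self):
        with pytest.raises(ValueError):
            af.DriverSpec(kind="focal", period=-1.0)
        with pytest.raises(ValueError):
            af.DriverSpec(kind="multiwavelet", wavelet_count=0)
        with pytest.raises(ValueError):
            af.SynthScene(fs=0.0)
        with pytest.raises(ValueError):
            af.SynthScene(grid_shape=(3, 8))
        with pytest.raises(ValueError, match="origin"):
            af.SynthScene(drivers=(af.DriverSpec(kind="focal", origin=(30.0, 0.0)),))

    def test_scene_json_round_trip(self):
        scene = af.synth.rotor_scene(origin=(3.5, -2.5), seed=9,
                                     delay_noise_sd_ms=4.0)
        again = af.SynthScene.from_dict(scene.to_dict())
        assert again == scene

    def test_movie_determinism(self):
        s = af.synth.multiwavelet_scene(seed=3, duration=2.0)
        g1 = af.render_movie(af.activation_times(s), s)
        g2 = af.render_movie(af.activation_times(s), s)
        assert np.array_equal(g1.frames, g2.frames)
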