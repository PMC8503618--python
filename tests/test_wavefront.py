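"""Wavefront isoline detection and windowed vector averaging."""

import numpy as np
import pytest

import afpathways as af
from afpathways import flow, wavefront
from afpathways.grid import GridMovie

CFG_SMALL = af.AnalysisConfig(window_s=1.0, frame_increment_samples=10)


def _movie(frames, fs=100.0, valid=None):
    return GridMovie(frames=np.asarray(frames, dtype=float), fs=fs,
                     grid_kind="interpolated", valid_mask=valid)


class TestDetectWavefronts:
    def test_subthreshold_frames_give_empty_masks(self):
        gm = _movie(np.full((100, 10, 10), 0.5))
        wm = wavefront.detect_wavefronts(gm, CFG_SMALL)
        assert not wm.masks.any()

    def test_planar_band_yields_one_leading_component(self):
        """A rising band moving rightward: the leading isoline edge is a
        single vertical component no wider than 2 px."""
        n, rows, cols = 100, 12, 30
        frames = np.zeros((n, rows, cols))
        cc = np.arange(cols)
        for t in range(n):
            centre = 0.3 * t
            frames[t] = np.exp(-0.5 * ((cc[None, :] - centre) / 3.0) ** 2)
        gm = _movie(frames)
        wm = wavefront.detect_wavefronts(gm, CFG_SMALL)
        found = False
        from scipy import ndimage
        for k in range(wm.masks.shape[0]):
            m = wm.masks[k]
            if not m.any():
                continue
            found = True
            lab, ncomp = ndimage.label(m, structure=np.ones((3, 3)))
            assert ncomp == 1
            cols_hit = np.unique(np.nonzero(m)[1])
            assert cols_hit.size <= 2  # thin leading edge
            centre = 0.3 * wm.lattice[k]
            assert (cols_hit > centre - 0.5).all()  # ahead of the crest
        assert found

    def test_component_size_rule_three_discarded_four_kept(self):
        frames = np.zeros((30, 12, 12))
        # static bright square patches turned on with rising intensity so
        # the temporal derivative is positive at lattice frames
        ramp = np.linspace(0.8, 1.0, 30)
        for t in range(30):
            frames[t, 2, 2:5] = ramp[t]  # 3-pixel line
            frames[t, 8, 2:6] = ramp[t]  # 4-pixel line
        gm = _movie(frames)
        cfg = af.AnalysisConfig(window_s=0.2, frame_increment_samples=5)
        wm = wavefront.detect_wavefronts(gm, cfg)
        hits = wm.masks.any(axis=0)
        assert not hits[2, 2:5].any()
        assert hits[8, 2:6].all()

    def test_wave_back_excluded(self):
        """Pixels on the falling (repolarizing) side are not wavefront."""
        n, rows, cols = 60, 10, 30
        frames = np.zeros((n, rows, cols))
        cc = np.arange(cols)
        for t in range(n):
            centre = 0.4 * t
            frames[t] = np.exp(-0.5 * ((cc[None, :] - centre) / 4.0) ** 2)
        gm = _movie(frames)
        cfg = af.AnalysisConfig(window_s=0.5, frame_increment_samples=10)
        wm = wavefront.detect_wavefronts(gm, cfg)
        for k in range(wm.masks.shape[0]):
            m = wm.masks[k]
            if not m.any():
                continue
            centre = 0.4 * wm.lattice[k]
            # all wavefront pixels ahead of the crest (leading side only)
            assert (np.nonzero(m)[1] > centre).all() or (np.nonzero(m)[1] < centre).all()
            dndt = frames[min(wm.lattice[k] + 1, n - 1)] - frames[max(wm.lattice[k] - 1, 0)]
            assert (dndt[m] > 0).all()

    def test_invalid_regions_produce_no_boundaries(self):
        valid = np.ones((10, 10), dtype=bool)
        valid[:, 5:] = False
        frames = np.zeros((30, 10, 10))
        frames[:] = np.linspace(0.85, 1.0, 30)[:, None, None]  # rising, all high
        gm = _movie(frames, valid=valid)
        cfg = af.AnalysisConfig(window_s=0.2, frame_increment_samples=5)
        wm = wavefront.detect_wavefronts(gm, cfg)
        # the super-level set fills the whole valid area: no interior
        # isoline, and the valid/invalid border must not count as one
        assert not wm.masks.any()


class TestAverageFlow:
    def _fields(self, u_list, v_list, valid=None):
        shape = np.asarray(u_list[0]).shape
        valid = valid if valid is not None else np.ones(shape, bool)
        return [
            flow.FlowField(u=np.asarray(u, float), v=np.asarray(v, float),
                           frame_time=k * 0.01, valid_mask=valid)
            for k, (u, v) in enumerate(zip(u_list, v_list))
        ]

    def _mask(self, masks, fs=100.0):
        masks = np.asarray(masks, bool)
        return wavefront.WavefrontMask(
            masks=masks, labels=masks.astype(np.int32),
            lattice=np.arange(masks.shape[0]) * 10, fs=fs)

    def test_coherent_vectors_average_to_unit(self):
        n = 6
        ones = [np.ones((3, 3))] * n
        zeros = [np.zeros((3, 3))] * n
        avg = wavefront.average_flow(
            self._fields(ones, zeros), self._mask([np.ones((3, 3))] * n))
        assert np.allclose(avg.u_avg, 1.0)
        assert np.allclose(avg.v_avg, 0.0)
        assert (avg.contribution_count == n).all()

    def test_alternating_vectors_cancel(self):
        us = [np.ones((3, 3)) * (1 if k % 2 == 0 else -1) for k in range(6)]
        vs = [np.zeros((3, 3))] * 6
        avg = wavefront.average_flow(
            self._fields(us, vs), self._mask([np.ones((3, 3))] * 6))
        assert np.allclose(avg.u_avg, 0.0)

    def test_non_wavefront_frames_dilute_average(self):
        """Normalization is by analyzed-frame count, not contributions."""
        us = [np.ones((2, 2))] * 4
        vs = [np.zeros((2, 2))] * 4
        masks = [np.ones((2, 2)), np.zeros((2, 2)), np.ones((2, 2)),
                 np.zeros((2, 2))]
        avg = wavefront.average_flow(self._fields(us, vs), self._mask(masks))
        assert np.allclose(avg.u_avg, 0.5)
        assert (avg.contribution_count == 2).all()

    def test_zero_contribution_pixels_have_zero_vector(self):
        us = [np.ones((2, 2))] * 3
        vs = [np.zeros((2, 2))] * 3
        m = np.zeros((2, 2))
        avg = wavefront.average_flow(self._fields(us, vs), self._mask([m] * 3))
        assert not avg.u_avg.any() and not avg.v_avg.any()

    def test_empty_field_list_rejected(self):
        with pytest.raises(ValueError, match="no analyzed"):
            wavefront.average_flow([], self._mask([np.zeros((2, 2))]))

    def test_triangle_inequality_on_magnitudes(self):
        rng = np.random.default_rng(0)
        us = [rng.normal(size=(4, 4)) for _ in range(8)]
        vs = [rng.normal(size=(4, 4)) for _ in range(8)]
        masks = [rng.uniform(size=(4, 4)) > 0.3 for _ in range(8)]
        avg = wavefront.average_flow(self._fields(us, vs), self._mask(masks))
        per_frame_max = np.max([np.hypot(u, v) for u, v in zip(us, vs)], axis=0)
        assert (avg.magnitude <= per_frame_max + 1e-12).all()


class TestAveragedPatterns:
    def test_planar_average_direction_within_10_degrees(self, planar_analysis):
        a = planar_analysis.averaged
        m = a.contribution_count > 0
        ang = np.degrees(np.arctan2(a.v_avg[m].mean(), a.u_avg[m].mean()))
        assert abs(ang) < 10.0

    def test_rotor_circulation_sign_follows_chirality(self):
        from scipy.interpolate import RegularGridInterpolator

        for chir in (1, -1):
            scene = af.synth.rotor_scene(origin=(3.5, 3.5), chirality=chir,
                                         seed=5)
            res = af.analyze_window(af.scene_movie(scene))
            a = res.averaged
            gi_u = RegularGridInterpolator((np.arange(25), np.arange(22)), a.u_avg)
            gi_v = RegularGridInterpolator((np.arange(25), np.arange(22)), a.v_avg)
            centre = np.array([10.5, 10.5])
            circ = 0.0
            for t in np.linspace(0, 2 * np.pi, 72, endpoint=False):
                p = centre + 9.0 * np.array([np.sin(t), np.cos(t)])
                tang = np.array([np.cos(t), -np.sin(t)])  # CCW tangent (row, col)
                circ += gi_v(p).item() * tang[0] + gi_u(p).item() * tang[1]
            assert np.sign(circ) == chir

    def test_multiwavelet_incoherence_cancels(self, planar_analysis):
        """Disorganised activation leaves much smaller averaged vectors
        than a repeatable planar wave."""
        scene = af.synth.multiwavelet_scene(seed=13)
        res = af.analyze_window(af.scene_movie(scene))
        planar_mag = planar_analysis.averaged.magnitude
        multi_mag = res.averaged.magnitude
        pm = np.median(planar_mag[planar_mag > 0])
        mm = np.median(multi_mag[multi_mag > 0]) if (multi_mag > 0).any() else 0.0
        assert mm < 0.25 * pm
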