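import numpy as np
import pytest
from scipy import ndimage

from pxct import forward, metrics, phantom, tomo
from conftest import pillar_interior_mask


def delta_series(shape=(32, 32, 32), voxel=(16, 20, 12), n_angles=180):
    vol = np.zeros(shape)
    vol[voxel] = 1.0
    ph = phantom.TissuePhantom(
        density=vol,
        labels=np.zeros(shape, dtype=np.int8),
        synapses=np.empty((0, 3)),
        voxel_size=1.0,
        rng_seed=0,
    )
    plan = phantom.AcquisitionPlan(angles=phantom.equispaced_angles(n_angles))
    return forward.acquire_series(ph, None, plan)


class TestFBP:
    def test_delta_recovery(self):
        # brute-force oracle: the 32^3 delta must reconstruct at its own voxel
        series = delta_series()
        rec = tomo.fbp(series, "ramlak")
        assert np.unravel_index(np.argmax(rec.volume), rec.volume.shape) == (16, 20, 12)

    def test_hann_suppresses_high_frequencies(self, static_series):
        hann = tomo.fbp(static_series, "hann").volume
        ramlak = tomo.fbp(static_series, "ramlak").volume

        def highband_power(vol):
            f = np.abs(np.fft.fftn(vol)) ** 2
            freqs = np.meshgrid(*[np.fft.fftfreq(s) for s in vol.shape], indexing="ij")
            r = np.sqrt(sum(g ** 2 for g in freqs))
            return f[r > 0.35].sum() / f.sum()

        assert highband_power(hann) < highband_power(ramlak)

    def test_zero_projections_zero_volume(self):
        pset = forward.PhaseProjectionSet(
            projections=np.zeros((10, 16, 16)),
            angles=phantom.equispaced_angles(10),
            times=np.linspace(0, 1, 10),
            pixel_size=1.0,
        )
        assert not np.any(tomo.fbp(pset, "hann").volume)

    def test_unknown_filter(self, static_series):
        with pytest.raises(ValueError, match="unknown filter"):
            tomo.fbp(static_series, "shepp")

    def test_static_correlation_invariant(self):
        ph = phantom.make_phantom(64, 30.0, texture=0.3, rng_seed=2)
        plan = phantom.AcquisitionPlan(angles=phantom.equispaced_angles(180))
        series = forward.acquire_series(ph, None, plan)
        rec = tomo.fbp(series, "ramlak")
        corr = np.corrcoef(rec.volume.ravel(), ph.density.ravel())[0, 1]
        assert corr > 0.95


class TestAlignProjections:
    def test_prealigned_shifts_small(self, static_series):
        _, shifts = tomo.align_projections(static_series)
        assert np.abs(shifts).max() < 0.1

    def test_recover_injected_shifts(self, static_series, rng):
        injected = rng.uniform(-3, 3, size=(len(static_series), 2))
        shifted = np.stack(
            [
                ndimage.shift(p, s, order=1, mode="nearest")
                for p, s in zip(static_series.projections, injected)
            ]
        )
        pset = forward.PhaseProjectionSet(
            projections=shifted,
            angles=static_series.angles,
            times=static_series.times,
            pixel_size=static_series.pixel_size,
        )
        _, estimated = tomo.align_projections(pset)
        err = np.abs(estimated - injected)
        # the mean vertical/horizontal gauge is unobservable; compare deviations
        err_centered = np.abs(
            (estimated - estimated.mean(0)) - (injected - injected.mean(0))
        )
        assert err_centered.max() < 0.5 or err.max() < 0.5

    def test_alignment_improves_reconstruction(self, small_phantom, static_series, rng):
        injected = rng.uniform(-3, 3, size=(len(static_series), 2))
        shifted = np.stack(
            [
                ndimage.shift(p, s, order=1, mode="nearest")
                for p, s in zip(static_series.projections, injected)
            ]
        )
        pset = forward.PhaseProjectionSet(
            projections=shifted,
            angles=static_series.angles,
            times=static_series.times,
            pixel_size=static_series.pixel_size,
        )
        aligned, _ = tomo.align_projections(pset)
        truth = small_phantom.density
        err_raw = np.corrcoef(tomo.fbp(pset).volume.ravel(), truth.ravel())[0, 1]
        err_ali = np.corrcoef(tomo.fbp(aligned).volume.ravel(), truth.ravel())[0, 1]
        assert err_ali > err_raw

    def test_degenerate_projections_rejected(self):
        pset = forward.PhaseProjectionSet(
            projections=np.zeros((5, 8, 8)),
            angles=phantom.equispaced_angles(5),
            times=np.linspace(0, 1, 5),
            pixel_size=1.0,
        )
        with pytest.raises(ValueError, match="degenerate"):
            tomo.align_projections(pset)

    def test_too_few_projections(self, static_series):
        with pytest.raises(ValueError):
            tomo.align_projections(static_series.subset(np.array([0, 1])))


class TestSplitSubtomograms:
    def test_k1_identity(self, static_series):
        subs = tomo.split_subtomograms(static_series, 1)
        assert len(subs) == 1
        np.testing.assert_array_equal(subs[0].projections, static_series.projections)

    def test_union_disjoint(self, static_series):
        subs = tomo.split_subtomograms(static_series, 4)
        all_idx = np.concatenate([s.meta["parent_indices"] for s in subs])
        assert sorted(all_idx.tolist()) == list(range(len(static_series)))

    def test_k4_on_16_angles_uniform_spacing(self, small_phantom):
        plan = phantom.AcquisitionPlan(angles=phantom.equispaced_angles(16), n_subtomos=4)
        series = forward.acquire_series(small_phantom, None, plan)
        subs = tomo.split_subtomograms(series, 4)
        for s in subs:
            assert len(s) == 4
            spacing = np.diff(np.sort(s.angles))
            np.testing.assert_allclose(spacing, 45.0)

    def test_interlaced_subsets_have_contiguous_dose_windows(self, small_phantom):
        plan = phantom.AcquisitionPlan(angles=phantom.equispaced_angles(16), n_subtomos=4)
        series = forward.acquire_series(small_phantom, None, plan)
        subs = tomo.split_subtomograms(series, 4)
        windows = sorted((s.times.min(), s.times.max()) for s in subs)
        for (lo1, hi1), (lo2, _) in zip(windows, windows[1:]):
            assert hi1 < lo2

    def test_merge_round_trip(self, static_series):
        subs = tomo.split_subtomograms(static_series, 3)
        merged = tomo.merge_subtomograms(subs)
        np.testing.assert_array_equal(merged.projections, static_series.projections)
        np.testing.assert_array_equal(merged.angles, static_series.angles)
        np.testing.assert_array_equal(merged.times, static_series.times)

    def test_invalid_k(self, static_series):
        with pytest.raises(ValueError):
            tomo.split_subtomograms(static_series, 0)


class TestEstimateFlow:
    def test_identical_volumes_zero_flow(self, small_phantom):
        f = tomo.estimate_flow(small_phantom.density, small_phantom.density)
        assert np.abs(f.displacement).max() < 0.05

    def test_global_shift_recovery(self, small_phantom):
        a = small_phantom.density
        d = np.zeros((3,) + a.shape)
        d[1] = 2.0
        b = forward.warp_volume(a, d)
        f = tomo.estimate_flow(a, b).displacement
        mask = pillar_interior_mask(a.shape)
        epe = np.sqrt(((f - d) ** 2).sum(axis=0))[mask].mean()
        assert epe < 0.25

    def test_sinusoidal_warp_recovery(self):
        # smooth textured volume so brightness constancy is informative everywhere
        rng = np.random.default_rng(5)
        n = 48
        vol = ndimage.gaussian_filter(rng.standard_normal((n, n, n)), 1.5)
        zz, _, xx = np.mgrid[:n, :n, :n].astype(float)
        d = np.zeros((3, n, n, n))
        d[1] = 3.0 * np.sin(2 * np.pi * xx / 32)
        d[2] = 3.0 * np.cos(2 * np.pi * zz / 32)
        b = forward.warp_volume(vol, d)
        f = tomo.estimate_flow(vol, b).displacement
        inner = np.zeros((n, n, n), dtype=bool)
        inner[6:-6, 6:-6, 6:-6] = True
        epe = np.sqrt(((f - d) ** 2).sum(axis=0))[inner].mean()
        assert epe < 0.5

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            tomo.estimate_flow(np.zeros((16, 16, 16)), np.zeros((16, 16, 8)))

    def test_boundary_margin_zeroed(self, small_phantom):
        a = small_phantom.density
        d = np.zeros((3,) + a.shape)
        d[2] = 1.5
        f = tomo.estimate_flow(a, forward.warp_volume(a, d), boundary_margin=3)
        assert not np.any(f.displacement[:, :3])
        assert not np.any(f.displacement[:, :, -3:])


class TestInterpolateFlows:
    def _nodes(self, rng):
        shape = (3, 8, 8, 8)
        return [np.zeros(shape), rng.standard_normal(shape), rng.standard_normal(shape)]

    def test_node_time_exact(self, rng):
        nodes = self._nodes(rng)
        out = tomo.interpolate_flows(nodes, [0.0, 0.5, 1.0], [0.5])
        np.testing.assert_array_equal(out[0], nodes[1])

    def test_midpoint_mean(self, rng):
        nodes = self._nodes(rng)
        out = tomo.interpolate_flows(nodes, [0.0, 0.5, 1.0], [0.75])
        np.testing.assert_allclose(out[0], 0.5 * (nodes[1] + nodes[2]))

    def test_clamped_outside(self, rng):
        nodes = self._nodes(rng)
        out = tomo.interpolate_flows(nodes, [0.0, 0.5, 1.0], [-1.0, 2.0])
        np.testing.assert_array_equal(out[0], nodes[0])
        np.testing.assert_array_equal(out[1], nodes[2])

    def test_single_node_constant(self, rng):
        nodes = [rng.standard_normal((3, 4, 4, 4))]
        out = tomo.interpolate_flows(nodes, [0.3], [0.0, 0.9])
        np.testing.assert_array_equal(out[0], nodes[0])
        np.testing.assert_array_equal(out[1], nodes[0])

    def test_duplicate_times_rejected(self, rng):
        nodes = self._nodes(rng)
        with pytest.raises(ValueError):
            tomo.interpolate_flows(nodes, [0.0, 0.0, 1.0], [0.5])


class TestInvertDisplacement:
    def test_translation_inverse(self):
        d = np.zeros((3, 24, 24, 24))
        d[1] = 1.7
        e = tomo.invert_displacement(d)
        np.testing.assert_allclose(e[1], 1.7, atol=1e-6)

    def test_roundtrip_on_smooth_field(self, small_phantom):
        dm = phantom.make_deformation([0, 1.0], 3.0, 16.0, small_phantom.shape, rng_seed=1)
        d = dm.control_fields[-1]
        e = tomo.invert_displacement(d)
        a = small_phantom.density
        restored = forward.warp_volume(forward.warp_volume(a, d), -e)
        mask = pillar_interior_mask(a.shape)
        err = np.abs(restored - a)[mask].mean() / a[mask].std()
        assert err < 0.15


@pytest.fixture(scope="module")
def deforming():
    ph = phantom.make_phantom(48, 30.0, texture=0.3, rng_seed=0)
    dm = phantom.make_deformation(np.linspace(0, 1, 5), 4.0, 14.0, ph.shape, rng_seed=0)
    plan = phantom.AcquisitionPlan(angles=phantom.equispaced_angles(64), n_subtomos=4)
    series = forward.acquire_series(ph, dm, plan, noise_sigma=0.1, rng_seed=1)
    return ph, dm, series


class TestNonrigidReconstruct:
    def test_zero_deformation_matches_rigid(self, small_phantom):
        plan = phantom.AcquisitionPlan(angles=phantom.equispaced_angles(64), n_subtomos=4)
        series = forward.acquire_series(small_phantom, None, plan)
        rigid = tomo.fbp(series, "hann").volume
        nonrigid = tomo.nonrigid_reconstruct(series, 4, flow_downsample=2).volume
        rms = np.sqrt(((nonrigid - rigid) ** 2).mean()) / np.ptp(rigid)
        assert rms < 0.01

    def test_nonrigid_beats_rigid_split_half(self, deforming):
        _, _, series = deforming
        rigid = metrics.fsc_split_half(series, {"mode": "rigid"}).resolution_nm
        nonrigid = metrics.fsc_split_half(
            series,
            {"mode": "nonrigid", "k_subtomos": 4, "flow_downsample": 2,
             "n_outer_iters": 2},
        ).resolution_nm
        assert nonrigid < rigid

    def test_true_fields_not_worse_than_estimated(self, deforming):
        ph, dm, series = deforming
        est = tomo.nonrigid_reconstruct(series, 4, flow_downsample=2).volume
        oracle = tomo.nonrigid_reconstruct(series, 4, true_deformation=dm).volume
        truth = ph.density
        scale = truth.std()

        def err(vol):
            v = (vol - vol.mean()) / vol.std() * scale + truth.mean()
            return np.sqrt(((v - truth) ** 2).mean())

        assert err(oracle) <= err(est)

    def test_k_too_small(self, deforming):
        _, _, series = deforming
        with pytest.raises(ValueError):
            tomo.nonrigid_reconstruct(series, 1)
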