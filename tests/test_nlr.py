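import dataclasses
import itertools

import numpy as np
import pytest

from perfmap.core import AIFCurve
from perfmap.model import gamma_variate_aif, tissue_curve
from perfmap.nlr import (NLRConfig, compute_maps, derive_brain_mask,
                         fit_voxel, fit_voxels, model_tissue_curve,
                         select_aif, select_vof)
from perfmap.phantom import LABELS, PhantomSpec, make_phantom

from conftest import small_spec

AIF_TIMES = np.arange(89) * 0.5
AIF = gamma_variate_aif({"t0": 4.0, "alpha": 3.0, "beta": 2.5,
                         "amplitude": 350.0}, AIF_TIMES)


def grid_search_sse(curve, aif, config, n=20):
    """Brute-force 20x20x20 grid over the bounds; returns the best SSE."""
    best = np.inf
    cbfs = np.linspace(*config.cbf_bounds, n)
    mtts = np.linspace(*config.mtt_bounds, n)
    delays = np.linspace(*config.delay_bounds, n)
    model = tissue_curve(aif, cbfs[:, None, None],
                         mtts[None, :, None], delays[None, None, :])
    sse = ((model - curve) ** 2).sum(axis=-1)
    return float(sse.min())


class TestModelTissueCurve:
    def test_zero_cbf(self):
        assert np.all(model_tissue_curve(AIF, 0.0, 5.0, 3.5) == 0.0)

    def test_matches_phantom_synthesis(self):
        # cross-module consistency at (60, 5, 3.5) on the 0.5 s grid
        spec = small_spec(noise_sd=0.0, n_frames=89)
        spec = dataclasses.replace(spec, duration=44.5,
                                   aif_params=dict(AIF.__dict__) and {
                                       "t0": 4.0, "alpha": 3.0, "beta": 2.5,
                                       "amplitude": 350.0})
        spec.tissue_params["normal"] = (60.0, 5.0, 3.5)
        bundle = make_phantom(spec)
        vox = np.argwhere(bundle.region_labels == LABELS["normal"])[0]
        phantom_curve = (bundle.stack.data[tuple(vox)] - spec.baseline_hu)
        model_curve = model_tissue_curve(bundle.aif, 60.0, 5.0, 3.5)
        assert np.abs(phantom_curve - model_curve).max() < 1e-9


class TestFitVoxel:
    def test_optimum_at_initial_point(self):
        curve = tissue_curve(AIF, 60.0, 5.0, 3.5)
        fit = fit_voxel(curve, AIF)
        assert fit.sse < 1e-10
        assert fit.cbf == pytest.approx(60.0, rel=1e-3)
        assert fit.mtt == pytest.approx(5.0, rel=1e-3)
        assert fit.delay == pytest.approx(3.5, rel=1e-3)

    def test_round_trip_30_8_2(self):
        curve = tissue_curve(AIF, 30.0, 8.0, 2.0)
        fit = fit_voxel(curve, AIF)
        assert fit.cbf == pytest.approx(30.0, rel=0.01)
        assert fit.mtt == pytest.approx(8.0, rel=0.01)
        assert fit.delay == pytest.approx(2.0, rel=0.01)
        assert fit.cbv == pytest.approx(30.0 * 8.0 / 60.0, rel=0.01)

    def test_beats_grid_search(self, rng):
        cfg = NLRConfig()
        for cbf, mtt, delay in ((30.0, 8.0, 2.0), (90.0, 4.0, 6.0),
                                (150.0, 12.0, 1.0)):
            curve = tissue_curve(AIF, cbf, mtt, delay)
            curve = curve + rng.normal(0, 1.0, curve.shape)
            fit = fit_voxel(curve, AIF, config=cfg)
            assert fit.sse <= grid_search_sse(curve, AIF, cfg) + 1e-9

    def test_sse_never_exceeds_initial_sse(self, rng):
        cfg = NLRConfig()
        init_curve = tissue_curve(AIF, *cfg.init)
        for _ in range(5):
            curve = tissue_curve(AIF, rng.uniform(5, 150),
                                 rng.uniform(1, 20), rng.uniform(0, 10))
            curve = curve + rng.normal(0, 2.0, curve.shape)
            fit = fit_voxel(curve, AIF, config=cfg)
            sse_init = float(((init_curve - curve) ** 2).sum())
            assert fit.sse <= sse_init + 1e-9

    def test_scaling_equivariance(self):
        # c * curve -> c * CBF (and CBV), same MTT/delay
        cfg = NLRConfig(max_iter=2000)
        curve = tissue_curve(AIF, 50.0, 6.0, 3.0)
        f1 = fit_voxel(curve, AIF, config=cfg)
        f2 = fit_voxel(2.0 * curve, AIF, config=cfg)
        assert f2.cbf == pytest.approx(2.0 * f1.cbf, rel=1e-6)
        assert f2.cbv == pytest.approx(2.0 * f1.cbv, rel=1e-6)
        assert f2.mtt == pytest.approx(f1.mtt, rel=1e-6)
        assert f2.delay == pytest.approx(f1.delay, rel=1e-6)

    def test_all_zero_curve_flagged(self):
        fit = fit_voxel(np.zeros_like(AIF_TIMES), AIF)
        assert fit.flag == "no-signal"
        assert fit.cbf == 0.0
        assert (fit.mtt, fit.delay) == (5.0, 3.5)

    def test_truncated_observation_flagged(self):
        curve = tissue_curve(AIF, 60.0, 29.0, 19.5)
        fit = fit_voxel(curve, AIF)
        assert fit.flag == "truncated"


class TestFitVoxels:
    @pytest.fixture(scope="class")
    def noisy_batch(self):
        rng = np.random.default_rng(11)
        true = np.column_stack([rng.uniform(10, 150, 40),
                                rng.uniform(2, 15, 40),
                                rng.uniform(0, 8, 40)])
        curves = tissue_curve(AIF, true[:, 0], true[:, 1], true[:, 2])
        return true, curves + rng.normal(0, 1.0, curves.shape)

    def test_engines_agree(self, noisy_batch):
        _, curves = noisy_batch
        a = fit_voxels(curves, AIF, config=NLRConfig(engine="numba"))
        b = fit_voxels(curves, AIF, config=NLRConfig(engine="numpy"))
        np.testing.assert_allclose(a["cbv"], b["cbv"], atol=1e-4)
        np.testing.assert_allclose(a["sse"], b["sse"], rtol=1e-6, atol=1e-9)

    def test_matches_scalar_reference(self, noisy_batch):
        _, curves = noisy_batch
        batch = fit_voxels(curves[:8], AIF)
        for i in range(8):
            ref = fit_voxel(curves[i], AIF)
            assert batch["sse"][i] == pytest.approx(ref.sse, rel=1e-3,
                                                    abs=1e-8)

    def test_noiseless_recovery_500_voxels(self):
        # median relative error < 1% per parameter over random draws
        rng = np.random.default_rng(42)
        cfg = NLRConfig()
        true = np.column_stack([
            rng.uniform(*cfg.cbf_bounds, 500),
            rng.uniform(*cfg.mtt_bounds, 500),
            rng.uniform(*cfg.delay_bounds, 500)])
        curves = tissue_curve(AIF, true[:, 0], true[:, 1], true[:, 2])
        fit = fit_voxels(curves, AIF, config=cfg)
        est = np.column_stack([fit["cbf"], fit["mtt"], fit["delay"]])
        rel = np.abs(est - true) / np.maximum(np.abs(true), 1e-9)
        assert np.median(rel, axis=0).max() < 0.01

    def test_noisy_recovery_median_cbf_error(self):
        rng = np.random.default_rng(43)
        cfg = NLRConfig()
        true = np.column_stack([
            rng.uniform(*cfg.cbf_bounds, 500),
            rng.uniform(*cfg.mtt_bounds, 500),
            rng.uniform(*cfg.delay_bounds, 500)])
        curves = tissue_curve(AIF, true[:, 0], true[:, 1], true[:, 2])
        curves = curves + rng.normal(0, 2.0, curves.shape)
        fit = fit_voxels(curves, AIF, config=cfg)
        rel = np.abs(fit["cbf"] - true[:, 0]) / np.maximum(true[:, 0], 1e-9)
        assert np.median(rel) < 0.10


class TestSelection:
    def test_aif_voxels_inside_artery(self, noisy_bundle):
        # default 100-voxel sample, desk-scale phantom with a ~150-voxel artery
        aif, coords = select_aif(noisy_bundle.stack, return_voxels=True)
        labels = noisy_bundle.region_labels[tuple(coords.T)]
        assert np.all(labels == LABELS["artery"])

    def test_aif_peak_dominates_tissue(self, small_noisy_bundle):
        b = small_noisy_bundle
        aif = select_aif(b.stack)
        for lab in ("normal", "penumbra", "core"):
            curves = b.stack.data[b.region_labels == LABELS[lab]]
            mean = curves.mean(axis=0)
            assert aif.peak >= (mean - mean[:3].mean()).max()

    def test_default_sample_size_is_100(self):
        import inspect
        assert inspect.signature(select_aif).parameters["n_voxels"].default == 100
        assert inspect.signature(select_vof).parameters["n_voxels"].default == 100

    def test_vof_peaks_later_than_aif(self, noisy_bundle):
        aif = select_aif(noisy_bundle.stack)
        vof = select_vof(noisy_bundle.stack)
        assert vof.time_to_peak >= aif.time_to_peak

    def test_fewer_candidates_warns(self, small_noisy_bundle):
        with pytest.warns(UserWarning, match="candidate"):
            select_aif(small_noisy_bundle.stack, n_voxels=10 ** 6)


class TestComputeMaps:
    def test_noiseless_phantom_round_trip(self, small_noiseless_bundle):
        b = small_noiseless_bundle
        maps = compute_maps(b.stack, aif=b.aif)
        for name in ("cbf", "cbv", "mtt", "ttp"):
            for region in ("normal", "penumbra", "core"):
                m = b.region_labels == LABELS[region]
                got = maps[name][m].mean()
                want = b.true_maps[name][m].mean()
                assert got == pytest.approx(want, rel=0.01), (name, region)

    def test_normalized_maps_in_unit_range(self, small_noiseless_bundle):
        maps = compute_maps(small_noiseless_bundle.stack,
                            aif=small_noiseless_bundle.aif)
        for name in maps.names:
            norm = maps.normalized(name)
            assert norm.min() >= 0.0 and norm.max() <= 1.0
            inside = norm < 1.0
            np.testing.assert_allclose(maps.denormalize(name, norm[inside]),
                                       maps[name][inside], atol=1e-9)

    def test_zero_flow_phantom_gives_zero_cbv(self):
        spec = small_spec(noise_sd=0.0)
        spec.tissue_params = {k: ((0.0,) + v[1:] if k != "artery" else v)
                              for k, v in spec.tissue_params.items()}
        b = make_phantom(spec)
        maps = compute_maps(b.stack, aif=b.aif)
        tissue = (b.region_labels > 0) & (b.region_labels != LABELS["artery"])
        assert np.abs(maps["cbv"][tissue]).max() == 0.0

    def test_empty_mask_rejected(self, small_noiseless_bundle):
        stack = small_noiseless_bundle.stack.copy()
        stack.brain_mask = np.zeros_like(stack.brain_mask)
        with pytest.raises(ValueError, match="mask"):
            compute_maps(stack, aif=small_noiseless_bundle.aif)

    def test_derived_mask_matches_labels(self, small_noisy_bundle):
        b = small_noisy_bundle
        stack = b.stack.copy()
        stack.brain_mask = None
        mask = derive_brain_mask(stack)
        agree = (mask == (b.region_labels > 0)).mean()
        assert agree > 0.98
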