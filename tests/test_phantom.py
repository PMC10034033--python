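import dataclasses

import numpy as np
import pytest

from perfmap.model import CBF_SI_SCALE, gamma_variate_aif
from perfmap.phantom import (InvalidSpecError, LABELS, PhantomSpec,
                             generate_cohort, make_param_maps, make_phantom,
                             region_labels, region_mask, synthesize_ctp)

from conftest import small_spec


def brute_force_tissue_curve(aif, cbf, mtt, delay, times):
    """Trapezoid-rule convolution of the (piecewise-linear) AIF with the
    box IRF, evaluated independently of the package's closed form.

    All AIF breakpoints and box edges are included in the quadrature grid,
    which makes the trapezoid rule exact for this integrand.
    """
    out = np.zeros_like(times, dtype=float)
    for i, t in enumerate(times):
        lo, hi = t - delay - mtt, t - delay
        lo = max(lo, aif.times[0])
        hi = min(hi, aif.times[-1])
        if hi <= lo:
            continue
        grid = np.union1d(aif.times[(aif.times > lo) & (aif.times < hi)],
                          [lo, hi])
        vals = np.interp(grid, aif.times, aif.values)
        out[i] = np.trapezoid(vals, grid)
    return cbf * CBF_SI_SCALE * out


class TestParamMaps:
    def test_central_volume_principle(self):
        spec = PhantomSpec(noise_sd=0.0)
        maps, labels = make_param_maps(spec)
        normal = labels == LABELS["normal"]
        # CBF 60 mL/100g/min for 5 s -> CBV = 5 mL/100g
        assert np.all(maps["cbv"][normal] == pytest.approx(5.0))

    def test_zero_flow_background(self):
        maps, labels = make_param_maps(PhantomSpec())
        bg = labels == LABELS["background"]
        assert np.all(maps["cbf"][bg] == 0.0)
        assert np.all(maps["cbv"][bg] == 0.0)

    def test_region_means_match_spec_exactly(self):
        spec = PhantomSpec()
        maps, labels = make_param_maps(spec)
        for name in ("normal", "penumbra", "core"):
            cbf, mtt, delay = spec.tissue_params[name]
            m = labels == LABELS[name]
            assert m.any()
            assert maps["cbf"][m].mean() == cbf
            assert maps["mtt"][m].mean() == mtt
            assert maps["ttp"][m].mean() == delay

    def test_core_is_worst_perfused(self):
        spec = PhantomSpec()
        maps, labels = make_param_maps(spec)
        by = {n: maps["cbv"][labels == LABELS[n]].mean()
              for n in ("normal", "penumbra", "core")}
        assert by["core"] < by["penumbra"] < by["normal"]
        dly = {n: maps["ttp"][labels == LABELS[n]].mean()
               for n in ("normal", "penumbra", "core")}
        assert dly["core"] > dly["penumbra"] > dly["normal"]

    def test_overlapping_regions_rejected(self):
        spec = small_spec()
        spec.regions["core"]["center_mm"] = spec.regions["artery"]["center_mm"] + (5.0,)
        spec.regions["penumbra"]["center_mm"] = spec.regions["core"]["center_mm"]
        with pytest.raises(InvalidSpecError, match="overlap"):
            region_labels(spec)

    def test_lesion_outside_brain_rejected(self):
        spec = small_spec()
        spec.regions["core"]["center_mm"] = (70.0, 70.0, 5.0)
        spec.regions["penumbra"]["center_mm"] = (70.0, 70.0, 5.0)
        with pytest.raises(InvalidSpecError):
            region_labels(spec)


class TestSynthesis:
    def test_zero_flow_zero_noise_is_flat_baseline(self):
        spec = small_spec(noise_sd=0.0)
        spec.tissue_params = {k: (0.0, v[1], v[2]) if k != "artery" else v
                              for k, v in spec.tissue_params.items()}
        maps, _ = make_param_maps(spec)
        aif = gamma_variate_aif(spec.aif_params, spec.times)
        bundle = synthesize_ctp(maps, aif, spec)
        tissue = (bundle.region_labels > 0) \
            & (bundle.region_labels != LABELS["artery"])
        assert np.allclose(bundle.stack.data[tissue], spec.baseline_hu)
        air = bundle.region_labels == LABELS["background"]
        assert np.allclose(bundle.stack.data[air], spec.air_hu)

    def test_noiseless_curve_matches_trapezoid_convolution_oracle(self):
        spec = small_spec(noise_sd=0.0)
        bundle = make_phantom(spec)
        for region in ("normal", "penumbra", "core"):
            cbf, mtt, delay = spec.tissue_params[region]
            vox = np.argwhere(bundle.region_labels == LABELS[region])[0]
            curve = bundle.stack.data[tuple(vox)] - spec.baseline_hu
            oracle = brute_force_tissue_curve(bundle.aif, cbf, mtt, delay,
                                              spec.times)
            assert np.abs(curve - oracle).max() < 1e-6

    def test_artery_carries_the_aif(self):
        spec = small_spec(noise_sd=0.0)
        bundle = make_phantom(spec)
        vox = np.argwhere(bundle.region_labels == LABELS["artery"])[0]
        curve = bundle.stack.data[tuple(vox)] - spec.baseline_hu
        np.testing.assert_allclose(curve, bundle.aif.values, atol=1e-9)

    def test_acquisition_protocol_frame_spacing(self):
        # 89 volumes over a 44.5-s acquisition -> 0.5 s between frames
        spec = PhantomSpec(n_frames=89, duration=44.5)
        assert spec.times.shape == (89,)
        assert np.allclose(np.diff(spec.times), 0.5)

    def test_seed_reproducibility(self):
        a = make_phantom(small_spec(noise_sd=2.0, seed=3))
        b = make_phantom(small_spec(noise_sd=2.0, seed=3))
        c = make_phantom(small_spec(noise_sd=2.0, seed=4))
        assert np.array_equal(a.stack.data, b.stack.data)
        assert not np.array_equal(a.stack.data, c.stack.data)

    def test_area_proportional_to_cbv(self):
        # conservation: baseline-subtracted AUC ratio equals the CBV ratio.
        # Needs full bolus washout inside the window and delay/MTT on the
        # frame grid, otherwise truncation breaks exact proportionality.
        spec = PhantomSpec(noise_sd=0.0, duration=89.0, n_frames=178)
        bundle = make_phantom(spec)
        areas, cbvs = [], []
        for region in ("normal", "penumbra", "core"):
            vox = np.argwhere(bundle.region_labels == LABELS[region])[0]
            curve = bundle.stack.data[tuple(vox)] - spec.baseline_hu
            areas.append(np.trapezoid(curve, spec.times))
            cbvs.append(bundle.true_maps["cbv"][tuple(vox)])
        for i in range(1, 3):
            assert areas[i] / areas[0] == pytest.approx(cbvs[i] / cbvs[0],
                                                        rel=1e-6)

    def test_motion_shifts_frames(self):
        spec = small_spec(noise_sd=0.0)
        still = make_phantom(spec)
        motion = [{"shift_mm": (0.0, 0.0, 0.0)} for _ in range(spec.n_frames)]
        motion[5] = {"shift_mm": (6.0, 0.0, 0.0)}  # +2 voxels along x
        moved = make_phantom(dataclasses.replace(spec, motion=motion))
        assert moved.stack.data.shape == still.stack.data.shape
        f5 = moved.stack.data[..., 5]
        np.testing.assert_allclose(f5[2:], still.stack.data[:-2, :, :, 5],
                                   atol=1e-9)
        np.testing.assert_allclose(moved.stack.data[..., 4],
                                   still.stack.data[..., 4], atol=1e-9)


class TestRegionGeometry:
    def test_sphere_mask_volume_close_to_analytic(self):
        # 10 mm sphere on a 2 mm grid: volume within a one-voxel surface shell
        desc = {"kind": "sphere", "center_mm": (20.0, 20.0, 20.0),
                "radius_mm": 10.0}
        mask = region_mask(desc, (20, 20, 20), (2.0, 2.0, 2.0))
        vol = mask.sum() * 8.0 / 1000.0          # cm^3
        analytic = 4.0 / 3.0 * np.pi             # (4/3) pi (1 cm)^3
        shell = 4.0 * np.pi * 1.0 ** 2 * 0.2     # surface * voxel size (cm)
        assert abs(vol - analytic) < shell

    def test_unknown_region_kind(self):
        with pytest.raises(InvalidSpecError):
            region_mask({"kind": "blob", "center_mm": (0, 0)}, (4, 4, 2),
                        (1, 1, 1))


class TestSpecValidation:
    @pytest.mark.parametrize("kw", [dict(n_frames=1), dict(duration=-1.0),
                                    dict(noise_sd=-0.1)])
    def test_invalid_scalars(self, kw):
        with pytest.raises(InvalidSpecError):
            PhantomSpec(**kw)

    def test_invalid_tissue_params(self):
        with pytest.raises(InvalidSpecError):
            PhantomSpec(tissue_params={"normal": (60.0, 0.0, 2.0)})

    def test_dict_round_trip(self):
        spec = small_spec(noise_sd=1.5, seed=9)
        again = PhantomSpec.from_dict(spec.to_dict())
        assert again == spec


class TestCohort:
    def test_cohort_composition_and_determinism(self):
        a = generate_cohort(6, seed=1, base_spec=small_spec())
        b = generate_cohort(6, seed=1, base_spec=small_spec())
        c = generate_cohort(6, seed=2, base_spec=small_spec())
        lesioned = [bool((x.region_labels == LABELS["core"]).any()) for x in a]
        assert sum(lesioned) == 2  # round(6/3)
        for x, y in zip(a, b):
            assert np.array_equal(x.stack.data, y.stack.data)
        assert any(not np.array_equal(x.stack.data, y.stack.data)
                   for x, y in zip(a, c))

    def test_subjects_differ(self):
        cohort = generate_cohort(4, seed=0, base_spec=small_spec())
        assert not np.array_equal(cohort[0].stack.data, cohort[1].stack.data)
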