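"""Registration: similarity, regularization, warping, composition, recovery."""

import numpy as np
import pytest

import imioreg as ir
from imioreg import preprocess
from imioreg.pipeline import _external_masks
from imioreg.register import downsample_mask, register_pair, resample_via_field
from imioreg.types import (
    DisplacementField,
    MultiChannelImage,
    RegistrationParams,
    TissueClass,
    TissueClassMap,
)

SP = (1.0, 1.0)


def two_channel_image(rng, shape=(8, 8), weights=(0.6, 0.4)):
    return MultiChannelImage(
        channels=rng.random((2,) + shape),
        channel_names=["ct", "body"],
        channel_weights=np.asarray(weights),
        spacing_mm=SP,
        slice_type="liver",
    )


def uniform_classmap(shape, cls=TissueClass.SOFT_TISSUE):
    weights = {
        TissueClass.AIR: 0.05,
        TissueClass.ADIPOSE: 0.05,
        TissueClass.SOFT_TISSUE: 0.05,
        TissueClass.BONE: 0.1,
    }
    return TissueClassMap(np.full(shape, int(cls), dtype=np.int8), weights)


class TestMultichannelSSD:
    def test_identity_pair_zero_energy(self, rng):
        img = two_channel_image(rng)
        zero = DisplacementField.zero((8, 8), SP)
        assert ir.multichannel_ssd(img, img, zero) == 0.0

    def test_linear_in_channel_weights(self, rng):
        fixed = two_channel_image(rng)
        moving = two_channel_image(rng)
        doubled_f = two_channel_image(np.random.default_rng(0), weights=(1.2, 0.8))
        doubled_f.channels = fixed.channels
        doubled_m = two_channel_image(np.random.default_rng(0), weights=(1.2, 0.8))
        doubled_m.channels = moving.channels
        zero = DisplacementField.zero((8, 8), SP)
        e1 = ir.multichannel_ssd(fixed, moving, zero)
        e2 = ir.multichannel_ssd(doubled_f, doubled_m, zero)
        assert e2 == pytest.approx(2 * e1, rel=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        """Vectorized energy equals a literal per-voxel interpolation sum."""
        fixed = two_channel_image(rng)
        moving = two_channel_image(rng)
        field = DisplacementField(rng.uniform(-1.5, 1.5, (8, 8, 2)), SP)
        expected = 0.0
        for c in range(2):
            w = fixed.channel_weights[c]
            M = moving.channels[c]
            for i in range(8):
                for j in range(8):
                    y = i + field.vectors[i, j, 0]
                    x = j + field.vectors[i, j, 1]
                    if not (0 <= y <= 7 and 0 <= x <= 7):
                        val = 0.0  # out of bounds: background value
                    else:
                        y0, x0 = min(int(np.floor(y)), 6), min(int(np.floor(x)), 6)
                        fy, fx = y - y0, x - x0
                        val = (
                            (1 - fy) * (1 - fx) * M[y0, x0]
                            + (1 - fy) * fx * M[y0, x0 + 1]
                            + fy * (1 - fx) * M[y0 + 1, x0]
                            + fy * fx * M[y0 + 1, x0 + 1]
                        )
                    expected += w * (fixed.channels[c][i, j] - val) ** 2
        got = ir.multichannel_ssd(fixed, moving, field)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_channel_mismatch_rejected(self, rng):
        fixed = two_channel_image(rng)
        moving = two_channel_image(rng)
        moving.channel_names = ["ct", "bone"]
        with pytest.raises(ValueError, match="channel"):
            ir.multichannel_ssd(fixed, moving, DisplacementField.zero((8, 8), SP))


class TestRegularizationEnergy:
    def test_constant_field_is_free(self):
        field = DisplacementField(np.full((10, 10, 2), 7.0), SP)
        assert ir.regularization_energy(field, uniform_classmap((10, 10))) == 0.0

    def test_single_spike_closed_form(self):
        v = np.zeros((9, 9, 2))
        v[4, 4, 0] = 1.0  # 1 mm spike, 4 neighbours
        field = DisplacementField(v, SP)
        soft = ir.regularization_energy(field, uniform_classmap((9, 9)))
        assert soft == pytest.approx(4 * 0.05 * 1.0)
        bone = ir.regularization_energy(field, uniform_classmap((9, 9), TissueClass.BONE))
        assert bone == pytest.approx(4 * 0.1 * 1.0)
        assert bone == pytest.approx(2 * soft)

    def test_grid_mismatch_rejected(self):
        field = DisplacementField(np.zeros((8, 8, 2)), SP)
        with pytest.raises(ValueError, match="grid"):
            ir.regularization_energy(field, uniform_classmap((9, 9)))


class TestWarpImage:
    def test_zero_field_identity(self, rng):
        img = rng.random((16, 16))
        out = ir.warp_image(img, DisplacementField.zero((16, 16), SP))
        assert np.allclose(out, img)

    def test_integer_translation_nearest_exact(self, rng):
        img = rng.random((16, 16))
        v = np.zeros((16, 16, 2))
        v[..., 1] = 3.0  # 3 voxels at 1 mm spacing
        out = ir.warp_image(img, DisplacementField(v, SP), "nearest", background=-1.0)
        assert np.array_equal(out[:, :-3], img[:, 3:])
        assert (out[:, -3:] == -1.0).all()

    def test_interpolation_ranges_on_binary_mask(self, rng):
        mask = (rng.random((32, 32)) > 0.5).astype(float)
        field = DisplacementField(rng.uniform(-2, 2, (32, 32, 2)), SP)
        linear = ir.warp_image(mask, field, "linear")
        nearest = ir.warp_image(mask, field, "nearest")
        assert linear.min() >= 0.0 and linear.max() <= 1.0
        assert set(np.unique(nearest)) <= {0.0, 1.0}
        assert not np.all(np.isin(linear, (0.0, 1.0)))

    def test_unknown_interpolation_rejected(self):
        with pytest.raises(ValueError, match="interpolation"):
            ir.warp_image(np.zeros((4, 4)), DisplacementField.zero((4, 4), SP), "cubic")


class TestCompose:
    def test_zero_is_identity_element(self, rng):
        f = DisplacementField(rng.uniform(-2, 2, (16, 16, 2)), SP)
        zero = DisplacementField.zero((16, 16), SP)
        assert np.allclose(ir.compose(zero, f).vectors, f.vectors)
        assert np.allclose(ir.compose(f, zero).vectors, f.vectors, atol=1e-9)

    def test_constant_translations_add(self):
        a = DisplacementField(np.full((8, 8, 2), 2.0), SP)
        b = DisplacementField(np.full((8, 8, 2), -0.5), SP)
        assert np.allclose(ir.compose(a, b).vectors, 1.5)

    def test_compose_with_numeric_inverse_is_near_zero(self):
        # smooth ~2 mm field on a 64² grid
        yy, xx = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        v = np.stack(
            [2.0 * np.sin(yy / 20.0), 2.0 * np.cos(xx / 17.0)], axis=-1
        )
        f = DisplacementField(v, SP)
        # fixed-point iteration for the inverse displacement
        inv = np.zeros_like(v)
        for _ in range(60):
            g = DisplacementField(inv, SP)
            comp = ir.compose(f, g)
            inv -= comp.vectors
        residual = ir.compose(f, DisplacementField(inv, SP)).magnitude()
        interior = residual[4:-4, 4:-4]
        assert interior.mean() < 0.1

    def test_spacing_mismatch_rejected(self):
        a = DisplacementField.zero((8, 8), (1.0, 1.0))
        b = DisplacementField.zero((8, 8), (2.0, 2.0))
        with pytest.raises(ValueError, match="spacing"):
            ir.compose(a, b)


class TestRegisterPair:
    def test_identity_pair_no_drift(self, registered_bulge_pair):
        std, masks, classmap, chan = registered_bulge_pair["fixed"]
        res = register_pair(chan, chan, classmap)
        spacing = res.field.spacing_mm[0]
        assert res.field.magnitude().mean() < 0.5 * spacing

    def test_translation_recovered_within_one_voxel(self, noisy_liver_subject):
        subject, spec = noisy_liver_subject
        ct = subject.slices["liver"]
        d = 3 * spec.spacing_mm
        warped, truth = ir.apply_synthetic_warp(ct, {"kind": "translation", "offset_mm": (d, 0.0)})
        ext = _external_masks(subject.truth_masks["liver"], "liver")
        ext_w = {k: ir.warp_image(v.astype(float), truth, "nearest") > 0.5 for k, v in ext.items()}
        std_m, masks_m, _ = preprocess.preprocess_subject(ct, ext, target_grid=256)
        std_f, masks_f, cm_f = preprocess.preprocess_subject(warped, ext_w, target_grid=256)
        chan_m = preprocess.assemble_channels(std_m, masks_m)
        chan_f = preprocess.assemble_channels(std_f, masks_f)
        res = register_pair(chan_f, chan_m, cm_f)
        body = downsample_mask(masks_f["body"], 1)
        err = np.hypot(*(res.field.vectors - truth.vectors[::2, ::2]).transpose(2, 0, 1))
        assert err[body].mean() < spec.spacing_mm

    def test_bulge_recovered_within_2mm(self, registered_bulge_pair):
        pair = registered_bulge_pair
        _, masks_f, cm_f, chan_f = pair["fixed"]
        chan_m = pair["moving"][3]
        res = register_pair(chan_f, chan_m, cm_f)
        body = downsample_mask(masks_f["body"], 1)
        truth = pair["truth"].vectors[::2, ::2]
        err = np.hypot(*(res.field.vectors - truth).transpose(2, 0, 1))
        assert err[body].mean() < 2.0

    def test_energy_monotone_per_level(self, registered_bulge_pair):
        pair = registered_bulge_pair
        _, _, cm_f, chan_f = pair["fixed"]
        res = register_pair(chan_f, pair["moving"][3], cm_f)
        for level, trace in res.energy_traces.items():
            diffs = np.diff(trace)
            assert (diffs <= 1e-6 * np.abs(np.asarray(trace[:-1])) + 1e-9).all(), level

    def test_output_grid_halves_input(self, registered_bulge_pair):
        pair = registered_bulge_pair
        _, _, cm_f, chan_f = pair["fixed"]
        res = register_pair(chan_f, pair["moving"][3], cm_f)
        assert res.field.grid_shape == (128, 128)  # 256² input
        assert res.field.spacing_mm[0] == pytest.approx(2 * chan_f.spacing_mm[0])

    def test_coarse_to_fine_never_worse_than_fine_only(self, registered_bulge_pair):
        pair = registered_bulge_pair
        _, _, cm_f, chan_f = pair["fixed"]
        chan_m = pair["moving"][3]
        full = register_pair(chan_f, chan_m, cm_f, RegistrationParams())
        fine_only = register_pair(
            chan_f, chan_m, cm_f, RegistrationParams(pyramid_levels=1, pyramid_stop_level=1)
        )
        assert full.energy_traces[1][-1] <= fine_only.energy_traces[1][-1] + 1e-9

    def test_slice_type_mismatch_rejected(self, rng):
        a = two_channel_image(rng)
        b = two_channel_image(rng)
        b.slice_type = "thigh"
        with pytest.raises(ValueError, match="slice_type"):
            register_pair(a, b, uniform_classmap((8, 8)))


class TestWarpRegisterRoundTrip:
    def test_endpoint_error_below_half_truth_magnitude(self, noisy_liver_subject):
        """Registering source onto a bulge-warped phantom cuts the endpoint
        error well below half the mean truth displacement (for deformations
        above the half-resolution quantization floor of ~1 output voxel)."""
        subject, _ = noisy_liver_subject
        ct = subject.slices["liver"]
        warp = {"kind": "bulge", "center_mm": (240.0, 200.0),
                "amplitude_mm": 6.0, "sigma_mm": 80.0}
        warped, truth = ir.apply_synthetic_warp(ct, warp)
        ext = _external_masks(subject.truth_masks["liver"], "liver")
        ext_w = {k: ir.warp_image(v.astype(float), truth, "nearest") > 0.5
                 for k, v in ext.items()}
        std_m, masks_m, _ = preprocess.preprocess_subject(ct, ext, target_grid=256)
        std_f, masks_f, cm_f = preprocess.preprocess_subject(warped, ext_w, target_grid=256)
        res = register_pair(
            preprocess.assemble_channels(std_f, masks_f),
            preprocess.assemble_channels(std_m, masks_m),
            cm_f,
        )
        body = downsample_mask(masks_f["body"], 1)
        truth_l1 = truth.vectors[::2, ::2]
        err = np.hypot(*(res.field.vectors - truth_l1).transpose(2, 0, 1))[body].mean()
        truth_mag = np.hypot(truth_l1[..., 0], truth_l1[..., 1])[body].mean()
        assert err < 0.5 * truth_mag


class TestMaskInfluence:
    def test_mask_channels_reduce_endpoint_error(self):
        """Guidance masks help (or tie) on bulge-warped pairs, over 10 seeds."""
        wins = 0
        deltas = []
        for seed in range(10):
            spec = ir.PhantomSpec("liver", grid_size=128, hu_noise_sd=10.0, seed=100 + seed)
            subject = ir.generate_subject(spec)
            ct = subject.slices["liver"]
            warp = {
                "kind": "bulge",
                "center_mm": (240.0, 210.0),
                "amplitude_mm": 5.0,
                "sigma_mm": 70.0,
            }
            warped, truth = ir.apply_synthetic_warp(ct, warp)
            ext = _external_masks(subject.truth_masks["liver"], "liver")
            ext_w = {
                k: ir.warp_image(v.astype(float), truth, "nearest") > 0.5
                for k, v in ext.items()
            }
            std_m, masks_m, _ = preprocess.preprocess_subject(ct, ext, target_grid=128)
            std_f, masks_f, cm_f = preprocess.preprocess_subject(warped, ext_w, target_grid=128)
            body = downsample_mask(masks_f["body"], 1)
            truth_l1 = truth.vectors[::2, ::2]

            def epe(channel_weights):
                cf = preprocess.assemble_channels(std_f, masks_f, channel_weights)
                cm = preprocess.assemble_channels(std_m, masks_m, channel_weights)
                res = register_pair(cf, cm, cm_f)
                err = np.hypot(*(res.field.vectors - truth_l1).transpose(2, 0, 1))
                return err[body].mean()

            with_masks = epe(None)
            ct_only = epe({"liver": 0.0, "spleen": 0.0, "body": 0.0, "vertebra": 0.0})
            deltas.append(ct_only - with_masks)
            wins += with_masks <= ct_only + 1e-9
        assert np.mean(deltas) > 0, deltas
        assert wins >= 7, deltas


class TestResampleViaField:
    def test_matches_warp_at_same_resolution(self, rng):
        img = rng.random((32, 32))
        field = DisplacementField(rng.uniform(-1, 1, (32, 32, 2)), SP)
        a = ir.warp_image(img, field, background=0.0)
        b = resample_via_field(img, SP, field, background=0.0)
        assert np.allclose(a, b)
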