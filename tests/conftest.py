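"""Shared fixtures: small phantom slices and a registered phantom pair.

Phantoms are generated at reduced grid sizes (64–256) so the suite stays
fast; all randomness is seeded.
"""

import numpy as np
import pytest

import imioreg as ir
from imioreg import preprocess
from imioreg.pipeline import _external_masks


@pytest.fixture(scope="session")
def liver_subject():
    """Noise-free liver phantom at 256² (analytic geometry checks)."""
    spec = ir.PhantomSpec("liver", grid_size=256, hu_noise_sd=0.0, smooth_sigma=0.0, seed=1)
    return ir.generate_subject(spec), spec


@pytest.fixture(scope="session")
def noisy_liver_subject():
    spec = ir.PhantomSpec("liver", grid_size=256, hu_noise_sd=8.0, seed=3)
    return ir.generate_subject(spec), spec


@pytest.fixture(scope="session")
def thigh_subject():
    spec = ir.PhantomSpec("thigh", grid_size=256, hu_noise_sd=0.0, smooth_sigma=0.0, seed=2)
    return ir.generate_subject(spec), spec


@pytest.fixture(scope="session")
def abdomen_subject():
    spec = ir.PhantomSpec("abdomen", grid_size=256, hu_noise_sd=0.0, smooth_sigma=0.0, seed=4)
    return ir.generate_subject(spec), spec


def preprocess_phantom(subject, grid_size):
    """Standardize a phantom slice and assemble its registration inputs."""
    (st,) = subject.slices.keys()
    ext = _external_masks(subject.truth_masks[st], st)
    std, masks, classmap = preprocess.preprocess_subject(
        subject.slices[st], ext, target_grid=grid_size
    )
    channels = preprocess.assemble_channels(std, masks)
    return std, masks, classmap, channels


@pytest.fixture(scope="session")
def registered_bulge_pair(noisy_liver_subject):
    """Source/warped liver pair with truth field, preprocessed both ways."""
    subject, spec = noisy_liver_subject
    ct = subject.slices["liver"]
    warp = {"kind": "bulge", "center_mm": (240.0, 200.0), "amplitude_mm": 4.0, "sigma_mm": 60.0}
    warped, truth = ir.apply_synthetic_warp(ct, warp)
    ext = _external_masks(subject.truth_masks["liver"], "liver")
    ext_w = {
        k: ir.warp_image(v.astype(float), truth, "nearest") > 0.5 for k, v in ext.items()
    }
    std_m, masks_m, cm_m = preprocess.preprocess_subject(ct, ext, target_grid=256)
    std_f, masks_f, cm_f = preprocess.preprocess_subject(warped, ext_w, target_grid=256)
    chan_m = preprocess.assemble_channels(std_m, masks_m)
    chan_f = preprocess.assemble_channels(std_f, masks_f)
    return {
        "moving": (std_m, masks_m, cm_m, chan_m),
        "fixed": (std_f, masks_f, cm_f, chan_f),
        "truth": truth,
        "warp": warp,
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240413)
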