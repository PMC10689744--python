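import numpy as np
import pytest

from reefspectra import classify as cl
from reefspectra import preprocess as pp
from reefspectra import scene as sc
from reefspectra import taxonomy as tx


@pytest.fixture(scope="session")
def demo_hier():
    return tx.demo_hierarchy()


@pytest.fixture(scope="session")
def demo_lib(demo_hier):
    return sc.demo_library(demo_hier.fine_ids)


@pytest.fixture(scope="session")
def lib3():
    """Three-category library for small classifier tests."""
    return sc.demo_library([1, 2, 3])


def identity_optics(n_bands: int, seed: int = 0) -> sc.OpticsConfig:
    """Flat unit illumination, no water, no noise: radiance == reflectance."""
    return sc.OpticsConfig(
        illumination_spectrum=np.ones(n_bands),
        attenuation_k=np.zeros(n_bands),
        sensor_height_m=1.0,
        noise_sd_additive=0.0,
        noise_sd_multiplicative=0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def scene3(lib3):
    """Patchy 3-category scene, 200 x 50 px at 2 cm."""
    return sc.generate_scene(
        [1, 2, 3], {1: 0.4, 2: 0.35, 3: 0.25}, patch_scale_m=0.3,
        dims=(200, 50), pixel_size_m=0.02, seed=5,
    )


@pytest.fixture(scope="session")
def trained_setup(scene3, lib3):
    """A small rendered + preprocessed cube with a trained SSRN.

    Shared across classifier tests; low noise so the learning problem is
    easy and fast.
    """
    optics = sc.default_optics(
        lib3.wavelengths_nm, noise_sd_additive=0.002,
        noise_sd_multiplicative=0.01, seed=2,
    )
    cube = sc.render_cube(scene3, lib3, optics)
    pre = pp.preprocess_cube(cube, lib3.plate_reflectance)
    ann = tx.sample_rois(scene3, n_rois=60, roi_size_px=5, skew=1.0, seed=3)
    ann = tx.split_train_validation(ann, 0.9, seed=4)
    cfg = cl.SSRNConfig(epochs=10, batch_size=128, seed=0)
    model = cl.build_model(cfg, pre.n_bands, 3)
    model = cl.train(model, pre, ann, cfg)
    return {"scene": scene3, "library": lib3, "cube": pre, "raw_cube": cube,
            "annotations": ann, "model": model}
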