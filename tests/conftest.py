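import numpy as np
import pandas as pd
import pytest

from pigmorph.features import extract_features, FEATURE_NAMES
from pigmorph.synthetic import ShapeSpec, make_shape, simulate_herd


def shape(kind, rotation_deg=0.0, center=None, canvas=(960, 540), border_test=False,
          **params):
    """Rasterize a synthetic shape with keyword size parameters."""
    return make_shape(
        ShapeSpec(kind, params, rotation_deg=rotation_deg, center=center,
                  canvas=canvas, border_test=border_test)
    )


@pytest.fixture(scope="session")
def herd():
    """The reference synthetic herd: 100 animals × 10 images, seed 42."""
    return simulate_herd(n_animals=100, images_per_animal=10, seed=42)


@pytest.fixture(scope="session")
def herd_features(herd):
    """Feature table extracted from the reference herd (shared; expensive)."""
    rows = []
    for s in herd:
        fv = extract_features(s.mask, s.camera_height_m)
        rows.append({"image_id": s.image_id, "animal_id": s.animal_id,
                     **fv.as_dict(), "weight_kg": s.weight_kg})
    return pd.DataFrame(rows, columns=["image_id", "animal_id", *FEATURE_NAMES,
                                       "weight_kg"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
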