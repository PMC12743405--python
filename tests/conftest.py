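import numpy as np
import pytest

from spermtopo.synthetic import generate_population, preset_from_tables


@pytest.fixture(scope="session")
def small_population():
    """50 cells/case/fraction population from the published presets."""
    cfg = preset_from_tables(seed=42, cells_per_case=50)
    return generate_population(cfg)


@pytest.fixture(scope="session")
def rendered_scene(tmp_path_factory):
    """One rendered 512x512 scene with 10 cells plus its ground truth."""
    from spermtopo.render import render_images

    cfg = preset_from_tables(seed=3, cells_per_case=12, image_shape=(512, 512))
    gt = generate_population(cfg)
    ids = list(gt.cells["nucleus_id"].iloc[:10])
    out = tmp_path_factory.mktemp("scene")
    image, cmap, truth = render_images(gt, ids, out, seed=3)
    return image, cmap, truth, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
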