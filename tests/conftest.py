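import numpy as np
import pytest

from orgaswell import SceneSpec, ShapeParams, render_scene


@pytest.fixture(scope="session")
def easy_scene():
    """Well-separated near-circular organoids, low noise."""
    spec = SceneSpec(
        image_size=(384, 384),
        n_organoids=10,
        shape_params=ShapeParams(mean_radius=16, irregularity=0.0),
        clustering=0.0,
        noise_sd=1.2,  # 1% of background
        rng_seed=11,
    )
    return render_scene(spec)


@pytest.fixture(scope="session")
def moderate_scene():
    """Irregular, partly clustered organoids at 2% noise."""
    spec = SceneSpec(
        image_size=(384, 384),
        n_organoids=12,
        shape_params=ShapeParams(mean_radius=16, irregularity=0.5, n_harmonics=4),
        clustering=0.3,
        noise_sd=2.4,
        rng_seed=23,
    )
    return render_scene(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_label_pair(rng, size=28, max_instances=6):
    """Random pred/gt label-mask pair built from overlapping rectangles.

    Rectangles are painted in label order, so later labels may overwrite
    earlier ones (a fully overwritten label simply vanishes from the
    mask). Used as fodder for the matching oracle.
    """
    from orgaswell import LabelMask

    def one_mask():
        labels = np.zeros((size, size), dtype=np.int64)
        n = int(rng.integers(0, max_instances + 1))
        for lid in range(1, n + 1):
            h = int(rng.integers(3, 10))
            w = int(rng.integers(3, 10))
            r = int(rng.integers(0, size - h))
            c = int(rng.integers(0, size - w))
            labels[r : r + h, c : c + w] = lid
        return LabelMask(labels=labels)

    return one_mask(), one_mask()
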