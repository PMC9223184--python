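import numpy as np
import pytest

import moldscan as ms


def make_planted(seed: int, n_per: int = 60, p: int = 200, n_inf: int = 10,
                 lo: float = 0.6, hi: float = 1.0):
    """Planted-informative-variable fixture: 4 ordered classes whose means are
    shifted along `n_inf` planted columns by `lo`..`hi` within-class SDs per
    adjacent level, buried among pure-noise columns."""
    rng = np.random.default_rng(seed)
    y = np.repeat(list(ms.LEVELS), n_per)
    X = rng.standard_normal((4 * n_per, p))
    planted = np.sort(rng.choice(p, n_inf, replace=False))
    d = rng.uniform(lo, hi, n_inf)
    for li in range(4):
        X[li * n_per : (li + 1) * n_per][:, planted] += li * d
    return X, y, planted


@pytest.fixture(scope="session")
def small_tables():
    """Desk-scale fast-path dataset: 48 samples, 60 + 30 bands."""
    cfg = ms.SceneConfig(n_per_level=12, vis_bands=60, lwnir_bands=30,
                         spatial_size=(48, 48), seed=11)
    return cfg, ms.generate_feature_tables(cfg)


@pytest.fixture(scope="session")
def small_scene():
    """One rendered moderate-level Vis-SWNIR scene with ground truth."""
    cfg = ms.SceneConfig(spatial_size=(48, 48), vis_bands=40, lwnir_bands=24, seed=7)
    raw, white, black, truth = ms.generate_scene(cfg, "moderate", 7)
    return cfg, raw, white, black, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
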