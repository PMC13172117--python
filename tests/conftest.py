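import numpy as np
import pytest

import cribmap as cm


@pytest.fixture(scope="session")
def demo_model() -> cm.LogisticCribModel:
    return cm.default_model()


@pytest.fixture(scope="session")
def small_config() -> cm.PhantomConfig:
    """A compact phantom grid used by most imaging tests."""
    return cm.PhantomConfig(
        grid_shape=(48, 48, 10),
        voxel_spacing=(0.7, 0.7, 3.0),
        prostate_semiaxes_mm=(13.0, 11.0, 10.0),
    )


@pytest.fixture(scope="session")
def fixture_cohort():
    return cm.build_fixture_cohort()


def brute_force_map(adc, mask, model, sizes, aggregation, min_mask_fraction=0.5):
    """Exhaustive double-loop window enumeration oracle for sliding_window_map."""
    nx, ny, nz = adc.shape
    best = np.full(adc.shape, -np.inf)
    touched = np.zeros(adc.shape, bool)
    for z in range(nz):
        for w in sizes:
            for i in range(nx - w + 1):
                for j in range(ny - w + 1):
                    mwin = mask[i : i + w, j : j + w, z]
                    nin = mwin.sum()
                    if nin < min_mask_fraction * w * w or nin == 0:
                        continue
                    p = model.predict(cm.extract_p90(adc[i : i + w, j : j + w, z][mwin]))
                    if aggregation == "cover":
                        sub = best[i : i + w, j : j + w, z]
                        np.maximum(sub, p, out=sub)
                        touched[i : i + w, j : j + w, z] = True
                    else:
                        ci, cj = i + w // 2, j + w // 2
                        best[ci, cj, z] = max(best[ci, cj, z], p)
                        touched[ci, cj, z] = True
    defined = touched & mask
    return np.where(defined, best, np.nan), defined
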