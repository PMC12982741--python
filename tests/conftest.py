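import numpy as np
import pytest

import lesionmorph as lm


@pytest.fixture(scope="session")
def small_cohort_config():
    """A 60-lesion strong-imprint cohort, small enough for per-test runs."""
    return lm.default_cohort_config(seed=7, n_patients=20)


@pytest.fixture(scope="session")
def small_cohort(small_cohort_config):
    pairs, table = lm.generate_cohort(small_cohort_config)
    return pairs, table


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    pairs, table = small_cohort
    features, dropped = lm.extract_table(pairs, list(table["lesion_id"]))
    assert not dropped
    return table, features


def random_blob_mask(rng, shape=(14, 14, 14), n_seeds=3, n_grow=120):
    """Random connected blob for erosion/shape property tests."""
    mask = np.zeros(shape, dtype=bool)
    pts = [tuple(rng.integers(3, s - 3) for s in shape)]
    mask[pts[0]] = True
    for _ in range(n_grow):
        base = pts[rng.integers(len(pts))]
        step = tuple(int(v) for v in rng.integers(-1, 2, size=3))
        cand = tuple(int(np.clip(b + s, 1, dim - 2)) for b, s, dim in zip(base, step, shape))
        mask[cand] = True
        pts.append(cand)
    return mask
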