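import numpy as np
import pytest

import patchsr as ps


@pytest.fixture(scope="session")
def brain_experiment():
    """Default simulated MS brain experiment (shared by the slow end-to-end
    checks; one full PBSR run plus the three baselines)."""
    return ps.run_brain_experiment(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20170131)


def make_toy_problem(rng, lr_shape=(3, 3, 3), scale=(2, 2, 2), lesion=True):
    """Small random super-resolution problem with positive tissue coverage
    everywhere (so the anatomy weights never lose all mass)."""
    hr_shape = tuple(n * s for n, s in zip(lr_shape, scale))
    lr = ps.VolumeGrid.from_spacing(
        10.0 + rng.uniform(0, 5, size=lr_shape), (2.0, 2.0, 2.0)
    )
    hr_affine = ps.initialize_hr(lr, scale).affine
    t1 = ps.VolumeGrid(100.0 + 10.0 * rng.standard_normal(hr_shape), hr_affine)
    flair = ps.VolumeGrid(80.0 + 10.0 * rng.standard_normal(hr_shape), hr_affine)
    raw = rng.uniform(0.1, 1.0, size=(3,) + hr_shape)
    probs = ps.TissueProbMaps(raw / raw.sum(axis=0), hr_affine)
    mask = np.zeros(hr_shape, dtype=bool)
    if lesion:
        mask[: hr_shape[0] // 2, : hr_shape[1] // 2, :] = True
    lesions = ps.LesionMask(mask, hr_affine)
    return lr, t1, flair, probs, lesions
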