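import numpy as np
import pytest

from radtex.glcm import GLCMTransformer
from radtex.phantoms import PhantomConfig, generate_cohort, split_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """40-patient phantom cohort with split assigned (session-cached)."""
    patches, records = generate_cohort(PhantomConfig(n_patients=40, seed=11))
    records = split_cohort(records, seed=11)
    return patches, records


@pytest.fixture(scope="session")
def small_stacks(small_cohort):
    patches, _ = small_cohort
    return GLCMTransformer().fit(patches).transform_stacks(patches)


def brute_force_glcm(levels: np.ndarray, offset, n_levels: int) -> np.ndarray:
    """Exhaustive triple-loop pair enumeration; the GLCM ground truth."""
    M = np.zeros((n_levels, n_levels), dtype=np.int64)
    I, J, K = levels.shape
    di, dj, dk = offset
    for i in range(I):
        for j in range(J):
            for k in range(K):
                i2, j2, k2 = i + di, j + dj, k + dk
                if 0 <= i2 < I and 0 <= j2 < J and 0 <= k2 < K:
                    M[levels[i, j, k] - 1, levels[i2, j2, k2] - 1] += 1
    return M
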