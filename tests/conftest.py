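import numpy as np
import pytest

from ctradiomics.volume import DiscretizedROI


def random_roi(seed: int, shape=(6, 6, 3), ng: int = 4, p_mask: float = 0.7) -> DiscretizedROI:
    """Random small discretized ROI for oracle-equivalence tests."""
    rng = np.random.default_rng(seed)
    mask = rng.random(shape) < p_mask
    if not mask.any():
        mask[tuple(c // 2 for c in shape)] = True
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = rng.integers(1, ng + 1, size=int(mask.sum()))
    edges = np.arange(ng + 1, dtype=float)
    return DiscretizedROI(levels=levels, n_levels=ng, bin_edges=edges)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across statistical tests."""
    from ctradiomics.synthetic import generate_cohort

    cohort, truth = generate_cohort(seed=2024)
    return cohort, truth
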