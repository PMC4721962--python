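import numpy as np
import pytest

from optofmri import simulate
from optofmri.protocol import make_protocol


@pytest.fixture(scope="session")
def protocol10():
    """10 Hz, 30% duty, six 20 s trains once per minute, 30 s baseline."""
    return make_protocol(10.0, 0.30)


@pytest.fixture(scope="session")
def noiseless_scene():
    return simulate.GroundTruthScene(
        shape=(10, 10, 4),
        rois=(
            simulate.RoiSpec("pos", ((0, 4), (0, 4), (0, 2)), 2.0),
            simulate.RoiSpec("neg", ((6, 10), (6, 10), (2, 4)), -1.5),
        ),
        noise_sd_percent=0.0,
        drift_slope_percent_per_min=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_run(noiseless_scene, protocol10):
    ds, truth = simulate.gen_bold_dataset(noiseless_scene, protocol10, seed=0)
    return ds, truth


def brute_force_signed_rank_p(diffs, alternative="greater"):
    """Independent oracle: enumerate all sign assignments of |differences|."""
    from itertools import product

    from scipy.stats import rankdata

    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    ranks = rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    count = total = 0
    for signs in product([1, -1], repeat=len(diffs)):
        w = ranks[np.array(signs) > 0].sum()
        total += 1
        if alternative == "greater":
            count += w >= w_obs - 1e-12
        else:
            count += w <= w_obs + 1e-12
    return count / total


def brute_force_rank_sum_p(a, b, alternative="greater"):
    """Independent oracle: enumerate all assignments of pooled values to groups."""
    from itertools import combinations

    from scipy.stats import rankdata

    pooled = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    ranks = rankdata(pooled)
    n1 = len(a)
    w_obs = ranks[:n1].sum()
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        w = sum(ranks[i] for i in idx)
        total += 1
        if alternative == "greater":
            count += w >= w_obs - 1e-12
        else:
            count += w <= w_obs + 1e-12
    return count / total
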