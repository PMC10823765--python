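import numpy as np
import pytest

from momlme import simulate
from momlme.model_core import ObservationFrame, build_design


@pytest.fixture
def five_obs_frame():
    """Family f1 = {s1: obs 1,2; s2: obs 3}, family f2 = {s3: obs 4,5}."""
    rng = np.random.default_rng(0)
    return ObservationFrame(
        subject_id=np.array(["s1", "s1", "s2", "s3", "s3"]),
        family_id=np.array(["f1", "f1", "f1", "f2", "f2"]),
        X=rng.standard_normal((5, 2)),
    )


@pytest.fixture
def small_sim():
    """A modest simulated dataset with known ground truth."""
    structure = simulate.simulate_structure(400, seed=10)
    truth = simulate.sample_true_params(8, 3, seed=11)
    frame, Y = simulate.simulate_outcomes(truth, structure, seed=12)
    return frame, Y, truth


def random_nested_frame(rng, n_families=8, p=3):
    """Random nested family/subject structure for oracle comparisons."""
    fam, sub = [], []
    for f in range(n_families):
        for m in range(rng.integers(1, 4)):
            for _ in range(rng.integers(1, 4)):
                fam.append(f"f{f}")
                sub.append(f"f{f}_m{m}")
    fam, sub = np.array(fam), np.array(sub)
    X = rng.standard_normal((fam.shape[0], p))
    return ObservationFrame(subject_id=sub, family_id=fam, X=X)


@pytest.fixture
def nested_frame():
    return random_nested_frame(np.random.default_rng(42))


def dense_pair_design(design):
    """Oracle: kernel rows for all N(N+1)/2 pairs, by dense enumeration."""
    n = design.n_obs
    ii, jj = np.triu_indices(n)
    L = np.empty((ii.shape[0], design.n_effects + 1))
    for e, eff in enumerate(design.effects):
        L[:, e] = eff.kernel_entries(ii, jj)
    L[:, -1] = (ii == jj).astype(float)
    return ii, jj, L
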