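import numpy as np
import pytest

from foldcv import (FixtureSpec, HarvestConfig, assemble_cvs, filter_features,
                    harvest_contacts, make_topology, sample_trajectory)


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec()


@pytest.fixture(scope="session")
def system(spec):
    """(topology, folded reference frame, misfolded reference frame)."""
    return make_topology(spec)


@pytest.fixture(scope="session")
def end_states(spec):
    """Short folded and unfolded (misfolded-basin) end-state runs."""
    folded, _ = sample_trajectory(spec, "folded", n_frames=150, seed=11)
    unfolded, _ = sample_trajectory(spec, "unfolded", n_frames=150, seed=12)
    return folded, unfolded


@pytest.fixture(scope="session")
def candidate_table(end_states):
    return harvest_contacts(*end_states, HarvestConfig())


@pytest.fixture(scope="session")
def feature_set(candidate_table):
    return filter_features(candidate_table)


@pytest.fixture(scope="session")
def cvs(feature_set):
    return assemble_cvs(feature_set)


def atom_index(top, res, name):
    """Index of the unique atom `name` in residue `res`."""
    idx = top.residue_atoms(res)
    hit = idx[top.names[idx] == name]
    assert len(hit) == 1
    return int(hit[0])


def random_rotation(rng):
    from scipy.spatial.transform import Rotation
    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
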