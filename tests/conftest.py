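import numpy as np
import pytest

from indelflex.synthetic_data import TrajectorySpec, generate_trajectories


@pytest.fixture(scope="session")
def small_ensemble():
    """4 systems x 3 replicates, 200 frames, residues 153-155 deleted in del*."""
    n = 30
    ids = np.arange(1, n + 1)
    deleted = np.array([10, 11, 12])
    del_ids = ids[~np.isin(ids, deleted)]
    sigma = np.full(n, 0.5)
    spec = TrajectorySpec(
        n_residues=n, duration_ns=20.0, frame_interval_ps=100.0, n_replicates=3,
        amplitude_profile={s: sigma for s in ("wt", "del", "wtg", "delg")},
        residue_ids_per_system={"del": del_ids, "delg": del_ids},
        seed=7)
    return generate_trajectories(spec)
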