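import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import pitnet_ith as pi


@pytest.fixture(scope="session")
def phantom_cohort():
    """Four textured 3-habitat phantoms with local feature maps.

    Shared by the habitat-recovery tests; building the per-voxel maps is
    the expensive step, so it is done once per session.  Returns a list of
    dicts with the phantom, its voxel map, planted labels per kept voxel,
    and a "pure window" flag (3x3x3 neighborhood entirely inside one
    habitat).
    """
    cohort = []
    for s in range(4):
        spec = pi.PhantomSpec(shape=(16, 16, 16), n_habitats=3, seed=100 + s)
        vol, mask, labels = pi.simulate_tumor_phantom(spec)
        vmap = pi.local_feature_maps(vol, mask, patient_id=s)
        truth = labels[tuple(vmap.voxel_indices.T)]
        m = mask.data
        pure = []
        for (z, y, x), t in zip(vmap.voxel_indices, truth):
            sl = tuple(
                slice(max(c - 1, 0), min(c + 2, n)) for c, n in zip((z, y, x), m.shape)
            )
            pure.append(bool((labels[sl][m[sl]] == t).all()))
        cohort.append(
            {
                "spec": spec,
                "volume": vol,
                "mask": mask,
                "labels": labels,
                "map": vmap,
                "truth": truth,
                "pure": np.array(pure),
            }
        )
    return cohort


@pytest.fixture(scope="session")
def habitat_model(phantom_cohort):
    return pi.fit_population_kmeans(
        [c["map"] for c in phantom_cohort], seed=0, k_override=3
    )
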