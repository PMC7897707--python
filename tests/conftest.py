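import numpy as np
import pytest

from scaffoldcount import (
    fuse_zstack,
    generate_scene,
    render_stack,
    segment_nuclei,
)

N_RECOVERY_SCENES = 50
NUCLEI_PER_SCENE = 50


@pytest.fixture(scope="session")
def recovery_counts():
    """Full-pipeline nucleus counts on seeded synthetic scenes.

    For each seed: generate a 50-nucleus scene under default imaging
    conditions (six planes over 530 um, moderate noise), render both
    channels, fuse the total channel and segment. Returns a list of
    (detected_count, true_count) pairs. Session-scoped because several
    tests measure different properties of the same study conditions.
    """
    results = []
    for seed in range(N_RECOVERY_SCENES):
        scene = generate_scene(NUCLEI_PER_SCENE, seed=seed)
        total, _ = render_stack(scene)
        objects, _ = segment_nuclei(fuse_zstack(total))
        results.append((len(objects), len(scene.nuclei)))
    return results


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
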