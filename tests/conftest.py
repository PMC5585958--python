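import numpy as np
import pytest

import mirset as ms


@pytest.fixture
def tiny_tables():
    """Hand-built instance small enough to reason about by eye.

    Universe (sorted): g1..g5. Targets:
      mir-a -> {g1, g3}; mir-b -> {g2, g3}; mir-c -> {g4}; mir-d -> {g1, g5}
    Categories: GO:1 = {g1, g2} 'alpha'; GO:2 = {g4} 'beta'; GO:3 = {g5, gX}
    (gX only annotated, never targeted).
    """
    inter = ms.InteractionTable(
        [("mir-a", "g1"), ("mir-a", "g3"), ("mir-b", "g2"), ("mir-b", "g3"),
         ("mir-c", "g4"), ("mir-d", "g1"), ("mir-d", "g5")]
    )
    ann = ms.AnnotationTable(
        [("g1", "GO:1", "alpha"), ("g2", "GO:1", "alpha"),
         ("g4", "GO:2", "beta"), ("g5", "GO:3", "gamma"), ("gX", "GO:3", "gamma")]
    )
    return inter, ann


@pytest.fixture(scope="session")
def small_scenario():
    """Mid-size generated scenario reused by read-only tests."""
    cfg = ms.ScenarioConfig(
        n_mirnas=80,
        n_genes=1000,
        n_categories=15,
        query_size=5,
        seed=42,
        target_count_law=ms.TargetCountLaw(
            log_mean=np.log(25), log_sd=1.0, min_targets=5, max_targets=300
        ),
    )
    return ms.generate_scenario(cfg)
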