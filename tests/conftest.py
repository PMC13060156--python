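import numpy as np
import pytest

from citherm import simulate as sim


@pytest.fixture
def small_design():
    """Two strains x two temperatures x {compatible, ci}, 30 replicates."""
    return sim.build_design({
        "strains": ["A", "B"],
        "temperatures": [18.0, 23.0],
        "cross_types": ["compatible", "ci"],
        "replicates_per_cell": 30,
    })


@pytest.fixture
def flat_params():
    """No overdispersion, no zero inflation; logit-0 hatch everywhere."""
    def _make(design, seed=0, **overrides):
        params = sim.SimParams(seed=seed, olre_sigma=0.0, zi_prob=0.0,
                               **overrides)
        params.cell_logit_mean = {cell: 0.0 for cell in design.cells}
        return params
    return _make


def recovery_design(n_cells=12, reps=30):
    """Design + generating parameters for ZIB parameter-recovery studies."""
    design = sim.build_design({
        "strains": ["s1", "s2"],
        "temperatures": [18.0, 23.0],
        "cross_types": ["compatible", "ci", "rescue"],
        "replicates_per_cell": reps,
    })
    rng = np.random.default_rng(12345)
    logits = {cell: float(rng.uniform(-1.5, 1.5)) for cell in design.cells}
    assert len(logits) == n_cells
    return design, logits
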