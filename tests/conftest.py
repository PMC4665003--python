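import numpy as np
import pytest

from ltrcage.io_formats import GenomeLayout
from ltrcage.simulate import SimulationPlan, SubfamilySpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_small_plan(seed: int = 0, **overrides) -> SimulationPlan:
    """A minutes-to-seconds cohort for generator and pipeline tests."""
    subfamilies = [
        SubfamilySpec("LTR12C-like", "LTR", 30, 800, 1200),
        SubfamilySpec("LTR7-like", "LTR", 15, 400, 500),
        SubfamilySpec("HERVH-int-like", "LTR", 6, 1500, 2500),
        SubfamilySpec("L1-full-like", "LINE", 8, 6000, 6500),
        SubfamilySpec("Alu-like", "SINE", 40, 280, 320),
        SubfamilySpec("SVA-like", "SVA", 8, 1000, 1400),
    ]
    defaults = dict(
        genome=GenomeLayout(("chrA", "chrB"), (2_000_000, 2_000_000)),
        n_tumor=8, n_nontumor=8, n_normal=2,
        n_coding_genes=40, subfamilies=subfamilies,
        n_activated=20, n_weak_activated=10, n_background_distal=40,
        n_divergent=10, n_line_antisense=5, seed=seed,
    )
    defaults.update(overrides)
    return SimulationPlan(**defaults)


@pytest.fixture
def small_plan():
    return make_small_plan(seed=11)
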