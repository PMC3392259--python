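import numpy as np
import pytest

import feaspace as fs


@pytest.fixture(scope="session")
def toy():
    return fs.build_toy_model()


@pytest.fixture(scope="session")
def mapped_set(toy):
    """A moderately sized mapped toy sample shared across test modules."""
    cfg = fs.SamplingConfig(n_samples=800, seed=42)
    return fs.map_to_physiology(fs.sample_enzyme_levels(cfg, toy), toy)


@pytest.fixture(scope="session")
def viability(mapped_set):
    return fs.apply_all_constraints(mapped_set, fs.ConstraintConfig())


@pytest.fixture(scope="session")
def scores(mapped_set, viability):
    return fs.classify_and_combine(fs.score_objectives(mapped_set, viability),
                                   fs.ObjectiveConfig())


def toy_steady_state_closed_form(r):
    """Independent closed-form oracle for the toy pathway steady state.

    Solving the two mass balances by hand: z1 = 2(r1-r2)/(r1+r2), the
    pathway flux is the harmonic mean J = 2 r1 r2/(r1+r2), and
    z2 = 2(J/r3 - 1).  Valid for the default fixture (no extra links).
    """
    r1, r2, r3 = r
    z1 = 2.0 * (r1 - r2) / (r1 + r2)
    J = 2.0 * r1 * r2 / (r1 + r2)
    z2 = 2.0 * (J / r3 - 1.0)
    x = np.exp([z1, z2])
    return x, np.array([J, J, J])
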