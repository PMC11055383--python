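import numpy as np
import pytest

import jointdemux as jd


@pytest.fixture(scope="session")
def small_cfg() -> jd.SimConfig:
    """Reduced-size study conditions used by most unit tests."""
    return jd.SimConfig(
        n_donors=4,
        n_variants=120,
        n_private_per_donor=25,
        n_cells=1200,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_experiment(small_cfg) -> jd.Experiment:
    return jd.simulate_experiment(small_cfg)


@pytest.fixture(scope="session")
def small_joint(small_experiment):
    exp = small_experiment
    m = jd.match_methods(exp.genetic_table, exp.hashing_table, exp.config.n_donors)
    joint = jd.joint_assign(exp.hashing_table, exp.genetic_table, m)
    return m, joint


def phi_contingency(x: np.ndarray, y: np.ndarray) -> float:
    """Independent oracle: 2x2 contingency-table phi coefficient."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    n11 = int(np.sum(x & y))
    n10 = int(np.sum(x & ~y))
    n01 = int(np.sum(~x & y))
    n00 = int(np.sum(~x & ~y))
    den = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    if den == 0:
        return 0.0
    return (n11 * n00 - n10 * n01) / np.sqrt(den)


@pytest.fixture(scope="session")
def toy_tables():
    """Hand-built hashing/genetic tables with a known donor map."""
    genetic = jd.AssignmentTable(
        "vireo_like",
        "genetic",
        {
            "c1": jd.singlet("donor0"),
            "c2": jd.singlet("donor1"),
            "c3": jd.singlet("donor0"),
            "c4": jd.singlet("donor1"),
            "c5": jd.doublet(),
            "c6": jd.negative(),
            "c7": jd.singlet("donor0"),
            "c8": jd.singlet("donor1"),
        },
    )
    hashing = jd.AssignmentTable(
        "multiseq_like",
        "hashing",
        {
            "c1": jd.singlet("H2"),
            "c2": jd.singlet("H1"),
            "c3": jd.singlet("H2"),
            "c4": jd.singlet("H1"),
            "c5": jd.doublet(),
            "c6": jd.singlet("H1"),
            "c7": jd.negative(),
            "c8": jd.negative(),
        },
    )
    # donor0 -> H2, donor1 -> H1 by construction
    return genetic, hashing
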