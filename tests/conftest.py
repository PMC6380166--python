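import numpy as np
import pytest

import refstab as rs


@pytest.fixture(scope="session")
def design45():
    """The default 5 treatments x 3 times x 3 replicates factorial design."""
    return rs.generate_design()


@pytest.fixture
def worked_cq():
    """Hand-checkable 3-gene x 4-sample Cq matrix, all efficiencies 2.

    g1 and g2 differ by a constant 0.1 cycles (perfectly proportional
    quantities); g3 swaps two samples, giving pairwise log-ratio SD
    sqrt(2/3) against both.
    """
    design = rs.generate_design(["C"], [1], 4)
    cq = np.array(
        [
            [20.0, 21.0, 22.0, 23.0],
            [20.1, 21.1, 22.1, 23.1],
            [20.0, 22.0, 21.0, 23.0],
        ]
    )
    return rs.CqMatrix(["g1", "g2", "g3"], design, cq, {g: 2.0 for g in ["g1", "g2", "g3"]})


@pytest.fixture(scope="session")
def scenario_specs():
    """Default ground-truth panel: 3 stable, 8 responsive, 3 noisy genes."""
    return rs.default_scenario()


def random_cq(n_genes, n_samples, seed, lo=16.0, hi=26.0, efficiency=None):
    """A random Cq matrix over a single-treatment design (test helper).

    Per-gene efficiencies are drawn in [1.9, 2.1] unless a common value
    is given.
    """
    rng = np.random.default_rng(seed)
    design = rs.generate_design(["C"], [1], n_samples)
    cq = rng.uniform(lo, hi, size=(n_genes, n_samples))
    genes = [f"g{i}" for i in range(n_genes)]
    if efficiency is None:
        eff = {g: float(e) for g, e in zip(genes, rng.uniform(1.9, 2.1, n_genes))}
    else:
        eff = {g: float(efficiency) for g in genes}
    return rs.CqMatrix(genes, design, cq, eff)
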