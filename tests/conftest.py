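import numpy as np
import pytest

import crmscan as c


@pytest.fixture(scope="session")
def library():
    """Default synthetic library: 6 true + 4 decoy families, seed 1."""
    return c.build_pwm_library(seed=1)


@pytest.fixture(scope="session")
def thresholds(library):
    """Calibrated optimized thresholds for the default library."""
    return c.calibrate_library(library, seed=1001)


@pytest.fixture(scope="session")
def planted_set(library, thresholds):
    """One positive ortholog set (seed 7) with its scan results."""
    regs, truth = c.simulate_ortholog_promoters(library, c.PlantSpec(seed=7))
    hits = {
        r.species: c.scan_sequence(library, r.sequence, thresholds=thresholds)
        for r in regs
    }
    return regs, truth, hits


def toy_pwm(counts, name="toy", family="TOY", pseudocount=c.pwm.DEFAULT_PSEUDOCOUNT):
    return c.PWM(name, family, np.asarray(counts), pseudocount=pseudocount)
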