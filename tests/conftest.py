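import numpy as np
import pytest

from pbmotif.probeio import Probe, ProbeSet
from pbmotif.simulate import synthetic_probes


@pytest.fixture
def toy_probes() -> ProbeSet:
    return ProbeSet((
        Probe("p1", "ACGTACGT", 0.1),
        Probe("p2", "TTTTGTCA", 0.8),
        Probe("p3", "GGGTCCCA", 0.5),
    ))


@pytest.fixture
def random_probes() -> ProbeSet:
    """120 random 30-nt probes with uniform random signals."""
    ps = synthetic_probes(120, 30, seed=42)
    rng = np.random.default_rng(43)
    return ps.with_signals(rng.uniform(0.01, 1.0, len(ps)))


@pytest.fixture
def planted_probes():
    """(probes, true_matrix): 300 random 30-nt probes whose signals are exact
    model occupancies of a known 3-nt motif (noiseless planted dataset)."""
    from pbmotif.regressor import BindingModel
    from pbmotif.simulate import random_motif

    ps = synthetic_probes(300, 30, seed=7)
    m = random_motif(3, 4.0, seed=8)
    model = BindingModel(ps, motif_length=3)
    m = model.calibrate_dG0(m, 1.2)
    return ps.with_signals(model.predict(m)), m
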