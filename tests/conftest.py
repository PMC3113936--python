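import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def short_gene():
    """A 30-codon random gene with E. coli codon usage."""
    from prokexpress import generate_random_gene

    return generate_random_gene(30, seed=101)


@pytest.fixture
def fast_gene():
    """Uniform fast (class A) codons: analytically tractable translation."""
    from prokexpress import GeneSequence

    return GeneSequence("GCG" * 29 + "TAA", name="uniform_fast")


def drain(sim, t_step=5000.0, max_t=2_000_000.0):
    """Switch off new initiations and run until the system is empty."""
    sim.k_eff_multiplier = 0.0
    sim.engine.recompute("promoter")
    while (sim.compartments or sim.rnaps or sim.n_oc_pending
           or sim.waiting_rnap is not None):
        if sim.engine.time > max_t:
            raise AssertionError("system failed to drain")
        sim.run(sim.engine.time + t_step, sample_interval=t_step)
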