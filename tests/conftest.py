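import numpy as np
import pytest

from bayesmmi.model_space import (
    CandidateModel,
    InitiationScheme,
    RuleSpec,
    Topology,
)


def make_candidate(subtypes, transitions=(), initiators=None, effects=None):
    """Hand-build a candidate: division+death for every subtype plus the
    given transitions; ``effects`` maps rule positions to an effect scheme."""
    rules = []
    for s in subtypes:
        rules.append(RuleSpec(kind="division", subject=s))
        rules.append(RuleSpec(kind="death", subject=s))
    hier = {("A", "N"), ("A", "A2"), ("N", "Y"), ("A2", "Y")}
    for a, b in transitions:
        rules.append(
            RuleSpec(
                kind="transition",
                subject=a,
                target=b,
                hierarchy="hierarchical" if (a, b) in hier else "non_hierarchical",
            )
        )
    return CandidateModel(
        topology=Topology(subtypes=tuple(subtypes)),
        a2_class="NE" if "A2" in subtypes else "not_present",
        rules=tuple(rules),
        initiation=InitiationScheme(initiators=tuple(initiators or subtypes)),
    )


@pytest.fixture
def ay_candidate():
    """Two-subtype growth model: A divides/dies/converts to Y, Y divides/dies."""
    return make_candidate(("A", "Y"), transitions=[("A", "Y")], initiators=("A",))


@pytest.fixture
def ay_params():
    """Rates with a 0.15/day spectral gap: steady state ~(0.65, 0.35)."""
    return {
        "k_div_A": 0.45,
        "k_die_A": 0.05,
        "k_div_Y": 0.22,
        "k_die_Y": 0.05,
        "k_tr_A_Y": 0.08,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
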