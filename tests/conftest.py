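import numpy as np
import pytest

from divergenome import ScenarioSpec, SelectionSpec
from divergenome.jcmut import HaplotypeAlignment


@pytest.fixture
def tiny_spec():
    """Small, fast scenario: N=1000, 10+10 samples, 10 kb, scaled rates."""
    return ScenarioSpec(
        label="tiny",
        N_e=1000,
        seq_length_bp=10_000,
        mu=5e-6,
        rec=1e-5,
    )


@pytest.fixture
def toy_alignment():
    """4+4 toy alignment with known per-site structure (L=6).

    Site 0: fixed difference A/T.  Site 1: monomorphic.  Site 2: shared
    polymorphism at equal frequencies.  Site 3: private polymorphism in
    pop1.  Site 4: fixed difference C/G.  Site 5: polymorphism in pop2.
    """
    seqs = [
        "AACACA",
        "AACACA",
        "AATTCA",
        "AATTCA",
        "TACAGA",
        "TACAGA",
        "TATAGC",
        "TATAGC",
    ]
    return HaplotypeAlignment.from_strings(seqs, ["p1"] * 4 + ["p2"] * 4)


@pytest.fixture
def selection_spec():
    return SelectionSpec(s_hom=0.01, s_het=0.005, s_other=0.0)
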