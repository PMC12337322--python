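import numpy as np
import pytest

import duplexmeth as dm
from duplexmeth.align import call_sites
from duplexmeth.extract import extract_quads
from duplexmeth.simulate import ChemistryErrorModel, simulate_reads


@pytest.fixture(scope="session")
def zero_errors():
    return ChemistryErrorModel.zero()


@pytest.fixture(scope="session")
def small_methylome():
    """20 kb single-contig methylome with the default state composition."""
    ref = dm.generate_reference(1, 20_000, 0.02, seed=101)
    return dm.assign_states(ref, dm.DEFAULT_STATE_FRACTIONS, seed=102)


@pytest.fixture(scope="session")
def panel():
    return dm.build_spikein_panel(seed=11)


@pytest.fixture(scope="session")
def zero_sim(small_methylome, zero_errors):
    """Error-free simulated run: (pairs, pair truth, call truth)."""
    return simulate_reads(small_methylome, 2000, zero_errors, seed=103)


@pytest.fixture(scope="session")
def zero_quads(zero_sim):
    pairs, _, _ = zero_sim
    quads, summary = extract_quads([(p.name, p.r1, p.r2) for p in pairs])
    return quads, summary


@pytest.fixture(scope="session")
def zero_sites(zero_quads, small_methylome):
    quads, _ = zero_quads
    return call_sites(quads, small_methylome.reference)
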