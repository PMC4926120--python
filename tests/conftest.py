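"""Shared fixtures: simulated libraries and the packaged reference oligo sets."""

import pytest

from barcodiag.fixtures import SimSpec, simulate_library
from barcodiag.seqio import (
    PrimerRecord,
    ProbeRecord,
    reference_specific_primers,
    reference_taqman_sets,
)


@pytest.fixture(scope="session")
def sim_library():
    """Six species x four sequences at the study's divergence regime."""
    return simulate_library(SimSpec(seed=101))


@pytest.fixture(scope="session")
def sim_matrix(sim_library):
    from barcodiag.distances import pairwise_matrix

    return pairwise_matrix(sim_library.alignment)


@pytest.fixture(scope="session")
def ref_primers():
    """The 12 published endpoint-PCR primers (six pairs)."""
    return reference_specific_primers()


@pytest.fixture(scope="session")
def ref_pairs(ref_primers):
    forwards = [p for p in ref_primers if p.orientation == "forward"]
    reverses = [p for p in ref_primers if p.orientation == "reverse"]
    return list(zip(forwards, reverses))


@pytest.fixture(scope="session")
def ref_taqman():
    """The 12 published qPCR primers and 6 probes."""
    oligos = reference_taqman_sets()
    primers = [o for o in oligos if isinstance(o, PrimerRecord)]
    probes = [o for o in oligos if isinstance(o, ProbeRecord)]
    return primers, probes
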