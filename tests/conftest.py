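import numpy as np
import pytest

from satellitome import (
    FamilySpec,
    RunConfig,
    default_family_specs,
    run_pipeline,
    simulate_study,
)
from satellitome.config import FAMILY_TABLE


@pytest.fixture(scope="session")
def specs():
    """The eight realized family specs (fixed generator seed)."""
    return default_family_specs(0)


@pytest.fixture(scope="session")
def spec_by_id(specs):
    return {s.family_id: s for s in specs}


@pytest.fixture(scope="session")
def study_sim():
    """One full seven-genome study simulation (seed 1)."""
    return simulate_study(1)


@pytest.fixture(scope="session")
def study_result(study_sim):
    """Full pipeline run on the seed-1 study simulation."""
    _, _, genomes = study_sim
    return run_pipeline(
        {sp: g[0] for sp, g in genomes.items()}, reference_species="C_acuminatum"
    )


def map_families_to_truth(families):
    """Map discovered families to the seeded ones by conserved-motif identity.

    A discovered family matches a seeded family when the seeded motif occurs
    in the discovered (circular) consensus.  Returns {discovered_id:
    seeded_id}; unmatched or ambiguous families are omitted.
    """
    mapping = {}
    for fam in families:
        circ = fam.consensus + fam.consensus
        matches = [
            fid
            for fid, (mlen, motif, *_rest) in FAMILY_TABLE.items()
            if motif in circ
        ]
        if len(matches) == 1:
            mapping[fam.family_id] = matches[0]
    return mapping
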