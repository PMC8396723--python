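"""Shared fixtures: synthetic families at two scales.

The full-scale family uses the generator's default study conditions
(~150 kb genomes, ten taxa); the small family uses the mini roster for
fast structural tests.
"""

from __future__ import annotations

import pytest

from plastomma.synthetic import (
    FamilyConfig,
    generate_family,
    make_plastome,
    mini_roster,
)


@pytest.fixture(scope="session")
def family():
    """Ten-taxon family under default (study-scale) conditions."""
    return generate_family(seed=11)


@pytest.fixture(scope="session")
def family_records(family):
    return family[0]

@pytest.fixture(scope="session")
def family_truth(family):
    return family[1]


@pytest.fixture(scope="session")
def small_family():
    """Five-taxon mini family (fast; ~16 kb genomes)."""
    config = FamilyConfig(
        n_taxa=5,
        lsc_len=7_000,
        ir_len=3_000,
        ssc_len=4_200,
        roster=mini_roster(),
        n_ssr_loci=4,
        ycf1_ir_overlap=400,
        min_gap=100,
    )
    return generate_family(config, seed=5)


@pytest.fixture(scope="session")
def mini_record_type1():
    return make_plastome("I", seed=2)


@pytest.fixture(scope="session")
def mini_record_type2():
    return make_plastome("II", seed=2)


@pytest.fixture(scope="session")
def mini_record_type3():
    return make_plastome("III", seed=2)
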