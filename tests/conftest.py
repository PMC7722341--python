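"""Shared fixtures: all test data is generated programmatically."""

import pytest

import nimtscan as ns


@pytest.fixture(scope="session")
def template():
    return ns.default_mito_template()


@pytest.fixture(scope="session")
def zero_rate_truth():
    """Simulation with all substitution rates zero: copies are exact."""
    params = ns.EvolutionParams(seed=3, sn=0, sp=0, st=0, n_insertions=6,
                                nuclear_length=25_000,
                                min_trnas_per_insertion=1,
                                functional_fraction=0)
    return ns.simulate(params)


@pytest.fixture(scope="session")
def evolved_truth():
    """A moderately diverged simulation used by several stages."""
    params = ns.EvolutionParams(seed=11, sn=0.02, sp=0.08, n_insertions=12,
                                nuclear_length=40_000,
                                min_trnas_per_insertion=1)
    return ns.simulate(params)


def perfect_hits(truth):
    """Hits exactly at the truth MTL loci (a perfect detector stand-in)."""
    return [ns.MtlHit(m.nuclear, m.isotype, 100.0, "builtin")
            for m in truth.mtls]
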