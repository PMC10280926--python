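"""Shared fixtures: synthetic artifacts reused across test modules."""

import pytest

from holobin.synthetic import (
    HolobiontSpec,
    generate_holobiont,
    generate_protein_panel,
)

TEN_SPECIES_GENUS_MAP = {
    f"Genus{g}_sp{s}": f"Genus{g}" for g in range(1, 6) for s in (1, 2)
}


@pytest.fixture(scope="session")
def zero_noise_holobiont():
    """A holobiont with no coverage noise and perfect gene labels."""
    spec = HolobiontSpec(
        seed=11,
        coverage_noise_sd=0.0,
        tax_label_error_rate=0.0,
        symbiont_len=200_000,
        host_n_scaffolds=20,
    )
    return generate_holobiont(spec)


@pytest.fixture(scope="session")
def default_holobiont():
    """A holobiont at the default (noisy) study-like conditions, scaled."""
    spec = HolobiontSpec(seed=7, symbiont_len=300_000, host_n_scaffolds=20)
    return generate_holobiont(spec)


@pytest.fixture(scope="session")
def small_panel():
    """A 30-family protein panel with absences and decoys."""
    return generate_protein_panel(
        30, ortholog_identity=0.8, decoy_identity=0.3, seed=5, present_fraction=0.8
    )
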