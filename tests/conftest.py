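from __future__ import annotations

import pytest

from epr.observations import ObservationId, build_matrix
from epr.synthetic import SyntheticConfig, generate


def obs(i: int) -> ObservationId:
    """Shorthand valid observation id for toy fixtures."""
    return ObservationId(family=f"GH{i}", function=f"3.2.1.{i}")


def toy_matrix(presence: dict[str, set[ObservationId]]):
    return build_matrix(presence)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but structured dataset: 1 phylum, 2 genera, 4 sections, 12 genomes."""
    config = SyntheticConfig(
        n_phyla=1,
        genera_per_phylum=2,
        sections_per_genus=2,
        species_per_section=3,
        universe_size=80,
        core_size=8,
        section_signature_size=10,
        species_extra_rate=0.02,
        seed=11,
    )
    return generate(config)


@pytest.fixture(scope="session")
def clean_dataset():
    """Zero-corruption dataset: pipeline output must equal ground truth."""
    config = SyntheticConfig(
        n_phyla=1,
        genera_per_phylum=2,
        sections_per_genus=2,
        species_per_section=3,
        universe_size=80,
        core_size=8,
        section_signature_size=10,
        species_extra_rate=0.0,
        noise_flip_prob=0.0,
        indecisive_fraction=0.0,
        nonsecreted_fraction=0.0,
        seed=5,
    )
    return generate(config)
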