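import numpy as np
import pandas as pd
import pytest

from dslst import (
    CommunitySpec,
    CountTable,
    SampleMetadata,
    TaxonomyTable,
    generate_community,
)


@pytest.fixture
def tiny_table() -> CountTable:
    return CountTable(
        ["A1", "A2", "A3"],
        ["S1", "S2"],
        np.array([[4, 0], [2, 3], [2, 7]]),
    )


@pytest.fixture
def tiny_taxonomy() -> TaxonomyTable:
    return TaxonomyTable(
        {
            "A1": ("Bacteria", "Proteobacteria", "Alpha", "Rhodobacterales", "F", "G1"),
            "A2": ("Bacteria", "Cyanobacteria", "Oxy", "Chloroplast", "F", "G2"),
            "A3": ("Archaea", "Thaumarchaeota", "Nitroso", "Nitrosopumilales", "F", "G3"),
        }
    )


@pytest.fixture
def tiny_metadata() -> SampleMetadata:
    frame = pd.DataFrame(
        {
            "station": ["ST1", "ST1"],
            "season": ["spring", "spring"],
            "layer": ["SURF", "DSL"],
            "profile_id": ["P1", "P1"],
            "depth_m": [5.0, 520.0],
        },
        index=pd.Index(["S1", "S2"], name="sample_id"),
    )
    return SampleMetadata(frame)


def random_count_table(rng: np.random.Generator, n_asvs=12, n_samples=6,
                       max_count=20) -> CountTable:
    counts = rng.integers(0, max_count + 1, size=(n_asvs, n_samples))
    # guarantee no all-zero samples
    counts[rng.integers(0, n_asvs), :] += 1
    return CountTable(
        [f"A{i}" for i in range(n_asvs)],
        [f"S{j}" for j in range(n_samples)],
        counts,
    )


@pytest.fixture(scope="session")
def default_community():
    """One medium-sized community shared by read-only tests."""
    spec = CommunitySpec(depth=20_000, seed=11)
    return generate_community(spec)


@pytest.fixture(scope="session")
def spring_only_spec() -> CommunitySpec:
    """Planted DSL fractions: 20% unique, 15% enriched, 10% EPI-shared."""
    return CommunitySpec(
        n_surface_specialist=10,
        n_dcm_specialist=5,
        n_mesopelagic_generalist=110,
        n_dsl_unique=40,
        n_dsl_enriched=30,
        n_seasonal_indicator=0,
        n_cosmopolitan=20,
        n_profiles=5,
        seasons=("spring",),
        season_layers={"spring": ("SURF", "DCM", "MS", "DSL", "MD")},
        enrichment_fold=10.0,
        depth=50_000,
        seed=0,
    )
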