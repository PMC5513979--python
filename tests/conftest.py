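import numpy as np
import pandas as pd
import pytest

from orthostress import (
    CountTable,
    AnnotationTable,
    OrthologMap,
    PipelineConfig,
    PlantedConservedSpec,
    SimulationConfig,
    generate_experiment,
)

FOCAL = ("dia1", "hap1", "hap2")


@pytest.fixture(scope="session")
def small_sim_config() -> SimulationConfig:
    """Three focal species, a handful of planted conserved orthologs."""
    return SimulationConfig(
        species=FOCAL,
        dino_species=(),
        n_core=150,
        n_shared=100,
        n_unique_per_species=50,
        conserved_planted=(
            PlantedConservedSpec(10, FOCAL, ("lowP",), "down", 2.0, baseline=100.0),
        ),
        seed=3,
    )


@pytest.fixture(scope="session")
def small_bundle(small_sim_config):
    return generate_experiment(small_sim_config)


@pytest.fixture()
def pipeline_config() -> PipelineConfig:
    return PipelineConfig(seed=0).validate()


@pytest.fixture()
def toy_count_table() -> CountTable:
    counts = pd.DataFrame(
        {"replete": [50, 30, 0, 20], "lowN": [10, 60, 0, 20], "lowP": [40, 30, 0, 20]},
        index=pd.Index(["c1", "c2", "c3", "c4"], name="contig_id"),
    )
    return CountTable(species_id="spA", counts=counts)


@pytest.fixture()
def toy_annotation() -> AnnotationTable:
    df = pd.DataFrame(
        {
            "length_bp": [500, 1000, 300, 800],
            "kegg_ko": ["K00001", "K00002", "", "K00003"],
            "kegg_module": ["M00001", "M00002", "", "M00001"],
            "function_label": ["a", "b", "", "c"],
        },
        index=pd.Index(["c1", "c2", "c3", "c4"], name="contig_id"),
    )
    return AnnotationTable(df)


@pytest.fixture()
def toy_ortholog_map() -> OrthologMap:
    return OrthologMap.from_frame(
        pd.DataFrame(
            [
                ("OG1", "spA", "c1"),
                ("OG1", "spA", "c2"),
                ("OG1", "spB", "d1"),
                ("OG2", "spA", "c4"),
            ],
            columns=["ortholog_id", "species_id", "contig_id"],
        )
    )
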