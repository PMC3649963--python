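import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import darscan as ds
from darscan.synthetic import (
    ChipFactorSpec,
    DatasetSpec,
    MotifPlantSpec,
    StudyConfig,
    subfamily_name,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_config(**overrides) -> StudyConfig:
    """A reduced study: 2 x 400 kb chromosomes, 10 subfamilies, 7 datasets."""
    base = dict(
        chrom_sizes={"chr1": 400_000, "chr2": 400_000},
        n_subfamilies=10,
        instances_per_subfamily=(40, 80),
        instance_length=(100, 200),
        n_genes=80,
        datasets=[
            DatasetSpec("H7esc", "hESC", "hESC", "UW", 250),
            DatasetSpec("H1esc", "hESC", "hESC", "Duke", 220),
            DatasetSpec("K562", "Leukemia", "Leukemia", "UW", 300),
            DatasetSpec("NHLF", "Fibroblast", "Fibroblast", "UW", 200),
            DatasetSpec("SAEC", "Epithelial", "Epithelial", "UW", 230),
            DatasetSpec("GM12865", "Lymphoblastoid", "Lymphoblastoid", "Duke", 220),
            DatasetSpec("HeLa-S3", "Solid_tumor", "Solid_tumor", "Duke", 240),
            DatasetSpec("HCM", "Muscle", "Muscle", "Duke", 200),
        ],
        enrichment={
            (subfamily_name(0), "hESC"): 8.0,
            (subfamily_name(1), "Leukemia"): 6.0,
        },
        chip_factors=[ChipFactorSpec("OCT4", "hESC", (subfamily_name(0),), 0.8, 60)],
        motif_plants=[MotifPlantSpec("MOTIF_A", subfamily_name(0), 0.6)],
        n_decoy_motifs=1,
        n_dsqtls=150,
        master_seed=11,
    )
    base.update(overrides)
    return StudyConfig(**base)


@pytest.fixture(scope="session")
def small_bundle():
    return ds.generate_study(small_config())


@pytest.fixture(scope="session")
def small_dar_output(small_bundle):
    config = ds.DARCallConfig(n_random=50_000, seed=7)
    return ds.call_dars(
        small_bundle.datasets,
        small_bundle.repeats,
        small_bundle.genes,
        small_bundle.chrom_sizes,
        config,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
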