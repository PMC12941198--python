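import numpy as np
import pytest

from sinetails.formats_io import GenomicInterval, SINEAnnotation
from sinetails.synthetic_fixtures import PlantSpec, plant_genome, synthetic_default_library


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture(scope="session")
def library():
    return synthetic_default_library()


@pytest.fixture(scope="session")
def planted_clean():
    """Zero-divergence planted genome: one copy of several categories, both strands."""
    specs = [
        PlantSpec(subfamily="SINEA1", category="A-rich", tail_length=20, strand="+"),
        PlantSpec(subfamily="SINEA2", category="(AAAT)n", tail_length=24, strand="-"),
        PlantSpec(subfamily="SINEB1", category="(AC)n", tail_length=18, strand="+"),
        PlantSpec(subfamily="SINEC1", category="AG-composite", tail_length=22, strand="-"),
        PlantSpec(subfamily="SINEA3", category="Other", tail_length=25, strand="+"),
    ]
    return plant_genome(specs, genome_len=8000, seed=11)


def make_annotation(chrom="chr1", start=100, end=400, strand="+",
                    subfamily="SINEA1", divergence=0.0, element_id="e1"):
    return SINEAnnotation(
        interval=GenomicInterval(chrom, start, end, strand),
        subfamily=subfamily,
        divergence_D=divergence,
        element_id=element_id,
    )
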