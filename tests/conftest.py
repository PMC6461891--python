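from __future__ import annotations

from dataclasses import dataclass

import pytest

from nmsrna import synth
from nmsrna.io import GenomeAnnotation, ReadInterval
from nmsrna.loci import SRNALocus
from nmsrna.pipeline import run_pipeline
from nmsrna.synth import PlantedLocus, SimulationConfig, SyntheticTruth


@dataclass
class SimData:
    config: SimulationConfig
    annotation: GenomeAnnotation
    truth: SyntheticTruth
    reads: dict[str, list[ReadInterval]]


def locus_matches_planted(locus: SRNALocus, planted: PlantedLocus) -> bool:
    """A called locus recovers a planted one when it covers at least half of
    the planted interval on the same strand."""
    ov = min(locus.end, planted.end) - max(locus.start, planted.start)
    return locus.strand == planted.strand and ov >= 0.5 * (planted.end - planted.start)


@pytest.fixture(scope="session")
def sim42() -> SimData:
    """The default synthetic data set at seed 42."""
    cfg = SimulationConfig(seed=42)
    ann, truth = synth.generate_genome(cfg)
    reads = synth.simulate_libraries(ann, truth, cfg)
    return SimData(cfg, ann, truth, reads)


@pytest.fixture(scope="session")
def pipeline42(sim42: SimData):
    """Full pipeline result on the default synthetic data set."""
    return run_pipeline(
        sim42.annotation,
        sim42.reads,
        sim42.config.manifest(),
        sim42.truth.target_records(),
    )
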