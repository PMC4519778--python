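import numpy as np
import pandas as pd
import pytest

from ateseq.annotation import TranscriptModel
from ateseq.simulate import (
    SimulationConfig,
    make_metadata,
    simulate_annotation,
    simulate_counts,
)


def make_transcript(exons, strand="+", tid="t", gid="g", cds=None, chrom="chr1"):
    return TranscriptModel(
        transcript_id=tid, gene_id=gid, chrom=chrom, strand=strand,
        exons=list(exons), cds=list(cds) if cds else None,
    )


@pytest.fixture(scope="session")
def metadata():
    """The default 2x2 sample sheet: 5 MDM + 4 IPSDM donors, both treatments."""
    return make_metadata(SimulationConfig())


@pytest.fixture(scope="session")
def small_simulation():
    """A 60-gene simulated cohort shared across tests."""
    cfg = SimulationConfig(n_genes=60, seed=7)
    genes, truth = simulate_annotation(cfg)
    counts, meta = simulate_counts(genes, truth, cfg)
    return cfg, genes, truth, counts, meta


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
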