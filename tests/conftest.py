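import numpy as np
import pytest

from nmdkit.synth import synth_gene_set
from nmdkit.transcript_io import GenomicInterval, TranscriptModel


def make_tx(tid, exons, strand="+", seqname="c", gene="g"):
    """Shorthand transcript builder for tests."""
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene,
        exons=[GenomicInterval(seqname, s, e, strand) for s, e in exons],
    )


def random_model(rng, tid="t", seqname="c", strand=None, max_exons=8):
    """A random non-degenerate exon chain."""
    n_exons = int(rng.integers(1, max_exons))
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    pos = int(rng.integers(0, 50))
    exons = []
    for _ in range(n_exons):
        pos += int(rng.integers(1, 30))  # intron (gap) >= 1
        length = int(rng.integers(1, 40))
        exons.append((pos, pos + length))
        pos += length
    return make_tx(tid, exons, strand=strand, seqname=seqname)


@pytest.fixture(scope="session")
def cohort():
    """A labelled synthetic gene set shared across tests."""
    return synth_gene_set(80, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(202)
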