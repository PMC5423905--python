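import numpy as np
import pytest

import splicescape as sp


@pytest.fixture(scope="session")
def annotation():
    """A mid-sized synthetic annotation reused across read-only tests."""
    return sp.make_genome_and_genes(n_genes=40, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_transcript(rng, gene_id="G", tid="T", strand="+", chrom="chr1",
                      max_exons=5, coord_span=60):
    """Random valid exon chain on a small coordinate grid (dense enough
    that two independent draws share structure often)."""
    n_exons = int(rng.integers(1, max_exons + 1))
    # 2*n_exons distinct sorted breakpoints define exons/introns
    points = sorted(rng.choice(coord_span, size=2 * n_exons, replace=False))
    exons = []
    for k in range(n_exons):
        s, e = int(points[2 * k]), int(points[2 * k + 1])
        exons.append(sp.GenomeInterval(chrom, s, e + 1, strand))
    # enforce intron >= 1: consecutive points distinct guarantees gap >= 1
    try:
        return sp.TranscriptModel(tid, gene_id, tuple(exons))
    except Exception:
        return random_transcript(rng, gene_id, tid, strand, chrom,
                                 max_exons, coord_span)
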