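import pytest

from acetylink.genome import Gene, GenomeAnnotation, Transcript
from acetylink.simulate import SimConfig, simulate_all


def make_gene(gid, chrom, strand, exons, tid=None):
    """Gene with a single transcript from 0-based half-open exons."""
    tid = tid or f"{gid}_t1"
    tx = Transcript(tid, gid, chrom, strand, sorted(exons))
    return Gene(gid, chrom, strand, tx.start, tx.end, {tid: tx})


@pytest.fixture
def toy_annotation():
    """Two genes on chr1: a + strand gene with TSS 99 and a - strand gene
    with TSS 10399 (0-based), plus an empty chromosome chr2."""
    plus = make_gene("gplus", "chr1", "+", [(99, 200), (299, 400)])
    minus = make_gene("gminus", "chr1", "-", [(10099, 10200), (10299, 10400)])
    return GenomeAnnotation(
        {"chr1": 2_000_000, "chr2": 1_000_000}, {"gplus": plus, "gminus": minus}
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A modest synthetic study shared by read-only tests."""
    cfg = SimConfig(seed=42, n_genes=200, n_peaks=300)
    return cfg, simulate_all(cfg)
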