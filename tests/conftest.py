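import numpy as np
import pytest

from annodepth import quantify, synthetic_data as sd


def make_transcript(tid, gene, fam, blocks):
    """blocks: list of (block_id, length)."""
    return sd.Transcript(
        transcript_id=tid, gene_id=gene, family_id=fam,
        blocks=tuple(sd.Block(b, ln) for b, ln in blocks))


@pytest.fixture
def two_paralogs():
    """Two single-isoform genes sharing exactly half their block length."""
    a = make_transcript("A.t1", "A", "famAB", [("s", 50), ("ua", 50)])
    b = make_transcript("B.t1", "B", "famAB", [("s", 50), ("ub", 50)])
    return sd.Annotation("pair", (a, b))


@pytest.fixture(scope="session")
def forged_small():
    """120-gene forged transcriptome with truth and 3e4 reads (shared)."""
    ann = sd.forge_transcriptome(120, isoform_dist=sd.ZeroTruncatedNegBin(4.0), seed=11)
    truth = sd.simulate_expression(ann, seed=12)
    reads = sd.simulate_reads(truth, ann, 30_000, seed=13)
    return ann, truth, reads


@pytest.fixture(scope="session")
def forged_small_quant(forged_small):
    ann, truth, reads = forged_small
    sq = quantify.quantify_sample(reads, ann)
    gq = quantify.summarize_to_gene(sq, ann, ann)
    return sq, gq


@pytest.fixture(scope="session")
def forged_default():
    """Default-scale forge (500 genes, 1e5 reads) used by heavier tests."""
    ann = sd.forge_transcriptome(500, seed=21)
    truth = sd.simulate_expression(ann, seed=22)
    reads = sd.simulate_reads(truth, ann, 100_000, seed=23)
    return ann, truth, reads


@pytest.fixture
def rng():
    return np.random.default_rng(0)
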