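"""Shared fixture: a sample pair differing only by 5x depth thinning.

The expression truth carries a heavy low-expression "shelf" (many genes
just above the detection boundary of the thinned sample), so the filtered
per-gene comparison shows the depth-driven median shift the correction is
supposed to remove.  Well-measured genes stay unbiased — the shift lives
in the detection-conditioned part of the reported table, which is exactly
what TMM has to recentre.
"""

from __future__ import annotations

import numpy as np

from annodepth import quantify
from annodepth import synthetic_data as sd

N_TOP = 1200
N_SHELF = 5000
N_READS = 80_000
KEEP_PROB = 0.2       # 5x depth disparity
SHELF_MASS = 0.35
SHELF_BAND = (1.1, 1.8)   # log10 tpm band of the shelf


def depth_replicates(seed: int, n_reps: int):
    """(annotation, deep GeneQuant, [thinned GeneQuant, ...]) — one deep
    sample and ``n_reps`` independently thinned replicates of it."""
    ann, truth, reads = _forge(seed)
    gq_deep = quantify.summarize_to_gene(quantify.quantify_sample(reads, ann), ann, ann)
    thins = []
    for r in range(n_reps):
        thin = sd.thin_reads(reads, KEEP_PROB, seed=seed + 2 + r)
        thins.append(quantify.summarize_to_gene(
            quantify.quantify_sample(thin, ann), ann, ann))
    return ann, gq_deep, thins


def _forge(seed: int):
    rng = np.random.default_rng(seed)
    n_genes = N_TOP + N_SHELF
    ann = sd.forge_transcriptome(
        n_genes, isoform_dist=sd.Constant(1),
        length_dist=sd.LogNormalLength(1200, 0.4), seed=seed)
    top = 10.0 ** rng.uniform(1.5, 4.5, N_TOP)
    shelf = 10.0 ** rng.uniform(*SHELF_BAND, N_SHELF)
    top *= (1.0 - SHELF_MASS) / top.sum()
    shelf *= SHELF_MASS / shelf.sum()
    mass = np.concatenate([top, shelf])
    rng.shuffle(mass)
    theta = {t.transcript_id: m for t, m in zip(ann.transcripts, mass)}
    total = sum(theta.values())
    truth = sd.ExpressionTruth({k: v / total for k, v in theta.items()})
    reads = sd.simulate_reads(truth, ann, N_READS, seed=seed + 1)
    return ann, truth, reads


def depth_pair(seed: int):
    """(annotation, deep GeneQuant, thinned GeneQuant) for one seed."""
    ann, gq_deep, thins = depth_replicates(seed, 1)
    return ann, gq_deep, thins[0]


def invariant_panel(ann, seed: int, frac: float = 1 / 3):
    """Seeded 'tissue-invariant' gene panel spanning all expression levels."""
    rng = np.random.default_rng(seed)
    genes = np.array(ann.gene_ids, dtype=object)
    return set(rng.choice(genes, size=int(len(genes) * frac), replace=False))
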