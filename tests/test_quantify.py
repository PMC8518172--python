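import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from annodepth import annotation_ops, quantify
from annodepth import synthetic_data as sd
from annodepth.errors import QuantificationError, ValidationError

from conftest import make_transcript
from emtools import build_instance, oracle_fit


class TestComputeTpm:
    def test_single_transcript(self):
        q = quantify.compute_tpm([10.0], [100.0])
        assert q.tpm.iloc[0] == 1e6

    def test_equal_lengths(self):
        q = quantify.compute_tpm([10.0, 30.0], [100.0, 100.0])
        np.testing.assert_allclose(q.tpm.to_numpy(), [250_000.0, 750_000.0],
                                   rtol=1e-12)

    def test_unequal_lengths(self):
        q = quantify.compute_tpm([5.0, 5.0], [100.0, 200.0])
        assert np.isclose(q.S, 0.075, rtol=1e-12)
        np.testing.assert_allclose(q.tpm.to_numpy(),
                                   [2e6 / 3.0, 1e6 / 3.0], rtol=1e-12)

    def test_all_zero_counts_error(self):
        with pytest.raises(QuantificationError):
            quantify.compute_tpm([0.0, 0.0], [100.0, 100.0])

    def test_shape_and_domain_errors(self):
        with pytest.raises(QuantificationError):
            quantify.compute_tpm([1.0, 2.0], [100.0])
        with pytest.raises(QuantificationError):
            quantify.compute_tpm([1.0], [0.0])
        with pytest.raises(QuantificationError):
            quantify.compute_tpm([-1.0, 2.0], [10.0, 10.0])

    @given(st.lists(st.tuples(st.floats(0, 1e4), st.floats(1, 1e5)),
                    min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_conservation_property(self, pairs):
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        if x.sum() <= 0:
            return
        q = quantify.compute_tpm(x, y)
        assert abs(q.tpm.sum() - 1e6) <= 1e-6 * 1e6
        # the defining identity, exactly as computed
        np.testing.assert_array_equal(
            q.tpm.to_numpy(), 1e6 * (x / y) / q.S)


class TestAssignReads:
    def test_unique_reads_are_tallied(self):
        sets = [(0,), (1,)]
        ann, reads = build_instance(sets, [7, 3], [100, 100])
        x = quantify.assign_reads(reads, ann)
        np.testing.assert_allclose(x, [7.0, 3.0], atol=1e-12)

    def test_removed_transcript_unmaps_reads(self):
        sets = [(0,), (1,)]
        ann, reads = build_instance(sets, [7, 3], [100, 100])
        sub = ann.subset(["t0"], label="sub")
        x = quantify.assign_reads(reads, sub)
        assert x.sum() == pytest.approx(7.0)  # 3 reads became unmapped

    def test_em_matches_closed_form_split(self):
        """6 unique-A, 2 unique-B, 8 ambiguous, equal lengths:
        ML gives p=0.75 -> x = [6 + 8*0.75, 2 + 8*0.25] = [12, 4]."""
        sets = [(0,), (1,), (0, 1)]
        ann, reads = build_instance(sets, [6, 2, 8], [100, 100])
        x = quantify.assign_reads(reads, ann, em_max_iter=10_000, em_tol=1e-13)
        np.testing.assert_allclose(x, [12.0, 4.0], atol=1e-6)

    def test_em_matches_oracle_on_random_instances(self, rng):
        for _ in range(25):
            n_tx = int(rng.integers(2, 4))
            subsets = [tuple(s) for s in _nonempty_subsets(n_tx)]
            counts = rng.integers(0, 8, size=len(subsets))
            if counts.sum() == 0:
                counts[0] = 1
            lengths = [int(l) for l in rng.integers(50, 400, size=n_tx)]
            ann, reads = build_instance(subsets, list(counts), lengths)
            x_em = quantify.assign_reads(reads, ann, em_max_iter=50_000, em_tol=1e-13)
            fit = oracle_fit(subsets, list(counts), lengths)
            gap = fit.neg_ll_of_counts(x_em, lengths) - fit.neg_ll_opt
            assert np.abs(x_em - fit.x).max() < 1e-3 or gap < 1e-8

    def test_symmetric_tie_splits_equally(self):
        ann, reads = build_instance([(0, 1)], [8], [100, 100])
        x = quantify.assign_reads(reads, ann)
        np.testing.assert_allclose(x, [4.0, 4.0], atol=1e-12)

    def test_count_conservation(self, forged_small):
        ann, _, reads = forged_small
        x = quantify.assign_reads(reads, ann)
        assert x.sum() == pytest.approx(len(reads), rel=1e-9)

    def test_depth_invariance_exact(self, forged_small):
        """Duplicating every read leaves tpm unchanged exactly."""
        ann, _, reads = forged_small
        doubled = sd.ReadSet(
            block_vocab=reads.block_vocab, tx_vocab=reads.tx_vocab,
            block_codes=np.concatenate([reads.block_codes, reads.block_codes]),
            origin_codes=np.concatenate([reads.origin_codes, reads.origin_codes]))
        q1 = quantify.quantify_sample(reads, ann)
        q2 = quantify.quantify_sample(doubled, ann)
        t1, t2 = q1.tpm.to_numpy(), q2.tpm.to_numpy()
        # exact, except transcripts EM drove into the subnormal-float range
        # (doubling is not exact below ~1e-308)
        meaningful = t1 > 1e-300
        np.testing.assert_array_equal(t1[meaningful], t2[meaningful])
        assert (t2[~meaningful] < 1e-300).all()


class TestRemovalLaw:
    def test_zero_read_disjoint_removal_scales_tpm_by_S_ratio(self):
        """Closed form: removing unexpressed, compatibility-disjoint
        transcripts keeps x and multiplies every tpm by S/S' >= 1."""
        txs = (
            make_transcript("a", "ga", "fa", [("ba", 200)]),
            make_transcript("b", "gb", "fb", [("bb", 100)]),
            make_transcript("dead1", "gd1", "fd1", [("bd1", 150)]),
            make_transcript("dead2", "gd2", "fd2", [("bd2", 300)]),
        )
        full = sd.Annotation("full", txs)
        truth = sd.ExpressionTruth({"a": 0.6, "b": 0.4, "dead1": 0.0, "dead2": 0.0})
        reads = sd.simulate_reads(truth, full, 5000, seed=3)
        sub = full.subset(["a", "b"], label="sub")

        q_full = quantify.quantify_sample(reads, full)
        q_sub = quantify.quantify_sample(reads, sub)
        # x unchanged
        np.testing.assert_array_equal(
            q_full.table.loc[["a", "b"], "reads_mapped"].to_numpy(),
            q_sub.table.loc[["a", "b"], "reads_mapped"].to_numpy())
        ratio = q_full.S / q_sub.S
        assert ratio >= 1.0
        np.testing.assert_allclose(
            q_sub.table.loc[["a", "b"], "tpm"].to_numpy(),
            q_full.table.loc[["a", "b"], "tpm"].to_numpy() * ratio, rtol=1e-9)


class TestSummarizeToGene:
    def test_gene_sum(self):
        q = quantify.compute_tpm([10.0, 20.0], [100.0, 100.0],
                                 transcript_ids=["g1.t1", "g1.t2"])
        ann = sd.Annotation("a", (
            make_transcript("g1.t1", "g1", "f1", [("b1", 100)]),
            make_transcript("g1.t2", "g1", "f1", [("b1", 50), ("b2", 50)]),
        ))
        gq = quantify.summarize_to_gene(q, ann)
        assert gq.tpm.loc["g1"] == pytest.approx(1e6)
        assert gq.reads_mapped.loc["g1"] == pytest.approx(30.0)

    def test_single_transcript_gene_identity(self, forged_small, forged_small_quant):
        ann, _, _ = forged_small
        sq, gq = forged_small_quant
        singles = [g for g, m in ann.gene_members.items() if len(m) == 1]
        for g in singles[:10]:
            tid = ann.gene_members[g][0]
            assert gq.tpm.loc[g] == pytest.approx(sq.tpm.loc[tid])

    def test_unknown_transcript_rejected(self, two_paralogs):
        q = quantify.compute_tpm([1.0], [100.0], transcript_ids=["ghost"])
        with pytest.raises(ValidationError):
            quantify.summarize_to_gene(q, two_paralogs)

    def test_represented_length_fraction(self, forged_small):
        ann, _, reads = forged_small
        multi = next(g for g, m in ann.gene_members.items() if len(m) >= 3)
        keep = [t for t in ann.transcript_ids
                if ann.by_id[t].gene_id != multi or t == ann.gene_members[multi][0]]
        sub = ann.subset(keep, label="sub")
        sq = quantify.quantify_sample(reads, sub)
        gq = quantify.summarize_to_gene(sq, sub, ann)
        expected = ann.by_id[ann.gene_members[multi][0]].length / sum(
            ann.by_id[t].length for t in ann.gene_members[multi])
        assert gq.table.loc[multi, "represented_length_fraction"] == pytest.approx(expected)

    def test_gene_sum_rescues_isoform_multimodality(self):
        """Transcript tpm stratifies with competitor presence; the gene-level
        sum is far more stable across >= 50 replicate subsamples."""
        txs = [
            make_transcript("G.t1", "G", "fG", [("s", 100), ("u1", 100)]),
            make_transcript("G.t2", "G", "fG", [("s", 100), ("u2", 100)]),
        ]
        for i in range(20):  # filler genes forming the sampling pool
            txs.append(make_transcript(f"F{i}.t1", f"F{i}", f"fF{i}",
                                       [(f"bf{i}", 200)]))
        ann = sd.Annotation("mm", tuple(txs))
        theta = {"G.t1": 0.25, "G.t2": 0.25}
        theta.update({f"F{i}.t1": 0.5 / 20 for i in range(20)})
        truth = sd.ExpressionTruth(theta)
        reads = sd.simulate_reads(truth, ann, 20_000, seed=9)

        scheme = annotation_ops.SweepScheme(
            fractions=(50.0,), reps_per_fraction=60,
            keep_ids=frozenset({"G.t1"}), seed=17)
        t1_tpm, g_tpm = [], []
        for sub in annotation_ops.subsample_sweep(ann, scheme):
            sq = quantify.quantify_sample(reads, sub)
            gq = quantify.summarize_to_gene(sq, sub, ann)
            t1_tpm.append(sq.tpm.loc["G.t1"])
            g_tpm.append(gq.tpm.loc["G"])
        assert np.var(g_tpm) < np.var(t1_tpm)


class TestParameterRecovery:
    def test_spearman_gene_recovery(self, forged_default):
        """>= 1e6 reads on the full annotation: Spearman(gene tpm, theta) >= 0.95."""
        from scipy.stats import spearmanr
        ann, truth, _ = forged_default
        reads = sd.simulate_reads(truth, ann, 1_000_000, seed=77)
        sq = quantify.quantify_sample(reads, ann)
        gq = quantify.summarize_to_gene(sq, ann, ann)
        gt = truth.gene_theta(ann)
        rho = spearmanr(gq.tpm.to_numpy(),
                        [gt[g] for g in gq.table.index]).statistic
        assert rho >= 0.95


def _nonempty_subsets(n):
    import itertools
    out = []
    for r in range(1, n + 1):
        out.extend(itertools.combinations(range(n), r))
    return out
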