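import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from annodepth import annotation_ops as ops
from annodepth import quantify
from annodepth import stats as ast
from annodepth import synthetic_data as sd
from annodepth.errors import ConfigurationError, ValidationError

from conftest import make_transcript


def _gene_quant(tpm: dict, reads: dict | None = None):
    reads = reads or {g: 100.0 for g in tpm}
    table = pd.DataFrame({
        "reads_mapped": pd.Series(reads, dtype=float),
        "tpm": pd.Series(tpm, dtype=float),
        "represented_length_fraction": 1.0,
    })
    table.index.name = "gene_id"
    return quantify.GeneQuant(table=table)


@pytest.fixture(scope="module")
def small_sweep(forged_small_session):
    """5 fractions x 4 reps quantified against the 120-gene forge."""
    ann, truth, reads = forged_small_session
    full_sq = quantify.quantify_sample(reads, ann)
    full_gq = quantify.summarize_to_gene(full_sq, ann, ann)
    genes = ast.stratified_select_genes(full_gq, n_bins=6,
                                        bin_range_log10=(0.5, 4.5), seed=1)
    keep = frozenset(t for g in genes for t in ann.gene_members[g])
    scheme = ops.SweepScheme(fractions=(10.0, 30.0, 50.0, 70.0, 90.0),
                             reps_per_fraction=4, keep_ids=keep, seed=2)
    entries = []
    for sub in ops.subsample_sweep(ann, scheme):
        frac, rep = sub.label.removeprefix("sub_").split("pct_rep")
        sq = quantify.quantify_sample(reads, sub)
        gq = quantify.summarize_to_gene(sq, sub, ann)
        entries.append(ast.SweepEntry(float(frac), int(rep), sq, gq, sub.label))
    return ann, reads, full_sq, full_gq, genes, entries


@pytest.fixture(scope="session")
def forged_small_session(forged_small):
    return forged_small


class TestStratifiedSelect:
    def test_one_gene_per_occupied_bin(self, forged_small_quant):
        _, gq = forged_small_quant
        genes = ast.stratified_select_genes(gq, n_bins=10,
                                            bin_range_log10=(0.5, 4.5), seed=0)
        logt = np.log10(gq.tpm.loc[genes])
        bins = np.digitize(logt, np.linspace(0.5, 4.5, 11)) - 1
        assert len(set(bins)) == len(genes)

    def test_edge_value_goes_to_upper_bin(self):
        # g_edge sits exactly on the 2-bin boundary at log10 tpm = 2.5
        gq = _gene_quant({"g_edge": 10 ** 2.5, "g_low": 10 ** 1.0})
        # bins: [0.5, 2.5), [2.5, 4.5) -> edge gene must be the bin-2 pick
        genes = ast.stratified_select_genes(gq, n_bins=2,
                                            bin_range_log10=(0.5, 4.5), seed=0)
        assert genes == ["g_low", "g_edge"]

    def test_single_gene_selected_regardless_of_seed(self):
        gq = _gene_quant({"only": 100.0, "outside": 10 ** 6.0})
        with pytest.warns(UserWarning):
            for seed in range(5):
                assert ast.stratified_select_genes(
                    gq, n_bins=4, bin_range_log10=(0.5, 4.5), seed=seed) == ["only"]

    def test_all_bins_empty_raises(self):
        gq = _gene_quant({"g": 10 ** 6.0})
        with pytest.warns(UserWarning):
            with pytest.raises(ValidationError):
                ast.stratified_select_genes(gq, n_bins=3,
                                            bin_range_log10=(0.5, 4.5), seed=0)

    def test_bad_params(self, forged_small_quant):
        _, gq = forged_small_quant
        with pytest.raises(ConfigurationError):
            ast.stratified_select_genes(gq, n_bins=0)
        with pytest.raises(ConfigurationError):
            ast.stratified_select_genes(gq, bin_range_log10=(2.0, 1.0))


class TestBuildSweepResult:
    def test_identity_subsample_all_zero(self, forged_small, forged_small_quant):
        ann, _, reads = forged_small
        sq, gq = forged_small_quant
        entry = ast.SweepEntry(100.0, 1, sq, gq, "identity")
        genes = list(gq.table.index[gq.tpm > 0][:5])
        out = ast.build_sweep_result([entry], sq, gq, genes)
        assert (out["log10_tpm_diff"].abs() < 1e-12).all()
        assert (out["log10_reads_diff"].abs() < 1e-12).all()
        assert not out["dropout"].any()

    def test_zero_read_removal_gives_uniform_S_shift(self):
        """TRIVIAL removal law: diffs = log10(S/S') for every gene, reads 0."""
        txs = (
            make_transcript("a", "ga", "fa", [("ba", 100)]),
            make_transcript("b", "gb", "fb", [("bb", 250)]),
            make_transcript("dead", "gd", "fd", [("bd", 400)]),
        )
        full = sd.Annotation("full", txs)
        truth = sd.ExpressionTruth({"a": 0.5, "b": 0.5, "dead": 0.0})
        reads = sd.simulate_reads(truth, full, 2000, seed=4)
        sub = full.subset(["a", "b"], label="sub")
        full_sq = quantify.quantify_sample(reads, full)
        full_gq = quantify.summarize_to_gene(full_sq, full, full)
        sq = quantify.quantify_sample(reads, sub)
        gq = quantify.summarize_to_gene(sq, sub, full)
        out = ast.build_sweep_result(
            [ast.SweepEntry(66.0, 1, sq, gq, "sub")], full_sq, full_gq, ["ga", "gb"])
        expected = np.log10(full_sq.S / sq.S)
        np.testing.assert_allclose(out["log10_tpm_diff"], expected, rtol=1e-9)
        np.testing.assert_allclose(out["log10_reads_diff"], 0.0, atol=1e-12)

    def test_missing_gene_rejected(self, forged_small_quant):
        sq, gq = forged_small_quant
        with pytest.raises(ValidationError):
            ast.build_sweep_result([], sq, gq, ["ghost"])

    def test_sweep_mean_diff_nonnegative(self, small_sweep):
        """DERIVED at reduced scale: inflation direction at every fraction."""
        _, _, full_sq, full_gq, genes, entries = small_sweep
        out = ast.build_sweep_result(entries, full_sq, full_gq, genes)
        clean = out[~out["dropout"]]
        by_frac = clean.groupby("fraction")["log10_tpm_diff"].mean()
        assert (by_frac >= 0).all()
        assert by_frac.loc[10.0] > by_frac.loc[90.0]


class TestInflationSignificance:
    def test_all_identical_no_calls(self):
        rows = [(f, r, "g", 0.0, 0.0, 1.0, 1.0, False)
                for f in (10.0, 50.0, 90.0) for r in range(6)]
        df = pd.DataFrame(rows, columns=[
            "fraction", "rep", "gene_id", "log10_tpm_diff", "log10_reads_diff",
            "S_sub", "represented_length_fraction", "dropout"])
        out = ast.inflation_significance(df)
        assert not out["significant"].any()

    def test_shifted_fraction_called(self, rng):
        rows = []
        for f in (10.0, 50.0, 90.0):
            shift = 2.0 if f == 10.0 else 0.0
            for r in range(30):
                rows.append((f, r, "g", shift + rng.normal(0, 0.01),
                             0.0, 1.0, 1.0, False))
        df = pd.DataFrame(rows, columns=[
            "fraction", "rep", "gene_id", "log10_tpm_diff", "log10_reads_diff",
            "S_sub", "represented_length_fraction", "dropout"])
        out = ast.inflation_significance(df).set_index("fraction")
        assert out.loc[10.0, "significant"]
        assert not out.loc[50.0, "significant"]

    def test_reference_is_largest_fraction(self, small_sweep):
        _, _, full_sq, full_gq, genes, entries = small_sweep
        out = ast.build_sweep_result(entries, full_sq, full_gq, genes)
        sig = ast.inflation_significance(out)
        assert 90.0 not in set(sig["fraction"])
        assert set(sig["fraction"]) == {10.0, 30.0, 50.0, 70.0}

    def test_smallest_fraction_significant_when_any(self, small_sweep):
        _, _, full_sq, full_gq, genes, entries = small_sweep
        out = ast.build_sweep_result(entries, full_sq, full_gq, genes)
        sig = ast.inflation_significance(out).set_index("fraction")
        if sig["significant"].any():
            assert sig.loc[10.0, "significant"]

    def test_degenerate_rejected(self):
        df = pd.DataFrame({"fraction": [10.0], "log10_tpm_diff": [0.1],
                           "dropout": [False]})
        with pytest.raises(ValidationError):
            ast.inflation_significance(df)


class TestDenominatorDiagnostic:
    def test_identical_quantification_ratio_one(self, forged_small_quant):
        sq, gq = forged_small_quant
        entry = ast.SweepEntry(100.0, 1, sq, gq, "identity")
        genes = list(gq.table.index[:5])
        out = ast.denominator_diagnostic([entry], sq, gq, genes)
        checked = out["ratio_law_ok"].dropna()
        assert len(checked) and checked.astype(bool).all()

    def test_halved_S_doubles_tpm(self):
        """TRIVIAL algebra: same counts, S halved -> tpm exactly doubled."""
        q1 = quantify.compute_tpm([10.0, 10.0], [100.0, 100.0], ["t1", "t2"])
        # drop a third transcript carrying the other half of S
        q_full = quantify.compute_tpm([10.0, 10.0, 20.0],
                                      [100.0, 100.0, 100.0], ["t1", "t2", "t3"])
        assert q_full.S == pytest.approx(2 * q1.S * 0.5 + q1.S)  # S doubled
        np.testing.assert_allclose(q1.tpm.to_numpy()[:2],
                                   2 * q_full.tpm.to_numpy()[:2], rtol=1e-12)

    def test_negative_S_tpm_correlation_across_sweep(self, small_sweep):
        """DERIVED at reduced scale: Spearman(S_sub, control tpm) < 0."""
        _, _, full_sq, full_gq, genes, entries = small_sweep
        out = ast.denominator_diagnostic(entries, full_sq, full_gq, genes)
        # pick the control gene observed most often with positive tpm
        counts = out[out["tpm"] > 0].groupby("gene_id").size()
        gene = counts.idxmax()
        sub = out[(out["gene_id"] == gene) & (out["tpm"] > 0)]
        rho = spearmanr(sub["S_sub"], sub["tpm"]).statistic
        assert rho < 0


class TestCharacterizeInflatedGenes:
    def test_no_gene_above_threshold(self):
        full = _gene_quant({"a": 100.0, "b": 200.0})
        rep = _gene_quant({"a": 101.0, "b": 201.0})
        report = ast.characterize_inflated_genes([rep], full, n_perm=10, seed=0)
        assert report.flagged == ()
        assert np.isnan(report.perm_percentile)

    def test_engineered_competitor_loss_flags_gene(self):
        """Family loses its competitors in every rep: the retained
        low-expression gene gains reads and tpm and is flagged."""
        report, ann, full_gq, reduced_gqs = _competitor_fixture(seed=5)
        assert "low" in report.flagged
        for gq in reduced_gqs:
            assert gq.reads_mapped.loc["low"] > full_gq.reads_mapped.loc["low"]

    def test_flagged_genes_are_low_expression(self):
        report, *_ = _competitor_fixture(seed=6, n_perm=500)
        assert report.perm_percentile < 5.0


def _competitor_fixture(seed, n_perm=200):
    rng = np.random.default_rng(seed)
    txs = [
        make_transcript("low.t1", "low", "famX", [("sX", 400), ("uL", 100)]),
        make_transcript("high.t1", "high", "famX", [("sX", 400), ("uH", 100)]),
    ]
    theta = {"low.t1": 2e-4, "high.t1": 0.05}
    rest = rng.dirichlet(np.full(60, 5.0)) * (1.0 - sum(theta.values()))
    for i in range(60):
        txs.append(make_transcript(f"F{i}.t1", f"F{i}", f"fF{i}",
                                   [(f"bf{i}", 500)]))
        theta[f"F{i}.t1"] = float(rest[i])
    ann = sd.Annotation("fx", tuple(txs))
    truth = sd.ExpressionTruth(theta)
    reads = sd.simulate_reads(truth, ann, 50_000, seed=seed + 1)
    full_sq = quantify.quantify_sample(reads, ann)
    full_gq = quantify.summarize_to_gene(full_sq, ann, ann)

    reduced = ann.subset([t for t in ann.transcript_ids if t != "high.t1"],
                         label="reduced")
    reduced_gqs = []
    for _ in range(3):
        sq = quantify.quantify_sample(reads, reduced)
        reduced_gqs.append(quantify.summarize_to_gene(sq, reduced, ann))
    report = ast.characterize_inflated_genes(reduced_gqs, full_gq,
                                             n_perm=n_perm, seed=seed)
    return report, ann, full_gq, reduced_gqs
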