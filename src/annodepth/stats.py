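"""Analysis computations for the annotation-depth experiments.

Everything here consumes quantification outputs and produces tidy tables:
control-gene selection, the per-(fraction, replicate, gene) log-difference
table, its significance profile (Kruskal–Wallis + Dunn vs the deepest
fraction + Benjamini–Hochberg), denominator diagnostics, and the
characterisation of genes inflated by competitor loss.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, ValidationError
from .quantify import GeneQuant, SampleQuant

__all__ = [
    "SweepEntry",
    "stratified_select_genes",
    "build_sweep_result",
    "inflation_significance",
    "denominator_diagnostic",
    "characterize_inflated_genes",
    "InflationReport",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SweepEntry:
    """One quantified subsample: its place in the sweep plus both quant levels."""

    fraction: float
    rep: int
    sample: SampleQuant
    gene: GeneQuant
    label: str = ""


def stratified_select_genes(
    full_gene_quant: GeneQuant,
    n_bins: int = 10,
    bin_range_log10: tuple[float, float] = (0.5, 4.5),
    seed: int = 0,
) -> list[str]:
    """One gene per occupied log10-tpm bin, drawn uniformly.

    Bins partition ``bin_range_log10`` into ``n_bins`` equal widths; a gene
    whose log10 tpm falls exactly on an interior bin edge belongs to the
    higher bin (and the upper range endpoint to the last bin).  Empty bins
    are skipped with a warning; all-empty is an error.
    """
    if n_bins < 1:
        raise ConfigurationError("n_bins must be >= 1")
    lo, hi = bin_range_log10
    if not (hi > lo):
        raise ConfigurationError("invalid bin range")

    tpm = full_gene_quant.tpm
    expressed = tpm[tpm > 0]
    logt = np.log10(expressed)
    edges = np.linspace(lo, hi, n_bins + 1)
    # right=False: value == edge goes to the upper bin
    bin_of = np.digitize(logt, edges, right=False) - 1
    bin_of[np.isclose(logt, hi)] = n_bins - 1  # close the top endpoint
    in_range = (bin_of >= 0) & (bin_of < n_bins)

    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    any_occupied = False
    for b in range(n_bins):
        members = expressed.index[in_range & (bin_of == b)]
        if len(members) == 0:
            warnings.warn(f"abundance bin {b} [{edges[b]:.2f}, {edges[b+1]:.2f}) is empty",
                          stacklevel=2)
            continue
        any_occupied = True
        chosen.append(str(rng.choice(np.array(members, dtype=object))))
    if not any_occupied:
        raise ValidationError("no gene falls in the requested abundance range")
    return chosen


def build_sweep_result(
    entries: Iterable[SweepEntry],
    full_sample: SampleQuant,
    full_gene: GeneQuant,
    test_genes: Sequence[str],
) -> pd.DataFrame:
    """Per-(fraction, rep, gene) log10 differences vs the full annotation.

    Columns: fraction, rep, gene_id, log10_tpm_diff, log10_reads_diff,
    S_sub, represented_length_fraction, dropout.  Genes with zero tpm in a
    subsample get a sentinel row (NaN diffs, dropout=True).
    """
    missing = [g for g in test_genes if g not in full_gene.table.index]
    if missing:
        raise ValidationError(f"test genes absent from the full quantification: {missing[:5]}")

    full_tpm = full_gene.tpm
    full_reads = full_gene.reads_mapped
    rows = []
    for e in entries:
        for g in test_genes:
            if g in e.gene.table.index:
                tpm_sub = float(e.gene.tpm.loc[g])
                reads_sub = float(e.gene.reads_mapped.loc[g])
                rlf = float(e.gene.table.loc[g, "represented_length_fraction"])
            else:
                tpm_sub, reads_sub, rlf = 0.0, 0.0, 0.0
            dropout = tpm_sub <= 0 or full_tpm.loc[g] <= 0
            if dropout:
                dtpm = np.nan
                dreads = np.nan
            else:
                dtpm = np.log10(tpm_sub) - np.log10(full_tpm.loc[g])
                fr = float(full_reads.loc[g])
                dreads = (np.log10(reads_sub) - np.log10(fr)
                          if reads_sub > 0 and fr > 0 else np.nan)
            rows.append((e.fraction, e.rep, g, dtpm, dreads, e.sample.S, rlf, dropout))
    return pd.DataFrame(rows, columns=[
        "fraction", "rep", "gene_id", "log10_tpm_diff", "log10_reads_diff",
        "S_sub", "represented_length_fraction", "dropout",
    ])


def _dunn_vs_reference(groups: dict[float, np.ndarray], reference: float):
    """Dunn's z statistics of each group against the reference group.

    Pooled-rank z with tie correction:
        z = (R̄_g − R̄_ref) / sqrt((N(N+1)/12 − T)(1/n_g + 1/n_ref)),
        T = Σ(t³ − t) / (12(N − 1)).
    """
    keys = list(groups)
    pooled = np.concatenate([groups[k] for k in keys])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_rank = {}
    pos = 0
    for k in keys:
        n_k = groups[k].size
        mean_rank[k] = ranks[pos:pos + n_k].mean()
        pos += n_k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum())
                     / (12.0 * (n_total - 1))) if n_total > 1 else 0.0
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    out = {}
    n_ref = groups[reference].size
    for k in keys:
        if k == reference:
            continue
        se = np.sqrt(base_var * (1.0 / groups[k].size + 1.0 / n_ref))
        if se == 0:
            z = 0.0
        else:
            z = (mean_rank[k] - mean_rank[reference]) / se
        out[k] = (float(z), float(2.0 * sps.norm.sf(abs(z))))
    return out


def inflation_significance(
    result: pd.DataFrame,
    alpha: float = 0.05,
    reference_fraction: float | None = None,
) -> pd.DataFrame:
    """Kruskal–Wallis across fractions + Dunn vs the deepest fraction + BH.

    ``result`` is a build_sweep_result table; dropout rows are excluded.
    Returns one row per non-reference fraction with columns
    fraction, n, kw_H, kw_p, dunn_z, p_raw, p_adj, significant.
    """
    clean = result[~result["dropout"] & np.isfinite(result["log10_tpm_diff"])]
    groups = {float(f): sub["log10_tpm_diff"].to_numpy()
              for f, sub in clean.groupby("fraction")}
    groups = {f: v for f, v in groups.items() if v.size >= 2}
    if len(groups) < 2:
        raise ValidationError("need >= 2 fractions with >= 2 observations each")
    reference = max(groups) if reference_fraction is None else float(reference_fraction)
    if reference not in groups:
        raise ValidationError(f"reference fraction {reference} has no usable observations")

    arrays = [groups[k] for k in sorted(groups)]
    if np.ptp(np.concatenate(arrays)) == 0:
        kw_h, kw_p = 0.0, 1.0  # all values identical: no evidence of any shift
    else:
        kw_h, kw_p = sps.kruskal(*arrays)

    dunn = _dunn_vs_reference(groups, reference)
    fracs = sorted(dunn)
    p_raw = np.array([dunn[f][1] for f in fracs])
    _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
    return pd.DataFrame({
        "fraction": fracs,
        "n": [groups[f].size for f in fracs],
        "kw_H": float(kw_h),
        "kw_p": float(kw_p),
        "dunn_z": [dunn[f][0] for f in fracs],
        "p_raw": p_raw,
        "p_adj": p_adj,
        "significant": p_adj < alpha,
    })


def denominator_diagnostic(
    entries: Iterable[SweepEntry],
    full_sample: SampleQuant,
    full_gene: GeneQuant,
    test_genes: Sequence[str],
    rtol: float = 1e-9,
) -> pd.DataFrame:
    """Per-quantification (S, tpm) pairs for the test genes.

    For genes whose mapped reads match the full quantification (within
    ``rtol``), verifies the closed-form tpm_sub / tpm_full = S_full / S_sub
    to ``rtol`` relative; the outcome is recorded in ``ratio_law_ok``
    (NaN when the gene's counts changed, so the law does not apply).
    """
    full_tpm = full_gene.tpm
    full_reads = full_gene.reads_mapped
    rows = []
    for e in entries:
        for g in test_genes:
            if g not in e.gene.table.index:
                continue
            tpm_sub = float(e.gene.tpm.loc[g])
            reads_sub = float(e.gene.reads_mapped.loc[g])
            fr, ft = float(full_reads.loc[g]), float(full_tpm.loc[g])
            constant_reads = fr > 0 and np.isclose(reads_sub, fr, rtol=max(rtol, 1e-12))
            if constant_reads and ft > 0 and tpm_sub > 0:
                lhs = tpm_sub / ft
                rhs = full_sample.S / e.sample.S
                ok = bool(np.isclose(lhs, rhs, rtol=rtol, atol=0.0))
            else:
                ok = np.nan
            rows.append((e.label, e.fraction, e.rep, g, e.sample.S, tpm_sub,
                         reads_sub, ok))
    return pd.DataFrame(rows, columns=[
        "label", "fraction", "rep", "gene_id", "S_sub", "tpm", "reads_mapped",
        "ratio_law_ok",
    ])


@dataclass(frozen=True)
class InflationReport:
    """Genes over-estimated in reduced annotations, vs a permutation null."""

    table: pd.DataFrame            # per gene: mean diffs, flagged
    flagged: tuple[str, ...]
    perm_percentile: float         # percentile of flagged mean expression; NaN if none
    perm_means: np.ndarray         # permutation null of mean log10 expression
    flagged_mean_expression: float
    flagged_mean_length_fraction: float


def characterize_inflated_genes(
    reduced_gene_quants: Sequence[GeneQuant],
    full_gene_quant: GeneQuant,
    n_perm: int = 1000,
    seed: int = 0,
    *,
    tpm_diff_threshold: float = 0.1,
) -> InflationReport:
    """Flag genes systematically over-estimated in reduced annotations.

    A gene is flagged when its mean log10 tpm difference (reduced vs full,
    over replicates where both are expressed) exceeds
    ``tpm_diff_threshold`` with a positive mean log10 reads difference.
    The flagged set's mean log10 full-annotation expression is ranked
    against ``n_perm`` equal-size random gene draws.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    full_tpm = full_gene_quant.tpm
    full_reads = full_gene_quant.reads_mapped

    sums: dict[str, list[float]] = {}
    reads_sums: dict[str, list[float]] = {}
    rlf: dict[str, list[float]] = {}
    for gq in reduced_gene_quants:
        for g in gq.table.index:
            if g not in full_tpm.index:
                continue
            t_sub, t_full = float(gq.tpm.loc[g]), float(full_tpm.loc[g])
            r_sub, r_full = float(gq.reads_mapped.loc[g]), float(full_reads.loc[g])
            if t_sub > 0 and t_full > 0:
                sums.setdefault(g, []).append(np.log10(t_sub) - np.log10(t_full))
            if r_sub > 0 and r_full > 0:
                reads_sums.setdefault(g, []).append(np.log10(r_sub) - np.log10(r_full))
            rlf.setdefault(g, []).append(float(gq.table.loc[g, "represented_length_fraction"]))

    records = []
    for g in sorted(sums):
        mean_dtpm = float(np.mean(sums[g]))
        mean_dreads = float(np.mean(reads_sums.get(g, [np.nan])))
        mean_rlf = float(np.mean(rlf[g]))
        flagged = mean_dtpm > tpm_diff_threshold and mean_dreads > 0
        records.append((g, mean_dtpm, mean_dreads, mean_rlf, flagged))
    table = pd.DataFrame(records, columns=[
        "gene_id", "mean_log10_tpm_diff", "mean_log10_reads_diff",
        "mean_represented_length_fraction", "flagged",
    ]).set_index("gene_id")

    flagged = tuple(table.index[table["flagged"]])
    rng = np.random.default_rng(seed)
    expressed = full_tpm[full_tpm > 0]
    log_expr = np.log10(expressed)
    if flagged:
        obs = float(log_expr.reindex(flagged).mean())
        draws = np.array([
            log_expr.iloc[rng.choice(len(log_expr), size=len(flagged), replace=False)].mean()
            for _ in range(n_perm)
        ])
        percentile = float((draws <= obs).mean() * 100.0)
        mean_rlf_flagged = float(table.loc[list(flagged),
                                           "mean_represented_length_fraction"].mean())
    else:
        obs, draws, percentile, mean_rlf_flagged = np.nan, np.array([]), np.nan, np.nan
        logger.info("no gene exceeds the inflation threshold")

    return InflationReport(table=table, flagged=flagged, perm_percentile=percentile,
                           perm_means=draws, flagged_mean_expression=obs,
                           flagged_mean_length_fraction=mean_rlf_flagged)
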