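"""Config-driven experiment runner tying the pipeline stages together.

Five named experiments mirror the study design:

* ``sweep``          — annotation-depth subsampling with control genes,
                       log-difference table, KW/Dunn significance,
                       denominator diagnostic
* ``paralogs``       — the sweep after removing the control genes' paralog
                       competitors; multi-modality comparison
* ``preclinicalize`` — per-gene transcript reduction to species profiles;
                       inflated-gene characterisation with permutations
* ``history``        — parametric gene-length variation (padding) and its
                       closed-form tpm effect
* ``correction``     — depth-thinned "species" samples, TMM correction,
                       housekeeping panel check

Outputs are TSV tables plus a machine-readable ``summary.json``; every
table is stamped with the config hash and seed.
"""

from __future__ import annotations

import json
import logging
import shutil
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation_ops, normalize, quantify, stats, synthetic_data, tableio
from .config import ExperimentConfig
from .errors import ConfigurationError

__all__ = ["run_experiment", "forge_from_config", "EXPERIMENTS"]

logger = logging.getLogger(__name__)

EXPERIMENTS = ("sweep", "paralogs", "preclinicalize", "history", "correction")


# ---------------------------------------------------------------------------
# shared plumbing
# ---------------------------------------------------------------------------

def forge_from_config(cfg: ExperimentConfig, *, n_genes: int | None = None,
                      isoform_mean: float | None = None, seed_offset: int = 0):
    """(annotation, truth, reads) for the configured forge/read parameters."""
    fp = cfg.forge
    mean = fp.isoform_mean if isoform_mean is None else isoform_mean
    iso = (synthetic_data.Constant(1) if mean <= 1.0
           else synthetic_data.ZeroTruncatedNegBin(mean, fp.isoform_shape))
    ann = synthetic_data.forge_transcriptome(
        n_genes=n_genes if n_genes is not None else fp.n_genes,
        isoform_dist=iso,
        family_spec=synthetic_data.FamilySpec(
            fraction_of_genes=fp.family_fraction,
            min_size=fp.family_min_size, max_size=fp.family_max_size,
            shared_frac_low=fp.shared_frac_low, shared_frac_high=fp.shared_frac_high),
        length_dist=synthetic_data.LogNormalLength(
            fp.length_mean, fp.length_sigma, fp.length_min),
        seed=cfg.seed + seed_offset,
    )
    truth = synthetic_data.simulate_expression(
        ann, fp.dynamic_range_log10, seed=cfg.seed + seed_offset + 1)
    reads = synthetic_data.simulate_reads(
        truth, ann, cfg.reads.n_reads, seed=cfg.seed + seed_offset + 2)
    return ann, truth, reads


def _quantify_pair(reads, annotation, full_annotation):
    sq = quantify.quantify_sample(reads, annotation)
    gq = quantify.summarize_to_gene(sq, annotation, full_annotation)
    return sq, gq


def _meta(cfg: ExperimentConfig) -> dict[str, str]:
    return {"config_hash": cfg.config_hash(), "seed": str(cfg.seed)}


def _sweep_scheme(cfg: ExperimentConfig, keep_ids) -> annotation_ops.SweepScheme:
    sp = cfg.sweep
    return annotation_ops.SweepScheme(
        fractions=tuple(sp.fractions), reps_per_fraction=sp.reps_per_fraction,
        keep_ids=frozenset(keep_ids), seed=cfg.seed + 100)


def _run_sweep_core(cfg: ExperimentConfig, ann, reads, outdir: Path):
    """Quantify full + sweep, select control genes, build all stats tables."""
    full_sq, full_gq = _quantify_pair(reads, ann, ann)
    control_genes = stats.stratified_select_genes(
        full_gq, n_bins=cfg.sweep.n_control_bins,
        bin_range_log10=(cfg.sweep.bin_lo_log10, cfg.sweep.bin_hi_log10),
        seed=cfg.seed + 200)
    keep_ids = [t for g in control_genes for t in ann.gene_members[g]]
    scheme = _sweep_scheme(cfg, keep_ids)

    entries = []
    manifest_rows = []
    for sub in annotation_ops.subsample_sweep(ann, scheme):
        frac_str, rep_str = sub.label.removeprefix("sub_").split("pct_rep")
        sq, gq = _quantify_pair(reads, sub, ann)
        entries.append(stats.SweepEntry(fraction=float(frac_str), rep=int(rep_str),
                                        sample=sq, gene=gq, label=sub.label))
        manifest_rows.append((sub.label, float(frac_str), int(rep_str),
                              sub.n_transcripts))

    result = stats.build_sweep_result(entries, full_sq, full_gq, control_genes)
    signif = stats.inflation_significance(result, alpha=cfg.stats.alpha)
    diag = stats.denominator_diagnostic(entries, full_sq, full_gq, control_genes)

    meta = _meta(cfg)
    tableio.write_quant(full_sq, outdir / "full_quant.tsv", meta)
    tableio.write_gene_quant(full_gq, outdir / "full_gene_quant.tsv", meta)
    tableio._write_tsv(pd.DataFrame(manifest_rows,
                                    columns=["label", "fraction", "rep", "n_transcripts"]),
                       outdir / "manifest.tsv", meta)
    tableio._write_tsv(result, outdir / "sweep_result.tsv", meta)
    tableio._write_tsv(signif, outdir / "significance.tsv", meta)
    tableio._write_tsv(diag, outdir / "denominator_diagnostic.tsv", meta)
    return full_sq, full_gq, control_genes, result, signif, diag


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def _experiment_sweep(cfg: ExperimentConfig, outdir: Path) -> dict:
    ann, truth, reads = forge_from_config(cfg)
    _, _, control_genes, result, signif, _ = _run_sweep_core(cfg, ann, reads, outdir)
    clean = result[~result["dropout"]]
    by_fraction = clean.groupby("fraction")["log10_tpm_diff"].mean()
    return {
        "experiment": "sweep",
        "n_annotations": len(cfg.sweep.fractions) * cfg.sweep.reps_per_fraction,
        "control_genes": control_genes,
        "mean_log10_tpm_diff_by_fraction": {str(k): float(v)
                                            for k, v in by_fraction.items()},
        "significant_fractions": [float(f) for f in
                                  signif.loc[signif["significant"], "fraction"]],
    }


def _bimodality_coefficient(values: np.ndarray) -> float:
    """Sarle's bimodality coefficient (skew² + 1) / (kurtosis + 3·corr)."""
    from scipy.stats import kurtosis, skew
    n = values.size
    if n < 4 or np.ptp(values) == 0:
        return np.nan
    g = skew(values)
    k = kurtosis(values)
    corr = 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    return float((g ** 2 + 1.0) / (k + corr))


def _experiment_paralogs(cfg: ExperimentConfig, outdir: Path) -> dict:
    ann, truth, reads = forge_from_config(cfg)
    full_sq, full_gq = _quantify_pair(reads, ann, ann)
    control_genes = stats.stratified_select_genes(
        full_gq, n_bins=cfg.sweep.n_control_bins,
        bin_range_log10=(cfg.sweep.bin_lo_log10, cfg.sweep.bin_hi_log10),
        seed=cfg.seed + 200)
    keep_ids = [t for g in control_genes for t in ann.gene_members[g]]
    scheme = _sweep_scheme(cfg, keep_ids)

    stripped = annotation_ops.remove_paralogs(ann, control_genes)
    n_removed = ann.n_transcripts - stripped.n_transcripts

    summaries = {}
    for tag, base in (("with_paralogs", ann), ("without_paralogs", stripped)):
        entries = []
        for sub in annotation_ops.subsample_sweep(base, scheme):
            frac_str, rep_str = sub.label.removeprefix("sub_").split("pct_rep")
            sq, gq = _quantify_pair(reads, sub, ann)
            entries.append(stats.SweepEntry(float(frac_str), int(rep_str), sq, gq,
                                            sub.label))
        result = stats.build_sweep_result(entries, full_sq, full_gq, control_genes)
        tableio._write_tsv(result, outdir / f"sweep_result_{tag}.tsv", _meta(cfg))
        clean = result[~result["dropout"]]
        summaries[tag] = {
            g: _bimodality_coefficient(sub["log10_tpm_diff"].to_numpy())
            for g, sub in clean.groupby("gene_id")
        }
    return {
        "experiment": "paralogs",
        "n_paralog_transcripts_removed": int(n_removed),
        "bimodality": {tag: {g: (None if np.isnan(v) else float(v))
                             for g, v in vals.items()}
                       for tag, vals in summaries.items()},
    }


def _experiment_preclinicalize(cfg: ExperimentConfig, outdir: Path) -> dict:
    ann, truth, reads = forge_from_config(cfg)
    full_sq, full_gq = _quantify_pair(reads, ann, ann)

    # lowest-expressed member of each paralog family is the retained ortholog
    drop_map: dict[str, str] = {}
    if cfg.species.drop_family_competitors:
        fam_members: dict[str, set[str]] = {}
        for t in ann.transcripts:
            fam_members.setdefault(t.family_id, set()).add(t.gene_id)
        gtheta = truth.gene_theta(ann)
        for fam, genes in fam_members.items():
            if len(genes) > 1:
                drop_map[fam] = min(genes, key=lambda g: (gtheta.get(g, 0.0), g))

    summary: dict = {"experiment": "preclinicalize", "species": {}}
    for name, frac in zip(cfg.species.names, cfg.species.transcript_fracs):
        profile = synthetic_data.make_species_profile(
            ann, name, frac, seed=cfg.seed + 300,
            drop_family_competitors_of=drop_map or None)
        orth_full, reduced = annotation_ops.preclinicalize(
            ann, profile, reps=cfg.species.reps, seed=cfg.seed + 301)
        gene_quants = []
        for sub in reduced:
            _, gq = _quantify_pair(reads, sub, ann)
            gene_quants.append(gq)
        report = stats.characterize_inflated_genes(
            gene_quants, full_gq, n_perm=cfg.stats.n_perm, seed=cfg.seed + 302,
            tpm_diff_threshold=cfg.stats.tpm_diff_threshold)
        tableio._write_tsv(report.table.reset_index(),
                           outdir / f"inflation_{name}.tsv", _meta(cfg))
        summary["species"][name] = {
            "n_reduced_annotations": len(reduced),
            "n_ortholog_genes": orth_full.n_genes,
            "flagged_genes": list(report.flagged),
            "perm_percentile": (None if np.isnan(report.perm_percentile)
                                else float(report.perm_percentile)),
        }
    return summary


def _experiment_history(cfg: ExperimentConfig, outdir: Path) -> dict:
    ann, truth, reads = forge_from_config(cfg)
    full_sq, full_gq = _quantify_pair(reads, ann, ann)
    # pad the most expressed quartile of genes by 2x (historic inflated lengths)
    gtpm = full_gq.tpm.sort_values(ascending=False)
    padded_genes = list(gtpm.index[: max(1, len(gtpm) // 4)])
    padded = annotation_ops.vary_gene_lengths(ann, {g: 2.0 for g in padded_genes},
                                              mode="padded")
    sq_pad, gq_pad = _quantify_pair(reads, padded, padded)
    diff = (np.log10(gq_pad.tpm.reindex(padded_genes))
            - np.log10(full_gq.tpm.reindex(padded_genes)))
    tableio._write_tsv(
        pd.DataFrame({"gene_id": padded_genes, "log10_tpm_diff": diff.to_numpy()}),
        outdir / "length_padding_effect.tsv", _meta(cfg))
    return {
        "experiment": "history",
        "n_padded_genes": len(padded_genes),
        "median_log10_tpm_diff_padded_genes": float(diff.median()),
    }


def _experiment_correction(cfg: ExperimentConfig, outdir: Path) -> dict:
    # a wider, low-expression-heavy transcriptome stresses the depth mechanism
    ann, truth, reads = forge_from_config(cfg, n_genes=max(cfg.forge.n_genes, 1000),
                                          isoform_mean=3.0, seed_offset=40)
    thin = synthetic_data.thin_reads(reads, cfg.normalize.thin_keep_prob,
                                     seed=cfg.seed + 400)
    _, gq_human = _quantify_pair(reads, ann, ann)
    _, gq_species = _quantify_pair(thin, ann, ann)

    result = normalize.normalize_cross_species(
        human_samples={"human_1": gq_human.tpm},
        species_samples={"species_1": gq_species.tpm},
        tpm_floor=cfg.normalize.tpm_floor,
        logratio_trim=cfg.normalize.logratio_trim,
        abs_expr_trim=cfg.normalize.abs_expr_trim,
        min_genes=cfg.normalize.min_genes)

    # housekeeping analog: a seeded tissue-invariant panel spanning all
    # expression levels (a third of the genes)
    rng = np.random.default_rng(cfg.seed + 401)
    genes = np.array(ann.gene_ids, dtype=object)
    hk = list(rng.choice(genes, size=len(genes) // 3, replace=False))
    hk_summary = normalize.housekeeping_check(result, hk)

    tableio._write_tsv(result.summary, outdir / "correction_summary.tsv", _meta(cfg))
    tableio._write_tsv(result.diffs, outdir / "correction_diffs.tsv", _meta(cfg))
    tableio._write_tsv(hk_summary, outdir / "housekeeping_summary.tsv", _meta(cfg))

    med = result.summary.set_index("stage")["median_log10_diff"]
    return {
        "experiment": "correction",
        "reference": result.reference,
        "tmm_factor": float(result.factors["species_1"].factor),
        "effective_scale": float(result.factors["species_1"].effective_scale),
        "median_log10_diff_pre": float(med.loc["pre"]),
        "median_log10_diff_post": float(med.loc["post"]),
    }


_DISPATCH = {
    "sweep": _experiment_sweep,
    "paralogs": _experiment_paralogs,
    "preclinicalize": _experiment_preclinicalize,
    "history": _experiment_history,
    "correction": _experiment_correction,
}


def run_experiment(cfg: ExperimentConfig, which: str) -> dict:
    """Run one named experiment; returns (and writes) its summary dict.

    Identical config + seed produce byte-identical tables.  On failure the
    partially written output directory is removed.
    """
    if which not in _DISPATCH:
        raise ConfigurationError(
            f"unknown experiment {which!r}; expected one of {EXPERIMENTS}")
    outdir = Path(cfg.outdir) / which
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        summary = _DISPATCH[which](cfg, outdir)
    except Exception:
        logger.exception("experiment %s failed; removing partial outputs", which)
        shutil.rmtree(outdir, ignore_errors=True)
        raise
    summary["config_hash"] = cfg.config_hash()
    summary["seed"] = cfg.seed
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
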