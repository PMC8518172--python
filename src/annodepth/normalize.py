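"""Trimmed mean of M-values (TMM) and the cross-sample tpm correction.

``tmm_factor`` implements TMM from its definition (double trimming of M by
``logratio_trim`` and of A by ``abs_expr_trim``, precision weighting by the
delta-method variance).  The returned ``factor`` is the scale-free
multiplier 2^(−weighted trimmed mean of M): it is exactly 1 for a sample
against itself and invariant to rescaling either vector.  The library-size
ratio on the filtered gene set is reported separately and applied together
with the factor by ``normalize_cross_species`` (a pure per-sample
rescaling, so within-sample gene ranks are untouched).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import NormalizationError, ValidationError

__all__ = [
    "TMMResult",
    "CorrectionResult",
    "tmm_factor",
    "normalize_cross_species",
    "housekeeping_check",
]

logger = logging.getLogger(__name__)

LOGRATIO_TRIM_DEFAULT = 0.30
ABS_EXPR_TRIM_DEFAULT = 0.05
MIN_GENES_DEFAULT = 10


@dataclass(frozen=True)
class TMMResult:
    factor: float                 # scale-free correction multiplier for the test sample
    logratio_trim: float
    abs_expr_trim: float
    genes_used: frozenset[str]    # genes surviving the double trim
    weighted_mean_m: float        # precision-weighted trimmed mean of M (test vs ref)
    lib_size_ratio: float         # N_ref / N_test on the filtered gene set

    def __post_init__(self) -> None:
        if not (self.factor > 0):
            raise NormalizationError(f"non-positive TMM factor {self.factor}")

    @property
    def effective_scale(self) -> float:
        """Full multiplier applied to the test sample (factor × library ratio)."""
        return self.factor * self.lib_size_ratio


def _align(ref, test) -> tuple[pd.Series, pd.Series]:
    ref = pd.Series(ref, dtype=float)
    test = pd.Series(test, dtype=float)
    common = ref.index.intersection(test.index)
    if len(common) == 0:
        raise ValidationError("expression vectors share no genes")
    return ref.loc[common], test.loc[common]


def tmm_factor(
    ref_expr,
    test_expr,
    logratio_trim: float = LOGRATIO_TRIM_DEFAULT,
    abs_expr_trim: float = ABS_EXPR_TRIM_DEFAULT,
    min_genes: int = MIN_GENES_DEFAULT,
) -> TMMResult:
    """TMM factor of ``test_expr`` against ``ref_expr``.

    Both are gene-indexed expression vectors (pd.Series or aligned arrays).
    Genes non-positive in either vector are discarded before library-size
    normalization.  Raises ``NormalizationError`` when fewer than
    ``min_genes`` genes survive the double trim.
    """
    if not (0.0 <= logratio_trim < 0.5) or not (0.0 <= abs_expr_trim < 0.5):
        raise NormalizationError("trim fractions must lie in [0, 0.5)")
    ref, test = _align(ref_expr, test_expr)
    keep_pos = (ref > 0) & (test > 0)
    ref, test = ref[keep_pos], test[keep_pos]
    if len(ref) == 0:
        raise NormalizationError("no genes positive in both samples")

    n_ref, n_test = float(ref.sum()), float(test.sum())
    r = ref.to_numpy() / n_ref
    t = test.to_numpy() / n_test
    M = np.log2(t) - np.log2(r)
    A = 0.5 * (np.log2(t) + np.log2(r))

    n = M.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_expr_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(M)
    rank_a = rankdata(A)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep.sum() < min_genes:
        raise NormalizationError(
            f"only {int(keep.sum())} genes survive trimming (< {min_genes})")

    # delta-method variance of M on the normalized proportions; weights are
    # its inverse.  Using proportions (not raw library sizes) keeps the
    # factor exactly invariant to rescaling either input vector.
    var = (1.0 - t) / t + (1.0 - r) / r
    var = np.maximum(var, 1e-12)
    f = float(np.sum(M[keep] / var[keep]) / np.sum(1.0 / var[keep]))

    return TMMResult(
        factor=float(2.0 ** (-f)),
        logratio_trim=logratio_trim,
        abs_expr_trim=abs_expr_trim,
        genes_used=frozenset(ref.index[keep]),
        weighted_mean_m=f,
        lib_size_ratio=n_ref / n_test,
    )


@dataclass(frozen=True)
class CorrectionResult:
    """Outcome of the cross-sample tpm correction."""

    reference: str
    factors: Mapping[str, TMMResult]          # per corrected sample
    corrected: Mapping[str, pd.Series]        # corrected tpm on reference gene ids
    diffs: pd.DataFrame                       # sample, gene_id, stage, log10_diff
    summary: pd.DataFrame                     # sample, stage, median_log10_diff, n_genes


def _pick_reference(samples: Mapping[str, pd.Series]) -> str:
    """Sample whose upper quartile is closest to the mean upper quartile."""
    quartiles = {}
    for name, expr in samples.items():
        pos = expr[expr > 0]
        quartiles[name] = float(np.percentile(pos, 75)) if len(pos) else 0.0
    target = float(np.mean(list(quartiles.values())))
    return min(quartiles, key=lambda k: (abs(quartiles[k] - target), k))


def normalize_cross_species(
    human_samples: Mapping[str, pd.Series],
    species_samples: Mapping[str, pd.Series],
    ortholog_map: Mapping[str, str] | None = None,
    tpm_floor: float = 1.0,
    *,
    logratio_trim: float = LOGRATIO_TRIM_DEFAULT,
    abs_expr_trim: float = ABS_EXPR_TRIM_DEFAULT,
    min_genes: int = MIN_GENES_DEFAULT,
    reference: str | None = None,
) -> CorrectionResult:
    """TMM-correct species tpm tables against a human reference.

    ``ortholog_map`` maps species gene ids to reference (human) gene ids,
    one-to-one; ``None`` means the tables already share gene ids.  Genes
    must exceed ``tpm_floor`` strictly, in both members of each compared
    pair, to enter the M/A computation.  Each species sample is multiplied
    by its ``TMMResult.effective_scale``; diagnostics report per-sample
    distributions of log10(tpm_species) − log10(median human tpm) before
    and after correction on a fixed gene set.
    """
    if tpm_floor < 0:
        raise ValidationError("tpm_floor must be >= 0")
    if not human_samples or not species_samples:
        raise ValidationError("need at least one sample on each side")
    if ortholog_map is not None:
        humans_mapped = list(ortholog_map.values())
        if len(set(ortholog_map)) != len(humans_mapped) or \
                len(set(humans_mapped)) != len(humans_mapped):
            raise ValidationError("ortholog map is not one-to-one")

    human = {k: pd.Series(v, dtype=float) for k, v in human_samples.items()}
    species: dict[str, pd.Series] = {}
    for name, expr in species_samples.items():
        expr = pd.Series(expr, dtype=float)
        if ortholog_map is not None:
            expr = expr[expr.index.isin(ortholog_map)]
            expr.index = expr.index.map(ortholog_map)
        species[name] = expr

    human_genes = set.union(*(set(v.index) for v in human.values()))
    common = sorted(set.union(*(set(v.index) for v in species.values())) & human_genes)
    if not common:
        raise ValidationError("empty ortholog intersection between the two sides")

    ref_name = reference if reference is not None else _pick_reference(human)
    if ref_name not in human:
        raise ValidationError(f"reference sample {ref_name!r} not among human samples")
    ref = human[ref_name]
    human_median = pd.concat(human.values(), axis=1).median(axis=1)

    factors: dict[str, TMMResult] = {}
    corrected: dict[str, pd.Series] = {}
    rows = []
    for name, expr in species.items():
        pair = pd.concat([ref, expr], axis=1, join="inner", keys=["ref", "test"])
        passing = pair[(pair["ref"] > tpm_floor) & (pair["test"] > tpm_floor)]
        res = tmm_factor(passing["ref"], passing["test"],
                         logratio_trim=logratio_trim, abs_expr_trim=abs_expr_trim,
                         min_genes=min_genes)
        factors[name] = res
        corr = expr * res.effective_scale
        corrected[name] = corr

        med = human_median.reindex(expr.index)
        mask = (expr > tpm_floor) & (med > tpm_floor)
        genes = expr.index[mask.fillna(False)]
        pre = np.log10(expr.loc[genes]) - np.log10(med.loc[genes])
        post = np.log10(corr.loc[genes]) - np.log10(med.loc[genes])
        for stage, diffs in (("pre", pre), ("post", post)):
            rows.append(pd.DataFrame({
                "sample": name, "gene_id": genes, "stage": stage,
                "log10_diff": diffs.to_numpy(),
            }))

    diffs = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["sample", "gene_id", "stage", "log10_diff"])
    summary = (diffs.groupby(["sample", "stage"])["log10_diff"]
               .agg(median_log10_diff="median", n_genes="size").reset_index())
    return CorrectionResult(reference=ref_name, factors=factors,
                            corrected=corrected, diffs=diffs, summary=summary)


def housekeeping_check(result: CorrectionResult,
                       housekeeping_genes: Iterable[str]) -> pd.DataFrame:
    """Median log differences restricted to a housekeeping panel.

    Returns a tidy frame (sample, stage, median_log10_diff, n_genes);
    empty, with a logged warning, when the panel does not intersect the
    compared gene set.
    """
    panel = set(housekeeping_genes)
    if not panel:
        raise ValidationError("housekeeping set is empty")
    sub = result.diffs[result.diffs["gene_id"].isin(panel)]
    if sub.empty:
        logger.warning("housekeeping panel does not intersect the compared genes")
        return pd.DataFrame(columns=["sample", "stage", "median_log10_diff", "n_genes"])
    return (sub.groupby(["sample", "stage"])["log10_diff"]
            .agg(median_log10_diff="median", n_genes="size").reset_index())
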