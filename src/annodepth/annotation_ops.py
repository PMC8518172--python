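"""Perturbed annotations: the subsampling sweep, paralog removal,
pre-clinicalization and parametric gene-length variation."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np

from .errors import ConfigurationError, ValidationError
from .synthetic_data import Annotation, Block, SpeciesProfile, Transcript

__all__ = [
    "SweepScheme",
    "subsample_sweep",
    "remove_paralogs",
    "preclinicalize",
    "vary_gene_lengths",
]


@dataclass(frozen=True)
class SweepScheme:
    """Protocol for the annotation-depth sweep.

    ``fractions`` are percentages of the sampling pool (the full annotation
    minus ``keep_ids``); every emitted annotation re-inserts the entire
    ``keep_ids`` control set.
    """

    fractions: tuple[float, ...] = tuple(range(1, 100))
    reps_per_fraction: int = 100
    keep_ids: frozenset[str] = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fractions:
            raise ConfigurationError("no fractions given")
        if any(not (0.0 < f < 100.0) for f in self.fractions):
            raise ConfigurationError("fractions must lie in (0, 100)")
        if self.reps_per_fraction < 1:
            raise ConfigurationError("reps_per_fraction must be >= 1")

    @property
    def n_annotations(self) -> int:
        return len(self.fractions) * self.reps_per_fraction


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def subsample_sweep(full: Annotation, scheme: SweepScheme) -> Iterator[Annotation]:
    """Yield one annotation per (fraction, replicate) of the scheme.

    Each annotation holds round(fraction% × pool size) transcripts sampled
    without replacement from the pool (full minus keep set), plus the whole
    keep set.  Labels are ``sub_{fraction:g}pct_rep{rep}``.  Deterministic
    given ``scheme.seed``.
    """
    all_ids = set(full.transcript_ids)
    if not scheme.keep_ids <= all_ids:
        missing = scheme.keep_ids - all_ids
        raise ValidationError(f"keep set not in the annotation: {sorted(missing)[:5]}")
    pool = np.array([t for t in full.transcript_ids if t not in scheme.keep_ids],
                    dtype=object)
    if pool.size == 0:
        raise ValidationError("sampling pool is empty after removing the keep set")

    rng = np.random.default_rng(scheme.seed)
    for frac in scheme.fractions:
        size = max(1, _round_half_up(frac / 100.0 * pool.size))
        for rep in range(1, scheme.reps_per_fraction + 1):
            sampled = rng.choice(pool, size=size, replace=False)
            ids = set(sampled) | scheme.keep_ids
            yield full.subset(ids, label=f"sub_{frac:g}pct_rep{rep}")


def remove_paralogs(full: Annotation, target_genes: Iterable[str]) -> Annotation:
    """Remove the paralog-family competitors of ``target_genes``.

    Every transcript whose family matches a target gene's family but whose
    gene is not itself a target is dropped; target genes' own transcripts
    are kept intact.
    """
    targets = set(target_genes)
    unknown = targets - set(full.gene_ids)
    if unknown:
        raise ValidationError(f"unknown gene ids: {sorted(unknown)[:5]}")
    target_families = {t.family_id for t in full.transcripts if t.gene_id in targets}
    kept = tuple(
        t for t in full.transcripts
        if t.family_id not in target_families or t.gene_id in targets
    )
    return Annotation(label=f"{full.label}_noparalogs", transcripts=kept,
                      version_tag=full.version_tag)


def preclinicalize(
    full: Annotation,
    profile: SpeciesProfile,
    reps: int,
    seed: int = 0,
) -> tuple[Annotation, list[Annotation]]:
    """Reduce per-gene transcript counts to a species profile's level.

    Returns ``(ortholog_full, reduced)``: the full-depth annotation
    restricted to the profile's ortholog genes, and ``reps`` reduced
    annotations in which every ortholog gene carries exactly
    ``per_gene_transcript_count[g]`` transcripts (sampled without
    replacement within a rep, independently across reps).
    """
    if reps < 1:
        raise ConfigurationError("reps must be >= 1")
    profile.validate_against(full)
    orth_ids = [t.transcript_id for t in full.transcripts
                if t.gene_id in profile.ortholog_genes]
    if not orth_ids:
        raise ValidationError(f"profile {profile.name!r} has no ortholog genes in common")
    ortholog_full = full.subset(orth_ids, label=f"{profile.name}_ortholog_full")

    rng = np.random.default_rng(seed)
    reduced: list[Annotation] = []
    for rep in range(1, reps + 1):
        chosen: list[str] = []
        for g in ortholog_full.gene_ids:
            members = ortholog_full.gene_members[g]
            want = profile.per_gene_transcript_count.get(g, len(members))
            if want >= len(members):
                chosen.extend(members)
            else:
                picked = rng.choice(np.array(members, dtype=object), size=want,
                                    replace=False)
                chosen.extend(picked)
        reduced.append(ortholog_full.subset(
            chosen, label=f"preclin_{profile.name}_rep{rep}"))
    return ortholog_full, reduced


def vary_gene_lengths(
    full: Annotation,
    length_factor: Mapping[str, float],
    mode: str = "padded",
) -> Annotation:
    """Parametric historical-annotation emulation: scale gene lengths.

    ``padded`` appends an unexpressed private block per transcript (no read
    ever carries a padding block, so length grows but counts cannot);
    ``trimmed`` drops trailing blocks until the transcript length falls to
    roughly factor × original (never below one block).
    """
    if mode not in ("padded", "trimmed"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    unknown = set(length_factor) - set(full.gene_ids)
    if unknown:
        raise ValidationError(f"unknown gene ids: {sorted(unknown)[:5]}")
    if any(f <= 0 for f in length_factor.values()):
        raise ConfigurationError("length factors must be positive")

    out: list[Transcript] = []
    for t in full.transcripts:
        factor = length_factor.get(t.gene_id, 1.0)
        if factor == 1.0:
            out.append(t)
            continue
        if mode == "padded":
            if factor < 1.0:
                raise ConfigurationError(
                    f"padded mode needs factor >= 1 (gene {t.gene_id}: {factor})")
            pad = int(round((factor - 1.0) * t.length))
            if pad == 0:
                out.append(t)
                continue
            blocks = t.blocks + (Block(f"{t.transcript_id}.pad", pad),)
        else:  # trimmed
            target = int(round(factor * t.length))
            if target < 1:
                raise ValidationError(
                    f"trimming {t.transcript_id} to {target} nt (< 1) is not allowed")
            blocks = list(t.blocks)
            length = t.length
            while len(blocks) > 1 and length - blocks[-1].length >= target:
                length -= blocks[-1].length
                blocks.pop()
            blocks = tuple(blocks)
        out.append(Transcript(transcript_id=t.transcript_id, gene_id=t.gene_id,
                              family_id=t.family_id, blocks=blocks))
    return Annotation(label=f"{full.label}_{mode}", transcripts=tuple(out),
                      version_tag=full.version_tag)
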