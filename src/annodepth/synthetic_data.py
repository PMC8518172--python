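"""Synthetic transcriptomes, expression ground truth and read sets.

The generative model is deliberately abstract: transcripts are ordered
tuples of *blocks* (shared segments standing in for mappable homology),
reads are (origin transcript, block) pairs, and a read's compatibility set
against any annotation is the set of annotated transcripts containing its
block.  This captures multi-mapping competition without nucleotide-level
alignment.

All generators are deterministic given their integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Mapping

import numpy as np
from scipy import optimize

from .errors import ConfigurationError, ValidationError

__all__ = [
    "Block",
    "Transcript",
    "Annotation",
    "ExpressionTruth",
    "SpeciesProfile",
    "ReadSet",
    "Constant",
    "ZeroTruncatedNegBin",
    "LogNormalLength",
    "FamilySpec",
    "forge_transcriptome",
    "simulate_expression",
    "simulate_reads",
    "thin_reads",
    "make_species_profile",
]

#: Lower edge (log10 tpm) of the abundance band populated by default.
LOG10_TPM_LO = 0.5
#: Number of abundance bins guaranteed to be occupied by the default truth.
N_ABUNDANCE_BINS = 10


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Block:
    """An abstract sequence segment; identity (block_id) encodes homology."""

    block_id: str
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError(f"block {self.block_id!r} has length {self.length} < 1")


@dataclass(frozen=True)
class Transcript:
    """One annotated transcript: an ordered tuple of blocks."""

    transcript_id: str
    gene_id: str
    family_id: str
    blocks: tuple[Block, ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValidationError(f"transcript {self.transcript_id!r} has no blocks")

    @property
    def length(self) -> int:
        """Transcript length in nucleotides (sum of block lengths)."""
        return sum(b.length for b in self.blocks)

    @property
    def block_ids(self) -> tuple[str, ...]:
        return tuple(b.block_id for b in self.blocks)


@dataclass(frozen=True)
class Annotation:
    """A versioned set of transcripts ('the transcriptome')."""

    label: str
    transcripts: tuple[Transcript, ...]
    version_tag: str = ""

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValidationError(f"annotation {self.label!r} is empty")
        ids = [t.transcript_id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"annotation {self.label!r} has duplicate transcript ids")

    # -- convenience views (cached; Annotation is immutable) ---------------

    @cached_property
    def by_id(self) -> Mapping[str, Transcript]:
        return {t.transcript_id: t for t in self.transcripts}

    @cached_property
    def transcript_ids(self) -> tuple[str, ...]:
        return tuple(t.transcript_id for t in self.transcripts)

    @cached_property
    def gene_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.transcripts:
            seen.setdefault(t.gene_id, None)
        return tuple(seen)

    @cached_property
    def gene_members(self) -> Mapping[str, tuple[str, ...]]:
        members: dict[str, list[str]] = {}
        for t in self.transcripts:
            members.setdefault(t.gene_id, []).append(t.transcript_id)
        return {g: tuple(v) for g, v in members.items()}

    @cached_property
    def block_index(self) -> Mapping[str, tuple[str, ...]]:
        """block_id -> transcript ids containing that block."""
        index: dict[str, list[str]] = {}
        for t in self.transcripts:
            for b in t.blocks:
                index.setdefault(b.block_id, []).append(t.transcript_id)
        return {b: tuple(v) for b, v in index.items()}

    @property
    def n_transcripts(self) -> int:
        return len(self.transcripts)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def lengths(self) -> np.ndarray:
        return np.array([t.length for t in self.transcripts], dtype=float)

    def subset(self, transcript_ids: Iterable[str], label: str,
               version_tag: str | None = None) -> "Annotation":
        """New annotation restricted to ``transcript_ids`` (original order kept)."""
        wanted = set(transcript_ids)
        unknown = wanted - set(self.transcript_ids)
        if unknown:
            raise ValidationError(f"unknown transcript ids: {sorted(unknown)[:5]} ...")
        kept = tuple(t for t in self.transcripts if t.transcript_id in wanted)
        return Annotation(label=label, transcripts=kept,
                          version_tag=self.version_tag if version_tag is None else version_tag)


@dataclass(frozen=True)
class ExpressionTruth:
    """Ground-truth molar proportions per transcript (sum to 1)."""

    theta: Mapping[str, float]

    def __post_init__(self) -> None:
        vals = np.fromiter(self.theta.values(), dtype=float)
        if vals.size == 0:
            raise ValidationError("empty expression truth")
        if (vals < 0).any():
            raise ValidationError("negative theta")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValidationError(f"theta sums to {vals.sum():.12f}, not 1")

    def gene_theta(self, annotation: Annotation) -> dict[str, float]:
        out: dict[str, float] = {}
        for t in annotation.transcripts:
            out[t.gene_id] = out.get(t.gene_id, 0.0) + self.theta.get(t.transcript_id, 0.0)
        return out


@dataclass(frozen=True)
class SpeciesProfile:
    """Annotation style of a (pre-clinical) species vs a reference annotation."""

    name: str
    per_gene_transcript_count: Mapping[str, int]
    ortholog_genes: frozenset[str]

    def __post_init__(self) -> None:
        bad = {g: c for g, c in self.per_gene_transcript_count.items() if c < 1}
        if bad:
            raise ValidationError(f"per-gene transcript counts < 1: {sorted(bad)[:5]}")

    def validate_against(self, full: Annotation) -> None:
        if not self.ortholog_genes <= set(full.gene_ids):
            extra = self.ortholog_genes - set(full.gene_ids)
            raise ValidationError(f"ortholog genes not in reference: {sorted(extra)[:5]}")
        for g, c in self.per_gene_transcript_count.items():
            have = len(full.gene_members.get(g, ()))
            if c > have:
                raise ValidationError(
                    f"profile {self.name!r} wants {c} transcripts for {g}, only {have} exist")


@dataclass(frozen=True)
class ReadSet:
    """Simulated reads stored columnarly.

    ``block_vocab``/``tx_vocab`` are the id vocabularies of the generating
    annotation; per-read data are integer codes into them.  Compatibility
    against any annotation is recomputed from the block id.
    """

    block_vocab: np.ndarray          # str array, code -> block_id
    tx_vocab: np.ndarray             # str array, code -> transcript_id
    block_codes: np.ndarray          # int per read
    origin_codes: np.ndarray         # int per read

    def __post_init__(self) -> None:
        if self.block_codes.shape != self.origin_codes.shape:
            raise ValidationError("block/origin arrays differ in length")

    def __len__(self) -> int:
        return int(self.block_codes.size)

    @property
    def origin_ids(self) -> np.ndarray:
        return self.tx_vocab[self.origin_codes]

    @property
    def block_ids(self) -> np.ndarray:
        return self.block_vocab[self.block_codes]

    def compatibility(self, annotation: Annotation, read_index: int) -> frozenset[str]:
        """Compatibility set of one read against ``annotation``."""
        block = self.block_vocab[self.block_codes[read_index]]
        return frozenset(annotation.block_index.get(block, ()))

    def compatibility_sizes(self, annotation: Annotation) -> np.ndarray:
        """Per-read |compatibility set| against ``annotation`` (vectorised)."""
        sizes = np.array(
            [len(annotation.block_index.get(b, ())) for b in self.block_vocab],
            dtype=int,
        )
        return sizes[self.block_codes]


# ---------------------------------------------------------------------------
# distribution specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Constant:
    """Degenerate distribution (always ``value``)."""

    value: int

    def __post_init__(self) -> None:
        if self.value < 1:
            raise ConfigurationError(f"Constant value must be >= 1, got {self.value}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return np.full(size, self.value, dtype=int)

    @property
    def mean(self) -> float:
        return float(self.value)


@dataclass(frozen=True)
class ZeroTruncatedNegBin:
    """Zero-truncated negative binomial parameterised by its truncated mean."""

    mean: float
    shape: float = 2.0  # NB dispersion r

    def __post_init__(self) -> None:
        if not (self.mean > 1.0):
            raise ConfigurationError(f"truncated mean must exceed 1, got {self.mean}")
        if self.shape <= 0:
            raise ConfigurationError("shape must be positive")
        object.__setattr__(self, "_p", self._solve_p())

    def _solve_p(self) -> float:
        r, target = self.shape, self.mean

        def trunc_mean(p: float) -> float:
            mu = r * (1.0 - p) / p
            p0 = p ** r
            return mu / (1.0 - p0) - target

        # p -> 1 gives truncated mean -> 1; p -> 0 gives +inf
        return float(optimize.brentq(trunc_mean, 1e-9, 1 - 1e-9))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        p = self._p
        out = np.empty(size, dtype=int)
        filled = 0
        while filled < size:
            draw = rng.negative_binomial(self.shape, p, size=max(size - filled, 16))
            draw = draw[draw >= 1]
            take = min(draw.size, size - filled)
            out[filled:filled + take] = draw[:take]
            filled += take
        return out


@dataclass(frozen=True)
class LogNormalLength:
    """Log-normal transcript/gene length distribution with a floor."""

    mean: float = 1500.0
    sigma: float = 0.6
    minimum: int = 50

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.sigma <= 0 or self.minimum < 1:
            raise ConfigurationError("invalid length distribution parameters")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        mu = math.log(self.mean) - self.sigma ** 2 / 2.0
        draw = np.rint(rng.lognormal(mu, self.sigma, size=size)).astype(int)
        return np.maximum(draw, self.minimum)


@dataclass(frozen=True)
class FamilySpec:
    """How many genes sit in paralog families and how much block length they share."""

    fraction_of_genes: float = 0.20
    min_size: int = 2
    max_size: int = 6
    shared_frac_low: float = 0.30
    shared_frac_high: float = 0.70

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_of_genes <= 1.0):
            raise ConfigurationError("fraction_of_genes must be in [0, 1]")
        if self.min_size < 2 or self.max_size < self.min_size:
            raise ConfigurationError("family sizes must satisfy 2 <= min <= max")
        if not (0.0 < self.shared_frac_low <= self.shared_frac_high < 1.0):
            raise ConfigurationError("shared fraction bounds must satisfy 0 < lo <= hi < 1")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _partition_length(rng: np.random.Generator, total: int, n_parts: int) -> list[int]:
    """Split ``total`` nt into ``n_parts`` positive integer pieces."""
    n_parts = max(1, min(n_parts, total))
    if n_parts == 1:
        return [total]
    w = rng.dirichlet(np.ones(n_parts))
    lens = np.maximum(1, np.floor(w * total).astype(int))
    # fix rounding so pieces sum to total exactly
    lens[-1] += total - int(lens.sum())
    while lens[-1] < 1:  # pathological roundings on tiny totals
        lens[np.argmax(lens[:-1])] -= 1
        lens[-1] += 1
    return [int(x) for x in lens]


def forge_transcriptome(
    n_genes: int,
    isoform_dist=None,
    family_spec: FamilySpec | None = None,
    length_dist: LogNormalLength | None = None,
    seed: int = 0,
    *,
    label: str = "full",
    version_tag: str = "v1",
    blocks_per_gene: tuple[int, int] = (3, 7),
    isoform_block_keep_prob: float = 0.6,
) -> Annotation:
    """Generate a multi-isoform transcriptome with paralog families.

    Each gene owns a pool of private blocks; genes in a paralog family
    additionally carry family-shared blocks making up a configurable
    fraction of the family's base length.  The first isoform of each gene
    is the full block pool; further isoforms keep a designated core block
    plus a random subset, so isoforms of one gene always share >= 1 block
    and blocks are shared across genes only within a family.

    Deterministic given ``seed``.
    """
    if n_genes < 1:
        raise ConfigurationError(f"n_genes must be >= 1, got {n_genes}")
    if not (0.0 < isoform_block_keep_prob <= 1.0):
        raise ConfigurationError("isoform_block_keep_prob must be in (0, 1]")
    isoform_dist = isoform_dist if isoform_dist is not None else ZeroTruncatedNegBin(7.0)
    family_spec = family_spec if family_spec is not None else FamilySpec()
    length_dist = length_dist if length_dist is not None else LogNormalLength()

    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]

    # --- partition genes into paralog families -----------------------------
    n_fam_genes = int(round(family_spec.fraction_of_genes * n_genes))
    order = rng.permutation(n_genes)
    families: list[list[str]] = []
    cursor = 0
    fam_counter = 0
    while cursor + family_spec.min_size <= n_fam_genes:
        size = int(rng.integers(family_spec.min_size, family_spec.max_size + 1))
        size = min(size, n_fam_genes - cursor)
        if size < family_spec.min_size:
            break
        families.append([gene_ids[j] for j in order[cursor:cursor + size]])
        cursor += size
        fam_counter += 1

    family_of: dict[str, str] = {g: f"fam_{g}" for g in gene_ids}  # singletons
    shared_blocks_of: dict[str, tuple[Block, ...]] = {g: () for g in gene_ids}
    base_len_of: dict[str, int] = {}

    for j, members in enumerate(families):
        fam_id = f"fam{j:04d}"
        shared_frac = float(rng.uniform(family_spec.shared_frac_low,
                                        family_spec.shared_frac_high))
        base_len = int(length_dist.sample(rng, 1)[0])
        shared_len = max(1, int(round(shared_frac * base_len)))
        shared_len = min(shared_len, base_len - 1)
        n_shared = int(rng.integers(1, 4))
        pieces = _partition_length(rng, shared_len, n_shared)
        shared = tuple(Block(f"{fam_id}.s{k}", piece) for k, piece in enumerate(pieces))
        for g in members:
            family_of[g] = fam_id
            shared_blocks_of[g] = shared
            base_len_of[g] = base_len

    # --- build genes --------------------------------------------------------
    iso_counts = isoform_dist.sample(rng, n_genes)
    transcripts: list[Transcript] = []
    for gi, g in enumerate(gene_ids):
        shared = shared_blocks_of[g]
        if shared:
            total_len = base_len_of[g]
            private_len = max(1, total_len - sum(b.length for b in shared))
        else:
            private_len = int(length_dist.sample(rng, 1)[0])
        n_priv = int(rng.integers(blocks_per_gene[0], blocks_per_gene[1] + 1))
        priv_pieces = _partition_length(rng, private_len, n_priv)
        private = tuple(Block(f"{g}.b{k}", piece) for k, piece in enumerate(priv_pieces))
        pool = shared + private
        core = private[0] if private else shared[0]

        k = int(iso_counts[gi])
        for t in range(k):
            if t == 0:
                blocks = pool  # canonical isoform carries everything
            else:
                keep = rng.random(len(pool)) < isoform_block_keep_prob
                blocks = tuple(b for b, m in zip(pool, keep) if m or b is core)
                if core not in blocks:
                    blocks = (core,) + blocks
            transcripts.append(Transcript(
                transcript_id=f"{g}.t{t + 1}",
                gene_id=g,
                family_id=family_of[g],
                blocks=blocks,
            ))

    return Annotation(label=label, transcripts=tuple(transcripts), version_tag=version_tag)


def simulate_expression(
    annotation: Annotation,
    dynamic_range_log10: float = 4.0,
    seed: int = 0,
    *,
    isoform_alpha: float = 1.5,
) -> ExpressionTruth:
    """Ground-truth molar proportions spanning ``dynamic_range_log10`` decades.

    Gene-level expected tpm targets are placed on [LOG10_TPM_LO,
    LOG10_TPM_LO + range]: when there are enough genes, two genes are
    pinned into each of the N_ABUNDANCE_BINS equal-width bins (including
    the exact interval endpoints) and the rest drawn log-uniformly, then
    rescaled so expected gene tpm sums to 10^6 exactly.  Gene mass is split
    across isoforms by a symmetric Dirichlet.
    """
    if not (dynamic_range_log10 > 0):
        raise ConfigurationError("dynamic_range_log10 must be > 0")
    rng = np.random.default_rng(seed)

    genes = list(annotation.gene_ids)
    n_genes = len(genes)
    lo, hi = LOG10_TPM_LO, LOG10_TPM_LO + dynamic_range_log10
    total = 1e6

    if n_genes == 1:
        gene_mass = np.array([total])
    else:
        perm = rng.permutation(n_genes)
        targets = np.empty(n_genes)
        n_pin = 2 * N_ABUNDANCE_BINS
        if n_genes >= 2 * n_pin:
            edges = np.linspace(lo, hi, N_ABUNDANCE_BINS + 1)
            pins = []
            for b in range(N_ABUNDANCE_BINS):
                pins.extend(rng.uniform(edges[b], edges[b + 1], size=2))
            pins[0], pins[-1] = lo, hi  # pin the exact endpoints
            targets[perm[:n_pin]] = pins
            targets[perm[n_pin:]] = rng.uniform(lo, hi, size=n_genes - n_pin)
            pinned = np.zeros(n_genes, dtype=bool)
            pinned[perm[:n_pin]] = True
        else:
            targets[:] = rng.uniform(lo, hi, size=n_genes)
            imin, imax = perm[0], perm[1 % n_genes]
            targets[imin], targets[imax] = lo, hi
            pinned = np.zeros(n_genes, dtype=bool)
            pinned[[imin, imax]] = True

        gene_mass = 10.0 ** targets
        pinned_mass = gene_mass[pinned].sum()
        rest_mass = gene_mass[~pinned].sum()
        if pinned_mass < 0.8 * total and rest_mass > 0:
            # rescale only the unpinned genes: pinned targets stay exact
            gene_mass[~pinned] *= (total - pinned_mass) / rest_mass
        else:  # not enough budget: plain normalisation (log shift, span kept)
            gene_mass *= total / gene_mass.sum()

    theta: dict[str, float] = {}
    for gi, g in enumerate(genes):
        members = annotation.gene_members[g]
        if len(members) == 1:
            split = np.array([1.0])
        else:
            split = rng.dirichlet(np.full(len(members), isoform_alpha))
        for tid, frac in zip(members, split):
            theta[tid] = gene_mass[gi] * frac / total

    vals = np.fromiter(theta.values(), dtype=float)
    norm = vals.sum()
    theta = {k: v / norm for k, v in theta.items()}
    return ExpressionTruth(theta=theta)


def simulate_reads(
    truth: ExpressionTruth,
    annotation: Annotation,
    n_reads: int,
    seed: int = 0,
) -> ReadSet:
    """Draw reads: origin transcript ∝ theta_i × length_i, block ∝ block length."""
    if n_reads < 0:
        raise ConfigurationError("n_reads must be >= 0")
    unknown = set(truth.theta) - set(annotation.transcript_ids)
    if unknown:
        raise ValidationError(
            f"truth refers to transcripts not in the annotation: {sorted(unknown)[:5]}")

    rng = np.random.default_rng(seed)
    tx_vocab = np.array(annotation.transcript_ids, dtype=object)
    block_vocab = np.array(list(annotation.block_index), dtype=object)
    block_code = {b: i for i, b in enumerate(block_vocab)}

    theta = np.array([truth.theta.get(t, 0.0) for t in tx_vocab], dtype=float)
    lengths = annotation.lengths()
    w = theta * lengths
    if n_reads > 0 and w.sum() <= 0:
        raise ValidationError("all transcripts have zero expression; cannot draw reads")

    block_codes = np.empty(n_reads, dtype=np.int64)
    origin_codes = np.empty(n_reads, dtype=np.int64)
    if n_reads > 0:
        p = w / w.sum()
        origins = rng.choice(len(tx_vocab), size=n_reads, p=p)
        pos = 0
        for ti in np.unique(origins):
            count = int((origins == ti).sum())
            tx = annotation.transcripts[ti]
            codes = np.array([block_code[b.block_id] for b in tx.blocks])
            lens = np.array([b.length for b in tx.blocks], dtype=float)
            draw = rng.choice(codes, size=count, p=lens / lens.sum())
            block_codes[pos:pos + count] = draw
            origin_codes[pos:pos + count] = ti
            pos += count

    return ReadSet(block_vocab=block_vocab, tx_vocab=tx_vocab,
                   block_codes=block_codes, origin_codes=origin_codes)


def thin_reads(reads: ReadSet, keep_prob: float, seed: int = 0) -> ReadSet:
    """Retain each read independently with probability ``keep_prob``."""
    if not (0.0 <= keep_prob <= 1.0):
        raise ConfigurationError(f"keep_prob must be in [0, 1], got {keep_prob}")
    rng = np.random.default_rng(seed)
    if keep_prob == 1.0:
        mask = np.ones(len(reads), dtype=bool)
    else:
        mask = rng.random(len(reads)) < keep_prob
    return ReadSet(block_vocab=reads.block_vocab, tx_vocab=reads.tx_vocab,
                   block_codes=reads.block_codes[mask],
                   origin_codes=reads.origin_codes[mask])


def make_species_profile(
    full: Annotation,
    name: str,
    transcript_frac: float,
    seed: int = 0,
    *,
    ortholog_genes: Iterable[str] | None = None,
    drop_family_competitors_of: Mapping[str, str] | None = None,
) -> SpeciesProfile:
    """Build a species profile with ``transcript_frac`` of the reference
    transcripts-per-gene (rounded, floor 1).

    ``ortholog_genes`` defaults to all genes.  ``drop_family_competitors_of``
    maps family_id -> the one gene of that family to keep as an ortholog;
    all other members of those families are removed from the ortholog set
    (modelling paralogs not yet annotated in the species).
    """
    if not (0.0 < transcript_frac <= 1.0):
        raise ConfigurationError("transcript_frac must be in (0, 1]")
    orthologs = set(full.gene_ids) if ortholog_genes is None else set(ortholog_genes)
    if drop_family_competitors_of:
        for t in full.transcripts:
            keep_gene = drop_family_competitors_of.get(t.family_id)
            if keep_gene is not None and t.gene_id != keep_gene:
                orthologs.discard(t.gene_id)
    counts = {
        g: max(1, int(round(transcript_frac * len(full.gene_members[g]))))
        for g in orthologs
    }
    return SpeciesProfile(name=name, per_gene_transcript_count=counts,
                          ortholog_genes=frozenset(orthologs))
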