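"""Experiment configuration: explicit seeds, lossless round-trips, hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["ExperimentConfig", "default_config", "DESK", "PAPER"]

DESK = "desk"
PAPER = "paper"


@dataclass(frozen=True)
class ForgeParams:
    n_genes: int = 500
    isoform_mean: float = 7.0
    isoform_shape: float = 2.0
    family_fraction: float = 0.20
    family_min_size: int = 2
    family_max_size: int = 6
    shared_frac_low: float = 0.30
    shared_frac_high: float = 0.70
    length_mean: float = 1500.0
    length_sigma: float = 0.6
    length_min: int = 50
    dynamic_range_log10: float = 4.0


@dataclass(frozen=True)
class ReadParams:
    n_reads: int = 100_000


@dataclass(frozen=True)
class SweepParams:
    #: desk default: 10 fractions spanning the band, incl. the 10%/90% probes
    fractions: tuple[int, ...] = (5, 10, 20, 30, 40, 50, 60, 70, 80, 90)
    reps_per_fraction: int = 20
    n_control_bins: int = 10
    bin_lo_log10: float = 0.5
    bin_hi_log10: float = 4.5


@dataclass(frozen=True)
class SpeciesParams:
    """Transcripts-per-gene targets as fractions of the reference (20–75% band)."""

    names: tuple[str, ...] = ("cyno", "dog", "rat", "mouse")
    transcript_fracs: tuple[float, ...] = (0.75, 0.30, 0.25, 0.40)
    reps: int = 20
    drop_family_competitors: bool = True


@dataclass(frozen=True)
class NormalizeParams:
    tpm_floor: float = 1.0
    logratio_trim: float = 0.30
    abs_expr_trim: float = 0.05
    min_genes: int = 10
    thin_keep_prob: float = 0.2


@dataclass(frozen=True)
class StatsParams:
    alpha: float = 0.05
    tpm_diff_threshold: float = 0.1
    n_perm: int = 1000


@dataclass(frozen=True)
class ExperimentConfig:
    seed: int = 0
    scale: str = DESK
    outdir: str = "results"
    forge: ForgeParams = field(default_factory=ForgeParams)
    reads: ReadParams = field(default_factory=ReadParams)
    sweep: SweepParams = field(default_factory=SweepParams)
    species: SpeciesParams = field(default_factory=SpeciesParams)
    normalize: NormalizeParams = field(default_factory=NormalizeParams)
    stats: StatsParams = field(default_factory=StatsParams)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        data = dict(data)
        try:
            for key, sub in (("forge", ForgeParams), ("reads", ReadParams),
                             ("sweep", SweepParams), ("species", SpeciesParams),
                             ("normalize", NormalizeParams), ("stats", StatsParams)):
                if key in data and isinstance(data[key], dict):
                    payload = dict(data[key])
                    for f_name, f_val in payload.items():
                        if isinstance(f_val, list):
                            payload[f_name] = tuple(f_val)
                    data[key] = sub(**payload)
            return cls(**data)
        except TypeError as exc:
            raise ConfigurationError(f"invalid config: {exc}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path} does not contain a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Digest of the scientific parameters (output location excluded)."""
        payload = self.to_dict()
        payload.pop("outdir", None)
        blob = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def with_seed(self, seed: int) -> "ExperimentConfig":
        return replace(self, seed=seed)


def default_config(scale: str = DESK, seed: int = 0,
                   outdir: str = "results") -> ExperimentConfig:
    """Desk scale keeps CI fast; paper scale mirrors the published protocol
    (1–99% × 100 reps sweep, 4 species × 100 reps pre-clinicalization)."""
    if scale == DESK:
        return ExperimentConfig(seed=seed, scale=DESK, outdir=outdir)
    if scale == PAPER:
        return ExperimentConfig(
            seed=seed, scale=PAPER, outdir=outdir,
            sweep=SweepParams(fractions=tuple(range(1, 100)),
                              reps_per_fraction=100),
            species=SpeciesParams(reps=100),
        )
    raise ConfigurationError(f"unknown scale {scale!r} (expected desk|paper)")
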