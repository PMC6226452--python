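"""Pipeline configuration: YAML schema, defaults, validation."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields

import yaml

log = logging.getLogger("cnescreen")


class ConfigError(ValueError):
    """Aggregated configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass
class SimulateParams:
    n_other_species: int = 10
    n_loss_species: int = 2
    depth: float = 0.75
    scattered: bool = False
    n_cnes: int = 400
    length_mean: float = 200.0
    constrained_rate: float = 0.15
    relaxed_fraction: float = 0.05
    relaxation_factor: float = 20.0
    spacing: int = 1000
    n_genes: int = 40
    n_motifs: int = 10
    peak_overlap_fraction: float = 0.5
    n_decoy_peaks: int = 50


@dataclass
class ScreenParams:
    z_cutoff: float = -3.0
    min_additional_species: int = 3
    min_nongap_frac: float = 0.3
    n_null_cnes: int = 1000
    required_species: list = field(default_factory=list)


@dataclass
class EnrichParams:
    basal_up: int = 5000
    basal_down: int = 1000
    max_extension: int = 300000
    merge_gap: int = 50
    n_subsamples: int = 10000


@dataclass
class MotifParams:
    n_gc_bins: int = 21
    n_seqs: int = 100
    seq_len: int = 200
    quantile: float = 0.9
    pseudocount: float = 0.01
    n_ic_bins: int = 20
    direction: str = "greater"
    n_motifs_scored: int = 2


@dataclass
class PathsParams:
    """External inputs; unset paths are filled by the simulate stage."""

    tree: str | None = None
    alignments_dir: str | None = None
    cnes_bed: str | None = None
    genes_tsv: str | None = None
    peaks_bed: str | None = None
    motifs_meme: str | None = None
    truth_tsv: str | None = None


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    simulate: SimulateParams = field(default_factory=SimulateParams)
    screen: ScreenParams = field(default_factory=ScreenParams)
    enrich: EnrichParams = field(default_factory=EnrichParams)
    motifs: MotifParams = field(default_factory=MotifParams)
    paths: PathsParams = field(default_factory=PathsParams)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


_SECTIONS = {
    "simulate": SimulateParams,
    "screen": ScreenParams,
    "enrich": EnrichParams,
    "motifs": MotifParams,
    "paths": PathsParams,
}
_REQUIRED = ["outdir", "seed"]


def _coerce(cls, raw: dict, section: str, errors: list[str]):
    known = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in raw.items():
        if key not in known:
            errors.append(f"unknown key {section}.{key}")
            continue
        default = getattr(cls(), key)
        if isinstance(default, bool):
            ok = isinstance(value, bool)
        elif isinstance(default, int):
            ok = isinstance(value, int) and not isinstance(value, bool)
        elif isinstance(default, float):
            ok = isinstance(value, (int, float)) and not isinstance(value, bool)
            value = float(value) if ok else value
        elif isinstance(default, str) or default is None:
            ok = value is None or isinstance(value, str)
        elif isinstance(default, list):
            ok = isinstance(value, list)
        else:  # pragma: no cover
            ok = True
        if not ok:
            errors.append(f"type mismatch for {section}.{key}: {value!r}")
            continue
        kwargs[key] = value
    for key in set(known) - set(kwargs):
        log.info("config default: %s.%s = %r", section, key, getattr(cls(), key))
    try:
        return cls(**kwargs)
    except TypeError:  # pragma: no cover
        return cls()


def validate_config(path) -> PipelineConfig:
    """Load, validate and default-fill a pipeline config.

    Unknown keys, type mismatches and missing required keys (outdir, seed)
    are aggregated into a single :class:`ConfigError`.  Any path named
    under ``paths:`` must exist.
    """
    import os

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a YAML mapping"])
    for key in _REQUIRED:
        if key not in raw:
            errors.append(f"missing required key: {key}")
    for key in raw:
        if key not in set(_REQUIRED) | set(_SECTIONS):
            errors.append(f"unknown key {key}")
    if "seed" in raw and not (
        isinstance(raw["seed"], int) and not isinstance(raw["seed"], bool)
    ):
        errors.append(f"seed must be an integer, got {raw['seed']!r}")
    if "outdir" in raw and not isinstance(raw.get("outdir"), str):
        errors.append("outdir must be a string")
    sections = {}
    for name, cls in _SECTIONS.items():
        sub = raw.get(name, {})
        if sub is None:
            sub = {}
        if not isinstance(sub, dict):
            errors.append(f"section {name} must be a mapping")
            sub = {}
        sections[name] = _coerce(cls, sub, name, errors)
    for f in fields(PathsParams):
        p = getattr(sections["paths"], f.name)
        if p is not None and not os.path.exists(p):
            errors.append(f"paths.{f.name} does not exist: {p}")
    if errors:
        raise ConfigError(errors)
    return PipelineConfig(
        outdir=raw["outdir"],
        seed=raw["seed"],
        simulate=sections["simulate"],
        screen=sections["screen"],
        enrich=sections["enrich"],
        motifs=sections["motifs"],
        paths=sections["paths"],
    )
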