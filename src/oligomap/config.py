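"""Run configuration: schema-validated YAML/JSON with strict unknown-key rejection.

A single global seed is expanded into independent per-stage substreams by
hashing the stage name into a ``numpy.random.SeedSequence`` spawn key, so the
order in which stages run never affects reproducibility.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2**31) derived from the global seed."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Generator for a named stage, independent of other stages' draws."""
    return np.random.default_rng(stage_seed(seed, stage))


@dataclass
class SimulateSection:
    n_classes: int = 8
    n_genes: int = 500
    cells_per_class: int = 200
    markers_per_class: int = 10
    base_mean: float = 0.5
    marker_fold: float = 8.0
    dispersion: float = 2.0
    dropout_midpoint: float = -2.3
    dropout_slope: float = 1.0
    domain_shift_sd: float = 0.3
    contamination_fraction: float = 0.05
    effect_log2fc: float = 1.0
    frac_de_genes: float = 0.1
    chimera_cells: int = 2000
    n_axons: int = 300
    g_mean: float = 0.8
    g_sd: float = 0.04
    mito_fraction: float = 0.1


@dataclass
class PreprocessSection:
    min_cells_per_gene_exclusive: int = 10
    mad_multiplier: float = 3.0
    max_mito_fraction: float = 1.0
    mito_gene_prefix: str = "MT-"
    n_top_genes: int = 2000
    max_pcs: int = 30
    elbow_drop_fraction: float = 0.1
    elbow_floor: int = 5
    k_neighbors: int = 20
    resolution: float = 1.0


@dataclass
class DemuxSection:
    min_fraction: float = 0.70
    basis: str = "umi_counts"


@dataclass
class AnnSection:
    hidden1: int = 64
    hidden2: int = 32
    l1_lambda: float = 0.001
    n_folds: int = 3
    epochs: int = 30
    steps_per_epoch: int = 64
    per_class_per_step: int = 16
    learning_rate: float = 0.001
    rho: float = 0.9
    epsilon: float = 1.0e-7
    confidence_threshold: float = 0.0


@dataclass
class DgeSection:
    min_log2fc: float = 0.25
    min_pct_in: float = 0.20
    max_pct_out: float = 0.60
    min_abs_log2fc: float = 0.5
    max_adj_p: float = 0.05


@dataclass
class MorphometrySection:
    min_axon_diameter: float = 0.4
    normality_alpha: float = 0.05
    lilliefors_sims: int = 1000


@dataclass
class RunConfig:
    """Validated pipeline configuration; ``seed`` drives every stochastic stage."""

    seed: int = 0
    out_dir: str = "oligomap_out"
    simulate: SimulateSection = field(default_factory=SimulateSection)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    demux: DemuxSection = field(default_factory=DemuxSection)
    ann: AnnSection = field(default_factory=AnnSection)
    dge: DgeSection = field(default_factory=DgeSection)
    morphometry: MorphometrySection = field(default_factory=MorphometrySection)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{path or 'config'}: expected a mapping, got {type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        key = sorted(unknown)[0]
        raise ConfigError(f"unknown config key: {path + '.' if path else ''}{key}")
    kwargs = {}
    for name, f in known.items():
        if name not in data:
            continue
        value = data[name]
        sub = f.type if is_dataclass(f.type) else None
        # dataclass fields declared via string annotations
        if sub is None and isinstance(f.type, str):
            sub = globals().get(f.type)
            sub = sub if is_dataclass(sub) else None
        if sub is not None:
            kwargs[name] = _build(sub, value, f"{path + '.' if path else ''}{name}")
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    Unknown keys are rejected with the offending key path; unspecified keys
    take their documented defaults.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    cfg = _build(RunConfig, data, "")
    _validate(cfg)
    return cfg


def _validate(cfg: RunConfig) -> None:
    sim = cfg.simulate
    if sim.markers_per_class * sim.n_classes > sim.n_genes:
        raise ConfigError("simulate: markers_per_class * n_classes exceeds n_genes")
    if not (0 <= sim.contamination_fraction < 0.3):
        raise ConfigError("simulate.contamination_fraction must be in [0, 0.3)")
    if not (0.5 < cfg.demux.min_fraction <= 1.0):
        raise ConfigError("demux.min_fraction must be in (0.5, 1]")
    if cfg.demux.basis not in ("umi_counts", "detected_genes"):
        raise ConfigError("demux.basis must be 'umi_counts' or 'detected_genes'")
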