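"""Run configuration: typed parameter blocks, YAML round-trip, strict keys."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "SimulationConfig",
    "PreprocessParams",
    "SegmentationParams",
    "CallingParams",
    "RunConfig",
    "ConfigError",
]


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Conditions of the emulated two-strain experiment.

    Defaults follow the experimental setup being emulated: EcoRI digestion
    (GAATTC), 60 bp probes, per-base termination probability 0.001, and an
    elevated hotspot termination probability of 0.05 so that a 2 bp
    AT-tract length change yields a visible step.
    """

    genome_length: int = 2_000_000
    recognition_seq: str = "GAATTC"
    probe_spacing: int = 250
    probe_length: int = 60
    p_term: float = 0.001
    hotspot_p_term: float = 0.05
    hotspot_tract_len: int = 40
    noise_sd_log2: float = 0.25
    affinity_sd_log2: float = 0.5
    background: float = 0.01
    gain_a: float = 1.0
    gain_b: float = 1.0
    end_mode: str = "exclude_runoff"
    multi_hit_fraction: float = 0.02
    chrom: str = "sim1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.probe_spacing < 1:
            raise ConfigError("probe_spacing must be >= 1")
        if self.hotspot_p_term < self.p_term:
            raise ConfigError("hotspot_p_term must be >= p_term")
        if self.noise_sd_log2 < 0 or self.affinity_sd_log2 < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        if not 0 <= self.p_term <= 1 or not 0 <= self.hotspot_p_term <= 1:
            raise ConfigError("termination probabilities must be in [0, 1]")
        if self.background < 0:
            raise ConfigError("background must be >= 0")
        if self.hotspot_tract_len < 2:
            raise ConfigError("hotspot_tract_len must be >= 2")


@dataclass
class PreprocessParams:
    """Variance-model constants: sigma^2 = alpha * local residual variance
    + beta / 2^y + sigma_floor2 (log2 scale)."""

    alpha: float = 1.0
    beta: float = 1e-4
    sigma_floor2: float = 0.005
    window_k: int = 7

    def __post_init__(self) -> None:
        if self.window_k < 5 or self.window_k % 2 == 0:
            raise ConfigError("window_k must be odd and >= 5")
        if self.sigma_floor2 <= 0:
            raise ConfigError("sigma_floor2 must be > 0")


@dataclass
class SegmentationParams:
    """Penalized joint line-fitting parameters.

    ``lambda_seg`` (per-segment penalty) and ``delta_shared`` (shared-
    boundary discount) default to data-size-dependent values when null:
    lambda = 2 ln(n) for an interval of n probes, delta = lambda / 2.
    ``kappa_slope`` couples the slopes of aligned segment pairs
    (units (log2/bp)^-2; slopes are ~1e-3 log2/bp, hence the large scale).
    """

    lambda_seg: float | None = 3.0
    delta_shared: float | None = None
    kappa_slope: float = 1e6
    min_probes: int = 2

    def __post_init__(self) -> None:
        if self.min_probes < 2:
            raise ConfigError("min_probes must be >= 2")
        if self.kappa_slope < 0:
            raise ConfigError("kappa_slope must be >= 0")

    def resolve(self, n: int) -> tuple[float, float, float]:
        """Concrete (lambda, delta, kappa) for an interval of n probes."""
        lam = self.lambda_seg if self.lambda_seg is not None else 2.0 * float(np.log(max(n, 2)))
        delta = self.delta_shared if self.delta_shared is not None else 0.5 * lam
        if not 0 <= delta <= lam:
            raise ConfigError("delta_shared must satisfy 0 <= delta <= lambda_seg")
        return lam, delta, self.kappa_slope


@dataclass
class CallingParams:
    """Boundary-classification thresholds.

    ``tau``: minimum between-channel step difference (log2) to emit a call;
    ``rho``: minimum step-magnitude ratio for the unequal-drop signature;
    both calibrated on the simulator (see docs/methods.md).
    ``tolerance``/``min_size`` parameterize evaluation against truth.
    """

    tau: float = 0.12
    rho: float = 1.05
    tolerance: int = 500
    min_size: int = 100

    def __post_init__(self) -> None:
        if self.tau < 0 or self.rho < 1:
            raise ConfigError("tau must be >= 0 and rho >= 1")


@dataclass
class RunConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    calling: CallingParams = field(default_factory=CallingParams)
    seed: int | None = None  # overrides sim.seed when set

    def __post_init__(self) -> None:
        if self.seed is not None:
            self.sim.seed = int(self.seed)

    # -- serialization --------------------------------------------------
    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
        sections = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(data) - set(sections)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for name, f in sections.items():
            if name not in data:
                continue
            if name == "seed":
                kwargs[name] = data[name]
                continue
            sub_cls = {"sim": SimulationConfig, "preprocess": PreprocessParams,
                       "segmentation": SegmentationParams, "calling": CallingParams}[name]
            sub = data[name]
            if not isinstance(sub, dict):
                raise ConfigError(f"config section {name!r} must be a mapping")
            valid = {sf.name for sf in dataclasses.fields(sub_cls)}
            bad = set(sub) - valid
            if bad:
                raise ConfigError(f"unknown keys in section {name!r}: {sorted(bad)}")
            kwargs[name] = sub_cls(**sub)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def digest(self) -> str:
        """Stable hash of the full configuration, for run manifests."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
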