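"""Validated run configuration loaded from TOML."""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

__all__ = ["SimulateConfig", "PreprocessConfig", "ActivationConfig", "SvmConfig", "RunConfig", "load_config"]


def _from_dict(cls, data: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class SimulateConfig:
    n_subjects: int = 4
    base_seed: int = 0
    grid: tuple[int, int] = (91, 128)
    experiment_frames: int = 1254
    time_scale: float = 1.0
    noise_snr: float = 2.0
    motion: bool = False
    motion_sd_px: float = 0.3

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.time_scale <= 0 or self.time_scale > 1:
            raise ValueError("time_scale must be in (0, 1]")
        if self.noise_snr <= 0:
            raise ValueError("noise_snr must be > 0")
        if len(self.grid) != 2 or min(self.grid) < 8:
            raise ValueError("grid must be (depth, width) with sides >= 8")
        object.__setattr__(self, "grid", tuple(int(g) for g in self.grid))


@dataclass(frozen=True)
class PreprocessConfig:
    passband_hz: float = 0.04
    stopband_atten_db: float = 60.0
    cutoff_rank: int = 20
    reference: str = "baseline_mean"
    motion_correct: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.passband_hz < 0.5:
            raise ValueError("passband_hz must be in (0, 0.5)")
        if self.stopband_atten_db <= 0:
            raise ValueError("stopband_atten_db must be > 0")
        if self.reference not in ("baseline_mean", "first_frame"):
            raise ValueError("reference must be 'baseline_mean' or 'first_frame'")


@dataclass(frozen=True)
class ActivationConfig:
    alpha: float = 0.01
    fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")


@dataclass(frozen=True)
class SvmConfig:
    epsilon: float | None = None  # None -> 0.1 * SD(y)
    C: float = 1.0
    tol: float = 1e-6
    fraction_test: float = 0.2
    max_passes: int | None = None

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if not 0 < self.fraction_test < 1:
            raise ValueError("fraction_test must be in (0, 1)")


@dataclass(frozen=True)
class RunConfig:
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    activation: ActivationConfig = field(default_factory=ActivationConfig)
    svm: SvmConfig = field(default_factory=SvmConfig)
    save_stacks: bool = False
    save_overlays: bool = True

    def hash(self) -> str:
        """Stable content hash for provenance records."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known_sections = {"simulate", "preprocess", "activation", "svm", "save_stacks", "save_overlays"}
        unknown = set(data) - known_sections
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        kwargs: dict = {}
        if "simulate" in data:
            sim = dict(data["simulate"])
            if "grid" in sim:
                sim["grid"] = tuple(sim["grid"])
            kwargs["simulate"] = _from_dict(SimulateConfig, sim, "simulate")
        if "preprocess" in data:
            kwargs["preprocess"] = _from_dict(PreprocessConfig, dict(data["preprocess"]), "preprocess")
        if "activation" in data:
            kwargs["activation"] = _from_dict(ActivationConfig, dict(data["activation"]), "activation")
        if "svm" in data:
            kwargs["svm"] = _from_dict(SvmConfig, dict(data["svm"]), "svm")
        if "save_stacks" in data:
            kwargs["save_stacks"] = bool(data["save_stacks"])
        if "save_overlays" in data:
            kwargs["save_overlays"] = bool(data["save_overlays"])
        return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return RunConfig.from_dict(data)
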