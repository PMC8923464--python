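"""Reproducibility plumbing: seeding, run manifests, and serialization.

A single global seed is expanded through ``numpy.random.SeedSequence`` into
independent per-module streams, so stimulus roving, rove-expectation draws,
and Monte-Carlo oracles never share a stream.  Every artifact written by
the CLI carries a JSON run manifest (config hash, seeds, preset, front-end
parameters, package version, timestamp) sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.io import wavfile

from .frontend import FrontendConfig
from .stimuli import Waveform

__all__ = [
    "SeedStreams",
    "RunManifest",
    "load_frontend_config",
    "write_manifest",
    "export_wav",
]

_STREAM_NAMES = ("stimuli", "observer", "experiments", "views")


class SeedStreams:
    """Independent per-module generators derived from one global seed."""

    def __init__(self, seed: int):
        self.seed = int(seed)
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAM_NAMES))
        self._rngs = {
            name: np.random.default_rng(ss) for name, ss in zip(_STREAM_NAMES, children)
        }

    def rng(self, module: str) -> np.random.Generator:
        return self._rngs[module]

    def child_seed(self, module: str) -> int:
        """A small integer seed drawn from the module's stream."""
        return int(self._rngs[module].integers(2**31))


@dataclass
class RunManifest:
    command: str
    seed: int
    preset: str
    config_hash: str
    frontend_params: dict
    package_version: str
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def write(self, path: Path):
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _hash_dict(d: dict) -> str:
    return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def load_frontend_config(path: str | Path | None) -> FrontendConfig:
    """Front-end configuration from a YAML file (missing keys default)."""
    if path is None:
        return FrontendConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    valid = {f.name for f in dataclasses.fields(FrontendConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown front-end config key(s): {sorted(unknown)}")
    return FrontendConfig(**raw)


def write_manifest(
    out_dir: Path, command: str, seed: int, preset: str, frontend_config: FrontendConfig
) -> Path:
    from . import __version__

    params = asdict(frontend_config)
    manifest = RunManifest(
        command=command,
        seed=seed,
        preset=preset,
        config_hash=_hash_dict(params),
        frontend_params=params,
        package_version=__version__,
    )
    path = Path(out_dir) / f"{command}_manifest.json"
    manifest.write(path)
    return path


def export_wav(wave: Waveform, path: str | Path, full_scale_pa: float | None = None) -> Path:
    """Write a waveform as float32 PCM WAV plus a sidecar JSON recording the
    full-scale ↔ pascal calibration constant."""
    path = Path(path)
    if full_scale_pa is None:
        full_scale_pa = max(float(np.max(np.abs(wave.samples))), 1e-12)
    data = (wave.samples / full_scale_pa).astype(np.float32)
    wavfile.write(path, int(wave.sample_rate), data)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "full_scale_pa": full_scale_pa,
                "sample_rate_hz": wave.sample_rate,
                "n_samples": len(wave.samples),
                "calibration": "sample value 1.0 corresponds to full_scale_pa pascals",
            },
            indent=2,
        )
        + "\n"
    )
    return path
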