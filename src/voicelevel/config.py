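"""Pipeline configuration with YAML round-trip.

Dotted keys mirror the sections users care about: ``apen.m``, ``apen.r``,
``f0.fmin``, ``f0.fmax``, ``hmm.n_states``, ``mlp.lr``, ``wavelet.scales``,
and so on.  Unspecified keys keep their defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class SystemConfig:
    # endpoint trimming
    trim_threshold_db: float = -35.0
    trim_min_voiced_s: float = 0.02
    # frame features
    frame_length_s: float = 0.025
    overlap: float = 0.75
    f0_fmin: float = 100.0
    f0_fmax: float = 600.0
    apen_m: int = 2
    apen_r: float = 0.2
    # word features
    higuchi_kmax: int = 8
    lyapunov_dimension: int = 5
    lyapunov_delay: int | None = None
    wavelet_order: int = 5
    wavelet_scales: tuple[int, ...] = (7, 8, 9)
    # HMM classifiers
    hmm_n_states: int = 8
    hmm_n_mix: int = 4
    em_max_iter: int = 50
    em_tol: float = 1e-5
    # neural networks
    mlp_hidden: int = 10
    mlp_lr: float = 0.01
    mlp_epochs: int = 2000
    # evaluation protocol
    train_frac: float = 0.6
    n_reps: int = 10
    split_mode: str = "utterance"  # or "child"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SystemConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat = {}
        for section, value in raw.items():
            if isinstance(value, dict):
                for key, v in value.items():
                    flat[f"{section}_{key}"] = v
            else:
                flat[section] = value
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "wavelet_scales" in flat:
            flat["wavelet_scales"] = tuple(flat["wavelet_scales"])
        return cls(**flat)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
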