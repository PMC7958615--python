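"""Shared run configuration: flat key-value YAML files, CLI overrides.

Precedence: built-in defaults < config file < explicit CLI flags.  The
shipped default file reproduces the published settings (sigma calibration,
k = 2*sigma, detection threshold 0.7, thresholds 0.50:0.05:0.95)."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from perikit.bone_loss import SeverityScale
from perikit.errors import ValidationError
from perikit.similarity_metrics import SigmaVector


def _default_config_dict() -> dict:
    ref = resources.files("perikit").joinpath("data/default.yaml")
    return yaml.safe_load(ref.read_text())


@dataclass
class RunConfig:
    sigma: SigmaVector
    k_constant: float
    detection_threshold: float
    thresholds: tuple[float, ...]
    ranking: str
    aggregation: str
    severity_scale: SeverityScale
    seed: int
    raw: dict = field(repr=False, default_factory=dict)

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        """Build from the shipped defaults, an optional YAML file, and keyword
        overrides (in rising precedence)."""
        data = _default_config_dict()
        if path is not None:
            with open(path) as fh:
                user = yaml.safe_load(fh)
            if not isinstance(user, dict):
                raise ValidationError(f"{path}: config must be a flat key-value mapping")
            data.update(user)
        data.update({k: v for k, v in overrides.items() if v is not None})
        thresholds = tuple(
            np.round(
                np.arange(
                    data["threshold_start"],
                    data["threshold_stop"] + data["threshold_step"] / 2,
                    data["threshold_step"],
                ),
                4,
            )
        )
        return cls(
            sigma=SigmaVector(tuple(float(s) for s in data["sigma"])),
            k_constant=float(data["k_constant"]),
            detection_threshold=float(data["detection_threshold"]),
            thresholds=thresholds,
            ranking=str(data["ranking"]),
            aggregation=str(data["aggregation"]),
            severity_scale=SeverityScale(
                tuple(float(t) for t in data["severity_thresholds"]),
                tuple(str(l) for l in data["severity_labels"]),
            ),
            seed=int(data["seed"]),
            raw=data,
        )

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def provenance(self) -> dict:
        from perikit import __version__

        return {
            "perikit_version": __version__,
            "config_hash": self.config_hash(),
            "seed": self.seed,
        }
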