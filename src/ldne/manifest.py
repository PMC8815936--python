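"""Run manifests: config snapshot, seed, versions and per-stage counts."""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path

import numpy as np

from . import __version__

__all__ = ["RunManifest"]


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class RunManifest:
    command: str
    seed: int | None
    config: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    version: str = __version__
    started: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, path) -> None:
        payload = _jsonable(self)
        payload["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")
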