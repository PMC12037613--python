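"""Run manifest: the reproducibility record every CLI stage writes.

A manifest snapshots the configuration, SHA-256 digests of every input
file, the RNG seed, wall-clock stage timings and the paths of every
output.  Re-running a stage with an identical manifest (same config,
same inputs, same seed) reproduces identical outputs for every
deterministic and seeded-stochastic stage.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .config import PipelineConfig


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    stage: str
    config: dict[str, Any]
    seed: int
    inputs: dict[str, str] = field(default_factory=dict)   # path -> sha256
    outputs: list[str] = field(default_factory=list)
    timings: dict[str, float] = field(default_factory=dict)

    @classmethod
    def start(cls, stage: str, config: PipelineConfig, seed: int) -> "RunManifest":
        return cls(stage=stage, config=config.to_dict(), seed=seed)

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = sha256_file(path)

    def add_output(self, path: str | Path) -> None:
        self.outputs.append(str(path))

    def time_stage(self, name: str):
        """Context manager recording the wall time of a sub-stage."""
        manifest = self

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                manifest.timings[name] = time.perf_counter() - self.t0
                return False

        return _Timer()

    def write(self, path: str | Path) -> None:
        payload = {
            "stage": self.stage,
            "config": self.config,
            "seed": self.seed,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "timings": self.timings,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            stage=d["stage"],
            config=d["config"],
            seed=d["seed"],
            inputs=d.get("inputs", {}),
            outputs=d.get("outputs", []),
            timings=d.get("timings", {}),
        )
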