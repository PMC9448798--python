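"""Run manifests: an audit record written by every CLI run.

A manifest captures the resolved config, all seeds, SHA-256 digests of
the input files, the tool version, per-stage wall times and the list of
files written — enough to re-run the stage and reproduce its metric log.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["RunManifest", "file_digest"]


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    command: str
    config: dict = field(default_factory=dict)
    seed: int | None = None
    inputs: dict[str, str] = field(default_factory=dict)   # path -> sha256
    outputs: list[str] = field(default_factory=list)
    timings: dict[str, float] = field(default_factory=dict)
    version: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__
        self._t0 = time.perf_counter()

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        if p.is_file():
            self.inputs[str(p)] = file_digest(p)
        elif p.is_dir():
            for f in sorted(p.rglob("*")):
                if f.is_file():
                    self.inputs[str(f)] = file_digest(f)

    def add_output(self, path: str | Path) -> None:
        self.outputs.append(str(path))

    def mark(self, stage: str) -> None:
        """Record elapsed wall time (seconds) since the previous mark."""
        now = time.perf_counter()
        self.timings[stage] = round(now - self._t0, 3)
        self._t0 = now

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "manifest.json"
        payload = {
            "command": self.command,
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "timings_s": self.timings,
        }
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
        return path
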