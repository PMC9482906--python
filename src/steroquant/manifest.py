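"""Run manifests: enough metadata to re-run a deterministic stage bit-identically."""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

__all__ = ["file_digest", "write_manifest", "read_manifest"]


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    outdir: str | Path,
    command: str,
    params: dict,
    inputs: list[str | Path] | None = None,
    seed: int | None = None,
    panel_name: str | None = None,
) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "params": params,
        "config_hash": hashlib.sha256(
            json.dumps(params, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "panel": panel_name,
        "seed": seed,
        "inputs": {str(p): file_digest(p) for p in (inputs or []) if Path(p).exists()},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path


def read_manifest(outdir: str | Path) -> dict:
    with open(Path(outdir) / "manifest.json") as fh:
        return json.load(fh)
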