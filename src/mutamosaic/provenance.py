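"""Run manifests: configuration hash, seeds, input checksums, versions."""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

from . import __version__


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, parameters: dict, seed: int | None = None,
                   inputs=()) -> Path:
    """Write ``manifest.json`` capturing everything that determines a run.

    ``parameters`` must contain every threshold the run used (calling
    threshold rule, background cutoff, alpha, Bonferroni multiplier, ...);
    nothing that affects the outputs is allowed to stay implicit.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "package": "mutamosaic",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": seed,
        "parameters": parameters,
        "parameters_sha256": hashlib.sha256(
            json.dumps(parameters, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path
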