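"""Run manifests: every output directory records its resolved configuration."""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

from .params import ParameterSet

try:
    from importlib.metadata import version as _pkg_version
    _VERSION = _pkg_version("raftsignal")
except Exception:  # pragma: no cover - not installed
    _VERSION = "unknown"


def write_manifest(outdir, params: ParameterSet, **extra) -> Path:
    """Write run_manifest.json with the fully resolved parameter set.

    Every artifact in ``outdir`` is reconstructible from this manifest and
    the package version alone.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "package": "raftsignal",
        "version": _VERSION,
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "parameters": params.to_dict(),
        **extra,
    }
    path = outdir / "run_manifest.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
    return path
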