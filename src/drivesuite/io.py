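"""Result writing with reproducibility manifests.

Every simulation output directory gets plain CSV tables (comma-separated,
header row, UTF-8, '.' decimal) plus exactly one ``manifest.json`` holding
the config snapshot, the seed, the package version, a timestamp and a
checksum inventory of the written files — enough to re-run and verify the
outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Dict, Mapping, Optional, Union

import pandas as pd

from . import __version__

__all__ = ["RunManifest", "write_results", "read_manifest"]

MANIFEST_NAME = "manifest.json"


@dataclasses.dataclass
class RunManifest:
    """Inventory of one simulation run's outputs."""

    config: Dict[str, Any]
    seed: int
    version: str
    created: str
    files: Dict[str, str]  # filename -> sha256

    def as_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: Union[str, Path],
    config: Optional[Dict[str, Any]] = None,
    seed: int = 0,
) -> RunManifest:
    """Write each table as ``<name>.csv`` plus a manifest.

    Re-running with the manifest's config and seed reproduces identical
    CSVs (all simulator randomness flows from the seed).  An unwritable
    directory raises the underlying :class:`OSError`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: Dict[str, str] = {}
    for name, df in tables.items():
        fname = f"{name}.csv"
        path = out / fname
        df.to_csv(path, index=False)
        files[fname] = _sha256(path)
    manifest = RunManifest(
        config=config or {},
        seed=seed,
        version=__version__,
        created=datetime.now(timezone.utc).isoformat(),
        files=files,
    )
    (out / MANIFEST_NAME).write_text(json.dumps(manifest.as_dict(), indent=2))
    return manifest


def read_manifest(out_dir: Union[str, Path]) -> RunManifest:
    doc = json.loads((Path(out_dir) / MANIFEST_NAME).read_text())
    return RunManifest(**doc)
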