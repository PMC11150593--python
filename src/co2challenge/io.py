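"""CSV / JSON persistence for traces, breath records and reports.

All tabular artifacts are plain CSV with an optional ``#``-prefixed comment
header carrying the run-manifest hash, so every file can be traced back to
the exact configuration and seed that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

__all__ = [
    "manifest_hash",
    "write_manifest",
    "read_manifest",
    "write_table",
    "read_table",
]


def manifest_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_manifest(config: dict, path: str | Path) -> str:
    digest = manifest_hash(config)
    payload = {"manifest_hash": digest, **config}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")
    return digest


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_table(df: pd.DataFrame, path: str | Path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
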