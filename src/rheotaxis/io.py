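"""Delimited-text tables with provenance headers.

Every tabular output of the pipeline carries a comment header of
``# key = value`` lines (package version, command, config hash, seed) so a
result file is traceable to the run that produced it; headers contain no
timestamps, keeping reruns byte-identical.
"""

from __future__ import annotations

import hashlib
import json

import pandas as pd

__all__ = ["config_hash", "write_table", "read_table"]


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a DataFrame as CSV preceded by '# key = value' provenance lines."""
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k} = {v}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a table written by :func:`write_table`; returns (df, meta)."""
    meta: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return df, meta
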