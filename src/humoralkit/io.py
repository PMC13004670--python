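"""Table I/O with a schema-version header comment.

Every table written by the pipeline starts with a single ``#``-prefixed
comment line carrying the schema version and optional provenance keys
(``config_hash``, ``seed``), so downstream stages can be diffed and traced.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

SCHEMA_VERSION = "humoralkit/v1"


def write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t", **meta) -> Path:
    """Write *df* with a ``# schema=...`` header line.

    Extra keyword arguments are recorded as ``key=value`` pairs on the
    header line. Floats are written with repr precision so a re-run with
    identical inputs is byte-identical.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pairs = [f"schema={SCHEMA_VERSION}"] + [f"{k}={v}" for k, v in sorted(meta.items())]
    with open(path, "w") as fh:
        fh.write("# " + " ".join(pairs) + "\n")
        df.to_csv(fh, sep=sep, index=False, lineterminator="\n")
    return path


def read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a table written by :func:`write_table` (header comments skipped)."""
    return pd.read_csv(path, sep=sep, comment="#")


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
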