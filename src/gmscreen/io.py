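"""Schema-checked TSV I/O with provenance headers.

All pipeline tables travel as tab-separated text (gzip-transparent).  Files
written by :func:`write_table` start with ``#``-prefixed comment lines
recording the tool version, the seed and a hash of the run configuration,
so any artifact can be traced to the run that produced it;
:func:`read_table` skips these lines and validates the header against a
declared schema.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .errors import SchemaError


def config_hash(config: Mapping) -> str:
    """Short stable hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def provenance_header(seed: int | None = None, config: Mapping | None = None) -> list[str]:
    lines = [f"# gmscreen v{__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config is not None:
        lines.append(f"# config_sha={config_hash(config)}")
    return lines


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config: Mapping | None = None,
) -> None:
    """Write a TSV with a provenance comment header."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for line in provenance_header(seed, config):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(
    path: str | Path,
    schema: Mapping[str, type] | None = None,
    required: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Read a TSV, skipping provenance comments and validating the header.

    ``schema`` maps column names to dtypes applied after parsing; columns in
    ``required`` (or in the schema) must be present — a missing column
    raises :class:`SchemaError` naming it.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such table: {path}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise SchemaError(f"{path}: cannot parse TSV: {exc}") from exc
    needed = set(required) | set(schema or ())
    missing = sorted(needed - set(df.columns))
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if schema:
        for col, dtype in schema.items():
            try:
                df[col] = df[col].astype(dtype)
            except (TypeError, ValueError) as exc:
                raise SchemaError(
                    f"{path}: column {col!r} cannot be cast to {dtype}: {exc}"
                ) from exc
    return df
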