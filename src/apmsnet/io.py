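"""Readers and writers for the pipeline's plain-text table dialects.

All tabular artifacts are tab-separated files with an optional block of
``# key=value`` metadata lines (seed, parameter values) ahead of the header.
Aligned footprint reads travel as six-column BED.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> Path:
    """Write ``df`` as TSV, preceded by ``# key=value`` metadata lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_meta(path: str | Path) -> dict:
    """Parse the leading ``# key=value`` lines of a table written by write_table."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def write_bed(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> Path:
    """Write reads as headerless 6-column BED (0-based half-open)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df[BED_COLUMNS].to_csv(fh, sep="\t", index=False, header=False)
    return path


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=BED_COLUMNS)
    return df


def sha256_file(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()
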