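"""CSV round-tripping with provenance headers.

Every writer prepends ``#``-comment header lines carrying the package
version, the seed in force and a hash of the run configuration, so outputs
are traceable; all readers skip such comments.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__


def config_hash(config: Mapping[str, Any] | None) -> str:
    """Short stable hash of a configuration mapping."""
    payload = json.dumps(
        config or {}, sort_keys=True, default=str
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    *,
    seed: int | None = None,
    config: Mapping[str, Any] | None = None,
) -> Path:
    """Write a CSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = (
        f"# kirbyhorizon v{__version__} seed={seed} "
        f"config={config_hash(config)}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)
    return path


def read_table(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (comments skipped)."""
    df = pd.read_csv(path, comment="#")
    if required:
        missing = set(required) - set(df.columns)
        if missing:
            raise SchemaError(
                f"{path}: missing required columns {sorted(missing)}"
            )
    return df


class SchemaError(ValueError):
    """An input file does not match the expected schema."""
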