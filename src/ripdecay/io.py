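"""Table I/O with provenance headers.

Every table the pipeline writes is a TSV with a header row preceded by
comment lines (``#``) recording the tool version, a hash of the effective
configuration and the seed, so that outputs are self-describing and
reruns with identical settings are byte-identical.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml


def config_hash(config: dict) -> str:
    payload = yaml.safe_dump(config, sort_keys=True, default_flow_style=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def provenance_header(seed: Optional[int] = None, config: Optional[dict] = None) -> str:
    from ripdecay import __version__

    parts = [f"# ripdecay v{__version__}"]
    if config is not None:
        parts.append(f"# config_hash={config_hash(config)}")
    if seed is not None:
        parts.append(f"# seed={seed}")
    return "\n".join(parts) + "\n"


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: Optional[int] = None,
    config: Optional[dict] = None,
    index: bool = False,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed, config=config))
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: str | Path, required_columns: Optional[set[str]] = None) -> pd.DataFrame:
    """Read a TSV, skipping ``#`` comment lines; errors name the file/row."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed TSV {path}: {exc}") from exc
    if required_columns:
        missing = required_columns - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
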