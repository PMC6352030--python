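"""CSV/JSON readers and writers for all study tables.

CSV dialect: comma-separated, UTF-8, "." decimal separator.  Columns
holding decimal-comma numbers (common in European exports) are
normalized on read with a warning.  Every writer's output is accepted
by its reader.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "read_measurements",
    "read_initial",
    "read_kinetics",
    "write_kinetics",
    "write_fit_report",
    "read_fit_report",
    "write_tukey_report",
    "write_truth",
    "read_truth",
    "RunManifest",
    "write_manifest",
    "config_hash",
]

log = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ["solute", "replicate", "tau_min", "mass_g", "dry_fraction"]
INITIAL_COLUMNS = ["solute", "replicate", "m0_g", "s0"]
KINETICS_COLUMNS = ["solute", "tau_min", "WC", "SG", "WL", "WLT", "CR"]


class SchemaError(ValueError):
    """An input table violates its schema (message names row/column)."""


def _coerce_numeric(df: pd.DataFrame, cols, name: str) -> None:
    """Convert columns to float, accepting decimal commas with a warning."""
    for col in cols:
        if pd.api.types.is_numeric_dtype(df[col]):
            continue
        normalized = df[col].astype(str).str.replace(",", ".", regex=False)
        converted = pd.to_numeric(normalized, errors="coerce")
        if converted.isna().any():
            row = int(converted.index[converted.isna()][0])
            raise SchemaError(
                f"{name}: column {col!r} has a non-numeric value at row {row}")
        log.warning("%s: normalized decimal commas in column %r", name, col)
        df[col] = converted


def _check_range(df, col, ok, name):
    bad = ~ok
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(f"{name}: column {col!r} out of range at row {row} "
                          f"(value {df[col].iloc[row]!r})")


def read_measurements(path) -> pd.DataFrame:
    """Read and validate a raw-measurements table."""
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"measurements {path}: missing column(s) {missing}")
    numeric = ["tau_min", "mass_g", "dry_fraction"] + (["a_w"] if "a_w" in df else [])
    _coerce_numeric(df, numeric, f"measurements {path}")
    _check_range(df, "tau_min", df["tau_min"] >= 0, f"measurements {path}")
    _check_range(df, "mass_g", df["mass_g"] > 0, f"measurements {path}")
    _check_range(df, "dry_fraction",
                 (df["dry_fraction"] > 0) & (df["dry_fraction"] <= 1),
                 f"measurements {path}")
    if "a_w" in df:
        ok = df["a_w"].isna() | ((df["a_w"] > 0) & (df["a_w"] < 1))
        _check_range(df, "a_w", ok, f"measurements {path}")
    return df


def read_initial(path) -> pd.DataFrame:
    """Read and validate a per-replicate initial-state table."""
    df = pd.read_csv(path)
    missing = [c for c in INITIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"initial {path}: missing column(s) {missing}")
    _coerce_numeric(df, ["m0_g", "s0"], f"initial {path}")
    _check_range(df, "m0_g", df["m0_g"] > 0, f"initial {path}")
    _check_range(df, "s0", (df["s0"] > 0) & (df["s0"] <= 1), f"initial {path}")
    return df


def write_kinetics(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_kinetics(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    numeric = [c for c in df.columns if c not in ("solute", "replicate")]
    _coerce_numeric(df, numeric, f"kinetics {path}")
    return df


def write_fit_report(df: pd.DataFrame, path) -> None:
    """Write a fit report; absent parameters stay as empty cells."""
    df.to_csv(path, index=False)


def read_fit_report(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_tukey_report(results, path) -> None:
    """Write Tukey summaries (mapping factor -> TukeyResult) as one table.

    Level/letter rows come first per factor, followed by the pairwise
    contrast rows with their +/- limits.
    """
    rows = []
    for factor, res in results.items():
        for level in res.means.index:
            rows.append({"factor": factor, "level": level,
                         "letter": res.letters[level], "mean": res.means[level],
                         "contrast": "", "limit": "", "difference": "",
                         "significant": ""})
        for _, c in res.contrasts.iterrows():
            rows.append({"factor": factor, "level": "", "letter": "", "mean": "",
                         "contrast": c["contrast"], "limit": c["limit"],
                         "difference": c["difference"],
                         "significant": bool(c["significant"])})
    pd.DataFrame(rows, columns=["factor", "level", "letter", "mean",
                                "contrast", "limit", "difference",
                                "significant"]).to_csv(path, index=False)


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def config_hash(obj) -> str:
    """Stable sha256 of a JSON-serialisable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    """Provenance record written alongside every command's outputs."""

    command: str
    inputs: dict
    outputs: list
    seed: object
    config_hash: str
    version: str
    timestamp: str


def write_manifest(out_dir, command: str, *, inputs=None, outputs=None,
                   seed=None, cfg_hash: str = "") -> Path:
    from . import __version__

    manifest = RunManifest(
        command=command,
        inputs={k: str(v) for k, v in (inputs or {}).items()},
        outputs=[str(p) for p in (outputs or [])],
        seed=seed,
        config_hash=cfg_hash,
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    path = Path(out_dir) / f"manifest_{command}.json"
    with open(path, "w") as fh:
        json.dump(asdict(manifest), fh, indent=2)
        fh.write("\n")
    return path
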