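"""Reading, validation and reporting for flat cohort tables.

Cohort tables are plain CSV/TSV with a header.  ``read_cohort`` applies an
optional column-name mapping, validates ids and numeric fields with row
numbers in error messages, and derives the binary activity flag from the
clinical threshold SLEDAI >= 8.  ``write_report`` emits a machine-readable
JSON report plus TSV tables; every output embeds the seed and a hash of
the configuration so reruns are attributable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__

#: SLEDAI threshold defining active lupus disease.
ACTIVITY_THRESHOLD = 8


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def read_cohort(
    path,
    mapping: dict[str, str] | None = None,
    *,
    required: tuple[str, ...] = (),
    numeric: tuple[str, ...] = (),
    id_column: str = "patient_id",
) -> pd.DataFrame:
    """Read and validate a cohort table.

    Parameters
    ----------
    path
        CSV (comma) or TSV (tab, by ``.tsv``/``.tab`` suffix) file.
    mapping
        Optional rename mapping ``{file column -> canonical column}``.
    required
        Canonical columns that must be present after renaming.
    numeric
        Columns coerced to float; non-numeric entries are reported with
        1-based data row numbers.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if mapping:
        df = df.rename(columns=mapping)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing mandatory columns {missing}")
    if id_column in df.columns:
        dup = df[id_column][df[id_column].duplicated()]
        if len(dup):
            raise ValueError(
                f"{path.name}: duplicate patient ids {sorted(set(dup.astype(str)))}"
            )
    for col in numeric:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            rows = (np.nonzero(bad.to_numpy())[0] + 1).tolist()
            raise ValueError(f"{path.name}: non-numeric {col!r} in data rows {rows}")
        df[col] = coerced
    if "SLEDAI" in df.columns:
        sledai = pd.to_numeric(df["SLEDAI"], errors="coerce")
        if sledai.isna().any() or (sledai < 0).any() or (sledai % 1 != 0).any():
            raise ValueError(f"{path.name}: SLEDAI must be a non-negative integer")
        df["SLEDAI"] = sledai.astype(int)
        df["active"] = (df["SLEDAI"] >= ACTIVITY_THRESHOLD).astype(int)
    return df


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def write_report(
    results: dict,
    outdir,
    *,
    config: dict | None = None,
    seed: int | None = None,
    tables: dict[str, pd.DataFrame] | None = None,
) -> dict[str, Path]:
    """Write a JSON report plus optional TSV tables to ``outdir``.

    ``results`` must be non-empty.  Returns the paths written.  Every
    file embeds (JSON) or is accompanied by (TSV header comment) the
    seed, config hash and package version.
    """
    if not results:
        raise ValueError("empty results; nothing to report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config or {}),
        "config": _jsonable(config or {}),
    }
    written: dict[str, Path] = {}
    report_path = outdir / "report.json"
    payload = {"meta": meta, "results": _jsonable(results)}
    report_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    written["report"] = report_path
    for name, table in (tables or {}).items():
        path = outdir / f"{name}.tsv"
        with open(path, "w") as fh:
            fh.write(f"# seed={seed} config_hash={meta['config_hash']} version={__version__}\n")
            table.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        written[name] = path
    return written


def format_performance_table(table: pd.DataFrame) -> pd.DataFrame:
    """Render an ``evaluate_rules`` result in the printed-table layout:
    cut-off probability, rule description, then the five accuracy columns
    rounded to 3 decimals."""
    out = pd.DataFrame(
        {
            "cutoff_p": table["cutoff_p"].round(3),
            "rule": [
                f"code_d >= {d} and code_c >= {c}"
                for d, c in zip(table["rule_d"], table["rule_c"])
            ],
            "sensitivity": table["sensitivity"].round(3),
            "specificity": table["specificity"].round(3),
            "ppv": table["ppv"].round(3),
            "npv": table["npv"].round(3),
            "youden": table["youden"].round(3),
        }
    )
    return out
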