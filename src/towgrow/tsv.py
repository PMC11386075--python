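"""Validated tab-separated-value dialects for every pipeline table.

All interchange is UTF-8 TSV with a header row: the study's tables are
small, and human-diffable text aids review. Each dialect declares its
required typed columns; reading validates the delimiter and schema, and a
write→read round trip is the identity.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import SchemaError

__all__ = ["SCHEMAS", "read_table", "write_table"]

#: required column → pandas dtype, per table kind. Extra columns are allowed.
SCHEMAS: dict[str, dict[str, str]] = {
    "qpcr": {
        "sample_id": "string", "target": "string", "dust_mass_mg": "float64",
        "dilution_factor": "float64", "extract_volume_ul": "float64",
        "cq_1": "float64",
    },
    "standards": {"copies_per_ul": "float64", "cq": "float64"},
    "conditions": {
        "sample_id": "string", "bag": "int64", "condition_class": "string",
        "wet_erh": "float64", "dry_erh": "float64",
        "wet_hours_per_day": "float64", "day": "float64",
    },
    "concentrations": {
        "sample_id": "string", "target": "string",
        "concentration_per_mg": "float64", "replicate_cv": "float64",
        "flags": "string",
    },
    "growth_rates": {
        "target": "string", "bag": "int64", "condition": "string",
        "rate": "float64", "stderr": "float64", "r_squared": "float64",
        "n_points": "int64",
    },
    "tow_curve": {
        "target": "string", "wet_erh": "float64", "time_elevated": "float64",
        "mean_relative_growth": "float64", "stderr": "float64",
    },
    "tow_fit": {
        "target": "string", "wet_erh": "float64", "model": "string",
        "parameter_hours": "float64", "sse": "float64",
    },
    "diversity": {"sample_id": "string", "richness": "int64", "shannon": "float64"},
    "permanova": {
        "factor": "string", "r_squared": "float64", "pseudo_f": "float64",
        "p_value": "float64", "n_permutations": "int64",
    },
    "diffabund": {
        "taxon_id": "string", "mean_group_a": "float64", "mean_group_b": "float64",
        "t_statistic": "float64", "p_value": "float64", "q_value": "float64",
        "direction": "string",
    },
    "totals": {"sample_id": "string", "total_per_mg": "float64"},
    "toc": {"sample_id": "string", "toc_mg_per_l": "float64"},
}


def write_table(df: pd.DataFrame, path, kind: str | None = None) -> Path:
    """Write a TSV table; validates against the schema when ``kind`` given."""
    path = Path(path)
    if kind is not None:
        _check_columns(df.columns, kind, str(path))
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def _check_columns(columns, kind: str, source: str) -> None:
    schema = SCHEMAS[kind]
    missing = [c for c in schema if c not in set(map(str, columns))]
    if missing:
        raise SchemaError(
            f"{source}: table kind '{kind}' is missing columns {missing}; "
            f"found {list(map(str, columns))}"
        )


def read_table(path, kind: str) -> pd.DataFrame:
    """Read and validate one TSV dialect into a typed DataFrame."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
    if header and "\t" not in header and "," in header:
        raise SchemaError(
            f"{path}: expected tab-delimited input but the header looks "
            "comma-delimited"
        )
    df = pd.read_csv(path, sep="\t", dtype="object")
    _check_columns(df.columns, kind, str(path))
    for col, dtype in SCHEMAS[kind].items():
        try:
            df[col] = df[col].astype(dtype)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: column '{col}' is not {dtype}: {exc}") from exc
    # best-effort typing for extra columns (e.g. cq_2, taxon columns)
    for col in df.columns:
        if col not in SCHEMAS[kind]:
            try:
                df[col] = pd.to_numeric(df[col])
            except (TypeError, ValueError):
                df[col] = df[col].astype("string")
    return df
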