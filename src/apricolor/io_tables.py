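"""Strict delimited-text IO and the packaged validation-panel fixtures.

Tables are UTF-8 comma-separated with a header row.  Reading is strict:
missing required columns and unparsable numerics raise a
:class:`TableFormatError` naming the offending row and column; unknown
columns are preserved pass-through and row order is stable.

Two fixtures ship with the package, transcribed from the printed
validation tables of the skin-color marker study: ``table1_gxc`` (the
40-seedling 'Goldrich' × 'Currot' population) and ``table2_cultivars``
(the 57-cultivar panel).  Each row carries the genotype call at SNP
S3_22924169, the aggregated hue (mean ± sd over six readings) and the
printed phenotype label.  The loader additionally derives the hue class
from the thresholds and flags rows where the printed label disagrees
(the 'Lito' row, labelled light orange at h° = 75.7, is such a case and
is surfaced rather than resolved).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from .colorimetry import classify_hue

__all__ = [
    "TableFormatError",
    "FIXTURE_NAMES",
    "read_table",
    "write_table",
    "load_fixture",
    "fixture_phenotype_records",
]

FIXTURE_NAMES = ("table1_gxc", "table2_cultivars")

_PRINTED_LABELS = {
    "Orange": "orange",
    "Light Orange": "light_orange",
    "Yellow": "yellow",
}


class TableFormatError(ValueError):
    """A delimited table violated its schema (named row/column in message)."""


def read_table(path, schema: Mapping[str, type]) -> pd.DataFrame:
    """Read a strict comma-separated UTF-8 table against a column schema.

    ``schema`` maps required column names to ``str``, ``int`` or
    ``float``.  Extra columns pass through untouched; row order is kept.
    """
    try:
        df = pd.read_csv(path, dtype=str, encoding="utf-8", keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path}: empty file (no header row)") from None
    missing = set(schema) - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing required columns {sorted(missing)}")
    for col, typ in schema.items():
        if typ is str:
            continue
        converted = pd.to_numeric(df[col].str.strip(), errors="coerce")
        if converted.isna().any():
            row = int((df.index[converted.isna()])[0])
            raise TableFormatError(
                f"{path}: column {col!r}, row {row + 2}: "
                f"cannot parse {df[col].iloc[row]!r} as {typ.__name__}"
            )
        if typ is int and not (converted == converted.round()).all():
            row = int(df.index[converted != converted.round()][0])
            raise TableFormatError(
                f"{path}: column {col!r}, row {row + 2}: non-integer value"
            )
        df[col] = converted.astype(typ)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table as UTF-8 comma-separated text with a header row."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8")


def _fixture_path(name: str):
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    return resources.files("apricolor.data").joinpath(f"{name}.csv")


@dataclass(frozen=True)
class Fixture:
    """A loaded validation panel: printed rows plus derived hue classes."""

    name: str
    table: pd.DataFrame

    @property
    def label_mismatches(self) -> pd.DataFrame:
        """Rows whose printed phenotype label disagrees with the thresholds."""
        return self.table[self.table["label_mismatch"]]


def load_fixture(name: str) -> Fixture:
    """Load a packaged validation table by name.

    Adds ``hue_class`` (derived from ``hue_mean`` via the 77°/83°
    thresholds), ``phenotype_printed`` (the printed label, normalized to
    the class vocabulary) and ``label_mismatch``.
    """
    schema = {
        "row_id": str,
        "individual_id": str,
        "ripening_date": str,
        "genotype": str,
        "hue_mean": float,
        "hue_sd": float,
        "phenotype": str,
    }
    with resources.as_file(_fixture_path(name)) as p:
        df = read_table(p, schema)
    df["phenotype_printed"] = df["phenotype"].map(_PRINTED_LABELS)
    if df["phenotype_printed"].isna().any():
        bad = df.loc[df["phenotype_printed"].isna(), "phenotype"].iloc[0]
        raise TableFormatError(f"{name}: unknown printed phenotype label {bad!r}")
    df["hue_class"] = [classify_hue(h).value for h in df["hue_mean"]]
    df["label_mismatch"] = df["hue_class"] != df["phenotype_printed"]
    return Fixture(name=name, table=df)


def fixture_phenotype_records(fixture: Fixture):
    """Phenotype records (one per row) for the concordance stage.

    Uses the printed aggregated hue (six readings per individual) and the
    threshold-derived class.
    """
    from .colorimetry import HueClass, PhenotypeRecord

    return [
        PhenotypeRecord(
            individual_id=r.individual_id,
            hue_mean=float(r.hue_mean),
            hue_sd=float(r.hue_sd),
            n_measurements=6,
            hue_class=HueClass(r.hue_class),
        )
        for r in fixture.table.itertuples(index=False)
    ]
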