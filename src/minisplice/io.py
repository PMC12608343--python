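"""Readers and writers for the pipeline's delimited-text formats, plus access
to the packaged fixture tables.

All tabular readers are column-name keyed (header order is irrelevant),
validate invariants on load, and report the offending file/line on error.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .acmg import ReclassRecord, validate_code
from .prioritize import PredictorScores
from .psi import PeakRecord, PeakTable
from .transcript import VariantEffectClass


class TableFormatError(ValueError):
    """A delimited input file does not match its documented schema."""


def _read_delimited(path: Union[str, Path], required: set[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path}: empty file") from None
    if df.empty:
        raise TableFormatError(f"{path}: no data rows")
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def _num(value: str, path: Path, line: int, column: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise TableFormatError(
            f"{path}:{line}: unparseable {column} value {value!r}"
        ) from None


def _opt_num(value) -> Optional[float]:
    if value is None:
        return None
    if isinstance(value, float):
        return None if math.isnan(value) else value
    value = str(value).strip()
    if value in {"", "-", "NA", "nan"}:
        return None
    return float(value)


# -- peak tables -------------------------------------------------------------

PEAK_COLUMNS = {"construct_id", "replicate", "length_nt", "height"}


def read_peak_tables(path: Union[str, Path]) -> dict[str, PeakTable]:
    """Read a CSV/TSV of fragment-analysis peaks, one :class:`PeakTable` per
    construct."""
    path = Path(path)
    df = _read_delimited(path, PEAK_COLUMNS)
    tables: dict[str, list[PeakRecord]] = {}
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            rec = PeakRecord(
                replicate=int(_num(row["replicate"], path, line, "replicate")),
                length=_num(row["length_nt"], path, line, "length_nt"),
                height=_num(row["height"], path, line, "height"),
            )
        except ValueError as exc:
            raise TableFormatError(f"{path}:{line}: {exc}") from None
        tables.setdefault(row["construct_id"], []).append(rec)
    return {cid: PeakTable(cid, peaks) for cid, peaks in tables.items()}


def write_peak_table(table: PeakTable, path: Union[str, Path]) -> None:
    df = table.to_frame()
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, index=False)


# -- predictor score tables --------------------------------------------------

SCORE_COLUMNS = {"variant", "gnomad_af", "ds_ag", "ds_al", "ds_dg", "ds_dl"}


def read_score_table(path: Union[str, Path]) -> list[PredictorScores]:
    path = Path(path)
    df = _read_delimited(path, SCORE_COLUMNS)
    out = []
    for i, row in df.iterrows():
        line = i + 2
        try:
            out.append(
                PredictorScores(
                    variant=row["variant"],
                    ds_ag=_num(row["ds_ag"], path, line, "ds_ag"),
                    ds_al=_num(row["ds_al"], path, line, "ds_al"),
                    ds_dg=_num(row["ds_dg"], path, line, "ds_dg"),
                    ds_dl=_num(row["ds_dl"], path, line, "ds_dl"),
                    spip_interpretation=row.get("spip_interpretation", "NTR"),
                    spip_confidence=_opt_num(row.get("spip_confidence", "")),
                    mmsplice_dlp=_opt_num(row.get("mmsplice_dlp", "")),
                    gnomad_af=_num(row["gnomad_af"], path, line, "gnomad_af"),
                    alphamissense=_opt_num(row.get("alphamissense", "")),
                )
            )
        except ValueError as exc:
            raise TableFormatError(f"{path}:{line}: {exc}") from None
    return out


# -- reclassification tables -------------------------------------------------

RECLASS_COLUMNS = {"variant", "effect", "delta_psi_abs", "criteria_before"}


def read_reclass_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read reclassification inputs (one row per assayed variant).

    Required columns: variant, effect, delta_psi_abs, criteria_before
    (semicolon-separated codes).  Optional: wt_baseline_psi, protein, exon,
    analyzed (yes/no), and published before/after columns for comparison.
    """
    path = Path(path)
    df = _read_delimited(path, RECLASS_COLUMNS)
    for i, row in df.iterrows():
        line = i + 2
        _num(row["delta_psi_abs"], path, line, "delta_psi_abs")
        try:
            VariantEffectClass(row["effect"].strip().lower())
        except ValueError:
            raise TableFormatError(
                f"{path}:{line}: unknown effect class {row['effect']!r}"
            ) from None
        for code in _split_codes(row["criteria_before"]):
            try:
                validate_code(code)
            except ValueError as exc:
                raise TableFormatError(f"{path}:{line}: {exc}") from None
    if "analyzed" not in df.columns:
        df["analyzed"] = "yes"
    if "wt_baseline_psi" not in df.columns:
        df["wt_baseline_psi"] = ""
    return df


def _split_codes(cell: str) -> list[str]:
    cell = (cell or "").strip()
    if cell in {"", "-"}:
        return []
    return [c.strip() for c in cell.replace(",", ";").split(";") if c.strip()]


def reclass_inputs(df: pd.DataFrame) -> list[dict]:
    """Typed per-row inputs for :func:`minisplice.acmg.reclassify`."""
    rows = []
    for _, row in df.iterrows():
        rows.append(
            {
                "variant": row["variant"],
                "effect": VariantEffectClass(row["effect"].strip().lower()),
                "delta_psi_abs": float(row["delta_psi_abs"]),
                "wt_baseline_psi": _opt_num(row.get("wt_baseline_psi", "")),
                "before": _split_codes(row["criteria_before"]),
                "analyzed": row.get("analyzed", "yes").strip().lower() == "yes",
                "protein": (row.get("protein", "") or "").strip() or None,
            }
        )
    return rows


def reclass_frame(records: list[ReclassRecord]) -> pd.DataFrame:
    """Tabular view of reclassification results mirroring the input schema."""

    def codes(s: Optional[set[str]]) -> str:
        return ";".join(sorted(s)) if s else "-"

    return pd.DataFrame(
        [
            {
                "variant": r.variant,
                "effect": r.effect.value,
                "delta_psi_abs": r.delta_psi_abs,
                "wt_baseline_psi": "" if r.wt_baseline_psi is None else r.wt_baseline_psi,
                "criteria_before": codes(r.before),
                "functional": r.functional,
                "criteria_after": codes(r.after),
                "class_before": str(r.class_before),
                "class_after": str(r.class_after) if r.class_after is not None else "-",
                "changed": r.changed,
                "direction": r.direction,
            }
            for r in records
        ]
    )


# -- packaged fixtures -------------------------------------------------------


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture table."""
    with resources.as_file(resources.files("minisplice") / "data" / name) as p:
        return Path(p)


def load_table2_fixture() -> pd.DataFrame:
    """The transcribed 28-variant reclassification table (27 analyzed)."""
    return read_reclass_table(fixture_path("table2_reclass.tsv"))


def load_table1_fixture() -> list[PredictorScores]:
    """The transcribed 28-variant predictor score table."""
    return read_score_table(fixture_path("table1_scores.tsv"))
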