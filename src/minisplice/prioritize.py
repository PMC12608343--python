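"""Multi-predictor selection of splice-impact candidates and the spliceogenic
census over a precomputed score table.

Selection semantics: the population-frequency cap is mandatory, and any one
predictor criterion suffices (OR) — a branchpoint-only hit with a flat
SpliceAI profile is still a candidate.  Every firing criterion is returned so
the decision is auditable per tool.

The census bins the SpliceAI DS MAX of every variant at or above the entry
threshold (0.2) into the conventional recall / recommended / precision bands
and breaks candidates down by region, consequence, and database membership.
The package never runs the predictors; it consumes their scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .transcript import classify_region

# DS MAX bands: [0.2, 0.5) high recall, [0.5, 0.8) recommended, [0.8, 1.0]
# high precision.
CENSUS_EDGES = (0.2, 0.5, 0.8)
CENSUS_LABELS = ("0.2-0.49", "0.5-0.79", "0.8-1.0")


@dataclass(frozen=True)
class PredictorScores:
    """One variant's splice-prediction scores and population frequency."""

    ds_ag: float
    ds_al: float
    ds_dg: float
    ds_dl: float
    spip_interpretation: str = "NTR"
    spip_confidence: Optional[float] = None
    mmsplice_dlp: Optional[float] = None
    gnomad_af: float = 0.0
    alphamissense: Optional[float] = None
    variant: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("ds_ag", "ds_al", "ds_dg", "ds_dl"):
            v = getattr(self, name)
            if v is None:
                raise ValueError(f"missing SpliceAI delta score {name}")
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.gnomad_af <= 1.0:
            raise ValueError(f"gnomad_af={self.gnomad_af} outside [0, 1]")
        if self.alphamissense is not None and not 0.0 <= self.alphamissense <= 1.0:
            raise ValueError(f"alphamissense={self.alphamissense} outside [0, 1]")


@dataclass(frozen=True)
class SelectionThresholds:
    """Cutoffs of the candidate-selection filter (defaults as published)."""

    spliceai_min: float = 0.2
    mmsplice_abs_min: float = 1.0
    spip_whitelist: tuple[str, ...] = (
        "Alter by SPiCE",
        "Alter BP",
        "Alter by MES (Poly TC)",
    )
    af_max: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.spliceai_min <= 1.0:
            raise ValueError("spliceai_min outside [0, 1]")
        if not 0.0 <= self.af_max <= 1.0:
            raise ValueError("af_max outside [0, 1]")


def spliceai_max(s: PredictorScores) -> float:
    """DS MAX: the maximum of the four SpliceAI delta scores."""
    return max(s.ds_ag, s.ds_al, s.ds_dg, s.ds_dl)


def passes_selection(
    s: PredictorScores, t: SelectionThresholds = SelectionThresholds()
) -> tuple[bool, list[str]]:
    """Apply the selection filter; return (decision, firing criteria).

    Missing optional tools simply do not fire.  SPiP matching is prefix-based
    on the whitelist, since interpretations print as compound labels
    ("Alter by SPiCE + Alter ESR").
    """
    firing: list[str] = []
    if spliceai_max(s) >= t.spliceai_min:
        firing.append(f"spliceai_ds_max>={t.spliceai_min}")
    interp = (s.spip_interpretation or "").strip()
    if any(interp.startswith(w) for w in t.spip_whitelist):
        firing.append("spip_interpretation")
    if s.mmsplice_dlp is not None and abs(s.mmsplice_dlp) > t.mmsplice_abs_min:
        firing.append(f"|mmsplice_dlp|>{t.mmsplice_abs_min}")
    if s.gnomad_af >= t.af_max:
        return False, firing
    return bool(firing), firing


def _share_1dp(count: int, total: int) -> float:
    """Bin share as a percentage, truncated (not rounded) to one decimal.

    Truncation is the convention reproduced by the reference bin counts
    (655/238/205 over 1098 print as 59.6/21.6/18.6)."""
    if total == 0:
        return 0.0
    return math.floor(count / total * 1000.0) / 10.0


@dataclass(frozen=True)
class CensusBin:
    label: str
    count: int
    share: float  # percent of all rows >= entry threshold


@dataclass
class CensusReport:
    total_rows: int
    total_selected: int  # ds_max >= entry threshold
    bins: list[CensusBin]
    by_region: dict[str, int] = field(default_factory=dict)
    by_consequence: dict[str, int] = field(default_factory=dict)
    by_database: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "total_rows": self.total_rows,
            "total_selected": self.total_selected,
            "bins": [
                {"label": b.label, "count": b.count, "share": b.share} for b in self.bins
            ],
            "by_region": self.by_region,
            "by_consequence": self.by_consequence,
            "by_database": self.by_database,
        }


def census(table: pd.DataFrame, entry_threshold: float = CENSUS_EDGES[0]) -> CensusReport:
    """Bin a DS MAX score table and break selected variants down.

    Expects a ``ds_max`` column in [0, 1]; optional columns ``region``
    (precomputed label) or ``position`` (an HGVS c. position object/string fed
    through :func:`minisplice.transcript.classify_region`), ``consequence``,
    and boolean ``db_*`` membership flags.
    """
    if "ds_max" not in table.columns:
        raise ValueError("score table needs a ds_max column")
    ds = pd.to_numeric(table["ds_max"])
    if ((ds < 0) | (ds > 1)).any():
        raise ValueError("ds_max values outside [0, 1]")

    selected = table.loc[ds >= entry_threshold].copy()
    sel_ds = ds[ds >= entry_threshold]
    n_sel = len(selected)

    bins = []
    edges = list(CENSUS_EDGES) + [1.0]
    for label, lo, hi in zip(CENSUS_LABELS, edges[:-1], edges[1:]):
        in_bin = (sel_ds >= lo) & ((sel_ds < hi) if hi < 1.0 else (sel_ds <= 1.0))
        count = int(in_bin.sum())
        bins.append(CensusBin(label, count, _share_1dp(count, n_sel)))

    by_region: dict[str, int] = {}
    if "region" in selected.columns:
        by_region = selected["region"].value_counts().to_dict()
    elif "position" in selected.columns:
        labels = selected["position"].map(classify_region)
        by_region = labels.value_counts().to_dict()

    by_consequence = (
        selected["consequence"].value_counts().to_dict()
        if "consequence" in selected.columns
        else {}
    )
    by_database = {
        col.removeprefix("db_"): int(selected[col].astype(bool).sum())
        for col in selected.columns
        if col.startswith("db_")
    }
    return CensusReport(
        total_rows=len(table),
        total_selected=n_sel,
        bins=bins,
        by_region={str(k): int(v) for k, v in by_region.items()},
        by_consequence={str(k): int(v) for k, v in by_consequence.items()},
        by_database=by_database,
    )


def census_from_counts(counts: Sequence[int]) -> list[CensusBin]:
    """Bin shares from already-tallied bin counts (one per DS MAX band)."""
    if len(counts) != len(CENSUS_LABELS):
        raise ValueError(f"expected {len(CENSUS_LABELS)} counts")
    total = sum(counts)
    return [
        CensusBin(label, int(c), _share_1dp(int(c), total))
        for label, c in zip(CENSUS_LABELS, counts)
    ]
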