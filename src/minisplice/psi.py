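"""Percent-spliced-in (PSI) quantification from fragment-analysis peak tables.

The capillary instrument reports, per biological replicate, a list of sized
fragments with fluorescence peak heights.  Each isoform's PSI is its summed
peak height across replicates divided by the summed height of all detected
isoforms across replicates, times 100 — i.e. a pooled, height-weighted share.
Replicate dispersion is the population standard deviation (divisor n) of the
per-replicate PSIs.

Variant effects are expressed against the wild-type construct as an absolute
delta (ΔPSI = PSI_variant − PSI_WT, percentage points) and a relative delta
(δPSI = PSI_variant / PSI_WT × 100).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .isoforms import (
    DEFAULT_LENGTH_TOLERANCE,
    MinigeneModel,
    SpliceEvent,
    infer_events,
)

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class PeakRecord:
    replicate: int
    length: float
    height: float
    isoform_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError("peak height must be >= 0")
        if self.length <= 0:
            raise ValueError("fragment length must be > 0")


@dataclass
class PeakTable:
    """All peaks of one construct across its biological replicates."""

    construct_id: str
    peaks: list[PeakRecord] = field(default_factory=list)

    @property
    def replicates(self) -> list[int]:
        return sorted({p.replicate for p in self.peaks})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "construct_id": self.construct_id,
                    "replicate": p.replicate,
                    "length_nt": p.length,
                    "height": p.height,
                    "isoform_id": p.isoform_id,
                }
                for p in self.peaks
            ],
            columns=["construct_id", "replicate", "length_nt", "height", "isoform_id"],
        )


@dataclass(frozen=True)
class IsoformQuant:
    isoform_id: str
    psi: float
    sd: float
    per_replicate_psi: tuple[float, ...]

    def rounded(self, ndigits: int = 1) -> "IsoformQuant":
        """Interface precision: one decimal place, matching assay reporting."""
        return IsoformQuant(
            self.isoform_id,
            round(self.psi, ndigits),
            round(self.sd, ndigits),
            tuple(round(p, ndigits) for p in self.per_replicate_psi),
        )


@dataclass(frozen=True)
class DeltaResult:
    delta_psi_abs: float
    delta_psi_rel: Optional[float]
    rel_defined: bool = True


def assign_isoforms(
    table: PeakTable,
    model: MinigeneModel,
    candidates: Sequence[SpliceEvent],
    tolerance: float = DEFAULT_LENGTH_TOLERANCE,
    min_height: float = 0.0,
) -> PeakTable:
    """Label every peak with the splice event its length matches.

    Peaks below ``min_height`` are dropped (count logged); lengths matching no
    candidate — or more than one within tolerance — keep the label
    ``unassigned`` so the quantification step can include or exclude them
    explicitly.
    """
    kept = [p for p in table.peaks if p.height >= min_height]
    dropped = len(table.peaks) - len(kept)
    if dropped:
        logger.warning(
            "%s: dropped %d peak(s) below min_height=%g", table.construct_id, dropped, min_height
        )
    if not kept:
        logger.warning("%s: no peaks above min_height", table.construct_id)
        return PeakTable(table.construct_id, [])

    assignments = infer_events([p.length for p in kept], model, candidates, tolerance)
    labelled = []
    for peak, assign in zip(kept, assignments):
        if assign.status == "assigned":
            iso = assign.event.name
        else:
            iso = UNASSIGNED
            logger.warning(
                "%s replicate %d: peak at %.1f nt %s (%s)",
                table.construct_id,
                peak.replicate,
                peak.length,
                assign.status,
                assign.note,
            )
        labelled.append(PeakRecord(peak.replicate, peak.length, peak.height, iso))
    return PeakTable(table.construct_id, labelled)


def compute_psi(
    table: PeakTable, include_unassigned: bool = False
) -> list[IsoformQuant]:
    """Pooled PSI per isoform plus per-replicate PSIs and their population SD.

    The denominator covers all detected isoforms; unexplained peaks are
    excluded unless ``include_unassigned``.  Heights of multiple peaks mapping
    to one isoform within a replicate are summed first.
    """
    peaks = [p for p in table.peaks if p.isoform_id is not None]
    if not include_unassigned:
        peaks = [p for p in peaks if p.isoform_id != UNASSIGNED]
    if not peaks:
        raise ValueError(f"{table.construct_id}: no labelled peaks to quantify")

    df = pd.DataFrame(
        {
            "isoform": [p.isoform_id for p in peaks],
            "replicate": [p.replicate for p in peaks],
            "height": [p.height for p in peaks],
        }
    )
    total = df["height"].sum()
    if total <= 0:
        raise ValueError(f"{table.construct_id}: zero total peak height")

    pooled = df.groupby("isoform")["height"].sum() / total * 100.0
    by_rep = df.pivot_table(
        index="isoform", columns="replicate", values="height", aggfunc="sum", fill_value=0.0
    )
    rep_totals = by_rep.sum(axis=0)
    per_rep_psi = by_rep.divide(rep_totals, axis=1) * 100.0

    out = []
    for isoform in pooled.index:
        reps = per_rep_psi.loc[isoform].to_numpy(dtype=float)
        out.append(
            IsoformQuant(
                isoform_id=str(isoform),
                psi=float(pooled[isoform]),
                sd=float(np.std(reps)),  # population SD, divisor n
                per_replicate_psi=tuple(float(x) for x in reps),
            )
        )
    return sorted(out, key=lambda q: -q.psi)


def compute_delta(variant_psi: float, wt_psi: float) -> DeltaResult:
    """ΔPSI (absolute, points) and δPSI (relative, %) of the full-length
    isoform in a variant construct versus wild type.

    δPSI is undefined when the wild-type PSI is zero; the absolute delta is
    still returned, with ``rel_defined`` flagged False.
    """
    for name, v in (("variant", variant_psi), ("wild-type", wt_psi)):
        if not 0 <= v <= 100:
            raise ValueError(f"{name} PSI {v} outside [0, 100]")
    delta_abs = variant_psi - wt_psi
    if wt_psi == 0:
        return DeltaResult(delta_abs, None, rel_defined=False)
    return DeltaResult(delta_abs, variant_psi / wt_psi * 100.0, rel_defined=True)


def quant_frame(quants: Sequence[IsoformQuant], construct_id: str) -> pd.DataFrame:
    """Tabular view of quantification results (one row per isoform)."""
    return pd.DataFrame(
        [
            {
                "construct_id": construct_id,
                "isoform_id": q.isoform_id,
                "psi": round(q.psi, 1),
                "sd": round(q.sd, 1),
                **{f"psi_rep{i + 1}": round(p, 1) for i, p in enumerate(q.per_replicate_psi)},
            }
            for q in quants
        ]
    )
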