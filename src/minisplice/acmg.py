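"""ACMG/AMP evidence combination and functional (PS3/BS3) reclassification.

Implements the standard five-tier combining rules over coded evidence items
(PVS1, PS1-4, PM1-6, PP1-5, BA1, BS1-4, BP1-7) and the splicing-assay
reclassification procedure built on them:

* PS3 (strong functional, pathogenic) is assigned when the minigene assay
  shows ΔPSI ≤ −54 percentage points of full-length isoform inclusion — the
  reduction calibrated against an intronic variant from a confirmed patient,
  whose only possible mechanism is splicing.
* BS3 (strong functional, benign) is assigned to intronic or synonymous
  variants with ΔPSI ≥ −10; missense and nonsense variants never receive BS3,
  since an intact splice pattern says nothing about protein-level damage.
* Exons with weak baseline inclusion gate the procedure: if the wild-type
  construct includes the full-length isoform in < 70% of transcripts and the
  variant decreases inclusion further, no functional criterion is applied
  (the assay cannot distinguish signal from the exon's intrinsic weakness).
  An *increase* in inclusion remains interpretable and is still considered.
* On reclassification of a missense/nonsense variant, protein-level criteria
  (PS1, PM1, PM5, PP2, BP1) are stripped: the functional evidence concerns
  splicing only, and those codes score amino-acid impact.

One deliberate deviation from a literal "any conflict → VUS" reading: PM2
(absence from population databases) is exempt from the pathogenic/benign
conflict test.  PM2 co-occurs with benign supporting codes on bona fide
likely-benign variants (rare but harmless), and treating it as conflicting
evidence would push every such variant to VUS.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Optional, Sequence

from .transcript import VariantEffectClass

# -- criterion catalogue -----------------------------------------------------

PATHOGENIC = "pathogenic"
BENIGN = "benign"

VERY_STRONG = "very-strong"
STRONG = "strong"
MODERATE = "moderate"
SUPPORTING = "supporting"
STAND_ALONE = "stand-alone"

#: code -> (polarity, strength); fixed by the guidelines.
CRITERIA: dict[str, tuple[str, str]] = {
    "PVS1": (PATHOGENIC, VERY_STRONG),
    **{f"PS{i}": (PATHOGENIC, STRONG) for i in range(1, 5)},
    **{f"PM{i}": (PATHOGENIC, MODERATE) for i in range(1, 7)},
    **{f"PP{i}": (PATHOGENIC, SUPPORTING) for i in range(1, 6)},
    "BA1": (BENIGN, STAND_ALONE),
    **{f"BS{i}": (BENIGN, STRONG) for i in range(1, 5)},
    **{f"BP{i}": (BENIGN, SUPPORTING) for i in range(1, 8)},
}

#: Protein-impact codes stripped when reclassifying a missense/nonsense
#: variant on splicing evidence.  PP3 is retained: in this context it scores
#: the splicing prediction, consistent with its presence in every
#: reclassified evidence set.
PROTEIN_IMPACT_CODES = frozenset({"PS1", "PM1", "PM5", "PP2", "BP1"})

#: PS3 requires at least this much *loss* of full-length inclusion (points).
PS3_DELTA_MAX = -54.0
#: BS3 requires the loss to be no worse than this (points).
BS3_DELTA_MIN = -10.0
#: Wild-type constructs below this full-length PSI are uninterpretable for
#: further decreases.
BASELINE_GATE_PSI = 70.0


def validate_code(code: str) -> str:
    code = code.strip().upper()
    if code not in CRITERIA:
        raise ValueError(f"unknown ACMG/AMP criterion code: {code!r}")
    return code


class FiveTierClass(IntEnum):
    """Ordered five-tier classification (Benign < ... < Pathogenic)."""

    BENIGN = 0
    LIKELY_BENIGN = 1
    VUS = 2
    LIKELY_PATHOGENIC = 3
    PATHOGENIC = 4

    def __str__(self) -> str:
        return {
            FiveTierClass.BENIGN: "Benign",
            FiveTierClass.LIKELY_BENIGN: "Likely benign",
            FiveTierClass.VUS: "VUS",
            FiveTierClass.LIKELY_PATHOGENIC: "Likely pathogenic",
            FiveTierClass.PATHOGENIC: "Pathogenic",
        }[self]

    @classmethod
    def parse(cls, text: str) -> "FiveTierClass":
        key = text.strip().lower().replace("_", " ")
        table = {
            "benign": cls.BENIGN,
            "likely benign": cls.LIKELY_BENIGN,
            "vus": cls.VUS,
            "uncertain significance": cls.VUS,
            "likely pathogenic": cls.LIKELY_PATHOGENIC,
            "pathogenic": cls.PATHOGENIC,
        }
        if key not in table:
            raise ValueError(f"unknown five-tier class: {text!r}")
        return table[key]


def _strength_counts(codes: Iterable[str], polarity: str) -> Counter:
    counts: Counter = Counter()
    for code in codes:
        pol, strength = CRITERIA[code]
        if pol == polarity:
            counts[strength] += 1
    return counts


def _pathogenic_tier(counts: Counter) -> Optional[FiveTierClass]:
    pvs = counts[VERY_STRONG]
    ps = counts[STRONG]
    pm = counts[MODERATE]
    pp = counts[SUPPORTING]
    if pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp == 1) or pp >= 2):
        return FiveTierClass.PATHOGENIC
    if ps >= 2:
        return FiveTierClass.PATHOGENIC
    if ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)):
        return FiveTierClass.PATHOGENIC
    if pvs >= 1 and pm == 1:
        return FiveTierClass.LIKELY_PATHOGENIC
    if ps == 1 and 1 <= pm <= 2:
        return FiveTierClass.LIKELY_PATHOGENIC
    if ps == 1 and pp >= 2:
        return FiveTierClass.LIKELY_PATHOGENIC
    if pm >= 3:
        return FiveTierClass.LIKELY_PATHOGENIC
    if pm == 2 and pp >= 2:
        return FiveTierClass.LIKELY_PATHOGENIC
    if pm == 1 and pp >= 4:
        return FiveTierClass.LIKELY_PATHOGENIC
    return None


def _benign_tier(counts: Counter) -> Optional[FiveTierClass]:
    if counts[STAND_ALONE] >= 1 or counts[STRONG] >= 2:
        return FiveTierClass.BENIGN
    if counts[STRONG] == 1 and counts[SUPPORTING] >= 1:
        return FiveTierClass.LIKELY_BENIGN
    if counts[SUPPORTING] >= 2:
        return FiveTierClass.LIKELY_BENIGN
    return None


def combine(criteria: Iterable[str]) -> FiveTierClass:
    """Combine evidence codes into a five-tier class.

    Pathogenic and benign arms are evaluated independently; any co-occurrence
    of benign codes with pathogenic codes other than PM2 is a conflict and
    yields VUS (see module docstring for the PM2 exemption).
    """
    codes = {validate_code(c) for c in criteria}
    benign_codes = {c for c in codes if CRITERIA[c][0] == BENIGN}
    path_codes_non_pm2 = {
        c for c in codes if CRITERIA[c][0] == PATHOGENIC and c != "PM2"
    }
    if benign_codes and path_codes_non_pm2:
        return FiveTierClass.VUS
    tier = _pathogenic_tier(_strength_counts(codes, PATHOGENIC))
    if tier is not None and not benign_codes:
        return tier
    tier = _benign_tier(_strength_counts(codes, BENIGN))
    if tier is not None:
        return tier
    return FiveTierClass.VUS


# -- functional-criterion assignment ----------------------------------------

FUNCTIONAL_NONE = "none"


def assign_functional(
    delta_psi_abs: float,
    effect: VariantEffectClass,
    wt_baseline_psi: Optional[float] = None,
    ps3_delta_max: float = PS3_DELTA_MAX,
    bs3_delta_min: float = BS3_DELTA_MIN,
    baseline_gate_psi: float = BASELINE_GATE_PSI,
) -> str:
    """Decide PS3 / BS3 / none for one assayed variant.

    The baseline gate applies first: a wild-type full-length PSI below the
    gate makes any further *decrease* uninterpretable (returns none), while
    increases remain eligible.  An unknown baseline (None) passes the gate.
    """
    if not -100.0 <= delta_psi_abs <= 100.0:
        raise ValueError(f"ΔPSI {delta_psi_abs} outside [-100, 100]")
    if (
        wt_baseline_psi is not None
        and wt_baseline_psi < baseline_gate_psi
        and delta_psi_abs < 0
    ):
        return FUNCTIONAL_NONE
    if delta_psi_abs <= ps3_delta_max:
        return "PS3"
    if delta_psi_abs >= bs3_delta_min and effect in (
        VariantEffectClass.INTRONIC,
        VariantEffectClass.SYNONYMOUS,
    ):
        return "BS3"
    return FUNCTIONAL_NONE


def strip_protein_criteria(
    before: Iterable[str], effect: VariantEffectClass
) -> set[str]:
    """Remove protein-impact codes from a missense/nonsense evidence set.

    Applied only while adding a functional splicing criterion; other effect
    classes pass through unchanged.
    """
    codes = {validate_code(c) for c in before}
    if effect in (VariantEffectClass.MISSENSE, VariantEffectClass.NONSENSE):
        return codes - PROTEIN_IMPACT_CODES
    return codes


# -- per-variant reclassification -------------------------------------------


@dataclass
class ReclassRecord:
    """Full before/after picture of one assayed variant."""

    variant: str
    effect: VariantEffectClass
    delta_psi_abs: float
    wt_baseline_psi: Optional[float]
    before: set[str]
    functional: str = FUNCTIONAL_NONE
    after: Optional[set[str]] = None
    class_before: FiveTierClass = FiveTierClass.VUS
    class_after: Optional[FiveTierClass] = None
    changed: bool = False
    direction: str = "none"  # toward-pathogenic | toward-benign | none
    protein_note: Optional[str] = None
    exon: Optional[int] = None

    @property
    def reclassified(self) -> bool:
        return self.functional != FUNCTIONAL_NONE


def reclassify(
    variant: str,
    effect: VariantEffectClass,
    delta_psi_abs: float,
    before: Iterable[str],
    wt_baseline_psi: Optional[float] = None,
    **extra,
) -> ReclassRecord:
    """Run the full procedure on one variant: combine the prior evidence,
    decide the functional criterion, strip protein codes where due, and
    recombine.

    Variants receiving no functional criterion keep empty after-columns and
    are reported as not reclassified.
    """
    before_set = {validate_code(c) for c in before}
    rec = ReclassRecord(
        variant=variant,
        effect=effect,
        delta_psi_abs=delta_psi_abs,
        wt_baseline_psi=wt_baseline_psi,
        before=before_set,
        class_before=combine(before_set),
        **extra,
    )
    rec.functional = assign_functional(delta_psi_abs, effect, wt_baseline_psi)
    if rec.functional == FUNCTIONAL_NONE:
        return rec
    rec.after = strip_protein_criteria(before_set, effect) | {rec.functional}
    rec.class_after = combine(rec.after)
    rec.changed = rec.class_after != rec.class_before
    if rec.changed:
        rec.direction = (
            "toward-pathogenic"
            if rec.class_after > rec.class_before
            else "toward-benign"
        )
    return rec


@dataclass
class CohortSummary:
    n: int
    functional_added: int
    changed: int
    retained: int  # functional criterion added, class unchanged
    not_reclassified: int  # no functional criterion
    transitions: dict[tuple[str, str], int]
    toward_pathogenic: int
    toward_benign: int

    def transition_count(self, before: str, after: str) -> int:
        return self.transitions.get((before, after), 0)


def summarize_cohort(records: Sequence[ReclassRecord]) -> CohortSummary:
    """Cohort-level counts and the before→after transition matrix.

    The transition matrix (over reclassified variants) is the stable ground
    truth; upgrade/downgrade counts under any naming convention derive from
    it.
    """
    if not records:
        raise ValueError("no records to summarize")
    transitions: Counter = Counter()
    for rec in records:
        if rec.reclassified:
            transitions[(str(rec.class_before), str(rec.class_after))] += 1
    reclassified = [r for r in records if r.reclassified]
    changed = [r for r in reclassified if r.changed]
    return CohortSummary(
        n=len(records),
        functional_added=len(reclassified),
        changed=len(changed),
        retained=len(reclassified) - len(changed),
        not_reclassified=len(records) - len(reclassified),
        transitions=dict(transitions),
        toward_pathogenic=sum(1 for r in changed if r.direction == "toward-pathogenic"),
        toward_benign=sum(1 for r in changed if r.direction == "toward-benign"),
    )
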