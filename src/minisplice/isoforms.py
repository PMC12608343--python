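"""Minigene constructs, splice events, fragment-length prediction and ORF
consequences.

A minigene places one or more gene exons (with flanking intronic sequence)
between two constitutively spliced vector exons; RT-PCR across the vector
exons yields one amplicon per splicing isoform.  Each aberrant isoform is
described here as a :class:`SpliceEvent` relative to the full-length
reference, from which the expected amplicon length and the coding-sequence
consequence (frame status, premature termination codon) follow
deterministically.

Splice-site coordinate convention: an acceptor coordinate names the *last*
intronic base of the 3' AG, a donor coordinate names the *first* intronic
base of the 5' GT.  A pseudoexon activated by a cryptic acceptor at c.X-263
and a novel donor at c.X-168 therefore spans the 94 bases strictly between
the two coordinates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence, Union

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .transcript import CVariantPosition, TranscriptModel, parse_hgvs_c


class EventKind(str, Enum):
    FULL_LENGTH = "full_length"
    EXON_SKIP = "exon_skip"
    TRUNCATION_5PRIME = "truncation_5prime"
    TRUNCATION_3PRIME = "truncation_3prime"
    EXTENSION = "extension"
    INTRON_RETENTION = "intron_retention"
    PSEUDOEXON_INCLUSION = "pseudoexon_inclusion"


@dataclass(frozen=True)
class SpliceEvent:
    """One transcript isoform relative to the reference.

    ``exon`` is the affected exon index (for intron retention / pseudoexon
    inclusion: the intron *following* that exon).  ``length`` is the
    truncation/extension/retention length in nt; for pseudoexons it may be
    omitted and derived from ``acceptor``/``donor``.
    """

    kind: EventKind
    exon: Optional[int] = None
    length: Optional[int] = None
    acceptor: Optional[CVariantPosition] = None
    donor: Optional[CVariantPosition] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length is not None and self.length <= 0:
            raise ValueError(f"event length must be positive, got {self.length}")
        if self.kind is EventKind.PSEUDOEXON_INCLUSION and self.length is None:
            if self.acceptor is None or self.donor is None:
                raise ValueError("pseudoexon needs either a length or acceptor+donor")
            object.__setattr__(self, "length", pseudoexon_length(self.acceptor, self.donor))

    @property
    def name(self) -> str:
        if self.label:
            return self.label
        parts = [self.kind.value]
        if self.exon is not None:
            parts.append(f"ex{self.exon}")
        if self.length is not None and self.kind is not EventKind.FULL_LENGTH:
            parts.append(f"{self.length}nt")
        return "_".join(parts)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind.value,
            "exon": self.exon,
            "length": self.length,
            "acceptor": str(self.acceptor) if self.acceptor else None,
            "donor": str(self.donor) if self.donor else None,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpliceEvent":
        def _pos(v):
            return parse_hgvs_c(v) if v else None

        return cls(
            kind=EventKind(d["kind"]),
            exon=d.get("exon"),
            length=d.get("length"),
            acceptor=_pos(d.get("acceptor")),
            donor=_pos(d.get("donor")),
            label=d.get("label"),
        )


def pseudoexon_length(
    acceptor: Union[CVariantPosition, str], donor: Union[CVariantPosition, str]
) -> int:
    """Length of a pseudoexon from its cryptic acceptor and donor coordinates.

    Both coordinates must be intronic offsets of the same sign hanging off the
    same anchor (same intron).  Under the site convention (acceptor = last
    intronic base of the AG, donor = first intronic base of the GT) the
    included segment is what lies strictly between the two coordinates:
    ``(c.X-263, c.X-168)`` gives 94 nt.
    """
    if isinstance(acceptor, str):
        acceptor = parse_hgvs_c(acceptor + "A>A") if ">" not in acceptor else parse_hgvs_c(acceptor)
    if isinstance(donor, str):
        donor = parse_hgvs_c(donor + "A>A") if ">" not in donor else parse_hgvs_c(donor)
    if acceptor.anchor != donor.anchor or acceptor.utr3 != donor.utr3:
        raise ValueError(
            f"acceptor {acceptor} and donor {donor} do not share an anchor "
            "(pseudoexon sites must lie in the same intron)"
        )
    if acceptor.offset == 0 or donor.offset == 0:
        raise ValueError("pseudoexon sites must be intronic (non-zero offset)")
    if (acceptor.offset < 0) != (donor.offset < 0):
        raise ValueError("pseudoexon sites must lie on the same side of the anchor")
    if acceptor.offset < 0:
        length = abs(acceptor.offset) - abs(donor.offset) - 1
    else:
        length = donor.offset - acceptor.offset - 1
    if length <= 0:
        raise ValueError(
            f"non-positive pseudoexon length {length} from acceptor {acceptor}, donor {donor}"
        )
    return length


@dataclass(frozen=True)
class Segment:
    """One piece of the cloned insert: a gene exon or a flanking intron chunk."""

    kind: str  # "exon" | "intron"
    name: str
    length: int
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"segment {self.name}: length must be positive")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(f"segment {self.name}: sequence/length mismatch")


@dataclass
class MinigeneModel:
    """A minigene construct as seen by the cDNA primer pair.

    ``upstream_flank_len`` / ``downstream_flank_len`` are the invariant vector
    contributions to every amplicon (vector exon + primer offset on each
    side); ``segments`` are the cloned insert pieces in genomic order.
    """

    construct_id: str
    upstream_flank_len: int
    downstream_flank_len: int
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.upstream_flank_len <= 0 or self.downstream_flank_len <= 0:
            raise ValueError("flank lengths must be positive")

    @property
    def insert_exons(self) -> list[Segment]:
        return [s for s in self.segments if s.kind == "exon"]

    def exon_segment(self, index: int) -> Segment:
        exons = self.insert_exons
        if not 1 <= index <= len(exons):
            raise ValueError(f"construct {self.construct_id} has no insert exon {index}")
        return exons[index - 1]

    def intron_segment_after(self, exon_index: int) -> Segment:
        """The intron segment immediately following insert exon ``exon_index``."""
        seen_exons = 0
        for seg in self.segments:
            if seg.kind == "exon":
                seen_exons += 1
            elif seg.kind == "intron" and seen_exons == exon_index:
                return seg
        raise ValueError(f"no intron segment after exon {exon_index}")

    @property
    def full_length(self) -> int:
        """Amplicon length of the correctly spliced (full-length) isoform."""
        return (
            self.upstream_flank_len
            + sum(s.length for s in self.insert_exons)
            + self.downstream_flank_len
        )


#: Largest fragment the sizing standard can call (GeneScan 500); bigger
#: isoforms are real but unquantifiable by capillary sizing.
DEFAULT_SIZE_CAP = 500

#: Capillary sizing jitter tolerated when matching peaks to expected lengths.
DEFAULT_LENGTH_TOLERANCE = 2


def expected_fragment_length(model: MinigeneModel, event: SpliceEvent) -> int:
    """Predicted amplicon length for one splicing isoform of a construct."""
    full = model.full_length
    kind = event.kind
    if kind is EventKind.FULL_LENGTH:
        return full
    if kind is EventKind.EXON_SKIP:
        if event.exon is None:
            raise ValueError("exon_skip needs an exon index")
        return full - model.exon_segment(event.exon).length
    if kind in (EventKind.TRUNCATION_5PRIME, EventKind.TRUNCATION_3PRIME):
        if event.length is None or event.exon is None:
            raise ValueError(f"{kind.value} needs exon and length")
        seg = model.exon_segment(event.exon)
        if event.length >= seg.length:
            raise ValueError(
                f"truncation of {event.length} nt >= exon length {seg.length}"
            )
        return full - event.length
    if kind is EventKind.EXTENSION:
        if event.length is None:
            raise ValueError("extension needs a length")
        return full + event.length
    if kind is EventKind.INTRON_RETENTION:
        if event.length is not None:
            return full + event.length
        if event.exon is None:
            raise ValueError("intron_retention needs a length or an exon index")
        return full + model.intron_segment_after(event.exon).length
    if kind is EventKind.PSEUDOEXON_INCLUSION:
        assert event.length is not None  # enforced in __post_init__
        return full + event.length
    raise ValueError(f"unknown event kind {kind}")


@dataclass(frozen=True)
class LengthAssignment:
    """Outcome of matching one observed fragment length to candidate events."""

    length: float
    event: Optional[SpliceEvent]
    status: str  # "assigned" | "unexplained" | "tie" | "oversize"
    note: str = ""


def infer_events(
    observed_lengths: Sequence[float],
    model: MinigeneModel,
    candidates: Sequence[SpliceEvent],
    tolerance: float = DEFAULT_LENGTH_TOLERANCE,
) -> list[LengthAssignment]:
    """Assign each observed fragment length to the unique candidate event
    within ``tolerance`` nt, or flag it unexplained (ties included).

    Flags, never fails: downstream quantification decides what to do with
    unexplained peaks.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    expected = [(ev, expected_fragment_length(model, ev)) for ev in candidates]
    out: list[LengthAssignment] = []
    for obs in observed_lengths:
        hits = [(ev, exp) for ev, exp in expected if abs(exp - obs) <= tolerance]
        if len(hits) == 1:
            out.append(LengthAssignment(obs, hits[0][0], "assigned"))
        elif not hits:
            out.append(LengthAssignment(obs, None, "unexplained", "no candidate within tolerance"))
        else:
            names = ", ".join(ev.name for ev, _ in hits)
            out.append(LengthAssignment(obs, None, "tie", f"ambiguous between: {names}"))
    return out


# -- coding-sequence editing -------------------------------------------------


class MissingSequenceError(ValueError):
    """The event touches a segment for which no sequence is available."""


def _coding_sequence(model: TranscriptModel) -> str:
    if len(model.exon_seqs) != len(model.exons):
        raise MissingSequenceError("transcript model lacks sequence for some exons")
    spliced = "".join(model.exon_seqs[e.index] for e in model.exons)
    return spliced[model.cds_start - 1 : model.cds_end]


def _exon_coding_span(model: TranscriptModel, exon_index: int) -> tuple[int, int]:
    """CDS-relative (1-based, inclusive) span contributed by one exon; (0, -1)
    when the exon is entirely untranslated."""
    t_start, t_end = model.exon_transcript_span(exon_index)
    s = max(t_start, model.cds_start) - model.cds_start + 1
    e = min(t_end, model.cds_end) - model.cds_start + 1
    if e < s:
        return 0, -1
    return s, e


def apply_event_to_cds(model: TranscriptModel, event: SpliceEvent) -> str:
    """Edit the reference coding sequence according to a splice event.

    Exon skips remove the exon's coding bases; truncations shorten an exon
    from one end; pseudoexon inclusion and intron retention insert intronic
    sequence at the corresponding junction.  Requires sequence on every
    touched segment.
    """
    cds = _coding_sequence(model)
    kind = event.kind
    if kind is EventKind.FULL_LENGTH:
        return cds
    if event.exon is None:
        raise ValueError(f"{kind.value} needs an exon index")
    s, e = _exon_coding_span(model, event.exon)
    if kind is EventKind.EXON_SKIP:
        if e < s:
            raise ValueError(f"exon {event.exon} contributes no coding bases")
        return cds[: s - 1] + cds[e:]
    if kind is EventKind.TRUNCATION_5PRIME:
        return cds[: s - 1] + cds[s - 1 + event.length :]
    if kind is EventKind.TRUNCATION_3PRIME:
        return cds[: e - event.length] + cds[e:]
    if kind in (EventKind.INTRON_RETENTION, EventKind.PSEUDOEXON_INCLUSION):
        intron_index = event.exon  # intron following this exon
        intron_seq = model.intron_seqs.get(intron_index)
        if intron_seq is None:
            raise MissingSequenceError(f"no sequence for intron {intron_index}")
        if kind is EventKind.INTRON_RETENTION:
            insert = intron_seq
        else:
            acceptor, donor = event.acceptor, event.donor
            if acceptor is None or donor is None:
                raise ValueError("pseudoexon insertion into sequence needs acceptor+donor")
            L = len(intron_seq)
            if acceptor.offset < 0:
                # offsets counted back from the start of the downstream exon:
                # offset -k is intron position L - k + 1 (1-based)
                lo = L - abs(acceptor.offset) + 2
                hi = L - abs(donor.offset)
            else:
                lo = acceptor.offset + 1
                hi = donor.offset - 1
            if not (1 <= lo <= hi <= L):
                raise ValueError("pseudoexon coordinates fall outside the intron sequence")
            insert = intron_seq[lo - 1 : hi]
            if event.length is not None and len(insert) != event.length:
                raise ValueError(
                    f"pseudoexon sequence length {len(insert)} != declared {event.length}"
                )
        return cds[:e] + insert + cds[e:]
    raise ValueError(f"cannot apply event kind {kind} to a coding sequence")


# -- ORF annotation ----------------------------------------------------------


@dataclass(frozen=True)
class OrfConsequence:
    frame_status: str  # "in_frame" | "frameshift"
    affected_codon: int
    ptc_codon: Optional[int] = None
    p_notation: Optional[str] = None


def annotate_orf(
    original_cds: str, edited_cds: str, edit_position: int
) -> OrfConsequence:
    """Frame status and premature-stop consequence of an edited coding sequence.

    ``edit_position`` is the 1-based coding coordinate of the first altered
    base.  Frame status follows the net length change mod 3; the premature
    stop is the first in-frame stop at or after the affected codon in the
    edited reading.  The shorthand protein notation
    ``p.(<aa><codon><newaa>fsTer<n>)`` counts the affected codon as 1.
    """
    if len(original_cds) % 3 != 0:
        raise ValueError(
            f"original CDS length {len(original_cds)} is not a codon multiple"
        )
    if not 1 <= edit_position <= len(original_cds) + 1:
        raise ValueError(f"edit position {edit_position} outside the CDS")
    net = len(edited_cds) - len(original_cds)
    frame_status = "in_frame" if net % 3 == 0 else "frameshift"
    affected_codon = math.ceil(edit_position / 3)

    edited_aa = str(Seq(edited_cds[: len(edited_cds) - len(edited_cds) % 3]).translate())
    ptc_codon = None
    for i in range(affected_codon - 1, len(edited_aa)):
        if edited_aa[i] == "*":
            ptc_codon = i + 1
            break
    # a stop at the reference terminus of an in-frame edit is not premature
    if (
        ptc_codon is not None
        and frame_status == "in_frame"
        and ptc_codon == (len(original_cds) + net) // 3
    ):
        ptc_codon = None

    p_notation = None
    if frame_status == "frameshift" and ptc_codon is not None:
        orig_aa = str(Seq(original_cds).translate())
        ref_aa = orig_aa[affected_codon - 1] if affected_codon <= len(orig_aa) else "?"
        new_aa = edited_aa[affected_codon - 1] if affected_codon <= len(edited_aa) else "?"
        ter_offset = ptc_codon - affected_codon + 1
        if new_aa == "*":
            p_notation = f"p.({seq3(ref_aa)}{affected_codon}Ter)"
        else:
            p_notation = (
                f"p.({seq3(ref_aa)}{affected_codon}{seq3(new_aa)}fsTer{ter_offset})"
            )
    return OrfConsequence(
        frame_status=frame_status,
        affected_codon=affected_codon,
        ptc_codon=ptc_codon,
        p_notation=p_notation,
    )


def events_to_json(events: Sequence[SpliceEvent], path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps([e.to_dict() for e in events], indent=2) + "\n")


def events_from_json(path: Union[str, Path]) -> list[SpliceEvent]:
    return [SpliceEvent.from_dict(d) for d in json.loads(Path(path).read_text())]
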