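"""Reference-transcript models and HGVS c.-notation coordinate arithmetic.

The coding (c.) coordinate system numbers exonic bases 1..n from the A of the
start codon; intronic positions hang off the nearest exonic base as a signed
offset (``c.1007-167`` is 167 bases upstream of the acceptor of the exon whose
first coding base is c.1007).  Everything downstream — minigene fragment
prediction, splice-event annotation, the reclassification engine — anchors on
the arithmetic defined here.

Coordinates are 1-based and inclusive throughout, matching HGVS convention.
Minus-strand genes are normalised to transcript orientation at load time, so
all c. math afterwards is strand-agnostic.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Union


class HgvsParseError(ValueError):
    """The HGVS string could not be parsed; message names the offending token."""


class UnsupportedVariantError(HgvsParseError):
    """Well-formed HGVS, but not an SNV (del/dup/ins/delins are out of scope)."""


class CoordinateError(ValueError):
    """A position falls outside the transcript model or its flanking introns."""


@dataclass(frozen=True)
class ExonDef:
    """One exon: 1-based inclusive genomic span.

    ``index`` is the 1-based exon number in transcript order.
    """

    index: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"exon {self.index}: start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CVariantPosition:
    """A single-nucleotide variant in HGVS c. coordinates.

    ``anchor`` is the c. coordinate of the nearest exonic base (negative for
    the 5' UTR; ``utr3`` marks ``c.*N`` 3'-UTR anchors).  ``offset`` is 0 for
    exonic positions, positive for intronic positions downstream of a donor,
    negative for intronic positions upstream of an acceptor.
    """

    anchor: int
    offset: int
    ref: str
    alt: str
    utr3: bool = False

    def __post_init__(self) -> None:
        if self.anchor == 0:
            raise ValueError("c. coordinates have no position 0")
        if self.utr3 and self.anchor < 0:
            raise ValueError("3'-UTR anchors are positive (c.*N)")

    @property
    def is_intronic(self) -> bool:
        return self.offset != 0

    def __str__(self) -> str:
        star = "*" if self.utr3 else ""
        off = f"{self.offset:+d}" if self.offset else ""
        return f"c.{star}{self.anchor}{off}{self.ref}>{self.alt}"


class VariantEffectClass(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SYNONYMOUS = "synonymous"
    INTRONIC = "intronic"
    UTR = "utr"


# SNV grammar: c.[*]<anchor>[(+|-)<offset>]<ref>><alt>
_SNV_RE = re.compile(
    r"^c\.(?P<star>\*)?(?P<anchor>-?\d+)(?P<offset>[+-]\d+)?"
    r"(?P<ref>[ACGT])>(?P<alt>[ACGT])$"
)
_NON_SNV_RE = re.compile(r"del|dup|ins|inv|\[")


def parse_hgvs_c(text: str) -> CVariantPosition:
    """Parse an SNV HGVS c. description, e.g. ``c.1007-167A>T``.

    Raises :class:`UnsupportedVariantError` for deletions/duplications/etc.
    and :class:`HgvsParseError` for anything else that does not match the SNV
    grammar.
    """
    text = text.strip()
    m = _SNV_RE.match(text)
    if m is None:
        if _NON_SNV_RE.search(text):
            raise UnsupportedVariantError(
                f"only single-nucleotide substitutions are supported: {text!r}"
            )
        prefix = text[:2]
        if prefix != "c.":
            raise HgvsParseError(f"expected 'c.' prefix, got {prefix!r} in {text!r}")
        raise HgvsParseError(f"malformed HGVS c. SNV description: {text!r}")
    anchor = int(m.group("anchor"))
    if anchor == 0:
        raise HgvsParseError(f"c.0 is not a valid coordinate: {text!r}")
    offset = int(m.group("offset")) if m.group("offset") else 0
    return CVariantPosition(
        anchor=anchor,
        offset=offset,
        ref=m.group("ref"),
        alt=m.group("alt"),
        utr3=m.group("star") is not None,
    )


def format_hgvs_c(pos: CVariantPosition) -> str:
    return str(pos)


@dataclass
class TranscriptModel:
    """Exon/intron/CDS architecture of a reference transcript.

    ``cds_start``/``cds_end`` are transcript-relative (1-based, spliced)
    coordinates of the first base of the start codon and the last base of the
    stop codon.  ``exon_seqs``/``intron_seqs`` optionally carry nucleotide
    sequence in transcript orientation, keyed by exon/intron number (intron
    ``i`` follows exon ``i``).
    """

    transcript_id: str
    exons: list[ExonDef]
    cds_start: int
    cds_end: int
    strand: str = "+"
    exon_seqs: dict[int, str] = field(default_factory=dict)
    intron_seqs: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("transcript needs at least one exon")
        idx = [e.index for e in self.exons]
        if idx != list(range(1, len(self.exons) + 1)):
            raise ValueError(f"exon indices must run 1..n, got {idx}")
        spans = sorted((e.start, e.end) for e in self.exons)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("exons overlap")
        if not (1 <= self.cds_start <= self.cds_end <= self.length):
            raise CoordinateError(
                f"CDS span {self.cds_start}..{self.cds_end} outside transcript "
                f"of length {self.length}"
            )
        for i, exon in enumerate(self.exons, start=1):
            seq = self.exon_seqs.get(i)
            if seq is not None and len(seq) != exon.length:
                raise ValueError(f"exon {i} sequence length mismatch")

    # -- basic geometry ----------------------------------------------------

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start + 1

    def exon(self, index: int) -> ExonDef:
        try:
            return self.exons[index - 1]
        except IndexError:
            raise CoordinateError(f"no exon {index} in {self.transcript_id}") from None

    def intron_length(self, index: int) -> int:
        """Genomic gap between exon ``index`` and exon ``index + 1``."""
        if not 1 <= index < len(self.exons):
            raise CoordinateError(f"no intron {index}")
        a, b = self.exon(index), self.exon(index + 1)
        if self.strand == "+":
            gap = b.start - a.end - 1
        else:
            gap = a.start - b.end - 1
        if gap <= 0:
            raise CoordinateError(f"exons {index}/{index + 1} are adjacent")
        return gap

    # -- transcript <-> genomic --------------------------------------------

    def transcript_to_genomic(self, tpos: int) -> int:
        if not 1 <= tpos <= self.length:
            raise CoordinateError(f"transcript position {tpos} outside 1..{self.length}")
        remaining = tpos
        for exon in self.exons:
            if remaining <= exon.length:
                if self.strand == "+":
                    return exon.start + remaining - 1
                return exon.end - remaining + 1
            remaining -= exon.length
        raise AssertionError("unreachable")

    def genomic_to_transcript(self, gpos: int) -> int:
        walked = 0
        for exon in self.exons:
            if exon.start <= gpos <= exon.end:
                if self.strand == "+":
                    return walked + (gpos - exon.start) + 1
                return walked + (exon.end - gpos) + 1
            walked += exon.length
        raise CoordinateError(f"genomic position {gpos} not exonic in {self.transcript_id}")

    # -- c. <-> transcript --------------------------------------------------

    def c_anchor_to_transcript(self, anchor: int, utr3: bool = False) -> int:
        if utr3:
            tpos = self.cds_end + anchor
        elif anchor > 0:
            tpos = self.cds_start + anchor - 1
        else:
            tpos = self.cds_start + anchor  # anchor < 0: c.-1 abuts the start codon
        if not 1 <= tpos <= self.length:
            raise CoordinateError(f"c. anchor {anchor} outside transcript")
        return tpos

    def transcript_to_c_anchor(self, tpos: int) -> tuple[int, bool]:
        """Return (anchor, utr3_flag) for a transcript position."""
        if tpos < self.cds_start:
            return tpos - self.cds_start, False
        if tpos > self.cds_end:
            return tpos - self.cds_end, True
        return tpos - self.cds_start + 1, False

    def exon_of_transcript_pos(self, tpos: int) -> ExonDef:
        walked = 0
        for exon in self.exons:
            if tpos <= walked + exon.length:
                return exon
            walked += exon.length
        raise CoordinateError(f"transcript position {tpos} outside transcript")

    def exon_transcript_span(self, index: int) -> tuple[int, int]:
        """Transcript-relative (start, end) of exon ``index``."""
        walked = 0
        for exon in self.exons:
            if exon.index == index:
                return walked + 1, walked + exon.length
            walked += exon.length
        raise CoordinateError(f"no exon {index}")


def c_to_genomic(pos: CVariantPosition, model: TranscriptModel) -> int:
    """Map a c. position (including intronic offsets) to a genomic coordinate.

    Intronic offsets must anchor on an exon boundary (positive offsets on the
    last base of an exon, negative on the first base) and must not run past
    the flanking intron.
    """
    tpos = model.c_anchor_to_transcript(pos.anchor, pos.utr3)
    gpos = model.transcript_to_genomic(tpos)
    if pos.offset == 0:
        return gpos
    exon = model.exon_of_transcript_pos(tpos)
    sign = 1 if model.strand == "+" else -1
    if pos.offset > 0:
        if model.transcript_to_genomic(tpos) != (exon.end if model.strand == "+" else exon.start):
            raise CoordinateError(
                f"positive intronic offset must anchor on an exon's last base: {pos}"
            )
        if exon.index < len(model.exons) and pos.offset > model.intron_length(exon.index):
            raise CoordinateError(f"offset {pos.offset:+d} exceeds intron {exon.index}: {pos}")
        return gpos + sign * pos.offset
    # negative offset: anchor must be the first base of its exon
    if model.transcript_to_genomic(tpos) != (exon.start if model.strand == "+" else exon.end):
        raise CoordinateError(
            f"negative intronic offset must anchor on an exon's first base: {pos}"
        )
    if exon.index > 1 and -pos.offset > model.intron_length(exon.index - 1):
        raise CoordinateError(f"offset {pos.offset:+d} exceeds intron {exon.index - 1}: {pos}")
    return gpos + sign * pos.offset


def genomic_to_c(
    gpos: int, model: TranscriptModel, ref: str = "N", alt: str = "N"
) -> CVariantPosition:
    """Inverse of :func:`c_to_genomic`.

    Intronic positions anchor on the nearer exon boundary; the proximal half
    of an intron (including its centre) takes a positive offset from the
    upstream exon, the distal half a negative offset from the downstream exon.
    """
    try:
        tpos = model.genomic_to_transcript(gpos)
    except CoordinateError:
        return _intronic_genomic_to_c(gpos, model, ref, alt)
    anchor, utr3 = model.transcript_to_c_anchor(tpos)
    return CVariantPosition(anchor=anchor, offset=0, ref=ref, alt=alt, utr3=utr3)


def _intronic_genomic_to_c(
    gpos: int, model: TranscriptModel, ref: str, alt: str
) -> CVariantPosition:
    for i in range(1, len(model.exons)):
        up, down = model.exon(i), model.exon(i + 1)
        if model.strand == "+":
            lo, hi = up.end + 1, down.start - 1
            inside = lo <= gpos <= hi
            d_up = gpos - up.end
            d_down = down.start - gpos
        else:
            lo, hi = down.end + 1, up.start - 1
            inside = lo <= gpos <= hi
            d_up = up.start - gpos
            d_down = gpos - down.end
        if not inside:
            continue
        _, up_t_end = model.exon_transcript_span(i)
        down_t_start, _ = model.exon_transcript_span(i + 1)
        if d_up <= d_down:
            anchor, utr3 = model.transcript_to_c_anchor(up_t_end)
            return CVariantPosition(anchor=anchor, offset=d_up, ref=ref, alt=alt, utr3=utr3)
        anchor, utr3 = model.transcript_to_c_anchor(down_t_start)
        return CVariantPosition(anchor=anchor, offset=-d_down, ref=ref, alt=alt, utr3=utr3)
    raise CoordinateError(f"genomic position {gpos} outside {model.transcript_id}")


# -- region classification --------------------------------------------------


@dataclass(frozen=True)
class RegionWindows:
    """Widths defining the splice region around each exon/intron junction.

    Defaults follow the VEP convention: the last/first 3 exonic bases and the
    first/last 8 intronic bases of each junction count as splice region.
    Intronic positions beyond ``intronic`` are deep-intronic.
    """

    exonic: int = 3
    intronic: int = 8


REGION_EXONIC = "exonic"
REGION_EXONIC_SPLICE = "exonic-splice-region"
REGION_SPLICE_INTRONIC = "splice-site-intronic"
REGION_DEEP_INTRONIC = "deep-intronic"


def classify_region(
    pos: CVariantPosition,
    windows: RegionWindows = RegionWindows(),
    model: Optional[TranscriptModel] = None,
) -> str:
    """Label a position exonic / exonic-splice-region / splice-site-intronic /
    deep-intronic.

    Intronic positions classify from the offset alone.  Distinguishing plain
    exonic from exonic-splice-region needs junction distances, hence a model;
    without one, exonic positions are labelled ``exonic``.
    """
    if pos.offset != 0:
        return (
            REGION_SPLICE_INTRONIC
            if abs(pos.offset) <= windows.intronic
            else REGION_DEEP_INTRONIC
        )
    if model is None:
        return REGION_EXONIC
    tpos = model.c_anchor_to_transcript(pos.anchor, pos.utr3)
    exon = model.exon_of_transcript_pos(tpos)
    t_start, t_end = model.exon_transcript_span(exon.index)
    dist_acceptor = tpos - t_start + 1 if exon.index > 1 else None
    dist_donor = t_end - tpos + 1 if exon.index < len(model.exons) else None
    for dist in (dist_acceptor, dist_donor):
        if dist is not None and dist <= windows.exonic:
            return REGION_EXONIC_SPLICE
    return REGION_EXONIC


# -- variant effect triage ---------------------------------------------------

_P_SYNONYMOUS_RE = re.compile(r"=\)?$")
_P_TER_RE = re.compile(r"(Ter|\*)\d*\)?$")


class IndeterminateEffectError(ValueError):
    """Exonic variant with neither protein notation nor sequence to triage it."""


def effect_class(
    pos: Union[CVariantPosition, str], protein_note: Optional[str] = None
) -> VariantEffectClass:
    """Triage a variant into missense/nonsense/synonymous/intronic/utr.

    Intronic beats everything (offset != 0); exonic coding variants are read
    off the p. notation: a trailing ``=`` means synonymous, ``Ter`` means
    nonsense, anything else missense.
    """
    if isinstance(pos, str):
        pos = parse_hgvs_c(pos)
    if pos.offset != 0:
        return VariantEffectClass.INTRONIC
    if pos.utr3 or pos.anchor < 0:
        return VariantEffectClass.UTR
    if protein_note is None or not protein_note.strip():
        raise IndeterminateEffectError(
            f"exonic variant {pos} needs p. notation (or sequence) to classify"
        )
    note = protein_note.strip()
    if _P_SYNONYMOUS_RE.search(note):
        return VariantEffectClass.SYNONYMOUS
    if _P_TER_RE.search(note):
        return VariantEffectClass.NONSENSE
    return VariantEffectClass.MISSENSE


# -- loaders -----------------------------------------------------------------


def transcript_from_json(source: Union[str, Path, dict]) -> TranscriptModel:
    """Load a transcript model from a JSON document (or already-parsed dict).

    Schema::

        {"transcript_id": ..., "strand": "+"|"-",
         "exons": [{"index": 1, "start": ..., "end": ...}, ...],
         "cds": {"start": ..., "end": ...},
         "exon_seqs": {"1": "ACGT..."}, "intron_seqs": {"1": "GT...AG"}}
    """
    if not isinstance(source, dict):
        source = json.loads(Path(source).read_text())
    exons = [ExonDef(e["index"], e["start"], e["end"]) for e in source["exons"]]
    return TranscriptModel(
        transcript_id=source["transcript_id"],
        exons=sorted(exons, key=lambda e: e.index),
        cds_start=source["cds"]["start"],
        cds_end=source["cds"]["end"],
        strand=source.get("strand", "+"),
        exon_seqs={int(k): v.upper() for k, v in source.get("exon_seqs", {}).items()},
        intron_seqs={int(k): v.upper() for k, v in source.get("intron_seqs", {}).items()},
    )


def transcript_from_gff3(
    gff3_path: Union[str, Path],
    transcript_id: str,
    fasta_path: Optional[Union[str, Path]] = None,
) -> TranscriptModel:
    """Build a transcript model from GFF3 exon/CDS features.

    Exons are taken from features of type ``exon`` whose ``Parent`` is the
    transcript; the CDS span comes from ``CDS`` features.  With a FASTA of the
    underlying contig, exon and intron sequences are extracted in transcript
    orientation.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    exon_feats = [
        f
        for f in db.features_of_type("exon")
        if transcript_id in f.attributes.get("Parent", [])
    ]
    cds_feats = [
        f
        for f in db.features_of_type("CDS")
        if transcript_id in f.attributes.get("Parent", [])
    ]
    if not exon_feats:
        raise ValueError(f"no exons with Parent={transcript_id} in {gff3_path}")
    strand = exon_feats[0].strand
    reverse = strand == "-"
    exon_feats.sort(key=lambda f: f.start, reverse=reverse)
    exons = [ExonDef(i, f.start, f.end) for i, f in enumerate(exon_feats, start=1)]

    model = TranscriptModel(
        transcript_id=transcript_id,
        exons=exons,
        cds_start=1,
        cds_end=sum(e.length for e in exons),
        strand=strand,
    )
    if cds_feats:
        g_first = min(f.start for f in cds_feats) if not reverse else max(f.end for f in cds_feats)
        g_last = max(f.end for f in cds_feats) if not reverse else min(f.start for f in cds_feats)
        model.cds_start = model.genomic_to_transcript(g_first)
        model.cds_end = model.genomic_to_transcript(g_last)

    if fasta_path is not None:
        from Bio import SeqIO
        from Bio.Seq import Seq

        contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
        seqid = exon_feats[0].seqid
        contig = contigs[seqid]

        def oriented(start: int, end: int) -> str:
            raw = contig[start - 1 : end]
            return str(Seq(raw).reverse_complement()) if reverse else raw

        for exon in model.exons:
            model.exon_seqs[exon.index] = oriented(exon.start, exon.end)
        for i in range(1, len(model.exons)):
            a, b = model.exon(i), model.exon(i + 1)
            if reverse:
                model.intron_seqs[i] = oriented(b.end + 1, a.start - 1)
            else:
                model.intron_seqs[i] = oriented(a.end + 1, b.start - 1)
    return model
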