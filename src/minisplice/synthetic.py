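"""Synthetic inputs for every pipeline stage.

Real minigene experiments produce (i) a construct with known architecture,
(ii) two-replicate fragment-analysis peak tables, and (iii) predictor score
tables for candidate selection.  The generators here emulate all three with
known ground truth so the whole pipeline is testable offline:

* :func:`gen_minigene` builds a randomized construct (vector exons, cloned
  exon, flanking introns) with valid GT/AG dinucleotides at every designed
  junction and, optionally, a planted cryptic acceptor/donor pair at chosen
  intronic offsets — the raw material for pseudoexon events.
* :func:`gen_peak_table` draws replicate peak heights around a known isoform
  mixture with multiplicative log-normal noise.  Fluorescence intensities are
  positive and scale-dependent, so noise is multiplicative; the default
  coefficient of variation (0.1) brackets the replicate scatter typical of
  two-replicate capillary runs.  Isoforms beyond the sizing-standard ceiling
  appear in the truth record but not in the table.
* :func:`gen_score_table` emits predictor score rows with controlled firing
  patterns (SpliceAI-only, SPiP-only, MMSplice-only, none, AF-blocked) and a
  truth label per row for filter auditing.

Ground truth is always returned (and written) alongside the data; nothing
downstream needs to reverse-engineer it.  All generators are deterministic
under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .isoforms import (
    DEFAULT_SIZE_CAP,
    EventKind,
    MinigeneModel,
    Segment,
    SpliceEvent,
    expected_fragment_length,
)
from .psi import PeakRecord, PeakTable
from .transcript import CVariantPosition, ExonDef, TranscriptModel

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


@dataclass
class GeneratedMinigene:
    """A randomized construct plus the transcript-style model behind it."""

    minigene: MinigeneModel
    transcript: TranscriptModel
    #: c. coordinate of the first base of the cloned exon (anchor for
    #: negative intronic offsets of the upstream intron).
    exon_anchor_c: int
    sequences: dict[str, str]

    def write_fasta(self, path: Union[str, Path]) -> None:
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        from Bio import SeqIO

        records = [
            SeqRecord(Seq(seq), id=name, description="synthetic minigene segment")
            for name, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")


def gen_minigene(
    seed: int,
    exon_len: int = 150,
    intron5_len: int = 300,
    intron3_len: int = 120,
    upstream_flank_len: int = 180,
    downstream_flank_len: int = 160,
    planted_acceptor_offset: Optional[int] = None,
    planted_donor_offset: Optional[int] = None,
    construct_id: str = "synthetic",
) -> GeneratedMinigene:
    """Generate a single-exon minigene with random sequence.

    Planted offsets are c.-style intronic offsets relative to the cloned
    exon: negative pairs plant a cryptic acceptor (AG ending at the acceptor
    offset) and donor (GT starting at the donor offset) in the upstream
    intron; positive pairs plant them in the downstream intron.
    """
    for name, v in (
        ("exon_len", exon_len),
        ("intron5_len", intron5_len),
        ("intron3_len", intron3_len),
        ("upstream_flank_len", upstream_flank_len),
        ("downstream_flank_len", downstream_flank_len),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    rng = np.random.default_rng(seed)

    vector_up = _random_seq(rng, upstream_flank_len)
    vector_down = _random_seq(rng, downstream_flank_len)
    intron5 = list(_random_seq(rng, intron5_len))
    intron3 = list(_random_seq(rng, intron3_len))
    exon = _random_seq(rng, exon_len)

    # designed junctions: every intron starts GT and ends AG
    intron5[0:2] = "GT"
    intron5[-2:] = "AG"
    intron3[0:2] = "GT"
    intron3[-2:] = "AG"

    if (planted_acceptor_offset is None) != (planted_donor_offset is None):
        raise ValueError("plant acceptor and donor offsets together")
    if planted_acceptor_offset is not None:
        a, d = planted_acceptor_offset, planted_donor_offset
        if (a < 0) != (d < 0):
            raise ValueError("planted sites must lie in the same intron")
        if a < 0:
            if abs(a) <= abs(d):
                raise ValueError("upstream-intron acceptor must lie 5' of the donor")
            if abs(a) + 1 > intron5_len:
                raise ValueError(
                    f"acceptor offset {a} incompatible with intron5_len={intron5_len}"
                )
            # offset -k is intron5 position intron5_len - k + 1 (1-based)
            ap = intron5_len - abs(a) + 1
            dp = intron5_len - abs(d) + 1
            intron5[ap - 2 : ap] = "AG"  # AG ends at the acceptor coordinate
            intron5[dp - 1 : dp + 1] = "GT"  # GT starts at the donor coordinate
        else:
            if a >= d:
                raise ValueError("downstream-intron acceptor must lie 5' of the donor")
            if d + 1 > intron3_len:
                raise ValueError(
                    f"donor offset {d} incompatible with intron3_len={intron3_len}"
                )
            intron3[a - 2 : a] = "AG"
            intron3[d - 1 : d + 1] = "GT"

    intron5_s = "".join(intron5)
    intron3_s = "".join(intron3)

    minigene = MinigeneModel(
        construct_id=construct_id,
        upstream_flank_len=upstream_flank_len,
        downstream_flank_len=downstream_flank_len,
        segments=[
            Segment("intron", "intron5", intron5_len, intron5_s),
            Segment("exon", "exon", exon_len, exon),
            Segment("intron", "intron3", intron3_len, intron3_s),
        ],
    )

    # transcript-style view: vector exon 1, cloned exon 2, vector exon 3 on a
    # contiguous synthetic contig; CDS trimmed to a codon multiple
    g = 1
    spans = []
    for length in (upstream_flank_len, intron5_len, exon_len, intron3_len, downstream_flank_len):
        spans.append((g, g + length - 1))
        g += length
    exons = [
        ExonDef(1, *spans[0]),
        ExonDef(2, *spans[2]),
        ExonDef(3, *spans[4]),
    ]
    t_len = upstream_flank_len + exon_len + downstream_flank_len
    transcript = TranscriptModel(
        transcript_id=f"{construct_id}_tx",
        exons=exons,
        cds_start=1,
        cds_end=t_len - (t_len % 3),
        exon_seqs={1: vector_up, 2: exon, 3: vector_down},
        intron_seqs={1: intron5_s, 2: intron3_s},
    )
    return GeneratedMinigene(
        minigene=minigene,
        transcript=transcript,
        exon_anchor_c=upstream_flank_len + 1,
        sequences={
            "vector_exon_up": vector_up,
            "intron5": intron5_s,
            "exon": exon,
            "intron3": intron3_s,
            "vector_exon_down": vector_down,
        },
    )


@dataclass
class SimulationConfig:
    """Study-design parameters for peak-table simulation.

    Defaults mirror the assay design: two biological replicates, multiplicative
    log-normal height noise with CV 0.1, and a 500-nt sizing ceiling.
    """

    seed: int
    isoform_truth: list[tuple[SpliceEvent, float]]
    n_replicates: int = 2
    noise_cv: float = 0.1
    total_height: float = 20000.0
    flank_lengths: tuple[int, int] = (180, 160)
    size_cap: int = DEFAULT_SIZE_CAP
    model: Optional[MinigeneModel] = None
    exon_len: int = 150

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        fracs = [f for _, f in self.isoform_truth]
        if any(f < 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("isoform fractions must be >= 0 and sum to 1")

    def resolved_model(self) -> MinigeneModel:
        if self.model is not None:
            return self.model
        up, down = self.flank_lengths
        return MinigeneModel(
            construct_id="sim",
            upstream_flank_len=up,
            downstream_flank_len=down,
            segments=[Segment("exon", "exon", self.exon_len)],
        )


@dataclass
class PeakTableTruth:
    """Sidecar ground truth written next to every simulated peak table."""

    fractions: dict[str, float]
    lengths: dict[str, int]
    oversize: list[str]
    seed: int

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "fractions": self.fractions,
                    "lengths": self.lengths,
                    "oversize": self.oversize,
                    "seed": self.seed,
                },
                indent=2,
            )
            + "\n"
        )


def gen_peak_table(cfg: SimulationConfig) -> tuple[PeakTable, PeakTableTruth]:
    """Simulate replicate fragment-analysis peaks over a known isoform mix.

    Per replicate, each isoform's height is ``total_height x fraction`` times
    a unit-mean log-normal factor with the configured CV.  Isoforms whose
    expected fragment exceeds ``size_cap`` are recorded as oversize truth and
    omitted from the table, as capillary sizing would.
    """
    rng = np.random.default_rng(cfg.seed)
    model = cfg.resolved_model()
    sigma = float(np.sqrt(np.log1p(cfg.noise_cv**2)))

    lengths = {ev.name: expected_fragment_length(model, ev) for ev, _ in cfg.isoform_truth}
    oversize = [name for name, L in lengths.items() if L > cfg.size_cap]

    peaks: list[PeakRecord] = []
    for rep in range(1, cfg.n_replicates + 1):
        for ev, frac in cfg.isoform_truth:
            if frac == 0 or ev.name in oversize:
                continue
            noise = rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma) if sigma else 1.0
            height = cfg.total_height * frac * noise
            peaks.append(PeakRecord(rep, float(lengths[ev.name]), float(height)))
    truth = PeakTableTruth(
        fractions={ev.name: f for ev, f in cfg.isoform_truth},
        lengths=lengths,
        oversize=oversize,
        seed=cfg.seed,
    )
    return PeakTable("sim", peaks), truth


# -- predictor score tables --------------------------------------------------

SCORE_CATEGORIES = ("spliceai_only", "spip_only", "mmsplice_only", "none", "af_blocked")
_SPIP_POSITIVE = ("Alter by SPiCE", "Alter BP", "Alter by MES (Poly TC)")


def gen_score_table(
    seed: int,
    n: int,
    mix: Optional[dict[str, float]] = None,
) -> pd.DataFrame:
    """Generate predictor score rows with controlled firing patterns.

    Returns a DataFrame with the documented score columns plus ``category``
    and ``truth_pass`` labels (AF-blocked and none rows are the negatives).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    mix = mix or {c: 1.0 for c in SCORE_CATEGORIES}
    unknown = set(mix) - set(SCORE_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown score categories: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    cats = list(mix)
    weights = np.array([mix[c] for c in cats], dtype=float)
    weights /= weights.sum()

    rows = []
    for i in range(n):
        cat = rng.choice(cats, p=weights)
        low4 = rng.uniform(0.0, 0.15, size=4)
        row = {
            "variant": f"c.{i + 1}A>G",
            "ds_ag": low4[0],
            "ds_al": low4[1],
            "ds_dg": low4[2],
            "ds_dl": low4[3],
            "spip_interpretation": "NTR",
            "spip_confidence": float(rng.uniform(0, 20)),
            "mmsplice_dlp": float(rng.uniform(-0.8, 0.8)),
            "gnomad_af": float(rng.uniform(0, 0.009)),
            "alphamissense": None,
            "category": cat,
            "truth_pass": cat in ("spliceai_only", "spip_only", "mmsplice_only"),
        }
        if cat == "spliceai_only":
            row[str(rng.choice(["ds_ag", "ds_al", "ds_dg", "ds_dl"]))] = float(
                rng.uniform(0.25, 1.0)
            )
        elif cat == "spip_only":
            label = str(rng.choice(_SPIP_POSITIVE))
            if rng.random() < 0.5:
                label += " + Alter ESR"
            row["spip_interpretation"] = label
            row["spip_confidence"] = float(rng.uniform(50, 100))
        elif cat == "mmsplice_only":
            sign = 1.0 if rng.random() < 0.5 else -1.0
            row["mmsplice_dlp"] = float(sign * rng.uniform(1.2, 4.0))
        elif cat == "af_blocked":
            row["ds_ag"] = float(rng.uniform(0.5, 1.0))
            row["mmsplice_dlp"] = float(rng.uniform(1.5, 4.0))
            row["gnomad_af"] = float(rng.uniform(0.02, 0.5))
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "variant",
            "ds_ag",
            "ds_al",
            "ds_dg",
            "ds_dl",
            "spip_interpretation",
            "spip_confidence",
            "mmsplice_dlp",
            "gnomad_af",
            "alphamissense",
            "category",
            "truth_pass",
        ],
    )


# -- end-to-end scenario helper ---------------------------------------------


def classification_scenario(
    seed: int,
    designed_delta: float,
    effect_intronic: bool = True,
    noise_cv: float = 0.1,
    wt_full_fraction: float = 0.95,
) -> tuple[SimulationConfig, SimulationConfig, SpliceEvent]:
    """Paired wild-type/variant simulation configs with a designed ΔPSI.

    The wild-type construct includes the full-length isoform at
    ``wt_full_fraction`` x 100 PSI; the variant shifts that by
    ``designed_delta`` points into an exon-skip isoform.  Used for
    end-to-end recovery checks of the PS3/BS3/none decision.
    """
    wt_frac = wt_full_fraction
    var_frac = wt_frac + designed_delta / 100.0
    if not 0.0 <= var_frac <= 1.0:
        raise ValueError("designed delta pushes the variant fraction outside [0, 1]")
    full = SpliceEvent(EventKind.FULL_LENGTH, label="full")
    skip = SpliceEvent(EventKind.EXON_SKIP, exon=1, label="skip")
    wt_cfg = SimulationConfig(
        seed=seed * 2 + 1,
        isoform_truth=[(full, wt_frac), (skip, 1.0 - wt_frac)],
        noise_cv=noise_cv,
    )
    var_cfg = SimulationConfig(
        seed=seed * 2 + 2,
        isoform_truth=[(full, var_frac), (skip, 1.0 - var_frac)],
        noise_cv=noise_cv,
    )
    return wt_cfg, var_cfg, full
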