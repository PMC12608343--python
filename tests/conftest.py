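"""Shared fixtures: a small fully-sequenced three-exon transcript model and a
matching minigene construct, built explicitly so tests can count bases by
hand."""

from __future__ import annotations

import numpy as np
import pytest

from minisplice import ExonDef, MinigeneModel, Segment, TranscriptModel

# codons free of stop triplets in any downstream combination we use
_SAFE_CODONS = ["GCT", "GGA", "CTG", "AAA", "TGC", "CGT", "ACC", "TTC"]


def make_cds(n_codons: int, seed: int = 0) -> str:
    """ATG + (n_codons - 2) safe codons + TAA."""
    rng = np.random.default_rng(seed)
    body = "".join(rng.choice(_SAFE_CODONS) for _ in range(n_codons - 2))
    return "ATG" + body + "TAA"


def make_intron(length: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    middle = "".join(rng.choice(list("ACGT")) for _ in range(length - 4))
    return "GT" + middle + "AG"


@pytest.fixture
def three_exon_model() -> TranscriptModel:
    """3 exons (30 + 45 + 36 nt), CDS spanning the whole transcript
    (37 codons), introns of 100 nt each, on a contig starting at 101."""
    cds = make_cds(37, seed=1)
    assert len(cds) == 111
    e1, e2, e3 = cds[:30], cds[30:75], cds[75:]
    return TranscriptModel(
        transcript_id="SYNTX1",
        exons=[ExonDef(1, 101, 130), ExonDef(2, 231, 275), ExonDef(3, 376, 411)],
        cds_start=1,
        cds_end=111,
        exon_seqs={1: e1, 2: e2, 3: e3},
        intron_seqs={1: make_intron(100, seed=2), 2: make_intron(100, seed=3)},
    )


@pytest.fixture
def minigene_model() -> MinigeneModel:
    """Single cloned exon of 150 nt between 180/160 nt vector flanks
    (full-length amplicon = 490 nt)."""
    return MinigeneModel(
        construct_id="MG1",
        upstream_flank_len=180,
        downstream_flank_len=160,
        segments=[
            Segment("intron", "intron5", 300),
            Segment("exon", "exon", 150),
            Segment("intron", "intron3", 120),
        ],
    )
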