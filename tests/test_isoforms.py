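"""Splice-event geometry, fragment-length prediction and ORF consequences."""

from __future__ import annotations

import math

import numpy as np
import pytest
from Bio.Data.CodonTable import standard_dna_table

from minisplice import (
    EventKind,
    MinigeneModel,
    Segment,
    SpliceEvent,
    annotate_orf,
    apply_event_to_cds,
    expected_fragment_length,
    infer_events,
    parse_hgvs_c,
    pseudoexon_length,
)
from conftest import make_cds, make_intron


class TestPseudoexonLength:
    def test_printed_deep_intronic_pair_gives_94(self):
        """Cryptic acceptor at c.1007-263 with novel donor at c.1007-168
        includes exactly the 94 bases strictly between them."""
        assert pseudoexon_length("c.1007-263", "c.1007-168") == 94

    def test_small_pair_counts_strictly_between(self):
        # acceptor -10, donor -5: included positions are -9..-6, i.e. 4 nt
        assert pseudoexon_length("c.200-10", "c.200-5") == 4

    def test_downstream_intron_positive_offsets(self):
        # acceptor +5, donor +10: included positions are +6..+9
        assert pseudoexon_length("c.200+5A>G", "c.200+10G>T") == 4

    def test_randomized_pairs_match_base_counting_oracle(self):
        """Against an explicit intron sequence: slice out the segment between
        the two site coordinates and count its bases."""
        rng = np.random.default_rng(42)
        intron = make_intron(400, seed=7)
        L = len(intron)
        for _ in range(50):
            a = int(rng.integers(10, L - 2))
            d = int(rng.integers(2, a - 1))
            # oracle: offset -k is intron position L-k+1; count positions
            # strictly between the acceptor and donor coordinates
            ap, dp = L - a + 1, L - d + 1
            oracle = len(intron[ap : dp - 1])
            if oracle <= 0:
                continue
            got = pseudoexon_length(f"c.500-{a}", f"c.500-{d}")
            assert got == oracle

    def test_sites_in_different_introns_rejected(self):
        with pytest.raises(ValueError):
            pseudoexon_length("c.100-50", "c.300-10")

    def test_non_positive_length_rejected(self):
        with pytest.raises(ValueError):
            pseudoexon_length("c.100-5", "c.100-4")


class TestFragmentLength:
    def test_full_length_is_flanks_plus_exons(self, minigene_model):
        full = SpliceEvent(EventKind.FULL_LENGTH)
        assert expected_fragment_length(minigene_model, full) == 180 + 150 + 160

    def test_3prime_truncation_shortens_by_its_length(self, minigene_model):
        full = expected_fragment_length(minigene_model, SpliceEvent(EventKind.FULL_LENGTH))
        trunc = SpliceEvent(EventKind.TRUNCATION_3PRIME, exon=1, length=125)
        assert full - expected_fragment_length(minigene_model, trunc) == 125

    def test_skip_of_only_exon_leaves_flanks(self, minigene_model):
        skip = SpliceEvent(EventKind.EXON_SKIP, exon=1)
        assert expected_fragment_length(minigene_model, skip) == 180 + 160

    def test_pseudoexon_adds_its_length(self, minigene_model):
        full = expected_fragment_length(minigene_model, SpliceEvent(EventKind.FULL_LENGTH))
        pe = SpliceEvent(
            EventKind.PSEUDOEXON_INCLUSION,
            exon=1,
            acceptor=parse_hgvs_c("c.500-263A>T"),
            donor=parse_hgvs_c("c.500-168A>T"),
        )
        assert expected_fragment_length(minigene_model, pe) == full + 94

    @pytest.mark.parametrize(
        "event, delta",
        [
            (SpliceEvent(EventKind.TRUNCATION_5PRIME, exon=1, length=6), -6),
            (SpliceEvent(EventKind.EXTENSION, exon=1, length=49), +49),
            (SpliceEvent(EventKind.INTRON_RETENTION, exon=1, length=300), +300),
            (SpliceEvent(EventKind.EXON_SKIP, exon=1), -150),
        ],
    )
    def test_length_additivity(self, minigene_model, event, delta):
        full = expected_fragment_length(minigene_model, SpliceEvent(EventKind.FULL_LENGTH))
        assert expected_fragment_length(minigene_model, event) == full + delta

    def test_inapplicable_event_rejected(self, minigene_model):
        with pytest.raises(ValueError):
            expected_fragment_length(
                minigene_model, SpliceEvent(EventKind.EXON_SKIP, exon=3)
            )


class TestInferEvents:
    def test_full_and_truncation_both_assigned(self, minigene_model):
        full = SpliceEvent(EventKind.FULL_LENGTH, label="full")
        trunc = SpliceEvent(EventKind.TRUNCATION_3PRIME, exon=1, length=125, label="t125")
        lengths = [
            expected_fragment_length(minigene_model, full),
            expected_fragment_length(minigene_model, trunc) + 1,  # within tolerance
        ]
        result = infer_events(lengths, minigene_model, [full, trunc], tolerance=2)
        assert [a.status for a in result] == ["assigned", "assigned"]
        assert [a.event.label for a in result] == ["full", "t125"]

    def test_empty_observed_list(self, minigene_model):
        assert infer_events([], minigene_model, []) == []

    def test_ambiguous_length_flagged_as_tie(self, minigene_model):
        a = SpliceEvent(EventKind.TRUNCATION_3PRIME, exon=1, length=10, label="a")
        b = SpliceEvent(EventKind.TRUNCATION_5PRIME, exon=1, length=11, label="b")
        obs = [expected_fragment_length(minigene_model, a)]
        (res,) = infer_events(obs, minigene_model, [a, b], tolerance=2)
        assert res.status == "tie" and res.event is None
        assert "a" in res.note and "b" in res.note

    def test_unmatched_length_flagged_unexplained(self, minigene_model):
        full = SpliceEvent(EventKind.FULL_LENGTH)
        (res,) = infer_events([9999.0], minigene_model, [full])
        assert res.status == "unexplained"


class TestApplyEventToCds:
    def test_pseudoexon_insertion_length(self, three_exon_model):
        pe = SpliceEvent(
            EventKind.PSEUDOEXON_INCLUSION,
            exon=1,
            acceptor=parse_hgvs_c("c.31-60A>T"),
            donor=parse_hgvs_c("c.31-20A>T"),
        )
        original = apply_event_to_cds(three_exon_model, SpliceEvent(EventKind.FULL_LENGTH))
        edited = apply_event_to_cds(three_exon_model, pe)
        assert len(edited) == len(original) + 39

    def test_edit_matches_manual_string_assembly(self, three_exon_model):
        """Exon skip / retention / pseudoexon all equal an explicit splice of
        the fixture's known segment strings."""
        m = three_exon_model
        e1, e2, e3 = (m.exon_seqs[i] for i in (1, 2, 3))
        i1 = m.intron_seqs[1]
        assert apply_event_to_cds(m, SpliceEvent(EventKind.EXON_SKIP, exon=2)) == e1 + e3
        assert (
            apply_event_to_cds(m, SpliceEvent(EventKind.INTRON_RETENTION, exon=1))
            == e1 + i1 + e2 + e3
        )
        pe = SpliceEvent(
            EventKind.PSEUDOEXON_INCLUSION,
            exon=1,
            acceptor=parse_hgvs_c("c.31-60A>T"),
            donor=parse_hgvs_c("c.31-20A>T"),
        )
        # offsets -60/-20 on a 100-nt intron: intron positions 42..80
        assert apply_event_to_cds(m, pe) == e1 + i1[41:80] + e2 + e3

    def test_truncations_shorten_the_right_end(self, three_exon_model):
        m = three_exon_model
        e1, e2, e3 = (m.exon_seqs[i] for i in (1, 2, 3))
        t5 = SpliceEvent(EventKind.TRUNCATION_5PRIME, exon=2, length=6)
        t3 = SpliceEvent(EventKind.TRUNCATION_3PRIME, exon=2, length=6)
        assert apply_event_to_cds(m, t5) == e1 + e2[6:] + e3
        assert apply_event_to_cds(m, t3) == e1 + e2[:-6] + e3

    def test_zero_length_event_rejected(self):
        with pytest.raises(ValueError):
            SpliceEvent(EventKind.TRUNCATION_3PRIME, exon=1, length=0)

    def test_missing_sequence_rejected(self, three_exon_model):
        three_exon_model.exon_seqs.pop(2)
        with pytest.raises(ValueError):
            apply_event_to_cds(three_exon_model, SpliceEvent(EventKind.EXON_SKIP, exon=2))


def _translate_oracle(cds: str) -> str:
    """Codon-by-codon translation using the standard codon table directly
    (independent of the implementation's whole-sequence translate)."""
    table = standard_dna_table.forward_table
    stops = set(standard_dna_table.stop_codons)
    aas = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        aas.append("*" if codon in stops else table[codon])
    return "".join(aas)


class TestAnnotateOrf:
    def test_94nt_insertion_after_c1006_is_frameshift_codon_336(self):
        """A 94-nt pseudoexon inserted after c.1006 shifts the frame; the
        affected codon is ceil(1007/3) = 336."""
        cds = make_cds(400, seed=5)  # 1200 nt
        rng = np.random.default_rng(6)
        insert = "".join(rng.choice(list("ACGT")) for _ in range(94))
        edited = cds[:1006] + insert + cds[1006:]
        orf = annotate_orf(cds, edited, edit_position=1007)
        assert orf.frame_status == "frameshift"
        assert orf.affected_codon == 336

    def test_in_frame_insertion(self):
        cds = make_cds(40, seed=8)
        edited = cds[:60] + "GCTGCA" + cds[60:]
        orf = annotate_orf(cds, edited, edit_position=61)
        assert orf.frame_status == "in_frame"

    def test_frame_law_and_ptc_match_translation_oracle(self):
        """100 random insertions/deletions: frame status follows net length
        mod 3, and the PTC codon equals a codon-wise translation scan."""
        rng = np.random.default_rng(99)
        for _ in range(100):
            cds = make_cds(int(rng.integers(50, 200)), seed=int(rng.integers(1 << 16)))
            p = int(rng.integers(0, len(cds) - 30))
            if rng.random() < 0.5:
                k = int(rng.integers(1, 120))
                ins = "".join(rng.choice(list("ACGT")) for _ in range(k))
                edited = cds[:p] + ins + cds[p:]
                net = k
            else:
                k = int(rng.integers(1, min(60, len(cds) - p - 3)))
                edited = cds[:p] + cds[p + k :]
                net = -k
            orf = annotate_orf(cds, edited, edit_position=p + 1)
            assert (orf.frame_status == "frameshift") == (net % 3 != 0)
            affected = math.ceil((p + 1) / 3)
            assert orf.affected_codon == affected
            aa = _translate_oracle(edited)
            stops = [i + 1 for i, c in enumerate(aa) if c == "*" and i + 1 >= affected]
            expected_ptc = stops[0] if stops else None
            if orf.frame_status == "frameshift":
                assert orf.ptc_codon == expected_ptc
                if expected_ptc is not None and expected_ptc > affected:
                    assert orf.p_notation.endswith(f"fsTer{expected_ptc - affected + 1})")

    def test_non_codon_original_rejected(self):
        with pytest.raises(ValueError):
            annotate_orf("ATGC", "ATGC", 1)
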