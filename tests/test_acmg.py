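"""Evidence combination, PS3/BS3 assignment, and the full reclassification
procedure against the transcribed study table."""

from __future__ import annotations

from itertools import combinations

import pytest

from minisplice import (
    FiveTierClass,
    VariantEffectClass,
    assign_functional,
    combine,
    reclassify,
    strip_protein_criteria,
    summarize_cohort,
)
from minisplice.acmg import FUNCTIONAL_NONE
from minisplice.io import load_table2_fixture, reclass_inputs

INTRONIC = VariantEffectClass.INTRONIC
SYNONYMOUS = VariantEffectClass.SYNONYMOUS
MISSENSE = VariantEffectClass.MISSENSE
NONSENSE = VariantEffectClass.NONSENSE


# --- independent combining-rules oracle -------------------------------------
# Written directly from the published rule text as nested conditionals over
# explicit code lists; shares no helpers with the implementation.

_PATH_STRENGTH = {"PVS1": "vs"}
for _c in ("PS1", "PS2", "PS3", "PS4"):
    _PATH_STRENGTH[_c] = "s"
for _c in ("PM1", "PM2", "PM3", "PM4", "PM5", "PM6"):
    _PATH_STRENGTH[_c] = "m"
for _c in ("PP1", "PP2", "PP3", "PP4", "PP5"):
    _PATH_STRENGTH[_c] = "p"
_BENIGN_STRENGTH = {"BA1": "a"}
for _c in ("BS1", "BS2", "BS3", "BS4"):
    _BENIGN_STRENGTH[_c] = "s"
for _c in ("BP1", "BP2", "BP3", "BP4", "BP5", "BP6", "BP7"):
    _BENIGN_STRENGTH[_c] = "p"


def combine_oracle(codes: frozenset[str]) -> FiveTierClass:
    vs = sum(1 for c in codes if _PATH_STRENGTH.get(c) == "vs")
    s = sum(1 for c in codes if _PATH_STRENGTH.get(c) == "s")
    m = sum(1 for c in codes if _PATH_STRENGTH.get(c) == "m")
    p = sum(1 for c in codes if _PATH_STRENGTH.get(c) == "p")
    a = sum(1 for c in codes if _BENIGN_STRENGTH.get(c) == "a")
    bs = sum(1 for c in codes if _BENIGN_STRENGTH.get(c) == "s")
    bp = sum(1 for c in codes if _BENIGN_STRENGTH.get(c) == "p")

    pathogenic = (
        (vs >= 1 and (s >= 1 or m >= 2 or (m == 1 and p >= 1) or p >= 2))
        or s >= 2
        or (s == 1 and (m >= 3 or (m == 2 and p >= 2) or (m == 1 and p >= 4)))
    )
    likely_path = (
        (vs >= 1 and m == 1)
        or (s == 1 and m in (1, 2))
        or (s == 1 and p >= 2)
        or m >= 3
        or (m == 2 and p >= 2)
        or (m == 1 and p >= 4)
    )
    benign = a >= 1 or bs >= 2
    likely_benign = (bs == 1 and bp >= 1) or bp >= 2

    has_benign_code = a + bs + bp > 0
    has_path_code_beyond_pm2 = any(
        c in _PATH_STRENGTH and c != "PM2" for c in codes
    )
    if has_benign_code and has_path_code_beyond_pm2:
        return FiveTierClass.VUS
    if pathogenic and not has_benign_code:
        return FiveTierClass.PATHOGENIC
    if likely_path and not has_benign_code:
        return FiveTierClass.LIKELY_PATHOGENIC
    if benign:
        return FiveTierClass.BENIGN
    if likely_benign:
        return FiveTierClass.LIKELY_BENIGN
    return FiveTierClass.VUS


class TestCombine:
    @pytest.mark.parametrize(
        "codes, expected",
        [
            ({"PVS1", "PM2", "PM3", "PP5"}, FiveTierClass.PATHOGENIC),
            ({"PP3", "PM2", "PP5"}, FiveTierClass.VUS),
            (set(), FiveTierClass.VUS),
            ({"PM2", "BP4", "BP6"}, FiveTierClass.LIKELY_BENIGN),
            ({"PM2", "PM3", "PP5", "BS3"}, FiveTierClass.VUS),
            ({"PM2", "BS2", "BP7", "BP6", "BS3"}, FiveTierClass.BENIGN),
            ({"PM3", "PP3", "PM2", "PP5", "PS3"}, FiveTierClass.PATHOGENIC),
        ],
    )
    def test_printed_and_edge_sets(self, codes, expected):
        assert combine(codes) == expected

    def test_agrees_with_brute_force_oracle_exhaustively(self):
        """All evidence sets of up to 6 codes drawn from a 12-code alphabet
        spanning every polarity and strength."""
        alphabet = [
            "PVS1", "PS1", "PS3", "PM1", "PM2", "PM3",
            "PP3", "PP5", "BA1", "BS3", "BP4", "BP7",
        ]
        checked = 0
        for k in range(0, 7):
            for subset in combinations(alphabet, k):
                codes = frozenset(subset)
                assert combine(codes) == combine_oracle(codes), sorted(codes)
                checked += 1
        assert checked == sum(
            1 for k in range(7) for _ in combinations(alphabet, k)
        )

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            combine({"PX9"})

    @pytest.mark.parametrize(
        "base",
        [
            {"PM2", "PM3"},
            {"PP3", "PP5"},
            {"PVS1", "PM2"},
            set(),
        ],
    )
    def test_ps3_never_moves_toward_benign(self, base):
        before = combine(base)
        after = combine(base | {"PS3"})
        assert after >= before

    @pytest.mark.parametrize("base", [{"PM2"}, {"BP7"}, {"PM2", "BP4", "BP6"}, set()])
    def test_bs3_never_moves_toward_pathogenic(self, base):
        before = combine(base)
        after = combine(base | {"BS3"})
        assert after <= before


class TestAssignFunctional:
    @pytest.mark.parametrize(
        "delta, effect, baseline, expected",
        [
            (-54.7, INTRONIC, None, "PS3"),
            (-1.0, INTRONIC, None, "BS3"),
            (-39.0, MISSENSE, None, FUNCTIONAL_NONE),
            (47.2, SYNONYMOUS, 22.7, "BS3"),
            (-22.7, MISSENSE, 22.7, FUNCTIONAL_NONE),
            (-1.2, NONSENSE, None, FUNCTIONAL_NONE),
            (-54.0, MISSENSE, None, "PS3"),
            (-53.9, INTRONIC, None, FUNCTIONAL_NONE),
            (-10.0, SYNONYMOUS, None, "BS3"),
            (-10.1, SYNONYMOUS, None, FUNCTIONAL_NONE),
        ],
    )
    def test_thresholds_and_gates(self, delta, effect, baseline, expected):
        assert assign_functional(delta, effect, baseline) == expected

    def test_low_baseline_gates_decreases_only(self):
        # a further decrease on a weakly included exon is uninterpretable...
        assert assign_functional(-60.0, INTRONIC, 22.7) == FUNCTIONAL_NONE
        # ...but an increase remains eligible
        assert assign_functional(0.5, INTRONIC, 22.7) == "BS3"

    def test_out_of_range_delta_rejected(self):
        with pytest.raises(ValueError):
            assign_functional(-150.0, INTRONIC)


class TestStripProteinCriteria:
    def test_missense_loses_protein_codes(self):
        before = {"PP3", "PM2", "PM1", "PM5", "PP2", "PM3", "PP5"}
        assert strip_protein_criteria(before, MISSENSE) == {"PP3", "PM2", "PM3", "PP5"}

    def test_second_printed_example(self):
        before = {"PM3", "PP3", "PM2", "PM5", "PP2", "PP5"}
        assert strip_protein_criteria(before, MISSENSE) == {"PM3", "PP3", "PM2", "PP5"}

    def test_intronic_set_unchanged(self):
        before = {"PM2", "PM1", "PP2", "PP3"}
        assert strip_protein_criteria(before, INTRONIC) == before

    def test_pp3_is_retained(self):
        assert "PP3" in strip_protein_criteria({"PP3", "PP2"}, NONSENSE)


class TestReclassify:
    def test_intronic_vus_to_likely_pathogenic(self):
        rec = reclassify("c.1006+6T>C", INTRONIC, -54.7, {"PP3", "PM2", "PP5"})
        assert rec.class_before == FiveTierClass.VUS
        assert rec.class_after == FiveTierClass.LIKELY_PATHOGENIC
        assert rec.direction == "toward-pathogenic"

    def test_synonymous_likely_benign_to_benign(self):
        rec = reclassify("c.624T>C", SYNONYMOUS, 52.6, {"PM2", "BS2", "BP7", "BP6"},
                         wt_baseline_psi=22.7)
        assert rec.class_before == FiveTierClass.LIKELY_BENIGN
        assert rec.class_after == FiveTierClass.BENIGN

    def test_zero_delta_intronic_gets_bs3(self):
        rec = reclassify("c.1189-8T>A", INTRONIC, 0.0, {"PM2", "BP6"})
        assert rec.functional == "BS3"
        assert rec.class_before == FiveTierClass.VUS
        assert rec.class_after == FiveTierClass.LIKELY_BENIGN

    def test_no_functional_criterion_means_not_reclassified(self):
        rec = reclassify("c.343G>C", MISSENSE, -39.0, {"PM3", "PM2", "PM1"})
        assert not rec.reclassified
        assert rec.after is None and rec.class_after is None and not rec.changed


@pytest.fixture(scope="module")
def fixture_rows():
    return reclass_inputs(load_table2_fixture())


@pytest.fixture(scope="module")
def records(fixture_rows):
    return [
        reclassify(
            variant=r["variant"],
            effect=r["effect"],
            delta_psi_abs=r["delta_psi_abs"],
            before=r["before"],
            wt_baseline_psi=r["wt_baseline_psi"],
        )
        for r in fixture_rows
        if r["analyzed"]
    ]


class TestCohortReproduction:
    def test_every_published_before_class_reproduced(self, fixture_rows):
        """combine() on all 28 transcribed before-criteria sets (including
        the excluded construct) returns the published class."""
        df = load_table2_fixture()
        for r, row in zip(reclass_inputs(df), df.itertuples()):
            got = combine(r["before"])
            assert str(got) == row.class_before_published, r["variant"]

    def test_every_published_after_class_and_criteria_reproduced(self, records):
        df = load_table2_fixture()
        published = {
            row.variant: (row.criteria_after_published, row.class_after_published)
            for row in df.itertuples()
            if row.analyzed == "yes"
        }
        assert len(records) == 27
        for rec in records:
            after_codes, after_class = published[rec.variant]
            if after_class == "-":
                assert not rec.reclassified, rec.variant
            else:
                assert rec.after == set(after_codes.split(";")), rec.variant
                assert str(rec.class_after) == after_class, rec.variant

    def test_cohort_counts(self, records):
        s = summarize_cohort(records)
        assert s.n == 27
        assert s.functional_added == 18
        assert s.changed == 13
        assert s.retained == 5
        assert s.not_reclassified == 9
        assert s.transition_count("Likely pathogenic", "Pathogenic") == 8
        assert s.transition_count("VUS", "Likely benign") == 3
        assert s.transition_count("VUS", "Likely pathogenic") == 1
        assert s.transition_count("Likely benign", "Benign") == 1

    def test_not_reclassified_are_all_missense_or_nonsense(self, records):
        skipped = [r for r in records if not r.reclassified]
        assert len(skipped) == 9
        assert all(r.effect in (MISSENSE, NONSENSE) for r in skipped)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort([])
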