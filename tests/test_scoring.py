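import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epath.exceptions import ConfigError
from epath.ko_tables import EssentialityCounts, KOAnnotation
from epath.scoring import (
    Thresholds,
    e_score,
    group_mean_score,
    load_scores,
    p_score,
    score_all,
    summarize_scores,
    write_scores,
)


def counts(eg_e, eg_m, non_eg, n=31, ko="K00001"):
    return EssentialityCounts(ko, eg_e, eg_m, non_eg, n)


class TestEScore:
    def test_always_essential_everywhere_approaches_ceiling(self):
        assert e_score(counts(31, 0, 0)) == pytest.approx((31 / 32) ** 2)
        assert round(e_score(counts(31, 0, 0)), 3) == 0.938

    def test_no_appearances_scores_zero(self):
        assert e_score(counts(0, 0, 0)) == 0.0

    def test_hand_evaluated_mixed_tally(self):
        # (2/5)^2 * (4/31)
        assert e_score(counts(1, 1, 2)) == pytest.approx((2 / 5) ** 2 * (4 / 31))

    def test_ceiling_by_brute_force_over_all_tallies(self):
        best = max(
            e_score(counts(e, 0, x, ko="K00001"))
            for e in range(32)
            for x in range(32 - e)
        )
        assert best == pytest.approx((31 / 32) ** 2)
        assert round(best, 3) == 0.938

    def test_zero_iff_never_essential(self):
        for eg_e, eg_m, non_eg in itertools.product(range(4), repeat=3):
            value = e_score(counts(eg_e, eg_m, non_eg, n=12))
            assert (value == 0) == (eg_e + eg_m == 0)

    @settings(deadline=None, max_examples=60)
    @given(st.data())
    def test_strictly_increasing_in_experimental_count(self, data):
        n = data.draw(st.integers(2, 31), label="n")
        eg_m = data.draw(st.integers(0, n - 1), label="eg_m")
        non_eg = data.draw(st.integers(0, n - 1 - eg_m), label="non_eg")
        eg_e = data.draw(st.integers(0, n - 1 - eg_m - non_eg), label="eg_e")
        lo = e_score(counts(eg_e, eg_m, non_eg, n=n))
        hi = e_score(counts(eg_e + 1, eg_m, non_eg, n=n))
        assert hi > lo


LYSINE = "Lysine biosynthesis//Peptidoglycan biosynthesis//"
MURAMYL = "UDP-N-acetylmuramyl tripeptide synthase//UDP-N-acetylmuramyl pentapeptide synthase//"


@pytest.fixture
def lysine_annotations():
    """The tripeptide-synthase scenario: an unscored KO shares its full pathway
    string with exactly one scored partner and its COG string with nobody scored."""
    return {
        "K15792": KOAnnotation(
            ko_id="K15792", kegg_pathway_annotation=LYSINE, cog_annotation=MURAMYL
        ),
        "K01928": KOAnnotation(
            ko_id="K01928",
            kegg_pathway_annotation=LYSINE,
            cog_annotation="UDP-N-acetylmuramyl unrelated//",
        ),
        "K09999": KOAnnotation(
            ko_id="K09999",
            kegg_pathway_annotation="Lysine biosynthesis//",  # prefix, not identical
            cog_annotation=MURAMYL,
        ),
    }


class TestGroupMeanScore:
    def test_single_scored_pathway_partner(self, lysine_annotations):
        value = group_mean_score(
            "K15792", "kegg_pathway", lysine_annotations, {"K01928": 0.59}
        )
        assert value == pytest.approx(0.59)

    def test_cog_group_without_scored_member_is_zero(self, lysine_annotations):
        value = group_mean_score(
            "K15792", "cog", lysine_annotations, {"K01928": 0.59}
        )
        assert value == 0.0

    def test_full_string_match_excludes_prefix_overlap(self, lysine_annotations):
        # K09999 shares tokens but not the byte-identical pathway string
        value = group_mean_score(
            "K15792", "kegg_pathway", lysine_annotations, {"K09999": 0.9, "K01928": 0.59}
        )
        assert value == pytest.approx(0.59)

    def test_token_match_mode_pools_overlapping_strings(self, lysine_annotations):
        value = group_mean_score(
            "K15792",
            "kegg_pathway",
            lysine_annotations,
            {"K09999": 0.9, "K01928": 0.6},
            match="token",
        )
        assert value == pytest.approx(0.75)

    def test_empty_string_forms_its_own_group(
        self, fatty_acid_annotations, fatty_acid_e_scores
    ):
        value = group_mean_score(
            "K10781", "cog", fatty_acid_annotations, fatty_acid_e_scores
        )
        assert value == pytest.approx(0.04)

    def test_eight_partner_pathway_group_mean(
        self, fatty_acid_annotations, fatty_acid_e_scores
    ):
        value = group_mean_score(
            "K10781", "kegg_pathway", fatty_acid_annotations, fatty_acid_e_scores
        )
        assert value == pytest.approx(0.57)

    def test_unknown_ko_is_lookup_error(self, lysine_annotations):
        with pytest.raises(KeyError):
            group_mean_score("K00404", "kegg_pathway", lysine_annotations, {})

    @settings(deadline=None, max_examples=40)
    @given(st.data())
    def test_mean_lies_within_group_range(self, data):
        n = data.draw(st.integers(2, 8), label="n")
        table = {
            f"K{i:05d}": KOAnnotation(
                ko_id=f"K{i:05d}", kegg_pathway_annotation="shared group//"
            )
            for i in range(1, n + 1)
        }
        scores = {
            ko: data.draw(st.floats(0, 0.9), label=ko) for ko in list(table)[1:]
        }
        value = group_mean_score("K00001", "kegg_pathway", table, scores)
        assert min(scores.values()) - 1e-12 <= value <= max(scores.values()) + 1e-12

    def test_constant_group_returns_the_constant(self):
        table = {
            f"K{i:05d}": KOAnnotation(
                ko_id=f"K{i:05d}", kegg_pathway_annotation="shared group//"
            )
            for i in range(1, 6)
        }
        scores = {ko: 0.42 for ko in table}
        for ko in table:
            assert group_mean_score(ko, "kegg_pathway", table, scores) == pytest.approx(0.42)


class TestPScore:
    def test_raw_mean_of_components(self):
        assert p_score(0.59, 0.0) == pytest.approx(0.295)

    def test_both_absent_is_absent(self):
        assert p_score(None, None) is None

    @given(st.floats(0, 1))
    def test_equal_components_are_idempotent(self, x):
        assert p_score(x, x) == pytest.approx(x)

    @given(
        st.floats(0, 1),
        st.floats(0, 1),
    )
    def test_mean_between_components(self, a, b):
        value = p_score(a, b)
        assert min(a, b) - 1e-12 <= value <= max(a, b) + 1e-12


class TestScoreAll:
    @pytest.fixture
    def small_fixture(self):
        annotations = {}
        # three tallied KOs share one pathway string; two reaction-linked KOs;
        # five annotated bystanders, one with no annotation at all
        for i in range(1, 4):
            annotations[f"K0000{i}"] = KOAnnotation(
                ko_id=f"K0000{i}",
                kegg_pathway_annotation="core pathway//",
                reaction_ids=frozenset({f"R0000{i}"}),
            )
        annotations["K00004"] = KOAnnotation(
            ko_id="K00004",
            kegg_pathway_annotation="side pathway//",
            reaction_ids=frozenset({"R00001"}),
        )
        annotations["K00005"] = KOAnnotation(
            ko_id="K00005",
            kegg_pathway_annotation="side pathway//",
            reaction_ids=frozenset({"R00002", "R00003"}),
        )
        for i in range(6, 10):
            annotations[f"K0000{i}"] = KOAnnotation(
                ko_id=f"K0000{i}", cog_annotation="bystander cog//"
            )
        annotations["K00010"] = KOAnnotation(ko_id="K00010")
        tallies = {
            "K00001": EssentialityCounts("K00001", 3, 0, 0, 3),
            "K00002": EssentialityCounts("K00002", 1, 1, 1, 3),
            "K00003": EssentialityCounts("K00003", 0, 0, 3, 3),
        }
        return annotations, tallies

    def test_direct_linked_and_absent_sources(self, small_fixture):
        annotations, tallies = small_fixture
        records = score_all(annotations, tallies)
        assert records["K00001"].e_score_source == "direct"
        assert records["K00004"].e_score_source == "reaction_linked"
        assert records["K00004"].e_score == pytest.approx(records["K00001"].e_score)
        assert records["K00005"].e_score == pytest.approx(
            (records["K00002"].e_score + records["K00003"].e_score) / 2
        )
        assert records["K00006"].e_score is None

    def test_p_score_absent_only_without_any_annotation(self, small_fixture):
        annotations, tallies = small_fixture
        records = score_all(annotations, tallies)
        assert records["K00010"].p_score is None
        assert all(
            records[k].p_score is not None for k in annotations if k != "K00010"
        )

    def test_no_tallies_leaves_every_e_score_absent(self, small_fixture):
        annotations, _ = small_fixture
        records = score_all(annotations, {})
        assert all(r.e_score is None for r in records.values())
        assert all(
            r.p_score in (None, 0.0) for r in records.values()
        )

    def test_constant_group_propagates_the_constant(self):
        annotations = {
            f"K{i:05d}": KOAnnotation(
                ko_id=f"K{i:05d}", kegg_pathway_annotation="only group//"
            )
            for i in range(1, 5)
        }
        tallies = {
            f"K{i:05d}": EssentialityCounts(f"K{i:05d}", 2, 0, 0, 2) for i in range(1, 5)
        }
        records = score_all(annotations, tallies)
        constant = (2 / 3) ** 2
        for r in records.values():
            assert r.p_score_kegg == pytest.approx(constant)

    def test_minmax_mode_rescales_components_to_unit_interval(self, small_fixture):
        annotations, tallies = small_fixture
        records = score_all(annotations, tallies, mode="minmax_standardized")
        kegg = [r.p_score_kegg for r in records.values() if r.p_score_kegg is not None]
        assert min(kegg) == 0.0 and max(kegg) == 1.0

    def test_unknown_mode_rejected(self, small_fixture):
        annotations, tallies = small_fixture
        with pytest.raises(ConfigError):
            score_all(annotations, tallies, mode="zscore")

    def test_write_load_round_trip(self, small_fixture, tmp_path):
        annotations, tallies = small_fixture
        records = score_all(annotations, tallies)
        path = tmp_path / "scores.tsv"
        write_scores(records, path)
        loaded = load_scores(path)
        assert set(loaded) == set(records)
        for ko, rec in records.items():
            got = loaded[ko]
            for name in ("e_score", "p_score_kegg", "p_score_cog", "p_score"):
                a, b = getattr(rec, name), getattr(got, name)
                assert (a is None) == (b is None)
                if a is not None:
                    assert b == pytest.approx(a)

    def test_summary_reports_both_scores(self, small_fixture):
        annotations, tallies = small_fixture
        summary = summarize_scores(score_all(annotations, tallies))
        assert summary.loc["e_score", "n"] == 5
        assert 0 <= summary.loc["e_score", "max"] <= 1


def test_thresholds_must_be_in_unit_interval():
    assert Thresholds().tau_e == 0.6 and Thresholds().tau_p == 0.03
    with pytest.raises(ConfigError):
        Thresholds(tau_e=1.5)
    with pytest.raises(ConfigError):
        Thresholds(tau_p=0.0)


def test_e_score_domain_error_for_zero_strains():
    with pytest.raises(Exception):
        EssentialityCounts("K00001", 0, 0, 0, 0)
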