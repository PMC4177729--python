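"""Category matching, the mean-weight score, bands, ISS, ultrahigh, trajectories."""

import itertools
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from ragmm import (
    Aberration,
    Band,
    CategoryMatch,
    IssInput,
    Sample,
    ScoreDomainError,
    Stage,
    TrajectoryError,
    classify_risk,
    combined_report,
    compute_rag_score,
    iss_stage,
    match_lesions,
    score_extremes,
    score_sample,
    trajectory,
)


def fish(descriptor, kind="translocation"):
    return Aberration(kind=kind, descriptor=descriptor, method="FISH")


def mutation(gene, consequence="nonsynonymous"):
    return Aberration(kind="mutation", gene=gene, method="sequencing", consequence=consequence)


def trisomy(chrom):
    return Aberration(kind="trisomy", descriptor=str(chrom), method="karyotype")


def match_names(kb, aberrations):
    return [m.category.name for m in match_lesions(kb, aberrations).matches]


class TestMatchLesions:
    def test_fish_translocation_matches_named_category(self, kb):
        assert match_names(kb, [fish("t(4;14)")]) == ["t(4;14)"]

    def test_mutation_in_dual_listed_gene_matches_functional_category_only(self, kb):
        # MMSET is listed under both t(4;14) and Epigenetic; sequence evidence
        # resolves to the functional category.
        assert match_names(kb, [mutation("MMSET")]) == ["Epigenetic"]

    def test_trisomies_collapse_to_single_hyperdiploidy_match(self, kb):
        mr = match_lesions(kb, [trisomy(3), trisomy(9), trisomy(15)])
        (m,) = mr.matches
        assert m.category.name == "Hyperdiploidy"
        assert len(m.supporting) == 3

    def test_mutation_matches_by_candidate_gene(self, kb):
        assert match_names(kb, [mutation("BRAF")]) == ["Proliferation"]

    def test_unmatched_aberrations_are_returned_not_dropped(self, kb):
        mr = match_lesions(kb, [mutation("ZZZ3"), trisomy(2), fish("t(4;14)")])
        assert [m.category.name for m in mr.matches] == ["t(4;14)"]
        assert len(mr.unmatched) == 2

    def test_non_hyperdiploid_trisomy_does_not_match(self, kb):
        mr = match_lesions(kb, [trisomy(8)])
        assert mr.matches == ()

    def test_secondary_t8_14_matches_translocation_category(self, kb):
        assert match_names(kb, [fish("t(8;14)")]) == ["Secondary t(8;14)"]

    def test_del13_both_notations_match(self, kb):
        assert match_names(kb, [fish("del(13)", kind="deletion")]) == ["Del(13/13q)"]
        assert match_names(kb, [fish("del(13q)", kind="deletion")]) == ["Del(13/13q)"]

    def test_cytogenetic_evidence_does_not_match_functional_categories(self, kb):
        # FGFR3-bearing t(4;14) must not also count as an FGFR3 mutation hit
        assert match_names(kb, [fish("t(4;14)")]) == ["t(4;14)"]

    def test_synonymous_mutation_never_matches(self, kb):
        mr = match_lesions(kb, [mutation("KRAS", consequence="synonymous")])
        assert mr.matches == ()
        assert len(mr.unmatched) == 1


class TestComputeScore:
    def _matches(self, kb, names):
        return tuple(
            CategoryMatch(category=kb.get(n), supporting=(fish("t(4;14)"),)) for n in names
        )

    @pytest.mark.parametrize(
        "names,expected",
        [
            (["Del(17p)", "+1q"], 3.0),  # all red
            (["Hyperdiploidy"], 1.0),  # green
            (["Del(17p)", "t(4;14)", "Hyperdiploidy"], 2.0),  # mean(3,2,1)
        ],
    )
    def test_hand_computed_means(self, kb, names, expected):
        assert compute_rag_score(self._matches(kb, names)) == expected

    def test_empty_matches_give_absent_score(self):
        assert compute_rag_score(()) is None

    def test_matches_brute_force_oracle_on_all_subsets_up_to_three(self, kb):
        # independent oracle: explicit sum/count over the subset's weights
        for size in (1, 2, 3):
            for combo in itertools.combinations(kb.categories, size):
                matches = tuple(
                    CategoryMatch(category=c, supporting=(fish("t(4;14)"),)) for c in combo
                )
                oracle = sum(c.weight for c in combo) / size
                assert compute_rag_score(matches) == pytest.approx(oracle)

    @settings(derandomize=True, max_examples=200)
    @given(st.permutations(list(range(22))), st.integers(1, 22))
    def test_score_is_permutation_invariant(self, kb, order, size):
        cats = [kb.categories[i] for i in order[:size]]
        matches = tuple(
            CategoryMatch(category=c, supporting=(fish("t(4;14)"),)) for c in cats
        )
        baseline = tuple(sorted(matches, key=lambda m: m.category.name))
        assert compute_rag_score(matches) == compute_rag_score(baseline)

    def test_extra_supporting_evidence_never_moves_the_score(self, kb):
        one = match_lesions(kb, [trisomy(3)])
        many = match_lesions(kb, [trisomy(3), trisomy(9), trisomy(15), trisomy(21)])
        assert compute_rag_score(one.matches) == compute_rag_score(many.matches) == 1.0

    def test_green_match_dilutes_an_all_red_set(self, kb):
        # the model's acknowledged behaviour: a low-risk lesion pulls the
        # mean down even alongside high-risk lesions
        reds = self._matches(kb, ["Del(17p)", "+1q"])
        diluted = reds + self._matches(kb, ["Hyperdiploidy"])
        assert compute_rag_score(diluted) < compute_rag_score(reds)

    def test_bounded_by_matched_group_weights(self, kb):
        for size in (1, 2, 3):
            for combo in itertools.combinations(kb.categories, size):
                matches = tuple(
                    CategoryMatch(category=c, supporting=(fish("t(4;14)"),)) for c in combo
                )
                weights = [c.weight for c in combo]
                score = compute_rag_score(matches)
                assert min(weights) <= score <= max(weights)

    def test_global_extremes_are_exactly_1_and_3(self, kb):
        lo, hi, n = score_extremes(kb)
        assert (lo, hi) == (1.0, 3.0)
        assert n == 2**22 - 1


class TestClassifyRisk:
    @pytest.mark.parametrize(
        "score,band",
        [
            (1.0, Band.LOW),
            (1.2, Band.LOW),
            (1.5, Band.LOW_INTERMEDIATE),  # lower-inclusive boundary
            (1.999, Band.LOW_INTERMEDIATE),
            (2.0, Band.HIGH_INTERMEDIATE),
            (2.5, Band.HIGH),
            (3.0, Band.HIGH),
        ],
    )
    def test_band_boundaries(self, score, band):
        assert classify_risk(score) is band

    @pytest.mark.parametrize("score", [0.5, 0.999, 3.001, float("nan"), float("inf")])
    def test_out_of_range_scores_rejected(self, score):
        with pytest.raises(ScoreDomainError):
            classify_risk(score)

    def test_exact_rational_scores_classify_exactly(self):
        assert classify_risk(Fraction(3, 2)) is Band.LOW_INTERMEDIATE
        assert classify_risk(Fraction(5, 2)) is Band.HIGH

    def test_grid_sweep_yields_exactly_four_bands(self):
        bands = {classify_risk(Fraction(i, 1000)) for i in range(1000, 3001)}
        assert bands == {Band.LOW, Band.LOW_INTERMEDIATE, Band.HIGH_INTERMEDIATE, Band.HIGH}


class TestIssStage:
    @pytest.mark.parametrize(
        "beta2m,albumin,stage",
        [
            (3.0, 3.6, Stage.I),
            (6.0, 4.0, Stage.III),
            (3.0, 3.0, Stage.II),  # footnote: low β2m but low albumin
            (4.0, 4.5, Stage.II),  # footnote: 3.5 ≤ β2m < 5.5 regardless of albumin
            (3.5, 5.0, Stage.II),  # boundary: β2m no longer < 3.5
            (5.5, 5.0, Stage.III),  # boundary: β2m ≥ 5.5
        ],
    )
    def test_staging_truth_table(self, beta2m, albumin, stage):
        assert iss_stage(IssInput(beta2m=beta2m, albumin=albumin)).stage is stage

    def test_negative_or_non_finite_inputs_rejected(self):
        with pytest.raises(ValueError):
            IssInput(beta2m=-1.0, albumin=4.0)
        with pytest.raises(ValueError):
            IssInput(beta2m=float("nan"), albumin=4.0)

    def test_every_grid_point_maps_to_exactly_one_stage(self):
        # dense grid over plausible clinical ranges; totality of the staging map
        for b in range(0, 101):
            for a in range(0, 61):
                stage = iss_stage(IssInput(beta2m=b / 10, albumin=a / 10)).stage
                assert stage in (Stage.I, Stage.II, Stage.III)


class TestCombinedReport:
    def _rag(self, kb, aberrations):
        result, _ = score_sample(kb, Sample(sample_id="S", aberrations=tuple(aberrations)))
        return result

    def test_iss_ii_with_two_adverse_lesions_is_ultrahigh(self, kb):
        rag = self._rag(kb, [fish("+1q", kind="gain"), fish("del(17p)", kind="deletion")])
        rep = combined_report(rag, iss_stage(IssInput(beta2m=4.0, albumin=4.0)))
        assert rep.adverse_count == 2
        assert rep.ultrahigh is True

    def test_single_adverse_lesion_is_not_ultrahigh(self, kb):
        rag = self._rag(kb, [fish("del(17p)", kind="deletion")])
        rep = combined_report(rag, iss_stage(IssInput(beta2m=6.0, albumin=4.0)))
        assert rep.iss.stage is Stage.III
        assert rep.adverse_count == 1
        assert rep.ultrahigh is False

    def test_iss_stage_i_gates_out_ultrahigh(self, kb):
        rag = self._rag(
            kb,
            [
                fish("+1q", kind="gain"),
                fish("del(17p)", kind="deletion"),
                fish("t(14;16)"),
            ],
        )
        rep = combined_report(rag, iss_stage(IssInput(beta2m=3.0, albumin=4.0)))
        assert rep.adverse_count == 3
        assert rep.ultrahigh is False

    def test_missing_iss_means_no_ultrahigh_flag(self, kb):
        rag = self._rag(kb, [fish("+1q", kind="gain"), fish("del(17p)", kind="deletion")])
        rep = combined_report(rag, None)
        assert rep.ultrahigh is False


class TestTrajectory:
    def _sample(self, t, aberrations):
        return Sample(sample_id="P", collection_time=t, aberrations=tuple(aberrations))

    def test_two_timepoint_deltas_and_new_categories(self, kb):
        pts = trajectory(
            [
                self._sample(0, [trisomy(3), trisomy(9)]),
                self._sample(1, [trisomy(3), fish("del(17p)", kind="deletion")]),
            ],
            kb,
        )
        assert [p.result.score for p in pts] == [1.0, 2.0]
        assert pts[0].delta is None
        assert pts[1].delta == 1.0
        assert pts[1].new_categories == frozenset({"Del(17p)"})
        assert pts[1].lost_categories == frozenset()

    def test_single_timepoint(self, kb):
        pts = trajectory([self._sample(0, [trisomy(3)])], kb)
        assert len(pts) == 1 and pts[0].delta is None

    def test_identical_samples_give_zero_delta(self, kb):
        pts = trajectory(
            [self._sample(0, [fish("t(4;14)")]), self._sample(1, [fish("t(4;14)")])], kb
        )
        assert pts[1].delta == 0.0
        assert pts[1].new_categories == pts[1].lost_categories == frozenset()

    def test_unordered_input_sorted_ascending(self, kb):
        pts = trajectory(
            [self._sample(5, [fish("t(4;14)")]), self._sample(1, [trisomy(3)])], kb
        )
        assert [p.timepoint for p in pts] == [1, 5]

    def test_duplicate_timepoints_rejected(self, kb):
        with pytest.raises(TrajectoryError, match="duplicate"):
            trajectory([self._sample(0, []), self._sample(0, [])], kb)
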