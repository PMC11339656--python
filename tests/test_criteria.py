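"""Criterion transformations: burden arithmetic, continuous curves, categorical maps."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from agreemip.criteria import (
    ELUTION_TECHNIQUE_SCORES,
    ELUTION_ZERO_POINTS,
    INHIBITOR_REMOVAL_SCORES,
    INITIATION_SCORES,
    PARTICLE_SIZE_SCORES,
    Burden,
    ElutionTechnique,
    InhibitorRemoval,
    Initiation,
    ParticleSize,
    Role,
    SubstanceUse,
    burden,
    round_score,
    score_c2_c3_c4,
    score_c5_c6_c7,
    score_elution_solvent,
    score_elution_technique,
    score_inhibitor_removal,
    score_initiation,
    score_particle_size,
    score_reusability,
)
from agreemip.hazards import UnknownHazardError

burdens = st.floats(min_value=0, max_value=5000, allow_nan=False)


class TestRounding:
    def test_half_rounds_away_from_zero(self):
        assert round_score(0.025) == 0.03
        assert round_score(0.005) == 0.01
        assert round_score(0.664) == 0.66

    def test_negative_mass_rejected_at_construction(self):
        with pytest.raises(ValueError, match="nonnegative"):
            SubstanceUse(name="x", mass_grams=-1.0)


class TestBurden:
    def test_empty_stage_has_zero_burden(self, tiny_table):
        assert burden([], tiny_table).x == 0.0

    def test_single_substance_is_mass_times_points(self, tiny_table):
        s = SubstanceUse("monomer", 2.5, frozenset({"H225", "H301"}), Role.functional_monomer)
        assert burden([s], tiny_table).x == pytest.approx(2.5 * 14)

    def test_mixture_equals_sum_of_single_substance_burdens(self, tiny_table):
        # per-component oracle: mixtures aggregate additively
        a = SubstanceUse("a", 1.2, frozenset({"H225"}), Role.porogen)
        b = SubstanceUse("b", 3.4, frozenset({"H301", "H400"}), Role.porogen)
        combined = burden([a, b], tiny_table).x
        assert combined == pytest.approx(burden([a], tiny_table).x + burden([b], tiny_table).x)

    def test_mixed_roles_rejected(self, tiny_table):
        a = SubstanceUse("a", 1, frozenset(), Role.porogen)
        b = SubstanceUse("b", 1, frozenset(), Role.template)
        with pytest.raises(ValueError, match="share a role"):
            burden([a, b], tiny_table)

    def test_negative_burden_rejected(self):
        with pytest.raises(ValueError):
            Burden(-0.1)


class TestContinuousCurves:
    @pytest.mark.parametrize("fn, cid", [(score_c2_c3_c4, 2), (score_c5_c6_c7, 5)])
    def test_zero_burden_scores_one(self, fn, cid):
        assert fn(Burden(0.0), cid).score == 1.0

    @pytest.mark.parametrize("fn, cid", [(score_c2_c3_c4, 3), (score_c5_c6_c7, 6)])
    def test_very_large_burden_rounds_to_zero(self, fn, cid):
        assert fn(Burden(1e5), cid).score == 0.0

    @given(x1=burdens, x2=burdens)
    def test_monotone_nonincreasing(self, x1, x2):
        lo, hi = sorted((x1, x2))
        for fn, cid in ((score_c2_c3_c4, 2), (score_c5_c6_c7, 5)):
            assert fn(Burden(lo), cid).score >= fn(Burden(hi), cid).score

    @given(x=burdens)
    def test_scores_in_range_and_two_decimal(self, x):
        for fn, cid in ((score_c2_c3_c4, 4), (score_c5_c6_c7, 7)):
            s = fn(Burden(x), cid).score
            assert 0.0 <= s <= 1.0
            assert s == round_score(s)

    def test_fast_and_slow_curves_differ_at_interior_point(self):
        # both reagent-class curves cover x = 60 g-pt but discriminate differently
        assert score_c2_c3_c4(Burden(60.0), 2).score != score_c5_c6_c7(Burden(60.0), 5).score

    def test_wrong_criterion_id_rejected(self):
        with pytest.raises(ValueError):
            score_c2_c3_c4(Burden(0), 5)
        with pytest.raises(ValueError):
            score_c5_c6_c7(Burden(0), 2)

    def test_hazard_free_massless_input_is_greenest(self, tiny_table):
        massless = SubstanceUse("trace", 0.0, frozenset({"H301"}), Role.cross_linker)
        hazard_free = SubstanceUse("benign", 10.0, frozenset(), Role.cross_linker)
        x = burden([massless, hazard_free], tiny_table)
        assert score_c2_c3_c4(x, 4).score == 1.0


class TestCategoricalMaps:
    """Each categorical map is total over its enum and hits its printed scores."""

    @pytest.mark.parametrize(
        "scorer, enum_cls, expected",
        [
            (score_inhibitor_removal, InhibitorRemoval, INHIBITOR_REMOVAL_SCORES),
            (score_initiation, Initiation, INITIATION_SCORES),
            (score_particle_size, ParticleSize, PARTICLE_SIZE_SCORES),
            (score_elution_technique, ElutionTechnique, ELUTION_TECHNIQUE_SCORES),
        ],
        ids=["inhibitor", "initiation", "particle-size", "elution-technique"],
    )
    def test_total_and_surjective_onto_printed_scores(self, scorer, enum_cls, expected):
        produced = {scorer(member).score for member in enum_cls}
        assert produced == set(expected.values())
        for member in enum_cls:
            assert scorer(member.value).score == expected[member]

    @pytest.mark.parametrize(
        "scorer",
        [score_inhibitor_removal, score_initiation, score_particle_size, score_elution_technique],
    )
    def test_unknown_category_rejected(self, scorer):
        with pytest.raises(ValueError, match="unknown category"):
            scorer("teleportation")

    @pytest.mark.parametrize(
        "choice, expected",
        [
            (InhibitorRemoval.not_needed_or_no_waste, 1.0),
            (InhibitorRemoval.solid_waste, 0.5),
            (InhibitorRemoval.liquid_waste, 0.2),
            (InhibitorRemoval.solid_and_liquid_waste, 0.0),
        ],
    )
    def test_inhibitor_waste_ordering(self, choice, expected):
        assert score_inhibitor_removal(choice).score == expected


class TestElutionSolvent:
    def test_forty_points_scores_exactly_zero(self, default_table):
        codes = {"H300", "H310", "H330", "H340"}  # 10 points each
        from agreemip.hazards import penalty_sum

        assert penalty_sum(codes, default_table) == ELUTION_ZERO_POINTS
        assert score_elution_solvent(codes, default_table).score == 0.0

    def test_hazard_free_solvent_scores_one(self, default_table):
        assert score_elution_solvent(set(), default_table).score == 1.0

    def test_monotone_nonincreasing_in_points(self, default_table):
        nested = [set(), {"H225"}, {"H225", "H301"}, {"H225", "H301", "H330"}]
        scores = [score_elution_solvent(c, default_table).score for c in nested]
        assert scores == sorted(scores, reverse=True)

    def test_strict_unknown_code_propagates(self, tiny_table):
        with pytest.raises(UnknownHazardError):
            score_elution_solvent({"H999"}, tiny_table)


class TestReusability:
    @pytest.mark.parametrize(
        "cycles, expected",
        [(1, 0.0), (2, 0.5), (5, 0.5), (9, 0.5), (10, 1.0), (50, 1.0)],
    )
    def test_cycle_bands(self, cycles, expected):
        assert score_reusability(cycles).score == expected

    @pytest.mark.parametrize("bad", [0, -3, 2.5, "many", True])
    def test_invalid_cycle_counts_rejected(self, bad):
        with pytest.raises(ValueError):
            score_reusability(bad)
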