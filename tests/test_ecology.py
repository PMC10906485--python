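"""Unit conversion, record selection and the five ecological classifiers."""

import math

import numpy as np
import pytest

from birdacuity.ecology import (
    ClassificationError,
    SpeciesRecord,
    aggregate_diet,
    classify_diet,
    classify_foraging,
    classify_habitat,
    classify_light,
    classify_prey_mobility,
    select_record,
    to_cpd,
)


class TestToCpd:
    @pytest.mark.parametrize(
        "value,unit,expected",
        [
            (1.0, "mar_arcmin", 30.0),
            (0.5, "mar_arcmin", 60.0),
            (10.0, "cpd", 10.0),
            (0.5, "mar_deg", 1.0),
            (180.0 / math.pi, "cycles_per_radian", 1.0),
        ],
    )
    def test_conversions(self, value, unit, expected):
        assert to_cpd(value, unit) == pytest.approx(expected)

    def test_mar_roundtrip_bijection(self):
        for cpd in (0.5, 4.6, 15.8, 143.0):
            mar = 30.0 / cpd  # arcmin per half-cycle
            assert to_cpd(mar, "mar_arcmin") == pytest.approx(cpd, abs=1e-12)

    def test_unknown_unit_and_nonpositive(self):
        with pytest.raises(ValueError, match="unknown"):
            to_cpd(1.0, "snellen")
        with pytest.raises(ValueError):
            to_cpd(0.0, "cpd")


def _rec(species="sp", acuity=10.0, method="RGC", year=2000):
    return SpeciesRecord(
        species=species, acuity_cpd=acuity, method=method, source_year=year
    )


class TestSelectRecord:
    def test_rgc_preferred_over_behavioral(self):
        chosen = select_record([_rec(method="behavioral", year=2001), _rec(method="RGC", year=1990)])
        assert chosen.method == "RGC"
        assert chosen.source_year == 1990

    def test_most_recent_within_method(self):
        chosen = select_record([_rec(year=1990), _rec(year=2010)])
        assert chosen.source_year == 2010

    def test_year_tie_broken_by_highest_acuity(self):
        chosen = select_record([_rec(acuity=8.0, year=2010), _rec(acuity=12.0, year=2010)])
        assert chosen.acuity_cpd == 12.0

    def test_single_and_empty(self):
        r = _rec()
        assert select_record([r]) is r
        with pytest.raises(ValueError):
            select_record([])

    def test_mixed_species_raise(self):
        with pytest.raises(ValueError, match="species"):
            select_record([_rec(species="a"), _rec(species="b")])


class TestHabitat:
    def test_complex_over_70(self):
        assert classify_habitat({"understory": 50, "mid_high": 30, "ground": 20}) == "complex"

    def test_generalist_when_no_sum_exceeds(self):
        assert classify_habitat({"ground": 60, "understory": 40}) == "generalist"

    def test_exact_70_is_generalist(self):
        assert classify_habitat({"ground": 70, "aerial": 30}) == "generalist"

    def test_open_and_horizon(self):
        assert classify_habitat({"aerial": 50, "open_water": 25, "ground": 25}) == "open"
        assert (
            classify_habitat({"ground": 30, "water_surface": 30, "canopy": 20, "aerial": 20})
            == "horizon"
        )

    def test_sum_over_100_raises(self):
        with pytest.raises(ValueError, match="100"):
            classify_habitat({"ground": 80, "aerial": 30})

    def test_permutation_invariance_and_uniqueness(self, rng):
        # at most one class sum can exceed 70 when the total is <= 100
        strata = ["understory", "mid_high", "aerial", "open_water", "ground",
                  "water_surface", "canopy"]
        for _ in range(200):
            raw = rng.dirichlet(np.ones(7)) * 100.0
            pct = dict(zip(strata, raw))
            cls = classify_habitat(pct)
            items = list(pct.items())
            rng.shuffle(items)
            assert classify_habitat(dict(items)) == cls
            exceed = [
                c for c, ss in (("complex", ("understory", "mid_high")),
                                ("open", ("aerial", "open_water")),
                                ("horizon", ("ground", "water_surface", "canopy")))
                if sum(pct[s] for s in ss) > 70
            ]
            assert len(exceed) <= 1
            assert cls == (exceed[0] if exceed else "generalist")


class TestLight:
    def test_nocturnal_overrides_keywords(self):
        assert classify_light(["grassland"], nocturnal=True) == "low"

    def test_listed_habitats(self):
        assert classify_light(["desert"], False) == "high"
        assert classify_light(["forest edge", "secondary forest"], False) == "medium"
        assert classify_light(["mangrove"], False) == "low"

    def test_majority_vote_and_tie(self):
        assert classify_light(["desert", "grassland", "mangrove"], False) == "high"
        assert classify_light(["desert", "mangrove"], False) == "medium"  # tie

    def test_unmatched_raises(self):
        with pytest.raises(ClassificationError):
            classify_light(["volcano rim"], False)


class TestDiet:
    def test_dominant_category(self):
        assert classify_diet({"plants": 60, "invertebrates": 30, "vertebrates_scavenged": 10}) == "plants"

    def test_omnivore_when_none_reach_50(self):
        assert classify_diet({"plants": 40, "invertebrates": 30, "vertebrates_scavenged": 30}) == "omnivore"

    def test_fifty_fifty_tie_is_omnivore(self):
        assert classify_diet({"plants": 50, "invertebrates": 50, "vertebrates_scavenged": 0}) == "omnivore"

    def test_exactly_50_wins_alone(self):
        assert classify_diet({"plants": 50, "invertebrates": 25, "vertebrates_scavenged": 25}) == "plants"

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            classify_diet({"plants": -1})

    def test_aggregation_from_raw_categories(self):
        agg = aggregate_diet({"fruit": 20, "seed": 20, "inv": 30, "vfish": 20, "scav": 10})
        assert agg == {"plants": 40.0, "invertebrates": 30.0, "vertebrates_scavenged": 30.0}
        with pytest.raises(ValueError, match="unknown"):
            aggregate_diet({"minerals": 10})


class TestPreyMobility:
    def test_pure_frugivore_immobile(self):
        assert classify_prey_mobility({"fruit": 100}) == "immobile"

    def test_pure_scavenger_immobile(self):
        assert classify_prey_mobility({"scav": 100}) == "immobile"

    def test_pure_insectivore_mobile(self):
        assert classify_prey_mobility({"inv": 100}) == "mobile"

    def test_live_vertebrates_mobile(self):
        assert classify_prey_mobility({"vfish": 60, "fruit": 40}) == "mobile"

    def test_exact_tie_raises(self):
        with pytest.raises(ClassificationError, match="tie"):
            classify_prey_mobility({"inv": 50, "scav": 50})

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            classify_prey_mobility({"inv": 0})


class TestForaging:
    @pytest.mark.parametrize("m", ["sallying", "aerial chase", "pursuit diving", "scavenging"])
    def test_distance_maneuvers_far(self, m):
        assert classify_foraging([m]) == "far"

    @pytest.mark.parametrize("m", ["gleaning", "pecking", "dabbling", "kicking/scratching", "probing"])
    def test_close_maneuvers_near(self, m):
        assert classify_foraging([m]) == "near"

    def test_primary_maneuver_decides(self):
        assert classify_foraging(["pecking", "sallying"]) == "near"
        assert classify_foraging(["sallying", "pecking"]) == "far"

    def test_unknown_token_raises(self):
        with pytest.raises(ClassificationError, match="hovering"):
            classify_foraging(["hovering"])

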