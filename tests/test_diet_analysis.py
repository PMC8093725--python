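import datetime as dt
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from sympatric import diet_analysis as diet
from sympatric import reference_diet as ref
from sympatric.diet_analysis import ScatRecord, Season


def scat(items, species="JUNGLE_CAT", date=dt.date(2015, 1, 10), **kw):
    return ScatRecord(scat_id="X1", species=species, date=date, items=items, **kw)


class TestSeasons:
    @pytest.mark.parametrize(
        "date,season",
        [
            (dt.date(2014, 1, 15), Season.COOL_DRY),
            (dt.date(2015, 11, 1), Season.COOL_DRY),
            (dt.date(2015, 4, 1), Season.HOT_DRY),
            (dt.date(2015, 7, 1), Season.RAINY),
            (dt.date(2015, 10, 31), Season.RAINY),
        ],
    )
    def test_month_ranges(self, date, season):
        assert diet.assign_season(date) is season


class TestTraceFilter:
    def test_removes_trace_items_and_renormalizes(self):
        s = scat({"murid_small": 0.97, "insect": 0.02, "reptile": 0.01})
        out = diet.apply_trace_filter(s)
        assert out.items == {"murid_small": 1.0}

    def test_leaves_non_trace_compositions_unchanged(self):
        s = scat({"murid_small": 0.5, "sciurid": 0.5})
        assert diet.apply_trace_filter(s).items == s.items

    def test_all_trace_scat_is_an_error(self):
        with pytest.raises(ValueError, match="trace"):
            diet.apply_trace_filter(scat({"insect": 0.02}))

    @given(
        st.lists(
            st.floats(min_value=0.001, max_value=1.0), min_size=2, max_size=6
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_output_always_sums_to_one_without_trace_items(self, raw):
        total = sum(raw)
        items = {f"c{i}": v / total for i, v in enumerate(raw)}
        try:
            out = diet.apply_trace_filter(scat(items))
        except ValueError:
            return  # everything trace
        assert sum(out.items.values()) == pytest.approx(1.0)
        assert all(v >= 0.03 / 2 for v in out.items.values())


class TestBiomassModel:
    def test_spot_value_small_murid_for_jungle_cat(self):
        # 5 * (0.033 - 0.025 * exp(-4.284 * 0.05/5))
        assert diet.biomass_per_scat(0.05, 5.0) == pytest.approx(
            0.04524, abs=5e-6
        )

    def test_limits_bound_the_output(self):
        w = 5.0
        tiny = diet.biomass_per_scat(1e-9, w)
        huge = diet.biomass_per_scat(1e6, w)
        assert tiny == pytest.approx(0.008 * w, rel=1e-6)
        assert huge == pytest.approx(0.033 * w, rel=1e-6)
        for prey in (0.01, 0.1, 1.0, 10.0):
            assert 0.008 * w < diet.biomass_per_scat(prey, w) < 0.033 * w

    def test_strictly_increasing_in_prey_mass(self):
        # up to prey/predator ratio ~5; beyond that the exponential term
        # saturates below double precision
        masses = np.logspace(-3, np.log10(12.0), 40)
        vals = [diet.biomass_per_scat(m, 2.5) for m in masses]
        assert np.all(np.diff(vals) > 0)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            diet.biomass_per_scat(0.0, 5.0)
        with pytest.raises(ValueError):
            diet.biomass_per_scat(0.1, -1.0)


class TestDietSummary:
    def test_single_scat_single_category_is_100_percent(self):
        s = diet.diet_summary([scat({"murid_small": 1.0})])
        assert s.bio_pct["murid_small"] == pytest.approx(100.0)
        assert s.vol_pct["murid_small"] == pytest.approx(100.0)
        assert s.occ_pct["murid_small"] == pytest.approx(100.0)

    def test_equal_mass_categories_split_biomass_evenly(self):
        scats = [
            ScatRecord("a", "JUNGLE_CAT", dt.date(2015, 1, 1),
                       {"reptile": 1.0}),
            ScatRecord("b", "JUNGLE_CAT", dt.date(2015, 1, 2),
                       {"crab": 1.0}),
        ]
        s = diet.diet_summary(scats)  # both categories weigh 0.100 kg
        assert s.bio_pct["reptile"] == pytest.approx(50.0)
        assert s.bio_pct["crab"] == pytest.approx(50.0)

    def test_insects_excluded_from_biomass_but_counted_elsewhere(self):
        scats = [
            ScatRecord("a", "LEOPARD_CAT", dt.date(2015, 1, 1),
                       {"murid_small": 0.9, "insect": 0.1}),
        ]
        s = diet.diet_summary(scats)
        assert "insect" not in s.bio_pct
        assert s.occ_pct["insect"] == pytest.approx(100.0)
        assert s.vol_pct["insect"] == pytest.approx(10.0)
        assert sum(s.bio_pct.values()) == pytest.approx(100.0, abs=0.5)

    def test_percentages_sum_to_100(self, small_dataset):
        for sp, scats in small_dataset.scats.items():
            s = diet.diet_summary(scats)
            assert sum(s.bio_pct.values()) == pytest.approx(100.0, abs=0.5)
            assert sum(s.vol_pct.values()) == pytest.approx(100.0, abs=0.5)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            diet.diet_summary([scat({"pangolin": 1.0})])

    def test_mixed_predators_rejected(self):
        scats = [
            ScatRecord("a", "JUNGLE_CAT", dt.date(2015, 1, 1),
                       {"bird": 1.0}),
            ScatRecord("b", "LEOPARD_CAT", dt.date(2015, 1, 1),
                       {"bird": 1.0}),
        ]
        with pytest.raises(ValueError, match="mix"):
            diet.diet_summary(scats)


class TestNicheIndices:
    def test_levins_uniform_equals_category_count(self):
        assert diet.levins_niche_breadth([0.25] * 4) == pytest.approx(4.0)

    def test_levins_specialist_equals_one(self):
        assert diet.levins_niche_breadth([1.0]) == pytest.approx(1.0)

    def test_levins_maximized_by_uniform(self, rng):
        k = 6
        uniform = diet.levins_niche_breadth([1 / k] * k)
        for _ in range(20):
            p = rng.dirichlet(np.ones(k))
            assert diet.levins_niche_breadth(p) <= uniform + 1e-9

    def test_levins_on_published_biomass_vectors(self):
        for key, expected in ref.PUBLISHED_NICHE_BREADTH.items():
            vec = list(ref.PROFILES[key]["bio"].values())
            assert diet.levins_niche_breadth(vec) == pytest.approx(
                expected, abs=0.03
            )

    def test_horns_identical_diets_overlap_completely(self):
        p = {"a": 0.6, "b": 0.4}
        assert diet.horns_overlap(p, p) == pytest.approx(1.0)

    def test_horns_disjoint_diets_do_not_overlap(self):
        assert diet.horns_overlap({"a": 1.0}, {"b": 1.0}) == pytest.approx(0.0)

    def test_horns_on_published_biomass_vectors(self):
        r0 = diet.horns_overlap(
            ref.JUNGLE_CAT_TOTAL["bio"], ref.LEOPARD_CAT_TOTAL["bio"]
        )
        assert r0 == pytest.approx(ref.PUBLISHED_HORNS_R0, abs=0.01)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_horns_symmetric_bounded_and_base_invariant(self, seed):
        r = np.random.default_rng(seed)
        k = int(r.integers(2, 8))
        p = r.dirichlet(np.ones(k))
        q = r.dirichlet(np.ones(k))
        r0 = diet.horns_overlap(p, q)
        assert 0.0 <= r0 <= 1.0
        assert r0 == pytest.approx(diet.horns_overlap(q, p), abs=1e-12)
        # base invariance: same formula with log2 via change of base
        pq = p + q
        def h(x):
            x = x[x > 0]
            return float(np.sum(x * np.log2(x)))
        alt = (h(pq) - h(p) - h(q)) / 2.0
        assert r0 == pytest.approx(min(1.0, max(0.0, alt)), abs=1e-9)


class TestCategoricalTests:
    def test_chisq_identical_diets(self):
        counts = {"a": 10, "b": 5, "c": 3}
        out = diet.compare_diets_chisq(counts, counts)
        assert out["chi2"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)
        assert out["df"] == 2

    def test_chisq_hand_computed_2x2(self):
        out = diet.compare_diets_chisq({"a": 10, "b": 0}, {"a": 0, "b": 10})
        assert out["chi2"] == pytest.approx(20.0)
        assert out["df"] == 1

    def test_chisq_drops_empty_categories_with_warning(self):
        with pytest.warns(UserWarning, match="all-zero"):
            out = diet.compare_diets_chisq(
                {"a": 5, "b": 5, "c": 0}, {"a": 5, "b": 5, "c": 0}
            )
        assert out["df"] == 1

    def test_fisher_hare_occurrence_matches_published(self):
        # 2 of 17 jungle-cat scats vs 0 of 130 leopard-cat scats
        assert diet.fisher_category_test(2, 15, 0, 130) == pytest.approx(
            0.0127, abs=5e-4
        )

    def test_fisher_reptile_occurrence_below_published_threshold(self):
        # 11 of 17 vs 24 of 130 -> p < .001
        assert diet.fisher_category_test(11, 6, 24, 106) < 0.001

    def test_fisher_balanced_table_is_uninformative(self):
        assert diet.fisher_category_test(1, 1, 1, 1) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table", [(2, 15, 0, 130), (11, 6, 24, 106), (3, 4, 5, 6), (0, 9, 8, 1)]
    )
    def test_fisher_agrees_with_hypergeometric_enumeration(self, table):
        a, b, c, d = table
        n, k1, k2 = a + b + c + d, a + b, a + c
        p_obs = hypergeom.pmf(a, n, k1, k2)
        total = 0.0
        for x in range(max(0, k1 + k2 - n), min(k1, k2) + 1):
            px = hypergeom.pmf(x, n, k1, k2)
            if px <= p_obs * (1 + 1e-9):
                total += px
        assert diet.fisher_category_test(a, b, c, d) == pytest.approx(
            min(1.0, total), rel=1e-6
        )


class TestPreyAccumulation:
    def test_identical_scats_give_flat_curve(self):
        scats = [
            ScatRecord(f"s{i}", "JUNGLE_CAT", dt.date(2015, 1, 1),
                       {"bird": 1.0})
            for i in range(5)
        ]
        out = diet.prey_accumulation(scats, n_perm=100, seed=0)
        np.testing.assert_allclose(out["mean"], 1.0)
        assert out["k_asymptote"] == 1

    def test_distinct_scats_accumulate_linearly(self):
        scats = [
            ScatRecord(f"s{i}", "JUNGLE_CAT", dt.date(2015, 1, 1),
                       {c: 1.0})
            for i, c in enumerate(["bird", "reptile", "crab", "hare"])
        ]
        out = diet.prey_accumulation(scats, n_perm=200, seed=0)
        np.testing.assert_allclose(out["mean"], [1, 2, 3, 4])

    def test_common_categories_reach_asymptote_quickly(self):
        # 3 categories, each in half the scats: expected richness saturates
        # after a handful of scats
        cats = ["bird", "reptile", "sciurid"]
        scats = [
            ScatRecord(f"s{i}", "JUNGLE_CAT", dt.date(2015, 1, 1),
                       {cats[i % 3]: 0.5, cats[(i + 1) % 3]: 0.5})
            for i in range(20)
        ]
        out = diet.prey_accumulation(scats, n_perm=500, seed=1)
        assert out["k_asymptote"] <= 5
        assert out["mean"][-1] == pytest.approx(out["richness"])

    def test_curve_is_monotone_with_valid_bands(self, small_dataset):
        scats = small_dataset.scats["LEOPARD_CAT"]
        out = diet.prey_accumulation(scats, n_perm=300, seed=1)
        assert np.all(np.diff(out["mean"]) >= 0)
        assert np.all(out["ci_low"] <= out["ci_high"])
        assert 1 <= out["k_asymptote"] <= len(scats)


class TestScatDiameters:
    def test_identical_groups_are_not_different(self):
        out = diet.scat_diameter_test([2.0, 2.1, 1.9], [2.0, 2.1, 1.9])
        assert out["t"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_separated_groups_reject_strongly(self, rng):
        a = 2.0 + rng.normal(0, 1e-3, 10)
        b = 1.0 + rng.normal(0, 1e-3, 10)
        assert diet.scat_diameter_test(a, b)["p"] < 1e-10

    def test_published_size_difference_detected_in_majority_of_replicates(
        self, rng
    ):
        hits = 0
        for _ in range(40):
            a = rng.normal(2.0, 0.2, 17)
            b = rng.normal(1.8, 0.2, 130)
            if diet.scat_diameter_test(a, b)["p"] < 0.05:
                hits += 1
        assert hits >= 25  # power well above one half

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            diet.scat_diameter_test([2.0], [1.8, 1.9])


class TestScatIO:
    def test_round_trip_through_csv(self, tmp_path, small_dataset):
        scats = small_dataset.scats["JUNGLE_CAT"]
        path = tmp_path / "scats.csv"
        diet.write_scats(scats, path)
        back = diet.read_scats(path, trace_threshold=None)
        assert len(back) == len(scats)
        orig = {s.scat_id: s for s in scats}
        for s in back:
            assert s.species == orig[s.scat_id].species
            for c, v in s.items.items():
                assert v == pytest.approx(orig[s.scat_id].items[c], abs=1e-6)

    def test_off_grid_volume_warns_but_reads(self, tmp_path):
        path = tmp_path / "scats.csv"
        path.write_text(
            "scat_id,species,date,diameter_cm,category,volume_pct\n"
            "S1,JUNGLE_CAT,2015-01-10,2.0,bird,97\n"
            "S1,JUNGLE_CAT,2015-01-10,2.0,insect,3\n"
        )
        with pytest.warns(UserWarning, match="5% grid"):
            scats = diet.read_scats(path)
        assert len(scats) == 1

    def test_catalogue_yaml_round_trip(self, tmp_path):
        path = tmp_path / "masses.yaml"
        path.write_text(
            "bird:\n  mass_kg: 0.35\ninsect:\n  mass_kg: null\n"
            "  in_biomass: false\n"
        )
        cat = diet.load_catalogue(path)
        assert cat["bird"].mass_kg == 0.35
        assert not cat["insect"].in_biomass
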