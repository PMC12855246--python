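"""Cohort accounting, compliance, Kaplan-Meier and the mortality table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import temcao
from temcao import (CohortLedger, ComplianceRule, build_attrition_ledger,
                    build_site_mortality_ledger, compliance_report, km_survival,
                    mortality_table, population_counts, product_limit)
from temcao.cohort import LEDGER_COLUMNS
from temcao.phantom import EventRates, generate_cohort

SITE_N = {"AG": 23, "DK": 30, "IW": 11, "MG": 28, "SD": 24, "YL": 19}
SITE_DEATHS = {  # cumulative deaths by day 3, 7, 30
    "AG": (4, 5, 16), "DK": (8, 8, 22), "IW": (2, 2, 7),
    "MG": (5, 5, 5), "SD": (14, 15, 16), "YL": (7, 8, 12),
}


class TestPopulationCounts:
    def test_attrition_chain_170_to_86(self):
        counts = population_counts(build_attrition_ledger())
        assert counts == {
            "enrolled": 170, "donors": 26, "ITT": 144,
            "procedural_dropouts": 9, "mITT": 135,
            "FT": 115, "lost_after_treatment": 29, "full_analysis": 86,
        }

    def test_empty_ledger_all_zeros(self):
        counts = population_counts(CohortLedger(pd.DataFrame(columns=LEDGER_COLUMNS)))
        assert all(v == 0 for v in counts.values())

    def test_no_deaths_collapses_chain(self):
        counts = population_counts(build_attrition_ledger(
            enrolled=50, donors=5, procedural_dropouts=0,
            partial_treatment_deaths=0, post_treatment_losses=0))
        assert counts["mITT"] == counts["FT"] == counts["full_analysis"] == 45

    def test_treatment_without_surgery_rejected(self):
        rows = [("s1", "A", "M", "study", "enrolled", 0, ""),
                ("s1", "A", "M", "study", "tnk_given", 0.1, "")]
        ledger = CohortLedger(pd.DataFrame(rows, columns=LEDGER_COLUMNS))
        with pytest.raises(ValueError, match="without surgery"):
            population_counts(ledger)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_attrition_monotone_on_random_ledgers(self, seed):
        rng = np.random.default_rng(seed)
        rates = EventRates(procedural_death=rng.random() * 0.3,
                           partial_treatment_death=rng.random() * 0.3,
                           death_by_day3=rng.random() * 0.4,
                           death_day3_to_7=rng.random() * 0.1,
                           death_day7_to_30=rng.random() * 0.1)
        ledger = generate_cohort({"A": 20, "B": 15}, rates, seed=seed,
                                 donors_per_site={"A": 3})
        c = population_counts(ledger)
        chain = [c["enrolled"], c["ITT"], c["mITT"], c["FT"], c["full_analysis"]]
        assert chain == sorted(chain, reverse=True)
        assert all(v >= 0 for v in c.values())


class TestCompliance:
    def _ledger_with(self, minutes=121.0, dose=1.5, length=5.0, donor_sex="M"):
        rows = [("s1", "A", "M", "study", "enrolled", 0, ""),
                ("s1", "A", "M", "study", "randomized", 0, ""),
                ("s1", "A", "M", "study", "surgery_start", 0, ""),
                ("s1", "A", "M", "study", "thrombus_injected", 0, ""),
                ("s1", "A", "M", "study", "tnk_given", 0.1, ""),
                ("s1", "A", "M", "study", "tnk_dose_mg_per_kg", 0.1, dose),
                ("s1", "A", "M", "study", "minutes_embolism_to_tnk", 0.1, minutes),
                ("s1", "A", "M", "study", "thrombus_length_cm", 0, length),
                ("s1", "A", "M", "study", "donor_sex", 0.1, donor_sex),
                ("s1", "A", "M", "study", "study_drug_given", 0.12, "")]
        return CohortLedger(pd.DataFrame(rows, columns=LEDGER_COLUMNS))

    def test_fully_compliant_subject_passes_all(self):
        flags, agg = compliance_report(self._ledger_with())
        assert flags.loc["s1"].tolist() == [True, True, True, True]
        assert all(v["percent"] == 100.0 for v in agg.values())

    def test_timing_window_arithmetic(self):
        # 136 min is the printed range maximum: inside the default window,
        # outside a +/-10 min window
        ledger = self._ledger_with(minutes=136.0)
        flags, _ = compliance_report(ledger)
        assert flags.loc["s1", "tnk_time"] == True  # noqa: E712
        tight = ComplianceRule(tnk_time_tolerance_min=10.0)
        flags, _ = compliance_report(ledger, tight)
        assert flags.loc["s1", "tnk_time"] == False  # noqa: E712

    def test_missing_attribute_is_unassessable_never_pass(self):
        ledger = self._ledger_with()
        frame = ledger.frame[ledger.frame["event"] != "donor_sex"]
        flags, agg = compliance_report(CohortLedger(frame))
        assert pd.isna(flags.loc["s1", "donor_sex"])
        assert agg["donor_sex"]["unassessable"] == 1
        assert agg["donor_sex"]["assessable"] == 0

    def test_synthetic_two_percent_violation_rate(self):
        # large synthetic cohort with 2% per-rule violations -> ~98%
        rates = EventRates(procedural_death=0, partial_treatment_death=0,
                           death_by_day3=0, death_day3_to_7=0, death_day7_to_30=0)
        ledger = generate_cohort({"A": 500, "B": 500}, rates, seed=17)
        _, agg = compliance_report(ledger)
        for rule in ("tnk_dose", "donor_sex"):
            assert agg[rule]["assessable"] == 1000
            assert agg[rule]["percent"] == pytest.approx(98.0, abs=1.5)


class TestKaplanMeier:
    def test_hand_product_limit_four_subjects(self):
        # deaths at days 1 and 2, two censored at 30:
        # S(1) = 3/4, S(2) = 3/4 * 2/3 = 1/2, flat to day 30
        s = product_limit([1, 2, 30, 30], [1, 1, 0, 0])
        assert s.at(1) == pytest.approx(0.75)
        assert s.at(2) == pytest.approx(0.50)
        assert s.at(30) == pytest.approx(0.50)
        assert s.survival_at[3.0] == pytest.approx(0.50)

    def test_no_deaths_survival_one(self):
        s = product_limit([30, 30, 30], [0, 0, 0])
        assert s.times.size == 0
        assert s.at(30) == 1.0

    def test_all_die_day_one(self):
        s = product_limit([1, 1, 1], [1, 1, 1])
        assert s.at(1) == 0.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            product_limit([-1, 2], [1, 0])

    def test_equals_empirical_survivor_without_early_censoring(self):
        # oracle: with censoring only after the last death, KM equals the
        # empirical survivor function
        rng = np.random.default_rng(8)
        deaths = rng.integers(1, 10, 20)
        durations = np.concatenate([deaths, np.full(10, 30.0)])
        events = np.concatenate([np.ones(20, int), np.zeros(10, int)])
        s = product_limit(durations, events)
        for t in range(1, 11):
            assert s.at(t) == pytest.approx(np.mean(durations > t))

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(9)
        durations = rng.integers(1, 31, 50)
        events = rng.integers(0, 2, 50)
        ours = product_limit(durations, events)
        kmf = lifelines.KaplanMeierFitter().fit(durations, events)
        for t in (3, 7, 15, 30):
            assert ours.at(t) == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]))

    def test_ledger_grouping(self):
        ledger = build_attrition_ledger()
        by_site = km_survival(ledger, group_by="site")
        assert set(by_site) == {"AG", "DK", "IW", "MG", "SD", "YL"}
        overall = km_survival(ledger)["all"]
        assert overall.n == 135  # the operated population


class TestMortalityTable:
    def test_printed_site_percentages(self):
        table = mortality_table(build_site_mortality_ledger(SITE_N, SITE_DEATHS))
        assert table.loc["SD", "pct_day3"] == 58.33
        assert table.loc["AG", "pct_day3"] == 17.39
        assert table.loc["DK", "pct_day3"] == 26.67
        assert table.loc["IW", "pct_day3"] == 18.18
        assert table.loc["MG", "pct_day3"] == 17.86
        assert table.loc["YL", "pct_day3"] == 36.84
        assert table.loc["SD", "pct_day7"] == 62.50
        assert table.loc["AG", "pct_day30"] == 69.57
        assert list(table.loc[list(SITE_N), "effective_n"]) == \
            [SITE_N[s] for s in SITE_N]

    def test_zero_death_site(self):
        table = mortality_table(build_site_mortality_ledger(
            {"A": 10}, {"A": (0, 0, 0)}))
        assert table.loc["A", "pct_day3"] == 0.0
        assert table.loc["A", "deaths_day30"] == 0

    def test_totals_conserve_cohort_deaths(self):
        table = mortality_table(build_site_mortality_ledger(SITE_N, SITE_DEATHS))
        sites = list(SITE_N)
        for h in (3, 7, 30):
            assert table.loc["total", f"deaths_day{h}"] == \
                table.loc[sites, f"deaths_day{h}"].sum()

    def test_percentages_recompute_from_counts(self):
        table = mortality_table(build_site_mortality_ledger(SITE_N, SITE_DEATHS))
        for site in SITE_N:
            for h in (3, 7, 30):
                expect = round(100.0 * table.loc[site, f"deaths_day{h}"]
                               / table.loc[site, "effective_n"], 2)
                assert table.loc[site, f"pct_day{h}"] == expect


class TestLedgerInfrastructure:
    def test_csv_round_trip(self, tmp_path):
        ledger = build_attrition_ledger(enrolled=20, donors=2,
                                        procedural_dropouts=1,
                                        partial_treatment_deaths=2,
                                        post_treatment_losses=3)
        path = tmp_path / "ledger.csv"
        ledger.to_csv(path)
        back = CohortLedger.from_csv(path)
        assert population_counts(back) == population_counts(ledger)

    def test_donor_randomization_rejected(self):
        rows = [("d1", "A", "M", "donor", "enrolled", 0, ""),
                ("d1", "A", "M", "donor", "randomized", 0, "")]
        with pytest.raises(ValueError, match="donor"):
            CohortLedger(pd.DataFrame(rows, columns=LEDGER_COLUMNS)).validate()

    def test_stratified_randomization_balanced(self):
        ledger = build_attrition_ledger()
        arms = ("drug", "control")
        assign = temcao.assign_treatments(ledger, arms, seed=1)
        subj = ledger.subjects()
        merged = subj.merge(assign.rename("arm"), left_on="subject_id",
                            right_index=True)
        assert set(merged["arm"]) == set(arms)
        for (_, _), block in merged.groupby(["site", "sex"]):
            counts = block["arm"].value_counts()
            assert abs(counts.get("drug", 0) - counts.get("control", 0)) <= 1
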