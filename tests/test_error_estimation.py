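"""Gold-standard confusion matrices, accuracy metrics, control-subset rates,
implausibility triage, linked/unlinked comparison and quality profiling."""

import numpy as np
import pandas as pd
import pytest

import linkqa
from linkqa import error_estimation as ee
from linkqa import synthetic_data as sd
from linkqa.linkage_engine import RuleCascade
from linkqa.records_io import ConfigError, LinkageStructure


def links_df(pairs, status="link"):
    return pd.DataFrame([(l, r) for l, r in pairs], columns=["left_key", "right_key"]) \
        .assign(status=status)


class TestConfusionMatrix:
    def test_perfect_linkage_has_no_errors(self):
        tm = sd.TruthMap(left={"l1": "P1", "l2": "P2"},
                         right={"r1": "P1", "r2": "P2"})
        uni = ee.PairUniverse(left_keys=("l1", "l2"), right_keys=("r1", "r2"))
        cm = ee.confusion_matrix(links_df([("l1", "r1"), ("l2", "r2")]), tm, uni)
        assert (cm.a, cm.b, cm.c, cm.d) == (2, 0, 0, 2)

    def test_linking_nothing_counts_all_true_pairs_missed(self):
        tm = sd.TruthMap(left={"l1": "P1", "l2": "P2"},
                         right={"r1": "P1", "r2": "P2"})
        uni = ee.PairUniverse(left_keys=("l1", "l2"), right_keys=("r1", "r2"))
        cm = ee.confusion_matrix(links_df([]), tm, uni)
        assert (cm.a, cm.b, cm.c, cm.d) == (0, 0, 2, 2)

    def test_matches_brute_force_recount_on_20x20_gold_standard(self):
        pop = linkqa.generate_population(sd.PopulationSpec(n_persons=20), seed=31)
        corr = linkqa.uniform_corruption(typo=0.1, missing=0.1)
        fa, _ = sd.derive_file(pop, corr, seed=32, file_id="a")
        fb, _ = sd.derive_file(pop, corr, seed=33, file_id="b")
        run = linkqa.link_files(fa, fb, ["nhs", "surname", "dob", "sex"],
                                blocking_keys=[])
        tm = sd.TruthMap.from_files(fa, fb)
        uni = ee.PairUniverse(left_keys=tuple(fa.df.index),
                              right_keys=tuple(fb.df.index))
        cm = ee.confusion_matrix(run.result, tm, uni)
        # brute force over all 400 pairs
        linked = set(zip(run.result.links["left_key"], run.result.links["right_key"]))
        a = b = c = d = 0
        for l in fa.df.index:
            for r in fb.df.index:
                is_true = fa.df.loc[l, "person_id"] == fb.df.loc[r, "person_id"]
                is_link = (l, r) in linked
                a += is_true and is_link
                b += (not is_true) and is_link
                c += is_true and not is_link
                d += (not is_true) and not is_link
        assert (cm.a, cm.b, cm.c, cm.d) == (a, b, c, d)
        assert cm.total == 400

    def test_partial_truth_raises_not_ignored(self):
        tm = sd.TruthMap(left={"l1": "P1"}, right={"r1": "P1", "r2": None})
        uni = ee.PairUniverse(left_keys=("l1",), right_keys=("r1", "r2"))
        with pytest.raises(ee.TruthCoverageError):
            ee.confusion_matrix(links_df([]), tm, uni)


class TestAccuracyMetrics:
    def test_prison_cohort_sensitivity(self):
        cm = ee.ConfusionMatrix(a=275, b=23, c=36, d=7535)
        m = ee.accuracy_metrics(cm)
        assert round(m.sensitivity.value, 3) == 0.884

    def test_prison_cohort_specificity(self):
        cm = ee.ConfusionMatrix(a=275, b=23, c=36, d=7535)
        m = ee.accuracy_metrics(cm)
        assert round(m.specificity.value, 3) == 0.997

    def test_symmetric_counts_give_half_everywhere(self):
        m = ee.accuracy_metrics(ee.ConfusionMatrix(a=25, b=25, c=25, d=25))
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            assert getattr(m, name).value == 0.5

    def test_zero_denominator_flagged_undefined(self):
        m = ee.accuracy_metrics(ee.ConfusionMatrix(a=0, b=0, c=0, d=10))
        assert not m.sensitivity.defined and not m.ppv.defined
        assert m.specificity.defined

    def test_formula_identities_hold_for_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            a, b, c, d = (int(x) for x in rng.integers(0, 500, size=4))
            m = ee.accuracy_metrics(ee.ConfusionMatrix(a=a, b=b, c=c, d=d))
            if m.sensitivity.defined:
                assert m.sensitivity.value * (a + c) == pytest.approx(a)
            if m.specificity.defined:
                assert m.specificity.value * (b + d) == pytest.approx(d)
            if m.ppv.defined:
                assert m.ppv.value * (a + b) == pytest.approx(a)
            if m.npv.defined:
                assert m.npv.value * (c + d) == pytest.approx(d)

    def test_clopper_pearson_interval_contains_point(self):
        p = ee.exact_proportion(275, 311)
        assert p.lo < p.value < p.hi
        assert p.lo == pytest.approx(0.843, abs=0.005)  # exact interval is conservative


class TestNegativeControls:
    def test_prison_cohort_false_match_rate(self):
        decisions = links_df([(f"n{i}", f"r{i}") for i in range(23)])
        negatives = [f"n{i}" for i in range(7558)]
        rate = ee.negative_control_rate(decisions, negatives)
        assert rate.value == pytest.approx(23 / 7558)

    def test_zero_linked_gives_zero_rate_with_interval(self):
        rate = ee.negative_control_rate(links_df([]), ["n1", "n2", "n3"])
        assert rate.value == 0.0
        assert rate.lo == 0.0 and rate.hi > 0.0

    def test_empty_control_set_undefined(self):
        rate = ee.negative_control_rate(links_df([]), [])
        assert not rate.defined

    def test_collision_rate_matches_brute_force_expectation(self):
        # negatives can only link through identifier collisions; compare the
        # realized rate against the truth-based false-match count
        pop = linkqa.generate_population(sd.PopulationSpec(n_persons=400), seed=41)
        cohort, _ = sd.derive_file(pop, sd.CorruptionSpec(), seed=41, file_id="c")
        register, _ = sd.derive_file(
            pop, sd.CorruptionSpec(), seed=42, file_id="d",
            include=pop["outcome"] == 1,
        )
        pos, neg = linkqa.make_control_subsets(cohort, register)
        run = linkqa.link_files(cohort, register,
                                ["surname", "dob", "sex", "postcode"],
                                blocking_keys=["dob"])
        rate = ee.negative_control_rate(run.result, neg)
        tm = sd.TruthMap.from_files(cohort, register)
        links = run.result.links
        false_links = sum(
            not tm.is_match(l, r)
            for l, r in zip(links["left_key"], links["right_key"])
            if l in set(neg)
        )
        assert rate.numer == false_links


class TestImplausibleFlags:
    def test_event_after_death_flagged(self):
        linked = pd.DataFrame({
            "left_key": ["l1", "l2"],
            "admission_date": ["2020-05-01", "2020-01-01"],
            "death_date": ["2020-04-01", "2020-02-01"],
        })
        rep = ee.flag_implausible(
            linked, [ee.rule_event_after_death("admission_date", "death_date")],
            mode="many_to_many",
        )
        assert rep.minimum_false_matches == 1
        assert rep.flagged["left_key"].tolist() == ["l1"]

    def test_sex_specific_code_flagged(self):
        linked = pd.DataFrame({
            "left_key": ["l1", "l2"],
            "sex": ["M", "F"],
            "proc_code": ["CAESAREAN", "CAESAREAN"],
        })
        rep = ee.flag_implausible(
            linked, [ee.rule_sex_specific("sex", "proc_code", ["CAESAREAN"], "F")],
            mode="many_to_many",
        )
        assert rep.minimum_false_matches == 1

    def test_multiplicity_pigeonhole(self):
        # one left record with 3 accepted links under 1:1 -> >= 2 false matches
        linked = pd.DataFrame({
            "left_key": ["l1", "l1", "l1"],
            "right_key": ["r1", "r2", "r3"],
        })
        rep = ee.flag_implausible(linked, [], mode="one_to_one")
        assert rep.minimum_false_matches == 2

    def test_rule_needing_missing_column_raises(self):
        with pytest.raises(ConfigError):
            ee.flag_implausible(
                pd.DataFrame({"left_key": ["l1"]}),
                [ee.rule_event_after_death("adm", "death")],
            )

    def test_flag_count_is_lower_bound_on_true_false_matches(self):
        # with unresolved many_to_many linkage on ambiguous identifiers,
        # multiplicity flags must never exceed the truth-based b
        pop = linkqa.generate_population(
            sd.PopulationSpec(n_persons=300, twin_rate=0.05), seed=51
        )
        fa, _ = sd.derive_file(pop, sd.CorruptionSpec(), seed=52, file_id="a")
        fb, _ = sd.derive_file(pop, sd.CorruptionSpec(), seed=53, file_id="b")
        run = linkqa.link_files(fa, fb, ["surname", "dob", "sex", "postcode"],
                                blocking_keys=["dob"], mode="many_to_many")
        tm = sd.TruthMap.from_files(fa, fb)
        uni = ee.PairUniverse(left_keys=tuple(fa.df.index),
                              right_keys=tuple(fb.df.index))
        cm = ee.confusion_matrix(run.result, tm, uni)
        rep = ee.flag_implausible(run.result.links, [], mode="one_to_one")
        assert rep.minimum_false_matches <= cm.b


class TestLinkedUnlinked:
    def test_nested_structure_estimates_missed_matches(self):
        cohort = pd.DataFrame({"age": range(100)}, index=[f"l{i}" for i in range(100)])
        ind = pd.Series([True] * 90 + [False] * 10, index=cohort.index)
        rep = ee.compare_linked_unlinked(cohort, ind, ["age"],
                                         LinkageStructure("nested"))
        assert rep.estimated_missed_matches == 10

    def test_intersection_structure_suppresses_missed_estimate(self):
        cohort = pd.DataFrame({"age": range(100)}, index=[f"l{i}" for i in range(100)])
        ind = pd.Series([True] * 90 + [False] * 10, index=cohort.index)
        rep = ee.compare_linked_unlinked(cohort, ind, ["age"],
                                         LinkageStructure("intersection"))
        assert rep.estimated_missed_matches is None
        assert len(rep.table)  # comparison still produced

    def test_balanced_binary_covariate_has_zero_std_diff(self):
        cohort = pd.DataFrame({"x": [0, 1] * 20}, index=[f"l{i}" for i in range(40)])
        ind = pd.Series([True, True, False, False] * 10, index=cohort.index)
        rep = ee.compare_linked_unlinked(cohort, ind, ["x"])
        assert rep.table["std_diff"].iloc[0] == pytest.approx(0.0)

    def test_differential_missed_matches_show_in_std_diff(self):
        # plant 3x missed-match rate in the minority subgroup: the linked
        # sample under-represents it, so the subgroup indicator's
        # standardized difference must be negative
        spec = sd.PopulationSpec(
            n_persons=3000, subgroup_fractions={"majority": 0.7, "minority": 0.3},
            outcome_model={"majority": 0.1, "minority": 0.1},
        )
        pop = linkqa.generate_population(spec, seed=61)
        rng = np.random.default_rng(62)
        base_miss = 0.1
        p_miss = np.where(pop["subgroup"] == "minority", 3 * base_miss, base_miss)
        linked_ind = pd.Series(rng.random(len(pop)) > p_miss)
        cohort = pop[["subgroup"]].copy()
        cohort["is_minority"] = (pop["subgroup"] == "minority").astype(float)
        cohort.index = [f"l{i}" for i in range(len(pop))]
        linked_ind.index = cohort.index
        rep = ee.compare_linked_unlinked(cohort, linked_ind, ["is_minority"],
                                         LinkageStructure("nested"))
        sdiff = rep.table.loc[rep.table["covariate"] == "is_minority", "std_diff"].iloc[0]
        assert sdiff < -0.1


class TestQualityProfile:
    def _file(self, df):
        from linkqa.records_io import RecordFile, IDENTIFIER
        schema = {c: IDENTIFIER for c in df.columns if c != "group"}
        schema["group"] = "attribute"
        return RecordFile(file_id="f", df=df, schema=schema)

    def test_complete_valid_records_are_all_linkable(self):
        df = pd.DataFrame({"nhs": ["4505577104"], "dob": ["1980-01-01"],
                           "group": ["a"]}, index=["r0"])
        prof = ee.identifier_quality_profile(
            self._file(df), validators={"nhs": ee.nhs_number_valid},
            cascade=RuleCascade.from_lists([["nhs"], ["dob"]]),
        )
        assert prof.minimum_unlinkable == 0
        assert prof.overall["missing_prop"].sum() == 0

    def test_record_missing_every_cascade_field_is_unlinkable(self):
        df = pd.DataFrame({"nhs": ["4505577104", None], "dob": ["1980-01-01", None],
                           "group": ["a", "a"]}, index=["r0", "r1"])
        prof = ee.identifier_quality_profile(
            self._file(df), cascade=RuleCascade.from_lists([["nhs"], ["dob"]])
        )
        assert prof.minimum_unlinkable == 1
        assert prof.unlinkable_keys == ["r1"]

    def test_invalid_nhs_number_detected(self):
        # valid check digit vs corrupted one
        assert ee.nhs_number_valid("4505577104")
        assert not ee.nhs_number_valid("4505577105")
        assert not ee.nhs_number_valid("45055771")
        df = pd.DataFrame({"nhs": ["4505577105"], "group": ["a"]}, index=["r0"])
        prof = ee.identifier_quality_profile(
            self._file(df), validators={"nhs": ee.nhs_number_valid}
        )
        assert prof.overall.loc[0, "invalid_prop"] == 1.0

    def test_planted_differential_missingness_recovered(self):
        spec = sd.PopulationSpec(
            n_persons=4000, subgroup_fractions={"a": 0.5, "b": 0.5},
            outcome_model={"a": 0.1, "b": 0.1},
        )
        pop = linkqa.generate_population(spec, seed=71)
        corr = sd.CorruptionSpec(
            fields={"postcode": sd.FieldCorruption(missing_rate=0.1)},
            differential={"b": 2.0},
        )
        rf, _ = sd.derive_file(pop, corr, seed=72)
        prof = ee.identifier_quality_profile(rf, covariates=["subgroup"])
        bg = prof.by_group
        row = bg[bg["identifier"] == "postcode"].set_index("level")["missing_prop"]
        assert row["b"] / row["a"] == pytest.approx(2.0, rel=0.3)


class TestMarginalsReport:
    def test_matching_marginals_give_zero_divergence(self):
        obs = pd.Series(["a"] * 30 + ["b"] * 70)
        rep = ee.marginals_report(obs, {"a": 0.3, "b": 0.7})
        assert rep.chi_square == pytest.approx(0.0)

    def test_disjoint_categories_raise(self):
        with pytest.raises(ConfigError):
            ee.marginals_report(pd.Series(["x", "y"]), {"a": 0.5, "b": 0.5})

    def test_planted_shift_is_largest_contributor(self):
        obs = pd.Series(["a"] * 40 + ["b"] * 35 + ["c"] * 25)
        rep = ee.marginals_report(obs, {"a": 0.30, "b": 0.40, "c": 0.30})
        assert rep.largest_contributor == "a"
        assert rep.chi_square > 0


def test_gold_subset_estimates_cover_full_truth_across_seeds():
    """A small gold-standard subset's sensitivity interval covers the
    truth-based full-universe sensitivity in nearly all of 20 seeds."""
    from linkqa.linkage_engine import ComparisonModel

    idents = ["nhs", "surname", "dob", "sex"]
    model = ComparisonModel(
        m={k: 0.92 for k in idents},
        u={"nhs": 1e-4, "surname": 0.02, "dob": 0.001, "sex": 0.5},
        prior_odds=0.01,
    )
    covered = 0
    for seed in range(20):
        pop = linkqa.generate_population(sd.PopulationSpec(n_persons=400), seed=100 + seed)
        corr = linkqa.uniform_corruption(typo=0.05, missing=0.05)
        fa, _ = sd.derive_file(pop, corr, seed=200 + seed, file_id="a")
        fb, _ = sd.derive_file(pop, corr, seed=300 + seed, file_id="b")
        run = linkqa.link_files(fa, fb, idents, model=model,
                                blocking_keys=["nhs", "dob", "surname"], upper=4.0)
        tm = sd.TruthMap.from_files(fa, fb)
        full = ee.accuracy_metrics(ee.confusion_matrix(
            run.result, tm,
            ee.PairUniverse(left_keys=tuple(fa.df.index),
                            right_keys=tuple(fb.df.index)),
        ))
        rng = np.random.default_rng(400 + seed)
        gold_persons = set(rng.choice(pop["person_id"], size=80, replace=False))
        gl = tuple(k for k, p in zip(fa.df.index, fa.df["person_id"]) if p in gold_persons)
        gr = tuple(k for k, p in zip(fb.df.index, fb.df["person_id"]) if p in gold_persons)
        sub = ee.accuracy_metrics(ee.confusion_matrix(
            run.result, tm, ee.PairUniverse(left_keys=gl, right_keys=gr)
        ))
        if sub.sensitivity.lo <= full.sensitivity.value <= sub.sensitivity.hi:
            covered += 1
    assert covered >= 18
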