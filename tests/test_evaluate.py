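"""Screen statistics: chi-square oracle agreement, counting brute force,
Bonferroni semantics, outcome agreement, macro-f1 closed forms."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

import larvaction as la
from larvaction.tagger import ActionDictionary

DIC = ActionDictionary()


def labelset_from_names(per_larva: dict[int, list[str]], dt=0.1) -> la.LabelSet:
    from larvaction.simulate import DEFAULT_DICTIONARY

    ls = la.LabelSet(dictionary=list(DEFAULT_DICTIONARY))
    index = {s.name: i for i, s in enumerate(DEFAULT_DICTIONARY)}
    for lid, names in per_larva.items():
        ls.assignments[lid] = [[index[n]] if n else [] for n in names]
        ls.times[lid] = np.arange(len(names)) * dt
    return ls


class TestChi2Compare:
    def test_identical_proportions(self):
        assert la.chi2_compare((50, 100), (50, 100)) == (0.0, 1.0)

    def test_hand_computed_pearson_example(self):
        chi2, p = la.chi2_compare((30, 100), (10, 100))
        assert chi2 == pytest.approx(12.5, abs=1e-9)
        assert p == pytest.approx(4.07e-4, rel=1e-2)

    def test_symmetric_in_groups(self):
        a = la.chi2_compare((13, 40), (22, 55))
        b = la.chi2_compare((22, 55), (13, 40))
        assert a == pytest.approx(b)

    def test_zero_margin_degenerate(self):
        assert la.chi2_compare((0, 30), (0, 40)) == (0.0, 1.0)
        assert la.chi2_compare((30, 30), (40, 40)) == (0.0, 1.0)

    @pytest.mark.parametrize("n_tables", [1000])
    def test_matches_scipy_oracle_on_random_tables(self, n_tables):
        rng = np.random.default_rng(0)
        for _ in range(n_tables):
            n_t, n_c = rng.integers(2, 200, size=2)
            k_t = int(rng.integers(0, n_t + 1))
            k_c = int(rng.integers(0, n_c + 1))
            table = np.array([[k_t, n_t - k_t], [k_c, n_c - k_c]])
            chi2, p = la.chi2_compare((k_t, int(n_t)), (k_c, int(n_c)))
            if min(table.sum(axis=0)) == 0:
                assert (chi2, p) == (0.0, 1.0)
            else:
                ref = chi2_contingency(table, correction=False)
                assert chi2 == pytest.approx(ref.statistic, abs=1e-9)
                assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            la.chi2_compare((5, 3), (1, 10))
        with pytest.raises(ValueError):
            la.chi2_compare((0, 0), (1, 10))


class TestWindowCounts:
    def test_simple_count(self):
        ls = labelset_from_names({i: ["hunch" if i < 4 else "crawl"] * 5
                                  for i in range(10)})
        assert la.window_counts(ls, None, "hunch", (0.0, 0.5)) == (4, 10)

    def test_window_before_any_data(self):
        ls = labelset_from_names({1: ["crawl"] * 5})
        assert la.window_counts(ls, None, "crawl", (-10.0, -9.0)) == (0, 0)

    def test_untagged_larvae_excluded_from_n(self):
        ls = labelset_from_names({1: ["crawl"] * 5, 2: [""] * 5})
        assert la.window_counts(ls, None, "crawl", (0.0, 0.5)) == (1, 1)

    @pytest.mark.parametrize("seed", range(20))
    def test_brute_force_equivalence_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        names = list(DIC.names) + [""]
        per_larva = {lid: [names[i] for i in rng.integers(0, len(names), 30)]
                     for lid in range(8)}
        ls = labelset_from_names(per_larva)
        t0, t1 = sorted(rng.uniform(0, 3.0, size=2))
        if t1 <= t0:
            t1 = t0 + 0.1
        action = names[rng.integers(0, len(DIC.names))]
        k, n = la.window_counts(ls, None, action, (t0, t1))
        # brute force directly over the raw assignment lists
        bk = bn = 0
        for lid, seq in per_larva.items():
            times = np.arange(len(seq)) * 0.1
            tagged = [nm for tt, nm in zip(times, seq) if t0 <= tt < t1 and nm]
            if tagged:
                bn += 1
                bk += action in tagged
        assert (k, n) == (bk, bn)


class TestProbabilityTimeseries:
    def test_all_crawl_rows(self):
        ls = labelset_from_names({i: ["crawl"] * 20 for i in range(5)})
        table = la.probability_timeseries(ls, None, DIC, bin_seconds=0.5)
        crawl = table[table["action"] == "crawl"]["probability"]
        other = table[table["action"] != "crawl"]["probability"]
        assert (crawl == 1.0).all()
        assert (other == 0.0).all()

    def test_single_label_probabilities_bounded_by_one(self):
        rng = np.random.default_rng(1)
        names = list(DIC.names) + [""]
        ls = labelset_from_names({lid: [names[i] for i in rng.integers(0, 8, 40)]
                                  for lid in range(6)})
        table = la.probability_timeseries(ls, None, DIC, bin_seconds=1.0)
        sums = table.groupby("t_bin")["probability"].sum()
        assert (sums <= len(DIC.names) + 1e-9).all()

    def test_step_at_stimulus_onset(self):
        tracks, labels, _ = la.simulate_assay(
            120, {"crawl": 1.0}, {"hunch": 0.5, "crawl": 0.5},
            seed=3, stimulus_onset=5.0, post_seconds=3.0)
        table = la.probability_timeseries(labels, tracks, DIC, bin_seconds=1.0)
        hunch = table[table["action"] == "hunch"].set_index("t_bin")["probability"]
        assert hunch.loc[3.0] < 0.1
        assert hunch.loc[5.0] == pytest.approx(0.5, abs=0.15)


class TestScreenCompare:
    def _lines(self, p_test, p_control, n=60, seed=0):
        ctrl = {"hunch": p_control, "crawl": 1 - p_control}
        test = {"hunch": p_test, "crawl": 1 - p_test}
        tc, lc, _ = la.simulate_assay(n, ctrl, ctrl, seed=seed,
                                      stimulus_onset=3.0, post_seconds=2.0)
        tt, lt, _ = la.simulate_assay(n, ctrl, test, seed=seed + 1,
                                      stimulus_onset=3.0, post_seconds=2.0)
        return {"control": (lc, tc), "line": (lt, tt)}

    def test_strong_increase_flagged_positive(self):
        results = la.screen_compare(self._lines(0.9, 0.05), "control", DIC,
                                    (3.0, 4.0))
        hunch = next(r for r in results if r.action == "hunch")
        assert hunch.outcome == "positive"
        crawl = next(r for r in results if r.action == "crawl")
        assert crawl.outcome == "negative"

    def test_bonferroni_multiplier_scales_corrected_p(self):
        lines = self._lines(0.6, 0.1)
        r1 = la.screen_compare(lines, "control", DIC, (3.0, 4.0), m=None)
        r471 = la.screen_compare(lines, "control", DIC, (3.0, 4.0), m=471)
        for a, b in zip(r1, r471):
            if np.isfinite(a.p_raw):
                assert b.p_corrected == pytest.approx(min(1.0, 471 * a.p_raw))
                assert a.p_corrected == pytest.approx(
                    min(1.0, len(r1) * a.p_raw))

    def test_m_smaller_than_tests_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            la.screen_compare(self._lines(0.5, 0.5), "control", DIC,
                              (3.0, 4.0), m=2)

    def test_empty_window_untestable(self):
        results = la.screen_compare(self._lines(0.5, 0.5), "control", DIC,
                                    (90.0, 91.0))
        assert all(r.outcome == "untestable" for r in results)


class TestAgreement:
    def test_identical_maps_fully_concordant(self):
        ref = {("l1", "hunch"): "positive", ("l1", "crawl"): "none"}
        summary = la.agreement(ref, dict(ref))
        assert summary.concordance == 1.0
        assert summary.opposite == 0

    def test_headline_fraction_232_of_293(self):
        ref = {i: "positive" for i in range(293)}
        cand = {i: ("positive" if i < 232 else "none") for i in range(293)}
        summary = la.agreement(ref, cand)
        assert summary.concordant == 232
        assert summary.concordance == pytest.approx(232 / 293)
        assert summary.effect_lost == 61

    @pytest.mark.parametrize("seed", range(10))
    def test_brute_force_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        levels = ["positive", "negative", "none"]
        keys = range(50)
        ref = {k: levels[i] for k, i in zip(keys, rng.integers(0, 3, 50))}
        cand = {k: levels[i] for k, i in zip(keys, rng.integers(0, 3, 50))}
        s = la.agreement(ref, cand)
        conc = sum(ref[k] == cand[k] for k in keys)
        opp = sum({ref[k], cand[k]} == {"positive", "negative"} for k in keys)
        lost = sum(ref[k] != "none" and cand[k] == "none" for k in keys)
        gained = sum(ref[k] == "none" and cand[k] != "none" for k in keys)
        assert (s.concordant, s.opposite, s.effect_lost, s.effect_gained) == \
            (conc, opp, lost, gained)
        assert s.total == 50

    def test_key_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            la.agreement({"a": "none"}, {"b": "none"})


class TestMacroF1:
    def test_perfect_predictions(self):
        assert la.macro_f1(["crawl", "bend"] * 5, ["crawl", "bend"] * 5, DIC) == 1.0

    def test_constant_prediction_closed_form(self):
        truth = ["crawl"] * 10 + ["bend"] * 10
        pred = ["crawl"] * 20
        assert la.macro_f1(truth, pred, DIC) == pytest.approx(1 / 3)

    def test_invariant_to_dictionary_order(self):
        truth = ["crawl", "bend", "stop", "bend"]
        pred = ["crawl", "stop", "stop", "bend"]
        d2 = ActionDictionary(tuple(reversed(DIC.names)))
        assert la.macro_f1(truth, pred, DIC) == la.macro_f1(truth, pred, d2)

    def test_untagged_excluded_pairwise(self):
        truth = ["crawl", "", "bend", "crawl"]
        pred = ["crawl", "bend", None, "crawl"]
        assert la.macro_f1(truth, pred, DIC) == 1.0

    def test_all_untagged_rejected(self):
        with pytest.raises(ValueError):
            la.macro_f1(["", ""], ["crawl", "bend"], DIC)
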