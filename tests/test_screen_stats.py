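"""Hit rates, z'-factor, 5-SD thresholds and replicate-rule hit calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nucleoscreen as ns
from nucleoscreen.phenotypes import PHENOTYPE_CLASSES
from nucleoscreen.screen_stats import ReadoutSpec, StatsError

SPECS = ns.default_readout_specs()


def _counts_row(readout, counts, **meta):
    row = {c: 0 for c in PHENOTYPE_CLASSES}
    row.update(counts)
    row.update({"readout": readout, "replicate": 1, "plate": "p1", "well": "A01"})
    row.update(meta)
    return row


class TestClassCounts:
    def test_three_cells_one_class_counted(self):
        cells = pd.DataFrame(
            {
                "readout": ["r"] * 3,
                "replicate": [1] * 3,
                "plate": ["p1"] * 3,
                "well": ["A01"] * 3,
                "predicted_class": ["mitotic"] * 3,
            }
        )
        out = ns.class_counts(cells)
        assert len(out) == 1
        assert out.iloc[0]["mitotic"] == 3

    def test_counts_equal_brute_force_tally_on_shuffled_input(self):
        rng = np.random.default_rng(0)
        n = 500
        cells = pd.DataFrame(
            {
                "readout": rng.choice(["a", "b"], n),
                "replicate": rng.integers(1, 3, n),
                "plate": ["p1"] * n,
                "well": rng.choice(["A01", "B02", "C03"], n),
                "predicted_class": rng.choice(PHENOTYPE_CLASSES, n),
            }
        )
        shuffled = cells.sample(frac=1.0, random_state=1).reset_index(drop=True)
        out = ns.class_counts(shuffled).set_index(["readout", "replicate", "plate", "well"])
        for key, grp in cells.groupby(["readout", "replicate", "plate", "well"]):
            for cls in PHENOTYPE_CLASSES:
                assert out.loc[key, cls] == (grp["predicted_class"] == cls).sum()

    def test_sites_within_a_well_are_pooled(self):
        cells = pd.DataFrame(
            {
                "readout": ["r"] * 4,
                "replicate": [1] * 4,
                "plate": ["p1"] * 4,
                "well": ["A01"] * 4,
                "site": [1, 1, 2, 3],
                "predicted_class": ["nucleolar"] * 4,
            }
        )
        out = ns.class_counts(cells)
        assert len(out) == 1 and out.iloc[0]["nucleolar"] == 4

    def test_empty_input_gives_empty_table(self):
        assert len(ns.class_counts(pd.DataFrame(columns=["predicted_class"]))) == 0

    def test_unknown_class_rejected(self):
        cells = pd.DataFrame(
            {"readout": ["r"], "replicate": [1], "plate": ["p"], "well": ["A01"],
             "predicted_class": ["blob"]}
        )
        with pytest.raises(ValueError, match="blob"):
            ns.class_counts(cells)


class TestHitRates:
    def test_minus_lmb_hand_count(self):
        counts = pd.DataFrame(
            [_counts_row("enp1_minus_lmb",
                         {"nucleoplasmic": 25, "nucleolar": 70,
                          "nucleolar_nucleoplasmic": 5, "mitotic": 9})]
        )
        out = ns.readout_hit_rate(counts, SPECS["enp1_minus_lmb"])
        assert out.iloc[0]["hit_rate"] == pytest.approx(0.25)
        assert out.iloc[0]["hit_count"] == 25
        assert out.iloc[0]["non_hit_count"] == 75

    def test_rpl29_hand_count(self):
        counts = pd.DataFrame(
            [_counts_row("rpl29_gfp",
                         {"nucleolar": 10, "nucleolar_nucleoplasmic": 5,
                          "nucleoplasmic": 5, "cytoplasmic": 80, "no_signal": 20})]
        )
        out = ns.readout_hit_rate(counts, SPECS["rpl29_gfp"])
        assert out.iloc[0]["hit_rate"] == pytest.approx(0.20)

    def test_all_excluded_classes_is_undefined(self):
        counts = pd.DataFrame(
            [_counts_row("enp1_plus_lmb", {"mitotic": 5, "apoptotic": 3})]
        )
        out = ns.readout_hit_rate(counts, SPECS["enp1_plus_lmb"])
        assert math.isnan(out.iloc[0]["hit_rate"])
        assert out.iloc[0]["undefined_reason"] != ""

    @given(extra=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_adding_excluded_cells_never_changes_the_rate(self, extra):
        counts = pd.DataFrame(
            [_counts_row("rps2_yfp",
                         {"nucleolar": 12, "cytoplasmic": 30, "mitotic": extra,
                          "no_signal": extra, "missegmented": extra})]
        )
        out = ns.readout_hit_rate(counts, SPECS["rps2_yfp"])
        assert out.iloc[0]["hit_rate"] == pytest.approx(12 / 42)

    def test_denominator_variants_for_minus_lmb(self):
        counts = pd.DataFrame(
            [_counts_row("enp1_minus_lmb",
                         {"nucleoplasmic": 10, "nucleolar": 60,
                          "nucleolar_nucleoplasmic": 20, "cytoplasmic": 10})]
        )
        methods = ns.default_readout_specs("methods_table")["enp1_minus_lmb"]
        results = ns.default_readout_specs("results_text")["enp1_minus_lmb"]
        interphase = ns.default_readout_specs("all_interphase")["enp1_minus_lmb"]
        assert ns.readout_hit_rate(counts, methods).iloc[0]["hit_rate"] == pytest.approx(10 / 90)
        assert ns.readout_hit_rate(counts, results).iloc[0]["hit_rate"] == pytest.approx(10 / 70)
        assert ns.readout_hit_rate(counts, interphase).iloc[0]["hit_rate"] == pytest.approx(10 / 100)

    def test_overlapping_class_sets_rejected(self):
        with pytest.raises(StatsError):
            ReadoutSpec("bad", frozenset({"nucleolar"}), frozenset({"nucleolar"}))


class TestZPrime:
    def test_zero_spread_groups_give_one(self):
        assert ns.zprime([0.9, 0.9, 0.9], [0.1, 0.1, 0.1]) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        assert ns.zprime([0.8, 0.9, 1.0], [0.0, 0.1, 0.2]) == pytest.approx(0.25)

    def test_equal_means_flagged_undefined(self):
        assert math.isnan(ns.zprime([0.5, 0.6], [0.6, 0.5]))

    def test_small_groups_rejected(self):
        with pytest.raises(StatsError):
            ns.zprime([0.9], [0.1, 0.2])

    @given(
        a=st.floats(min_value=0.05, max_value=50.0),
        b=st.floats(min_value=-10.0, max_value=10.0),
        sign=st.sampled_from([-1.0, 1.0]),
    )
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, a, b, sign):
        pos = np.array([0.7, 0.85, 0.9, 0.95])
        neg = np.array([0.05, 0.1, 0.0, 0.12])
        base = ns.zprime(pos, neg)
        scaled = ns.zprime(sign * a * pos + b, sign * a * neg + b)
        assert scaled == pytest.approx(base, rel=1e-9)

    @given(
        pos=st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=8),
        neg=st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=8),
    )
    @settings(max_examples=100, deadline=None)
    def test_never_exceeds_one(self, pos, neg):
        if np.mean(pos) == np.mean(neg):
            assert math.isnan(ns.zprime(pos, neg))
        else:
            assert ns.zprime(pos, neg) <= 1.0


class TestThreshold:
    def test_hand_computed_example(self):
        assert ns.dmso_threshold([0.02, 0.03, 0.04]) == pytest.approx(0.08)

    def test_constant_rates_give_threshold_at_mean(self):
        assert ns.dmso_threshold([0.07, 0.07, 0.07]) == pytest.approx(0.07)

    def test_single_well_rejected(self):
        with pytest.raises(StatsError):
            ns.dmso_threshold([0.05])


def _rates_frame(records):
    return pd.DataFrame(
        records,
        columns=["readout", "replicate", "plate", "well", "role", "compound_id", "hit_rate"],
    )


class TestCallHits:
    def _with_thresholds(self, rates, thr=0.5):
        reps = sorted(rates["replicate"].unique())
        thresholds = pd.DataFrame(
            [{"readout": r, "replicate": p, "dmso_mean": 0.0, "dmso_sd": 0.0,
              "threshold": thr, "n_dmso": 2}
             for r in rates["readout"].unique() for p in reps]
        )
        return thresholds

    def test_two_of_three_above_is_a_hit(self):
        rates = _rates_frame(
            [("r", i, "p1", "A03", "library", "c1", v)
             for i, v in zip((1, 2, 3), (0.9, 0.1, 0.8))]
        )
        report = ns.call_hits(rates, self._with_thresholds(rates), k=2, n_replicates=3)
        assert report.hits == ["c1"]

    def test_all_below_is_not_a_hit(self):
        rates = _rates_frame(
            [("r", i, "p1", "A03", "library", "c1", 0.1) for i in (1, 2, 3)]
        )
        report = ns.call_hits(rates, self._with_thresholds(rates), k=2, n_replicates=3)
        assert report.hits == []

    def test_undefined_rate_marks_compound_incomplete(self):
        rates = _rates_frame(
            [("r", 1, "p1", "A03", "library", "c1", 0.9),
             ("r", 2, "p1", "A03", "library", "c1", float("nan")),
             ("r", 3, "p1", "A03", "library", "c1", 0.9)]
        )
        report = ns.call_hits(rates, self._with_thresholds(rates), k=2, n_replicates=3)
        assert report.hits == []
        assert report.incomplete[0]["compound_id"] == "c1"

    def test_matches_brute_force_over_random_table(self):
        rng = np.random.default_rng(3)
        recs = []
        for c in range(50):
            for rep in (1, 2, 3):
                recs.append(("r", rep, "p1", f"A{c % 16 + 1:02d}", "library",
                             f"c{c}", float(rng.uniform(0, 1))))
        rates = _rates_frame(recs)
        thr = self._with_thresholds(rates, thr=0.6)
        report = ns.call_hits(rates, thr, k=2, n_replicates=3)
        expected = []
        for c in range(50):
            sub = rates[rates["compound_id"] == f"c{c}"]
            if (sub["hit_rate"] > 0.6).sum() >= 2:
                expected.append(f"c{c}")
        assert report.hits == sorted(expected)

    def test_missing_threshold_rejected(self):
        rates = _rates_frame([("r", 1, "p1", "A03", "library", "c1", 0.9)])
        thr = pd.DataFrame(
            [{"readout": "other", "replicate": 1, "threshold": 0.5}]
        )
        with pytest.raises(StatsError):
            ns.call_hits(rates, thr)


class TestQcReport:
    def _counts(self, wells):
        rows = []
        for well, n in wells:
            row = {c: 0 for c in PHENOTYPE_CLASSES}
            row["nucleolar"] = n
            row.update({"readout": "r", "replicate": 1, "plate": "p1", "well": well})
            rows.append(row)
        return pd.DataFrame(rows)

    def test_single_well_flagged_with_undefined_sd(self):
        rep = ns.qc_report(self._counts([("A01", 100)]))
        row = rep["cells"].iloc[0]
        assert row["mean_cells"] == 100
        assert math.isnan(row["sd_cells"]) and bool(row["single_well"])

    def test_two_identical_wells_have_zero_sd(self):
        rep = ns.qc_report(self._counts([("A01", 80), ("A02", 80)]))
        assert rep["cells"].iloc[0]["sd_cells"] == 0.0

    def test_totals_match_simulated_ground_truth(self):
        maps = ns.build_screen_layout([f"c{i}" for i in range(10)], plates=1)
        counts = ns.simulate_screen_tables(
            maps, ns.EffectModel(), cells_per_well=200, replicates=1, seed=4,
            readouts=("rps2_yfp",),
        )
        rep = ns.qc_report(counts)
        assert rep["cells"].iloc[0]["total_cells"] == counts[list(PHENOTYPE_CLASSES)].sum().sum()
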