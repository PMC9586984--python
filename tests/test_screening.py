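"""Cutoff application, policy metrics, published-count arithmetic, tuning."""

import numpy as np
import pytest

from acpscreen._round import percent_half_up, round_half_up
from acpscreen.errors import NoModelsError, UndefinedFractionError
from acpscreen.registry import ModelRegistry
from acpscreen.screening import (
    Cell,
    apply_cutoff,
    compare_policies,
    evaluate_policy,
    load_counts,
    prevalence_3dp,
    result_from_counts,
    tune_prevalence_level,
)

from conftest import single_stratum_registry
from oracles import brute_force_tune


class TestApplyCutoff:
    def test_fractional_cutoff_semantics(self):
        ais = np.array([8.0, 9.0])
        y = np.array([0.0, 1.0])
        below, above = apply_cutoff(ais, y, 8.8)
        assert (below.n, above.n) == (1, 1)
        assert above.n_pos == 1

    def test_extreme_cutoffs(self):
        ais = np.arange(10.0)
        y = np.ones(10)
        _, above = apply_cutoff(ais, y, 0.0)
        assert above.n == 10
        below, above = apply_cutoff(ais, y, 25.0)
        assert above.n == 0 and below.n == 10


# Published prevalences (3 decimals, half-up) per (table, stratification,
# cutoff_label, category) — the worked examples the bundled counts transcribe.
PRINTED_PREVALENCES = [
    ("md_stratified", "all", "none", "total", 0.189),
    ("md_stratified", "without_md", "none", "total", 0.176),
    ("md_stratified", "without_md", "acp50", "below", 0.145),
    ("md_stratified", "without_md", "acp50", "above", 0.612),
    ("md_stratified", "md", "none", "total", 0.442),
    ("md_stratified", "md", "acp50", "below", 0.234),
    ("md_stratified", "md", "acp50", "above", 0.775),
    ("acp_policies", "none", "none", "total", 0.174),
    ("acp_policies", "three_factor", "acp50", "below", 0.145),
    ("acp_policies", "three_factor", "acp50", "above", 0.637),
    ("acp_policies", "five_factor", "acp50", "below", 0.139),
    ("acp_policies", "five_factor", "acp50", "above", 0.654),
    ("acp_policies", "five_factor", "acp75", "below", 0.163),
    ("acp_policies", "five_factor", "acp75", "above", 0.765),
    ("sleep_cutoff", "none", "ais6", "below", 0.096),
    ("sleep_cutoff", "none", "ais6", "above", 0.449),
    ("sleep_cutoff", "three_factor", "acp26", "below", 0.100),
    ("sleep_cutoff", "three_factor", "acp26", "above", 0.471),
    ("sleep_cutoff", "three_factor", "acp28.3", "below", 0.101),
    ("sleep_cutoff", "three_factor", "acp28.3", "above", 0.480),
    ("sleep_cutoff", "five_factor", "acp25", "below", 0.095),
    ("sleep_cutoff", "five_factor", "acp25", "above", 0.462),
    ("sleep_cutoff", "five_factor", "acp28.3", "below", 0.100),
    ("sleep_cutoff", "five_factor", "acp28.3", "above", 0.479),
]


class TestPublishedCounts:
    @pytest.mark.parametrize("table,strat,cutoff,category,expected", PRINTED_PREVALENCES)
    def test_every_printed_prevalence_reproduces(self, table, strat, cutoff, category, expected):
        counts = load_counts(table)
        row = counts[
            (counts["stratification"] == strat)
            & (counts["cutoff_label"] == cutoff)
            & (counts["category"] == category)
        ].iloc[0]
        cell = Cell(int(row["n"]), int(row["n_pos"]))
        assert prevalence_3dp(cell) == expected

    def test_count_tables_internally_consistent(self):
        """Below+above cells rebuild each stratum total; positives <= sizes."""
        t1 = load_counts("md_stratified")
        without = t1[t1["stratification"] == "without_md"]
        assert without.loc[without["category"] != "total", "n"].sum() == 8024
        md = t1[t1["stratification"] == "md"]
        assert md.loc[md["category"] != "total", "n"].sum() == 416
        for name in ("md_stratified", "acp_policies", "sleep_cutoff"):
            counts = load_counts(name)
            assert (counts["n_pos"] <= counts["n"]).all()

    def test_ppv_of_acp_policies(self):
        counts = load_counts("acp_policies")
        three50 = result_from_counts(counts, "three_factor", "acp50")
        five50 = result_from_counts(counts, "five_factor", "acp50")
        five75 = result_from_counts(counts, "five_factor", "acp75")
        assert percent_half_up(three50.ppv_above) == 63.7
        assert percent_half_up(five50.ppv_above) == 65.4
        assert percent_half_up(five75.ppv_above) == 76.5
        assert (five50.detected, five50.screened) == (315, 482)
        assert (five75.detected, five75.screened) == (101, 132)
        # moving from three to five factors screens 66 more, detects 50 more
        assert five50.screened - three50.screened == 66
        assert five50.detected - three50.detected == 50

    def test_fixed_ais6_reference_policy(self):
        counts = load_counts("sleep_cutoff")
        ais6 = result_from_counts(counts, "none", "ais6")
        assert (ais6.screened, ais6.detected) == (1555, 698)
        assert round_half_up(ais6.ppv_above, 3) == 0.449
        assert ais6.below.n == 5466 and ais6.below.n_pos == 524

    def test_tuned_policy_fractions(self):
        counts = load_counts("sleep_cutoff")
        ais6 = result_from_counts(counts, "none", "ais6")
        acp26 = result_from_counts(counts, "three_factor", "acp26")
        acp25 = result_from_counts(counts, "five_factor", "acp25")
        c26 = compare_policies(acp26, ais6)
        c25 = compare_policies(acp25, ais6)
        assert c26.detected_pct == 94.8      # 662 of 698
        assert c26.screened_fraction == pytest.approx(1407 / 1555)
        assert c26.screened_pct == 90.5      # 1407/1555 = 90.48%, half-up
        assert c25.detected_pct == 99.7      # 696 of 698
        assert c25.screened_pct == 96.9      # 1507 of 1555


class TestEvaluatePolicy:
    def test_degenerate_all_positive_above(self, tmp_path):
        registry = single_stratum_registry(3000, 21, -2.0, 0.25)
        m = registry["0xxxxx"]
        # raise the cutoff until every screened record is positive
        for cutoff in range(24, 0, -1):
            above = m.y[m.ais >= cutoff]
            if len(above) and above.all():
                res = evaluate_policy(registry, fixed_ais=cutoff)
                assert res.ppv_above == 1.0
                break
        else:
            pytest.skip("no fully-positive tail in this draw")

    def test_conservation_and_ppv_identity(self):
        registry = single_stratum_registry(5000, 22, -2.0, 0.25)
        for kwargs in ({"fixed_ais": 6.0}, {"level": 0.5}, {"level": 0.9}):
            res = evaluate_policy(registry, **kwargs)
            assert res.below.n + res.above.n == res.total_n
            assert res.below.n_pos + res.above.n_pos == res.total_pos
            assert res.ppv_above == res.above.prevalence  # same quantity, bit-exact

    def test_requires_one_rule_and_fitted_models(self):
        registry = single_stratum_registry(500, 23, -2.0, 0.25)
        with pytest.raises(ValueError):
            evaluate_policy(registry, fixed_ais=6.0, level=0.5)
        empty = ModelRegistry((1,), 0.05, 5)
        with pytest.raises(NoModelsError):
            evaluate_policy(empty, fixed_ais=6.0)

    def test_out_of_range_acp_not_clamped(self):
        registry = single_stratum_registry(2000, 24, -2.0, 0.25)
        res = evaluate_policy(registry, level=0.999999)  # ACP far above 24
        assert res.screened == 0


class TestComparePolicies:
    def test_identity_is_100_percent(self):
        registry = single_stratum_registry(2000, 25, -2.0, 0.25)
        res = evaluate_policy(registry, fixed_ais=6.0)
        comp = compare_policies(res, res)
        assert comp.detected_pct == 100.0 and comp.screened_pct == 100.0

    def test_zero_reference_detection(self):
        registry = single_stratum_registry(2000, 26, -2.0, 0.25)
        res = evaluate_policy(registry, fixed_ais=6.0)
        nothing = evaluate_policy(registry, fixed_ais=25.0)
        with pytest.raises(UndefinedFractionError):
            compare_policies(res, nothing)


class TestTune:
    def test_matches_brute_force_oracle(self):
        registry = single_stratum_registry(2000, 27, -2.0, 0.25)
        m = registry["0xxxxx"]
        target = int(m.y[m.ais >= 6.0].sum())  # fixed AIS>=6 detection
        q_star, res = tune_prevalence_level(registry, target, 0.1)
        oracle_q = brute_force_tune(
            [(m.fit.beta0, m.fit.beta1, m.ais, m.y)], target, 0.1)
        assert q_star == pytest.approx(oracle_q, abs=1e-9)
        assert res.detected == int(m.y[m.ais >= (res.counts["cutoff"].iloc[0])].sum())

    def test_target_zero_takes_largest_quiet_level(self):
        registry = single_stratum_registry(1000, 28, -2.0, 0.25)
        q_star, res = tune_prevalence_level(registry, 0, 0.5)
        assert q_star == 99.5  # largest grid level with minimal detection
        m = registry["0xxxxx"]
        min_detected = min(
            int(m.y[m.ais >= m.acp(q / 100).ais_value].sum())
            for q in np.arange(0.5, 100.0, 0.5)
        )
        assert res.detected == min_detected

    def test_target_above_total_warns_and_maximizes(self):
        registry = single_stratum_registry(1000, 29, -2.0, 0.25)
        m = registry["0xxxxx"]
        with pytest.warns(UserWarning):
            q_star, res = tune_prevalence_level(registry, m.n_pos + 100, 0.5)
        assert res.detected == m.n_pos  # everyone above at a low enough level

    def test_detected_and_screened_monotone_in_level(self):
        registry = single_stratum_registry(4000, 30, -2.0, 0.25)
        detected, screened = [], []
        for q in np.arange(5.0, 100.0, 5.0):
            res = evaluate_policy(registry, level=q / 100.0)
            detected.append(res.detected)
            screened.append(res.screened)
        assert all(a >= b for a, b in zip(detected, detected[1:]))
        assert all(a >= b for a, b in zip(screened, screened[1:]))
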