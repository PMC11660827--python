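import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from txrescue.counts import normalize_fpm
from txrescue.de import run_de
from txrescue.rescue import (
    classify_strategy_a,
    classify_strategy_b,
    classify_study,
    group_ci,
    intervals_overlap,
    summarize_strategies,
)


def t_interval_oracle(values, level=0.95):
    """Independent t-interval on log2(x+1), back-transformed."""
    y = [math.log2(v + 1) for v in values]
    n = len(y)
    m = sum(y) / n
    sd = math.sqrt(sum((v - m) ** 2 for v in y) / (n - 1))
    half = stats.t.ppf(1 - (1 - level) / 2, n - 1) * sd / math.sqrt(n)
    return 2 ** (m - half) - 1, 2 ** (m + half) - 1


def brute_force_five_rules(control, disease, drug, fpm_min=3.0, lfc_min=1.0):
    """One-function, step-by-step evaluator of the five rules."""
    mc = sum(control) / len(control)
    md = sum(disease) / len(disease)
    me = sum(drug) / len(drug)
    lfc = math.log2((md + 1) / (mc + 1))
    r1 = max(mc, md, me) > fpm_min
    r2 = abs(lfc) > lfc_min
    ci_c, ci_d, ci_e = (t_interval_oracle(v) for v in (control, disease, drug))

    def disjoint(a, b):
        return a[1] < b[0] or b[1] < a[0]

    r3 = disjoint(ci_c, ci_d)
    r4 = disjoint(ci_d, ci_e)
    r5 = not disjoint(ci_c, ci_e)
    return (r1, r2, r3, r4, r5), r1 and r2 and r3 and r4 and r5


class TestGroupCi:
    def test_zero_variance_point_interval(self):
        ci = group_ci([10, 10, 10, 10])
        assert ci.lower == pytest.approx(10) and ci.upper == pytest.approx(10)

    def test_matches_independent_t_interval_oracle(self):
        values = [10, 11, 9, 10]
        ci = group_ci(values)
        lo, hi = t_interval_oracle(values)
        assert ci.lower == pytest.approx(lo, rel=1e-9)
        assert ci.upper == pytest.approx(hi, rel=1e-9)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            group_ci([10])

    def test_linear_scale(self):
        ci = group_ci([10.0, 14.0], scale="linear")
        m, sd = 12.0, math.sqrt(8.0)
        half = stats.t.ppf(0.975, 1) * sd / math.sqrt(2)
        assert ci.lower == pytest.approx(m - half)
        assert ci.upper == pytest.approx(m + half)


class TestIntervalsOverlap:
    def test_identical_intervals_overlap(self):
        a = group_ci([5, 6, 7])
        assert intervals_overlap(a, a)

    def test_touching_endpoints_count_as_overlap(self):
        a = group_ci([0.5, 1.5])  # any intervals; override bounds directly
        b = group_ci([0.5, 1.5])
        a.lower, a.upper = 0.0, 1.0
        b.lower, b.upper = 1.0, 2.0
        b.estimate = 1.5
        assert intervals_overlap(a, b)
        b.lower = 1.1
        assert not intervals_overlap(a, b)

    def test_scale_mismatch_rejected(self):
        a = group_ci([1, 2, 3])
        b = group_ci([1, 2, 3], scale="linear")
        with pytest.raises(ValueError):
            intervals_overlap(a, b)


class TestStrategyB:
    def test_textbook_rescued_gene(self):
        control, disease, drug = [10, 11, 9, 10], [40, 44, 38, 42, 41], [11, 10, 12, 9, 10]
        call = classify_strategy_b("g", control, disease, drug)
        assert call.rules_passed == (True,) * 5
        assert call.strategy_b_sensitive
        assert call.direction_disease == "up"
        assert call.log2fc_disease == pytest.approx(math.log2(42 / 11))

    def test_identical_groups_fail_ci_separation(self):
        v = [10, 10, 10, 10]
        call = classify_strategy_b("g", v, v, v)
        assert not call.rules_passed[2]  # R3: identical CIs overlap
        assert not call.strategy_b_sensitive

    def test_abundance_gate_blocks_low_expression(self):
        call = classify_strategy_b("g", [0.1, 0.12, 0.11], [1.0, 1.1, 0.9],
                                   [0.1, 0.11, 0.09])
        assert not call.rules_passed[0]
        assert not call.strategy_b_sensitive

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            classify_strategy_b("g", [1], [1, 2], [1, 2])

    def test_equals_brute_force_on_random_genes(self):
        rng = np.random.default_rng(21)
        for _ in range(300):
            base = rng.lognormal(np.log(10), 1.5)
            groups = [list(base * rng.lognormal(rng.normal(0, 0.7), 0.4, size=n))
                      for n in (4, 5, 5)]
            call = classify_strategy_b("g", *groups)
            rules, sensitive = brute_force_five_rules(*groups)
            assert call.rules_passed == rules
            assert call.strategy_b_sensitive == sensitive

    def test_direction_partition(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            groups = [list(rng.lognormal(2, 1, size=n)) for n in (4, 5, 5)]
            call = classify_strategy_b("g", *groups)
            assert call.direction_disease in ("up", "down", "none")
            if call.direction_disease == "none":
                assert not call.strategy_b_sensitive

    def test_widening_ci_flips_rules_monotonically(self):
        """Raising the level can only break R3/R4 and only establish R5."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            groups = [list(rng.lognormal(3, 0.8, size=n)) for n in (4, 5, 5)]
            narrow = classify_strategy_b("g", *groups, ci_level=0.90)
            wide = classify_strategy_b("g", *groups, ci_level=0.99)
            for idx in (2, 3):  # disjointness rules
                assert not (wide.rules_passed[idx] and not narrow.rules_passed[idx])
            assert not (narrow.rules_passed[4] and not wide.rules_passed[4])


class TestStrategyA:
    @staticmethod
    def _de_pair(lfc_cd, deg_cd, lfc_ce, deg_ce):
        def mk(lfc, deg, name):
            table = pd.DataFrame(
                {"gene_id": ["g"], "log2fc": [lfc], "p_nb_wald": [0.01],
                 "p_mod_t": [0.01], "fdr_nb_wald": [0.01 if deg else 0.5],
                 "fdr_mod_t": [0.01 if deg else 0.5],
                 "consensus_deg": [deg], "degenerate": [False]})
            from txrescue.de import DEResult
            return DEResult(name, "control", "x", 0.05, table)
        return mk(lfc_cd, deg_cd, "control_vs_disease"), mk(lfc_ce, deg_ce,
                                                            "control_vs_disease_drug")

    def test_textbook_rescue(self):
        de_cd, de_ce = self._de_pair(2.0, True, 0.3, False)
        assert classify_strategy_a("g", de_cd, de_ce)

    def test_persistent_gene_not_normalized(self):
        de_cd, de_ce = self._de_pair(2.0, True, 1.8, True)
        assert not classify_strategy_a("g", de_cd, de_ce)

    def test_missing_gene_rejected(self):
        de_cd, de_ce = self._de_pair(2.0, True, 0.3, False)
        with pytest.raises(KeyError):
            classify_strategy_a("missing", de_cd, de_ce)

    def test_equals_boolean_oracle_on_random_tables(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            lfc_cd, lfc_ce = rng.normal(0, 2), rng.normal(0, 2)
            deg_cd, deg_ce = bool(rng.integers(2)), bool(rng.integers(2))
            de_cd, de_ce = self._de_pair(lfc_cd, deg_cd, lfc_ce, deg_ce)
            expected = (deg_cd and abs(lfc_cd) >= 1) and \
                       (not deg_ce and abs(lfc_ce) <= 1)
            assert classify_strategy_a("g", de_cd, de_ce) == expected


class TestSummarize:
    @staticmethod
    def synthetic_calls(n_up, n_down, sens_up, sens_down):
        """Call table with prescribed direction/sensitivity bookkeeping."""
        rows = []
        for i in range(n_up + n_down):
            direction = "up" if i < n_up else "down"
            sensitive = (i < sens_up) if direction == "up" \
                else (i - n_up < sens_down)
            rows.append({"gene_id": f"g{i}", "direction": direction,
                         "strategy_a": sensitive, "strategy_b": sensitive,
                         "log2fc_control_disease": 2.0 if direction == "up" else -2.0,
                         "log2fc_control_drug": 0.1})
        return pd.DataFrame(rows)

    def test_published_style_percentages(self):
        calls = self.synthetic_calls(1790, 2439 - 1790, 1000, 547)
        s = summarize_strategies(calls)
        assert round(s.pct_up) == 73
        cells = s.cells
        down_sens = cells[(cells["direction"] == "down")
                          & (cells["strategy"] == "A") & cells["sensitive"]]
        assert round(float(down_sens["pct_of_direction"].iloc[0])) == 84

    def test_counts_partition_regulated_total(self):
        calls = self.synthetic_calls(30, 20, 12, 5)
        s = summarize_strategies(calls)
        for strategy in ("A", "B"):
            sub = s.cells[s.cells["strategy"] == strategy]
            assert int(sub["n"].sum()) == s.n_regulated

    def test_empty_sensitive_set(self):
        calls = self.synthetic_calls(5, 5, 0, 0)
        s = summarize_strategies(calls)
        assert s.jaccard_ab == 0.0 and s.overlap_a_in_b == 0.0
        sens = s.cells[s.cells["sensitive"]]
        assert (sens["pct_of_direction"] == 0).all()


class TestClassifyStudy:
    def test_vectorized_matches_per_gene_calls(self, three_group_counts):
        cm = three_group_counts
        am = normalize_fpm(cm)
        de_cd = run_de(cm, ("control", "disease"))
        de_ce = run_de(cm, ("control", "disease_drug"))
        table = classify_study(am, de_cd, de_ce)
        for i in (0, 1, 7, 33):
            call = classify_strategy_b(
                cm.gene_ids[i],
                am.group_values(i, "control"),
                am.group_values(i, "disease"),
                am.group_values(i, "disease_drug"),
            )
            row = table.iloc[i]
            got = tuple(bool(row[c]) for c in
                        ("r1_abundance", "r2_lfc", "r3_ctrl_dis_disjoint",
                         "r4_dis_drug_disjoint", "r5_ctrl_drug_overlap"))
            assert got == call.rules_passed
            assert bool(row["strategy_b"]) == call.strategy_b_sensitive
        # the planted rescued gene is found by both strategies
        assert bool(table.iloc[0]["strategy_b"])
        assert bool(table.iloc[0]["strategy_a"])
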