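import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from telodiff import (
    QpcrTable,
    ValidationError,
    analyze_qpcr,
    randomisation_test,
    read_qpcr,
    relative_ratio,
    select_housekeeper,
    simulate_qpcr,
)


def table_from_cq(cq_by_gene, groups, efficiency=None, housekeeping=()):
    """Build a QpcrTable from per-gene sample-level Cq lists (duplicated wells)."""
    rows = []
    samples = [f"s{i}" for i in range(len(groups))]
    for gene, cqs in cq_by_gene.items():
        for s, g, cq in zip(samples, groups, cqs):
            for rep in (1, 2):
                rows.append(
                    {"sample": s, "group": g, "gene": gene, "replicate": rep, "cq": cq}
                )
    return QpcrTable(pd.DataFrame(rows), dict(efficiency or {}), list(housekeeping))


GROUPS_33 = ["case"] * 3 + ["control"] * 3


class TestSelectHousekeeper:
    def test_most_stable_candidate_selected(self):
        t = table_from_cq(
            {
                "HK1": [20, 21, 22, 20, 21, 22],
                "HK2": [20, 20, 20, 20, 20, 20],
                "G": [25, 25, 25, 25, 25, 25],
            },
            GROUPS_33,
            housekeeping=["HK1", "HK2"],
        )
        assert select_housekeeper(t) == "HK2"

    def test_single_candidate_returned(self):
        t = table_from_cq(
            {"HK1": [20] * 6, "G": [25] * 6}, GROUPS_33, housekeeping=["HK1"]
        )
        assert select_housekeeper(t) == "HK1"

    def test_tie_broken_by_input_order(self):
        t = table_from_cq(
            {"HK1": [20] * 6, "HK2": [20] * 6}, GROUPS_33,
            housekeeping=["HK1", "HK2"],
        )
        assert select_housekeeper(t) == "HK1"

    def test_incomplete_candidates_rejected(self):
        rows = pd.DataFrame(
            [
                {"sample": "s0", "group": "case", "gene": "HK", "replicate": 1, "cq": 20.0},
                {"sample": "s1", "group": "control", "gene": "G", "replicate": 1, "cq": 22.0},
            ]
        )
        t = QpcrTable(rows, {}, ["HK"])
        with pytest.raises(ValidationError, match="complete"):
            select_housekeeper(t)


class TestRelativeRatio:
    def test_no_difference_gives_unit_ratio(self):
        t = table_from_cq(
            {"G": [25] * 6, "HK": [20] * 6}, GROUPS_33
        )
        assert relative_ratio(t, "G", "HK") == pytest.approx(1.0)

    def test_two_cycle_delay_quarters_expression(self):
        # case Cq two cycles later, reference unchanged, E = 2 -> 2^-2
        t = table_from_cq(
            {"G": [27, 27, 27, 25, 25, 25], "HK": [20] * 6}, GROUPS_33
        )
        assert relative_ratio(t, "G", "HK") == pytest.approx(0.25)

    def test_equal_shift_cancels(self):
        t = table_from_cq(
            {"G": [27, 27, 27, 25, 25, 25], "HK": [22, 22, 22, 20, 20, 20]},
            GROUPS_33,
        )
        assert relative_ratio(t, "G", "HK") == pytest.approx(1.0)

    def test_equals_ddcq_oracle_when_efficiency_two(self):
        # oracle: classic 2^(-ddCq) computed directly from group means
        rng = np.random.default_rng(8)
        for _ in range(100):
            g = rng.normal(25, 2, size=6)
            hk = rng.normal(20, 1, size=6)
            t = table_from_cq({"G": g, "HK": hk}, GROUPS_33)
            d_target = g[:3].mean() - g[3:].mean()
            d_ref = hk[:3].mean() - hk[3:].mean()
            ddcq = d_target - d_ref
            assert relative_ratio(t, "G", "HK") == pytest.approx(
                2.0 ** (-ddcq), rel=1e-12
            )

    def test_missing_group_rejected(self):
        t = table_from_cq({"G": [25] * 4, "HK": [20] * 4}, ["case"] * 4)
        with pytest.raises(ValidationError, match="both groups"):
            relative_ratio(t, "G", "HK")


class TestRandomisationTest:
    def test_identical_groups_give_p_one(self):
        t = table_from_cq({"G": [25] * 6, "HK": [20] * 6}, GROUPS_33)
        p, _ = randomisation_test(t, "G", "HK")
        assert p == 1.0

    def test_noiseless_shift_attains_exhaustive_minimum(self):
        # 6 vs 6, planted 4-cycle shift: only the true assignment and its
        # group-swapped complement reach the observed |log2 ratio|
        t = simulate_qpcr(6, ["G"], ["HK"], {"G": -4.0}, cq_noise_sd=0.0, seed=3)
        p, n = randomisation_test(t, "G", "HK")
        assert n == math.comb(12, 6) == 924
        assert p == pytest.approx(2 / 924)

    def test_group_relabelling_invariance(self):
        rng = np.random.default_rng(12)
        g = rng.normal(25, 1, size=6)
        hk = rng.normal(20, 0.5, size=6)
        t1 = table_from_cq({"G": g, "HK": hk}, GROUPS_33)
        t2 = table_from_cq({"G": g, "HK": hk},
                           ["control"] * 3 + ["case"] * 3)
        p1, _ = randomisation_test(t1, "G", "HK")
        p2, _ = randomisation_test(t2, "G", "HK")
        assert p1 == pytest.approx(p2)

    def test_exhaustive_matches_bruteforce_oracle(self):
        # independent enumeration over all C(6,3) reallocations
        rng = np.random.default_rng(21)
        g = rng.normal(25, 1, size=6)
        hk = rng.normal(20, 0.5, size=6)
        t = table_from_cq({"G": g, "HK": hk}, GROUPS_33)
        p, n = randomisation_test(t, "G", "HK")

        def ratio(case_idx):
            case = np.array([i in case_idx for i in range(6)])
            dt = g[~case].mean() - g[case].mean()
            dr = hk[~case].mean() - hk[case].mean()
            return abs(np.log2(2.0**dt / 2.0**dr))

        obs = ratio((0, 1, 2))
        count = sum(ratio(c) >= obs - 1e-12 for c in combinations(range(6), 3))
        assert p == pytest.approx(count / 20) and n == 20

    def test_monte_carlo_agrees_with_exhaustive(self):
        t = simulate_qpcr(6, ["G"], ["HK"], {"G": -0.6}, cq_noise_sd=0.4, seed=17)
        p_ex, n_ex = randomisation_test(t, "G", "HK", n_perm=2000)
        assert n_ex == 924
        rng = np.random.default_rng(99)
        p_mc, n_mc = randomisation_test(t, "G", "HK", n_perm=500, rng=rng)
        assert n_mc == 500
        se = math.sqrt(p_ex * (1 - p_ex) / 500)
        assert abs(p_mc - p_ex) <= 2 * se + 1 / 500

    def test_type_i_error_near_nominal(self):
        # null tables: reject rate at p<0.05 close to (and bounded near) 0.05
        rejections = 0
        n_tables = 500
        rng = np.random.default_rng(31)
        for i in range(n_tables):
            g = rng.normal(25, 0.5, size=8)
            hk = rng.normal(20, 0.5, size=8)
            t = table_from_cq({"G": g, "HK": hk}, ["case"] * 4 + ["control"] * 4)
            p, _ = randomisation_test(t, "G", "HK")
            rejections += p < 0.05
        rate = rejections / n_tables
        assert abs(rate - 0.05) <= 0.03

    def test_single_group_degenerate_rejected(self):
        t = table_from_cq({"G": [25] * 4, "HK": [20] * 4},
                          ["case", "case", "case", "control"])
        with pytest.raises(ValidationError, match="at least 2"):
            randomisation_test(t, "G", "HK")


class TestTableAndIO:
    def test_bad_efficiency_rejected(self):
        with pytest.raises(ValidationError, match="efficiency"):
            table_from_cq({"G": [25] * 6}, GROUPS_33, efficiency={"G": 3.0})

    def test_nonpositive_cq_rejected(self):
        rows = pd.DataFrame(
            [{"sample": "s0", "group": "case", "gene": "G", "replicate": 1, "cq": -1.0}]
        )
        with pytest.raises(ValidationError, match="Cq"):
            QpcrTable(rows)

    def test_round_trip_and_analysis(self, tmp_path):
        t = simulate_qpcr(
            4, ["G1", "G2"], ["HK1", "HK2"], {"G1": -2.0},
            cq_noise_sd=0.0, seed=5,
        )
        t.write(tmp_path / "wells.tsv")
        back = read_qpcr(tmp_path / "wells.tsv", housekeeping=["HK1", "HK2"])
        res = analyze_qpcr(back, seed=1).set_index("gene")
        assert res.loc["G1", "ratio"] == pytest.approx(0.25, abs=1e-10)
        assert res.loc["G2", "ratio"] == pytest.approx(1.0, abs=1e-10)
        assert res.loc["G1", "p_perm"] < 0.05
        assert "HK1" not in res.index
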