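"""Adaptive regulation calling: fold change, CUT, Welch test, WIR/WPR."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import genefabric as gf
from genefabric.regulation import (
    call_regulome,
    cut_value,
    false_hit_audit,
    fold_change,
    regulation_test,
    wir,
    wpr,
)


class TestFoldChange:
    @pytest.mark.parametrize("c,r,expected", [(2.0, 2.0, 1.0), (1.0, 2.0, -2.0), (6.0, 2.0, 3.0)])
    def test_reciprocal_convention(self, c, r, expected):
        assert fold_change(c, r) == pytest.approx(expected)

    @given(a=st.floats(0.01, 100), b=st.floats(0.01, 100))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, a, b):
        if not math.isclose(a, b):
            assert fold_change(a, b) == pytest.approx(-fold_change(b, a))

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 1.0)


class TestCut:
    def test_zero_rev_gives_unit_cut(self):
        assert cut_value(0.0, 0.0) == 1.0

    def test_equal_revs(self):
        # both REVs at 38.8% put CUT in the regime of printed per-gene cutoffs
        assert cut_value(38.8, 38.8) == pytest.approx(1.5487, abs=1e-3)
        assert 1.38 <= cut_value(38.8, 38.8) <= 1.90

    def test_strictly_increasing_in_each_rev(self):
        base = cut_value(20.0, 30.0)
        assert cut_value(25.0, 30.0) > base
        assert cut_value(20.0, 35.0) > base

    def test_negative_rev_rejected(self):
        with pytest.raises(ValueError):
            cut_value(-1.0, 10.0)


class TestWelch:
    def test_identical_groups_p_one(self):
        assert regulation_test([1, 1, 1, 1], [1, 1, 1, 1]) == 1.0

    def test_zero_variance_different_means(self):
        assert regulation_test([2, 2, 2], [1, 1, 1]) == 0.0

    def test_matches_hand_coded_welch_oracle(self):
        """Equals an independent Welch-Satterthwaite implementation."""

        def welch_oracle(x, y):
            from scipy import stats as sps

            x, y = np.asarray(x, float), np.asarray(y, float)
            vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
            t = (x.mean() - y.mean()) / math.sqrt(vx + vy)
            df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
            return 2 * sps.t.sf(abs(t), df)

        rng = np.random.default_rng(3)
        for _ in range(25):
            x = rng.lognormal(size=4)
            y = rng.lognormal(sigma=2.0, size=4)
            assert regulation_test(x, y) == pytest.approx(welch_oracle(x, y), abs=1e-10)

    def test_planted_fold_four_detected(self):
        """Fold 4 at CV 10%, n = 4 is essentially always significant."""
        hits = 0
        n_seeds = 40
        rng = np.random.default_rng(8)
        for _ in range(n_seeds):
            ref = rng.normal(1.0, 0.1, 4)
            can = rng.normal(4.0, 0.4, 4)
            hits += regulation_test(can, ref) < 0.05
        assert hits / n_seeds >= 0.95


class TestWir:
    def test_printed_low_expression_case(self):
        assert abs(wir(3.30, -2.47, 0.0242)) == pytest.approx(4.73, abs=5e-3)
        assert wir(3.30, -2.47, 0.0242) < 0  # down-regulation carries the sign

    def test_printed_high_expression_case(self):
        # unrounded inputs in the source give 95.74; rounded ones land nearby
        assert abs(wir(94.30, -2.12, 0.0969)) == pytest.approx(95.4, abs=0.4)

    def test_no_change_gives_zero(self):
        assert wir(10.0, 1.0, 0.5) == 0.0

    def test_monotonicity(self):
        base = abs(wir(10.0, 2.0, 0.1))
        assert abs(wir(20.0, 2.0, 0.1)) > base
        assert abs(wir(10.0, 3.0, 0.1)) > base
        assert abs(wir(10.0, 2.0, 0.5)) < base


def _records(rows):
    return pd.DataFrame(rows, columns=["gene", "contrast", "x", "CUT", "p", "significant", "WIR"])


class TestRegulomeCalls:
    def test_printed_decisions(self):
        """An adaptive cutoff admits a modest fold on a stable gene and
        rejects a large fold with a weak p-value."""
        rec = _records(
            [
                ("CREB3L4", "PTA->NOR", -1.40, 1.38, 0.040, None, -1.0),
                ("DNM1", "PTB->NOR", -2.12, 1.66, 0.0969, None, -95.0),
                ("FLAT", "PTA->NOR", 1.0, 1.2, 0.001, None, 0.0),
            ]
        )
        reg = call_regulome(rec)
        assert list(reg["gene"]) == ["CREB3L4"]
        assert reg["direction"].iloc[0] == "down"

    def test_regulome_never_contains_weak_p(self, expression_set, gene_stats):
        rec = gf.build_regulation_table(gene_stats, expression_set, "PTA", "NOR")
        reg = call_regulome(rec)
        assert (reg["p"] < 0.05).all()
        assert (reg["x"].abs() > reg["CUT"]).all()

    def test_planted_folds_recovered(self, expression_set, gene_stats):
        rec_a = gf.build_regulation_table(gene_stats, expression_set, "PTA", "NOR").set_index("gene")
        rec_b = gf.build_regulation_table(gene_stats, expression_set, "PTB", "NOR").set_index("gene")
        assert rec_a.loc["G0001", "significant"]
        assert rec_a.loc["G0001", "x"] > 1
        assert rec_b.loc["G0010", "significant"]
        assert rec_b.loc["G0010", "x"] < -1


class TestFalseHitAudit:
    def test_false_negative_and_positive(self):
        rec = _records(
            [
                ("FN", "PTA->NOR", -1.40, 1.38, 0.040, None, -1.0),  # |x| < 1.5 yet significant
                ("FP", "PTA->NOR", 1.60, 1.70, 0.020, None, 1.0),   # |x| > 1.5 but below its CUT
                ("OK", "PTA->NOR", 1.20, 1.30, 0.200, None, 0.1),   # neither list
            ]
        )
        fp, fn = false_hit_audit(rec)
        assert list(fp["gene"]) == ["FP"]
        assert list(fn["gene"]) == ["FN"]

    def test_adaptive_rule_stricter_for_noisy_genes(self):
        """On null data the CUT rule calls fewer noisy genes (REV > 50%)
        than the uniform |x| > 1.5 rule."""
        cfg = gf.SyntheticConfig(n_genes=400, n_conditions=2, cv_range=(0.15, 0.8), seed=21)
        table, _ = gf.generate_dataset(cfg)
        es = gf.normalize(gf.filter_probes(table))
        stats_df = gf.compute_descriptors(es)
        rec = gf.build_regulation_table(stats_df, es, "PTA", "NOR")
        noisy = stats_df[(stats_df["condition"] == "NOR") & (stats_df["REV"] > 50)]["gene"]
        sub = rec[rec["gene"].isin(set(noisy))]
        cut_calls = ((sub["x"].abs() > sub["CUT"]) & (sub["p"] < 0.05)).sum()
        uniform_calls = ((sub["x"].abs() > 1.5) & (sub["p"] < 0.05)).sum()
        assert cut_calls <= uniform_calls


class TestWpr:
    def test_single_gene_pathway(self):
        rec = _records([("A", "c", 2.0, 1.2, 0.01, True, 4.4)])
        assert wpr(["A"], rec) == pytest.approx(4.4)

    def test_unregulated_pathway_is_zero(self):
        rec = _records([("A", "c", 1.0, 1.2, 0.9, False, 0.0), ("B", "c", 1.0, 1.1, 0.5, False, 0.0)])
        assert wpr(["A", "B"], rec) == 0.0

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(4)
        wirs = rng.normal(size=5)
        rec = _records([(f"g{i}", "c", 2.0, 1.5, 0.1, True, w) for i, w in enumerate(wirs)])
        assert wpr([f"g{i}" for i in range(5)], rec) == pytest.approx(
            float(np.mean(np.abs(wirs))), abs=1e-12
        )

    def test_empty_pathway_rejected(self):
        with pytest.raises(ValueError):
            wpr(["missing"], _records([("A", "c", 1.0, 1.1, 0.5, False, 0.0)]))
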