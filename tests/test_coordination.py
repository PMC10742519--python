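"""Pairwise coordination: COR, significance thresholds, classes, COORD."""

import math

import numpy as np
import pandas as pd
import pytest

import genefabric as gf
from genefabric.coordination import (
    CorRecord,
    PairClass,
    classify_matrix,
    classify_pair,
    coord_score,
    coordination_profile,
    coordination_score,
    cor_pair,
    critical_cor,
    delta_cor,
    pearson_pvalue,
)


class TestCorPair:
    def test_self_correlation_is_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        rec = cor_pair(x, x)
        assert rec.cor == pytest.approx(1.0)
        assert classify_pair(rec) is PairClass.SYN

    @pytest.mark.parametrize(
        "cor,m,expected,places",
        [(-0.96624, 4, 0.0338, 4), (0.958562, 4, 0.04144, 5), (0.970449, 4, 0.02955, 5)],
    )
    def test_p_values_from_printed_correlations(self, cor, m, expected, places):
        assert round(pearson_pvalue(cor, m), places) == expected

    def test_zero_variance_flagged_undefined(self):
        rec = cor_pair([2, 2, 2, 2], [1, 2, 3, 4])
        assert math.isnan(rec.cor)
        assert classify_pair(rec) is PairClass.NONE

    def test_matches_scipy_pearson(self):
        rng = np.random.default_rng(0)
        from scipy import stats as sps

        for _ in range(20):
            x = rng.lognormal(size=6)
            y = rng.lognormal(size=6)
            rec = cor_pair(x, y)
            r, p = sps.pearsonr(np.log2(x), np.log2(y))
            assert rec.cor == pytest.approx(r, abs=1e-12)
            assert rec.p == pytest.approx(p, abs=1e-12)


class TestCriticalCor:
    @pytest.mark.parametrize("m,expected", [(4, 0.95), (8, 0.71), (12, 0.58)])
    def test_printed_thresholds(self, m, expected):
        assert round(critical_cor(m), 2) == expected

    def test_strictly_decreasing_in_m(self):
        vals = [critical_cor(m) for m in range(3, 40)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_matches_permutation_oracle(self):
        """Brute-force null: max |r| quantile over permutations of one
        profile approximates the analytic two-tailed critical value."""
        rng = np.random.default_rng(1)
        for m in (4, 8, 12):
            rs = []
            for _ in range(4000):
                x = rng.standard_normal(m)
                y = rng.standard_normal(m)
                rs.append(abs(np.corrcoef(x, y)[0, 1]))
            emp = np.quantile(rs, 0.95)
            assert emp == pytest.approx(critical_cor(m), abs=0.02)

    def test_m_below_3_rejected(self):
        with pytest.raises(ValueError):
            critical_cor(2)


class TestClassify:
    @pytest.mark.parametrize(
        "cor,m,expected",
        [
            (0.3, 4, PairClass.NONE),
            (-0.96624, 4, PairClass.ANT),
            (0.0, 4, PairClass.IND),
            (0.05, 4, PairClass.IND),  # tie at the independence cut
            (0.96, 4, PairClass.SYN),
            (0.72, 8, PairClass.SYN),
            (-0.60, 12, PairClass.ANT),
        ],
    )
    def test_labels(self, cor, m, expected):
        rec = CorRecord(cor, m, pearson_pvalue(cor, m))
        assert classify_pair(rec) is expected


def _cormat(values, genes):
    return pd.DataFrame(values, index=genes, columns=genes)


class TestCoordScore:
    @pytest.mark.parametrize(
        "syn,ant,ind,expected",
        [(20.76, 20.76, 4.68, 36.84), (12.28, 9.65, 12.28, 9.65), (0.0, 0.0, 100.0, -100.0)],
    )
    def test_identity(self, syn, ant, ind, expected):
        assert coordination_score(syn, ant, ind) == pytest.approx(expected, abs=1e-9)

    def test_from_matrix(self):
        genes = ["A", "B", "C", "D"]
        C = np.eye(4)
        C[0, 1] = C[1, 0] = 0.99   # SYN
        C[0, 2] = C[2, 0] = -0.97  # ANT
        C[0, 3] = C[3, 0] = 0.01   # IND
        C[1, 2] = C[2, 1] = 0.5    # NONE
        C[1, 3] = C[3, 1] = np.nan  # undefined, stays in denominator
        C[2, 3] = C[3, 2] = 0.02   # IND
        s = coord_score(_cormat(C, genes), m=4, pathway="P", condition="NOR")
        assert s.n_pairs == 6
        assert s.pct_syn == pytest.approx(100 / 6)
        assert s.pct_ant == pytest.approx(100 / 6)
        assert s.pct_ind == pytest.approx(200 / 6)
        assert s.coord == pytest.approx(s.pct_syn + s.pct_ant - s.pct_ind, abs=1e-9)

    def test_single_gene_pathway_rejected(self):
        with pytest.raises(ValueError):
            coord_score(_cormat([[1.0]], ["A"]), m=4)


class TestProfileAndDelta:
    def test_profile_excludes_self_and_insignificant(self):
        genes = ["A", "B", "C"]
        C = np.array([[1.0, 0.99, 0.3], [0.99, 1.0, 0.0], [0.3, 0.0, 1.0]])
        prof = coordination_profile("A", _cormat(C, genes), m=4)
        assert prof == [("B", PairClass.SYN)]

    def test_gene_with_no_significant_partner(self):
        genes = ["A", "B"]
        C = np.array([[1.0, 0.4], [0.4, 1.0]])
        assert coordination_profile("A", _cormat(C, genes), m=4) == []

    def test_missing_gene_raises(self):
        with pytest.raises(KeyError):
            coordination_profile("Z", _cormat(np.eye(2), ["A", "B"]), m=4)

    def test_delta_cor_zero_for_identical_structure(self):
        C = _cormat(np.array([[1.0, 0.5], [0.5, 1.0]]), ["A", "B"])
        res = delta_cor("A", ["A", "B"], C, C.copy())
        assert res.value == 0.0

    def test_delta_cor_bound_case(self):
        genes = [f"g{i}" for i in range(11)]
        full = _cormat(np.ones((11, 11)), genes)
        none = _cormat(np.eye(11), genes)
        res = delta_cor("g0", genes, full, none)
        assert res.value == pytest.approx(10.0)
        assert res.n_pairs == 10

    def test_delta_cor_skips_undefined_pairs(self):
        C1 = _cormat(np.array([[1, 0.9, np.nan], [0.9, 1, 0], [np.nan, 0, 1]]), list("ABC"))
        C0 = _cormat(np.eye(3), list("ABC"))
        res = delta_cor("A", list("ABC"), C1, C0)
        assert res.n_skipped == 1
        assert res.value == pytest.approx(0.9)


class TestOnSyntheticData:
    def test_block_pairs_classified_synergistic(self, expression_set, small_config):
        """Block mates at loading 0.99 land SYN in the profile for most
        pairs of the fixture."""
        block = list(small_config.correlation_blocks[0][0])
        cormat, m = gf.correlation_matrix(expression_set, "NOR")
        labels = classify_matrix(cormat.loc[block, block], m)
        iu = np.triu_indices(len(block), 1)
        frac_syn = (labels.to_numpy()[iu] == "SYN").mean()
        assert frac_syn > 0.5

    def test_sign_recovery_in_majority_of_seeds(self):
        """Planted +/- pairs at loading 0.99 classified SYN/ANT in the
        majority of seeds (realistic array: 400 genes, CV 20%)."""
        syn_hits = ant_hits = 0
        n_seeds = 12
        for s in range(n_seeds):
            cfg = gf.SyntheticConfig(
                n_genes=400, n_conditions=1, cv_range=(0.2, 0.2),
                correlation_blocks=[(["G0001", "G0002"], 0.99), (["G0003", "G0004"], -0.99)],
                seed=5000 + s,
            )
            table, _ = gf.generate_dataset(cfg)
            es = gf.normalize(gf.filter_probes(table))
            cormat, m = gf.correlation_matrix(es, "NOR")
            r_star = critical_cor(m)
            syn_hits += cormat.loc["G0001", "G0002"] >= r_star
            ant_hits += cormat.loc["G0003", "G0004"] <= -r_star
        assert syn_hits / n_seeds > 0.5
        assert ant_hits / n_seeds > 0.5

    def test_spot_mode_gives_more_paired_values(self, expression_set):
        cormat, m = gf.correlation_matrix(
            expression_set, "NOR", genes=["G0020"], mode="spot"
        )
        assert m == expression_set.upsilon["G0020"] * expression_set.n_replicas
        assert m > expression_set.n_replicas

    def test_spot_mode_requires_equal_spot_counts(self, expression_set):
        with pytest.raises(ValueError, match="equal spot counts"):
            gf.correlation_matrix(expression_set, "NOR", genes=["G0001", "G0020"], mode="spot")

    def test_classification_matrix_symmetric(self, expression_set):
        cormat, m = gf.correlation_matrix(expression_set, "NOR")
        labels = classify_matrix(cormat, m)
        assert (labels.to_numpy() == labels.to_numpy().T).all()
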