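import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import fisher_oracle
from tcrep.errors import ValidationError
from tcrep.repertoire import Clonotype, Repertoire
from tcrep.stats import (
    add_cd8_treg,
    chi_square_gof,
    cluster_flow_profiles,
    derive_prognosis_label,
    dunn_posthoc,
    fisher_exact_2x2,
    kruskal_wallis,
    pearson_r,
    peptide_prognosis_association,
)


class TestPrognosisLabel:
    @pytest.mark.parametrize("rfs,responded,expected", [
        (3.0, False, "worst"),
        (3.0, True, "poor"),
        (6.0, True, "good"),      # boundary: exactly 6 months
        (12.0, True, "good"),
        (12.1, True, "excellent"),
    ])
    def test_derivation(self, rfs, responded, expected):
        assert derive_prognosis_label("p", rfs, responded).label == expected

    def test_negative_rfs(self):
        with pytest.raises(ValidationError):
            derive_prognosis_label("p", -1.0, True)


class TestCd8Treg:
    def test_ratio_and_missing(self):
        flow = pd.DataFrame({"cd8": [30.0, 10.0], "cd4_foxp3": [5.0, 0.0]},
                            index=["a", "b"])
        out = add_cd8_treg(flow)
        assert out.loc["a", "cd8_treg"] == pytest.approx(6.0)
        assert np.isnan(out.loc["b", "cd8_treg"])


class TestKruskalWallis:
    def test_hand_oracle(self):
        # frozen from a hand evaluation of the rank-sum formula
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res["statistic"] == pytest.approx(7.2, abs=1e-12)
        assert res["dof"] == 2

    def test_all_identical(self):
        res = kruskal_wallis([[5, 5, 5], [5, 5, 5], [5, 5, 5]])
        assert res["statistic"] == 0.0
        assert res["p_value"] == 1.0

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            groups = [rng.integers(0, 6, size=rng.integers(3, 10)).tolist()
                      for _ in range(3)]
            if len({v for g in groups for v in g}) == 1:
                continue
            ours = kruskal_wallis(groups)
            ref = sps.kruskal(*groups)
            assert ours["statistic"] == pytest.approx(ref.statistic, abs=1e-10)
            assert ours["p_value"] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_two_groups_equal_squared_standardized_rank_sum(self):
        # with two groups, H equals z^2 of the standardized rank-sum
        rng = np.random.default_rng(5)
        a = rng.normal(size=8).tolist()
        b = rng.normal(1.0, size=11).tolist()
        h = kruskal_wallis([a, b])["statistic"]
        n, na = 19, 8
        ranks = sps.rankdata(a + b)
        ra = ranks[:na].sum()
        mean = na * (n + 1) / 2
        var = na * (n - na) * (n + 1) / 12
        z = (ra - mean) / np.sqrt(var)
        assert h == pytest.approx(z**2, abs=1e-10)

    def test_monotone_transform_invariance(self):
        groups = [[1.0, 2, 3], [2.5, 5, 6], [7, 8, 9.5]]
        res1 = kruskal_wallis(groups)
        res2 = kruskal_wallis([[np.exp(v) for v in g] for g in groups])
        assert res1["statistic"] == pytest.approx(res2["statistic"])


class TestDunn:
    def test_extreme_pair_has_largest_z(self):
        res = dunn_posthoc([[1, 2, 3], [4, 5, 6], [7, 8, 9]],
                           labels=["lo", "mid", "hi"])
        res["absz"] = res.z.abs()
        top = res.sort_values("absz", ascending=False).iloc[0]
        assert {top.group_a, top.group_b} == {"lo", "hi"}

    def test_bh_adjustment_monotone(self):
        res = dunn_posthoc([[1, 2, 3], [4, 5, 6], [7, 8, 9]], adjust="bh")
        assert (res.p_adjusted >= res.p_value - 1e-12).all()

    def test_null_is_not_systematically_significant(self):
        rng = np.random.default_rng(17)
        rejections, total = 0, 0
        for _ in range(50):
            pooled = rng.normal(size=24)
            groups = np.split(rng.permutation(pooled), 3)
            res = dunn_posthoc([g.tolist() for g in groups])
            rejections += int((res.p_value < 0.05).sum())
            total += len(res)
        assert rejections / total < 0.12

    def test_empty_group_excluded(self):
        res = dunn_posthoc([[1, 2], [], [3, 4]], labels=["a", "b", "c"])
        assert set(res.group_a) | set(res.group_b) == {"a", "c"}


class TestFisher:
    def test_enumeration_example(self):
        assert fisher_exact_2x2([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_symmetric_table(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_degenerate_margin(self):
        assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0

    def test_matches_scipy_and_oracle_random(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 12, size=4)
            ours = fisher_exact_2x2([[a, b], [c, d]])
            assert ours == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-10)
            assert ours == pytest.approx(
                sps.fisher_exact([[a, b], [c, d]])[1], abs=1e-9)


class TestChiSquareGof:
    def test_proportional(self):
        res = chi_square_gof([50, 50], [0.5, 0.5])
        assert res["statistic"] == 0.0
        assert res["p_value"] == pytest.approx(1.0)

    def test_direct_formula(self):
        res = chi_square_gof([10, 0], [0.5, 0.5])
        assert res["statistic"] == pytest.approx(10.0)

    def test_single_category_error(self):
        with pytest.raises(ValidationError):
            chi_square_gof([10], [1.0])


class TestPearson:
    def test_perfect_linear(self):
        assert pearson_r([1, 2, 3], [3, 5, 7])["r"] == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert pearson_r([1, 2, 3], [-1, -2, -3])["r"] == pytest.approx(-1.0)

    def test_hand_computation(self):
        res = pearson_r([1, 2, 3, 4], [1, 3, 2, 4])
        assert res["r"] == pytest.approx(0.8, abs=1e-12)

    def test_zero_variance_flagged(self):
        res = pearson_r([1, 1, 1], [1, 2, 3])
        assert not res["defined"]


def four_group_cohort(rng, planted_excellent=None, n_per_group=5):
    reps, labels = [], {}
    for g in ("worst", "poor", "good", "excellent"):
        for i in range(n_per_group):
            pid = f"{g}{i}"
            labels[pid] = g
            clones = [Clonotype(f"CASS{pid.upper()}F", templates=5)]
            for k in range(4):
                clones.append(Clonotype(
                    "C" + "".join(rng.choice(list("ACDEFGHIK"), 8)) + "F",
                    templates=int(rng.integers(1, 6))))
            if planted_excellent and g == "excellent":
                clones.append(Clonotype(planted_excellent, templates=4))
            reps.append(Repertoire(pid, clones))
    return reps, labels


class TestPeptideAssociation:
    def test_planted_excellent_peptide_associated(self):
        rng = np.random.default_rng(21)
        reps, labels = four_group_cohort(rng, planted_excellent="CASSLVNTEAFF")
        table = peptide_prognosis_association(reps, labels)
        row = table[table.cdr3_aa == "CASSLVNTEAFF"].iloc[0]
        assert bool(row.associated)

    def test_uniform_peptide_not_associated(self):
        reps, labels = [], {}
        for g in ("worst", "poor", "good", "excellent"):
            for i in range(4):
                pid = f"{g}{i}"
                labels[pid] = g
                reps.append(Repertoire(pid, [
                    Clonotype("CASSLVNTEAFF", templates=5),
                    Clonotype(f"CASS{pid.upper()}F", templates=5)]))
        table = peptide_prognosis_association(reps, labels)
        row = table[table.cdr3_aa == "CASSLVNTEAFF"].iloc[0]
        assert not bool(row.associated)

    def test_shuffled_labels_type_one_control(self):
        rng = np.random.default_rng(33)
        reps, labels = four_group_cohort(rng, n_per_group=6)
        pids = sorted(labels)
        flagged, tested = 0, 0
        for _ in range(25):
            shuffled = dict(zip(pids, rng.permutation([labels[p]
                                                       for p in pids])))
            table = peptide_prognosis_association(reps, shuffled)
            flagged += int(table.associated.sum())
            tested += len(table)
        if tested:
            assert flagged / tested < 0.12


class TestFlowClustering:
    def test_duplicated_rows_forced_k2(self):
        a = [10.0, 1.0, 8.0, 2.0]
        b = [1.0, 10.0, 2.0, 8.0]
        flow = pd.DataFrame([a] * 4 + [b] * 4,
                            columns=["m1", "m2", "m3", "m4"],
                            index=[f"p{i}" for i in range(8)])
        res = cluster_flow_profiles(flow, k_range=range(1, 5), b_refs=10,
                                    seed=1)
        assert res["k"] == 2
        lab = res["labels"]
        assert len(set(lab.iloc[:4])) == 1
        assert len(set(lab.iloc[4:])) == 1
        assert lab.iloc[0] != lab.iloc[-1]

    def test_two_blobs_selects_k2(self):
        chosen = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = np.abs(rng.normal([20, 20, 4, 4], 3.0, size=(8, 4)))
            b = np.abs(rng.normal([4, 4, 20, 20], 3.0, size=(8, 4)))
            flow = pd.DataFrame(np.vstack([a, b]),
                                columns=["m1", "m2", "m3", "m4"])
            res = cluster_flow_profiles(flow, k_range=range(1, 5), b_refs=20,
                                        seed=seed + 100)
            chosen.append(res["k"])
        assert sum(k == 2 for k in chosen) >= 8

    def test_homogeneous_blob_prefers_k1(self):
        chosen = []
        for seed in range(10):
            rng = np.random.default_rng(seed + 50)
            flow = pd.DataFrame(np.abs(rng.normal(10, 3, size=(12, 4))),
                                columns=["m1", "m2", "m3", "m4"])
            res = cluster_flow_profiles(flow, k_range=range(1, 5), b_refs=20,
                                        seed=seed + 300)
            chosen.append(res["k"])
        assert sum(k == 1 for k in chosen) >= 6

    def test_too_small_input_rejected(self):
        flow = pd.DataFrame({"m1": [1.0, 2.0], "m2": [2.0, 1.0]})
        with pytest.raises(ValidationError):
            cluster_flow_profiles(flow)
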