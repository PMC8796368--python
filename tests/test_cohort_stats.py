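"""Cohort statistics: ICC, pairings, D statistics, correlated-p combination."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from methdep import (
    ProbeManifest,
    SampleSheet,
    age_group_contrast,
    build_pairing,
    combine_correlated_pvalues,
    icc_oneway,
    island_proportions,
    mann_whitney_one_sided,
    pair_squared_diffs,
    relative_range,
    select_one_per_family,
    select_representative_pairing,
    spearman_with_ci,
)


def toy_sheet(n_pairs=20, n_plates=2, zygosity=("MZ", "DZ"), seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for f in range(n_pairs):
        plate = f % n_plates
        chip = f // 3
        zyg = zygosity[f % len(zygosity)]
        sex1 = "M" if rng.random() < 0.5 else "F"
        sex2 = sex1 if zyg == "MZ" else ("F" if rng.random() < 0.5 else "M")
        for t, sex in ((1, sex1), (2, sex2)):
            rows.append(
                {
                    "sample_id": f"S{f:03d}_{t}",
                    "family_id": f"F{f:03d}",
                    "pair_id": f"P{f:03d}",
                    "zygosity": zyg,
                    "sex": sex,
                    "age": 25.0,
                    "plate": f"plate{plate}",
                    "beadchip": f"chip{chip}",
                }
            )
    return SampleSheet(pd.DataFrame(rows))


def toy_table(sheet, n_chrom=6, seed=0, ind_sd=1.0, chrom_sd=0.2):
    rng = np.random.default_rng(seed)
    rows = []
    for sid in sheet.table["sample_id"]:
        base_t = rng.normal(3.3, ind_sd)
        base_k = rng.normal(-7.3, ind_sd)
        for c in range(1, n_chrom + 1):
            rows.append(
                {
                    "sample_id": sid,
                    "chrom": c,
                    "post_mean_logtau": base_t + rng.normal(0, chrom_sd),
                    "post_mean_logkappa": base_k + rng.normal(0, chrom_sd),
                    "range_bp": math.exp(rng.normal(8, 0.3)),
                    "var_explained": rng.uniform(0.3, 0.9),
                }
            )
    return pd.DataFrame(rows)


class TestIcc:
    def test_perfect_consistency_gives_one(self):
        t = pd.DataFrame(
            {
                "sample_id": np.repeat(["a", "b", "c"], 4),
                "v": np.repeat([1.0, 2.0, 3.0], 4),
            }
        )
        res = icc_oneway(t, "v")
        assert res["icc"] == pytest.approx(1.0)

    def test_matches_hand_anova_on_toy_table(self):
        # 4 individuals x 3 replicates; oracle: hand-computed mean squares
        values = {
            "a": [5.1, 4.9, 5.3],
            "b": [7.2, 7.0, 6.8],
            "c": [4.0, 4.4, 4.2],
            "d": [6.1, 6.5, 6.0],
        }
        t = pd.DataFrame(
            [(s, v) for s, vs in values.items() for v in vs],
            columns=["sample_id", "v"],
        )
        all_v = [v for vs in values.values() for v in vs]
        grand = np.mean(all_v)
        msb = 3 * sum((np.mean(vs) - grand) ** 2 for vs in values.values()) / 3
        msw = sum(
            (v - np.mean(vs)) ** 2 for vs in values.values() for v in vs
        ) / 8
        expected = (msb - msw) / (msb + 2 * msw)
        res = icc_oneway(t, "v")
        assert res["icc"] == pytest.approx(expected, rel=1e-12)

    def test_matches_pingouin_reference(self):
        # independent cross-check against the reference ICC implementation
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        t = pd.DataFrame(
            {
                "sample_id": np.repeat([f"s{i}" for i in range(12)], 5),
                "chrom": np.tile(np.arange(5), 12),
                "v": (np.repeat(rng.normal(0, 1, 12), 5)
                      + rng.normal(0, 0.5, 60)),
            }
        )
        res = icc_oneway(t, "v")
        ref_table = pingouin.intraclass_corr(
            data=t, targets="sample_id", raters="chrom", ratings="v"
        )
        ref = ref_table[ref_table["Type"].str.startswith("ICC(1,1)")
                        | (ref_table["Type"] == "ICC1")].iloc[0]
        assert res["icc"] == pytest.approx(float(ref["ICC"]), abs=1e-9)
        ci_col = "CI95%" if "CI95%" in ref_table.columns else "CI95"
        lo, hi = ref[ci_col]
        assert res["ci_low"] == pytest.approx(lo, abs=0.011)
        assert res["ci_high"] == pytest.approx(hi, abs=0.011)

    def test_null_simulation_near_zero(self):
        rng = np.random.default_rng(0)
        iccs = []
        for _ in range(20):
            t = pd.DataFrame(
                {
                    "sample_id": np.repeat([f"s{i}" for i in range(30)], 6),
                    "v": rng.normal(size=180),
                }
            )
            iccs.append(icc_oneway(t, "v")["icc"])
        assert abs(np.mean(iccs)) < 0.1

    def test_too_few_replicates_rejected(self):
        t = pd.DataFrame({"sample_id": ["a", "a", "b"], "v": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="fewer than 2"):
            icc_oneway(t, "v")

    def test_select_one_per_family(self):
        sheet = toy_sheet(10)
        chosen = select_one_per_family(sheet, seed=1)
        assert len(chosen) == 10
        fams = sheet.table.set_index("sample_id").loc[chosen, "family_id"]
        assert fams.is_unique
        assert chosen == select_one_per_family(sheet, seed=1)
        assert chosen != select_one_per_family(sheet, seed=7)


class TestPairings:
    def test_true_twins_deterministic(self):
        sheet = toy_sheet(15)
        (scheme,) = build_pairing(sheet, "true_twins")
        assert len(scheme.pairs) == 15
        co = sheet.co_twin_pairs()
        assert all(frozenset(p) in co for p in scheme.pairs)

    def test_matched_plate_shares_plate_and_avoids_cotwins(self):
        sheet = toy_sheet(20, n_plates=3)
        co = sheet.co_twin_pairs()
        meta = sheet.table.set_index("sample_id")
        for scheme in build_pairing(sheet, "matched_plate", seed=4, n_repeats=5):
            for a, b in scheme.pairs:
                assert meta.at[a, "plate"] == meta.at[b, "plate"]
                assert frozenset((a, b)) not in co

    def test_matched_plate_chip_shares_both(self):
        sheet = toy_sheet(30, n_plates=2)
        meta = sheet.table.set_index("sample_id")
        for scheme in build_pairing(sheet, "matched_plate_chip", seed=4, n_repeats=3):
            for a, b in scheme.pairs:
                assert meta.at[a, "plate"] == meta.at[b, "plate"]
                assert meta.at[a, "beadchip"] == meta.at[b, "beadchip"]

    def test_seed_determinism(self):
        sheet = toy_sheet(20)
        p1 = build_pairing(sheet, "random", seed=5, n_repeats=3)
        p2 = build_pairing(sheet, "random", seed=5, n_repeats=3)
        p3 = build_pairing(sheet, "random", seed=6, n_repeats=3)
        assert [s.pairs for s in p1] == [s.pairs for s in p2]
        assert [s.pairs for s in p1] != [s.pairs for s in p3]

    def test_representative_is_median_ranked(self):
        sheet = toy_sheet(20)
        table = toy_table(sheet)
        cands = build_pairing(sheet, "random", seed=0, n_repeats=7)
        rep = select_representative_pairing(cands, table)
        meds = [
            pair_squared_diffs(table, c, ("post_mean_logtau",))[
                "d_post_mean_logtau"
            ].median()
            for c in cands
        ]
        # rank ceil(7/2) = 4 (1-based) among the 7 medians
        expected_idx = int(np.argsort(meds, kind="stable")[3])
        assert rep is cands[expected_idx]


class TestPairSquaredDiffs:
    def test_arithmetic_symmetry_and_zero(self):
        sheet = toy_sheet(2, n_plates=1)
        table = toy_table(sheet, n_chrom=2)
        ids = sheet.table["sample_id"].tolist()
        table.loc[table["sample_id"] == ids[0], "post_mean_logtau"] = 1.0
        table.loc[table["sample_id"] == ids[1], "post_mean_logtau"] = 3.0
        from methdep.cohort_stats import PairingScheme

        d_ab = pair_squared_diffs(table, PairingScheme("x", [(ids[0], ids[1])]))
        d_ba = pair_squared_diffs(table, PairingScheme("x", [(ids[1], ids[0])]))
        assert (d_ab["d_post_mean_logtau"] == 4.0).all()
        np.testing.assert_array_equal(
            d_ab["d_post_mean_logtau"], d_ba["d_post_mean_logtau"]
        )
        d_self = pair_squared_diffs(
            table.assign(
                post_mean_logtau=0.0, post_mean_logkappa=0.0
            ),
            PairingScheme("x", [(ids[0], ids[1])]),
        )
        assert (d_self["d_post_mean_logtau"] == 0.0).all()


class TestMannWhitney:
    def test_matches_exact_enumeration(self):
        g, l = [10.0, 11.0, 12.0], [1.0, 2.0, 3.0]
        res = mann_whitney_one_sided(g, l)
        # oracle: enumerate all C(6,3) group assignments of the pooled values
        pooled = g + l
        u_obs = sum(1 for x in g for y in l if x > y)
        count = 0
        total = 0
        for comb in itertools.combinations(range(6), 3):
            gg = [pooled[i] for i in comb]
            ll = [pooled[i] for i in range(6) if i not in comb]
            u = sum(1 for x in gg for y in ll if x > y)
            total += 1
            count += u >= u_obs
        assert res["p"] == pytest.approx(count / total)
        assert res["U"] == u_obs

    def test_wrong_direction_gives_large_p(self, rng):
        lo = rng.normal(0, 1, 50)
        hi = rng.normal(2, 1, 50)
        assert mann_whitney_one_sided(lo, hi)["p"] > 0.99

    def test_monotone_transform_invariance(self, rng):
        a = rng.normal(1, 1, 15)
        b = rng.normal(0, 1, 12)
        p1 = mann_whitney_one_sided(a, b)["p"]
        p2 = mann_whitney_one_sided(np.exp(a), np.exp(b))["p"]
        assert p1 == pytest.approx(p2)

    def test_all_identical_values(self):
        res = mann_whitney_one_sided([1.0] * 5, [1.0] * 4)
        assert res["p"] == 1.0


class TestCombineCorrelated:
    def test_reduces_to_fisher_at_zero_correlation(self):
        p = pd.Series([0.01, 0.2, 0.5, 0.04], index=[1, 2, 3, 4])
        est = pd.DataFrame(np.eye(4) * 0.0 + np.diag([1, 2, 3, 4]))
        # force exactly zero off-diagonal correlation with orthogonal columns
        est = pd.DataFrame(
            {
                0: [1, -1, 1, -1, 0, 0, 0, 0],
                1: [1, 1, -1, -1, 0, 0, 0, 0],
                2: [0, 0, 0, 0, 1, -1, 1, -1],
                3: [0, 0, 0, 0, 1, 1, -1, -1],
            },
            dtype=float,
        )
        res = combine_correlated_pvalues(p, est)
        x = -2 * np.log(p).sum()
        fisher = sps.chi2.sf(x, 2 * len(p))
        assert res.p_combined == pytest.approx(fisher, abs=1e-12)
        assert res.scale_c == pytest.approx(1.0)
        assert res.dof_f == pytest.approx(8.0)

    def test_perfect_correlation_recovers_single_test(self, rng):
        # k identical chromosomes with equal p: combined ~ the single p
        base = rng.normal(size=40)
        est = pd.DataFrame({i: base for i in range(6)})
        p_single = 0.03
        res = combine_correlated_pvalues(
            pd.Series([p_single] * 6), est
        )
        assert res.p_combined == pytest.approx(p_single, rel=0.2)

    def test_moderate_correlation_brackets(self, rng):
        base = rng.normal(size=60)
        est = pd.DataFrame(
            {i: 0.7 * base + 0.7 * rng.normal(size=60) for i in range(3)}
        )
        p = pd.Series([0.01, 0.04, 0.20])
        res = combine_correlated_pvalues(p, est)
        fisher = sps.chi2.sf(-2 * np.log(p).sum(), 6)
        assert fisher < res.p_combined < p.max()

    def test_null_calibration_under_correlation(self):
        """Combined p approximately uniform under a correlated null
        (one-sided t tests on equicorrelated normal statistics)."""
        rng = np.random.default_rng(12345)
        k, m = 8, 25
        rho = 0.5
        combined = []
        for _ in range(2000):
            shared_a = rng.standard_normal((m, 1))
            shared_b = rng.standard_normal((m, 1))
            a = math.sqrt(rho) * shared_a + math.sqrt(1 - rho) * rng.standard_normal((m, k))
            b = math.sqrt(rho) * shared_b + math.sqrt(1 - rho) * rng.standard_normal((m, k))
            t, p = sps.ttest_ind(a, b, alternative="greater")
            est = pd.DataFrame(np.vstack([a, b]))
            combined.append(
                combine_correlated_pvalues(pd.Series(p), est).p_combined
            )
        ks = sps.kstest(combined, "uniform")
        assert ks.pvalue > 0.01

    def test_zero_p_floored(self):
        est = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 3)))
        res = combine_correlated_pvalues(pd.Series([0.0, 0.5, 0.5]), est)
        assert 0 < res.p_combined < 1


class TestChromosomeProfiles:
    def test_relative_range_identity_and_scale_invariance(self):
        sheet = toy_sheet(4, n_plates=1)
        table = toy_table(sheet, n_chrom=5, seed=2)
        const = table.copy()
        const["range_bp"] = 3000.0
        per_chrom, rel = relative_range(const)
        assert np.allclose(per_chrom, 1.0)
        scaled = table.copy()
        one = scaled["sample_id"] == scaled["sample_id"].iloc[0]
        scaled.loc[one, "range_bp"] *= 10
        p1, _ = relative_range(table)
        p2, _ = relative_range(scaled)
        np.testing.assert_allclose(p1, p2)

    def test_spearman_matches_rank_pearson_oracle(self, rng):
        x = rng.normal(size=22)
        y = 0.5 * x + rng.normal(size=22)
        res = spearman_with_ci(x, y)
        oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert res["rho"] == pytest.approx(oracle, rel=1e-10)
        z = math.atanh(res["rho"])
        assert res["ci_low"] == pytest.approx(math.tanh(z - 1.959964 / math.sqrt(19)), abs=1e-6)

    def test_spearman_monotone_and_edge_cases(self, rng):
        x = np.arange(10.0)
        assert spearman_with_ci(x, -np.exp(x))["rho"] == pytest.approx(-1.0)
        y = rng.normal(size=10)
        r1 = spearman_with_ci(x, y)["rho"]
        r2 = spearman_with_ci(np.exp(x), y)["rho"]
        assert r1 == pytest.approx(r2)
        with pytest.raises(ValueError, match="constant"):
            spearman_with_ci(np.ones(10), y)

    def test_island_proportions_toy_and_counting(self, rng):
        rows = []
        for c, (n, n_isl) in enumerate([(10, 2), (10, 4)], start=1):
            for i in range(n):
                rows.append(
                    {"probe_id": f"cg{c}_{i}", "chrom": c, "pos": 100 * (i + 1),
                     "island": i < n_isl}
                )
        man = ProbeManifest(pd.DataFrame(rows))
        rel = island_proportions(man)
        assert rel.loc[1] == pytest.approx(0.2 / 0.3)
        assert rel.loc[2] == pytest.approx(0.4 / 0.3)
        # counting oracle on a random manifest
        big = pd.DataFrame(
            {
                "probe_id": [f"cg{i}" for i in range(600)],
                "chrom": rng.integers(1, 7, 600),
                "pos": np.arange(1, 601) * 50,
                "island": rng.random(600) < 0.3,
            }
        )
        rel2 = island_proportions(ProbeManifest(big))
        props = big.groupby("chrom")["island"].mean()
        np.testing.assert_allclose(rel2, props / props.median())


class TestAgeContrast:
    def make_aged_table(self, shift, seed=0, n=40):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            old = i < n // 3
            age = 60.0 if old else 25.0
            base = rng.normal(3.3, 0.4) + (shift if old else 0.0)
            for c in range(1, 7):
                rows.append(
                    {
                        "sample_id": f"s{i}",
                        "chrom": c,
                        "age": age,
                        "post_mean_logtau": base + rng.normal(0, 0.1),
                        "post_mean_logkappa": rng.normal(-7.3, 0.3),
                        "var_explained": rng.uniform(0.4, 0.8),
                    }
                )
        return pd.DataFrame(rows)

    def test_detects_simulated_shift(self):
        table = self.make_aged_table(shift=-0.5)
        res = age_group_contrast(table)
        assert res["post_mean_logtau"]["combined"].p_combined < 0.05

    def test_null_is_not_significant(self):
        ps = []
        for seed in range(5):
            table = self.make_aged_table(shift=0.0, seed=seed)
            res = age_group_contrast(table)
            ps.append(res["post_mean_logtau"]["combined"].p_combined)
        assert min(ps) > 0.001
        assert np.mean([p < 0.05 for p in ps]) <= 0.4

    def test_direction_swap_complements(self):
        table = self.make_aged_table(shift=-0.5)
        p_young = age_group_contrast(
            table, parameters={"post_mean_logtau": "young_greater"}
        )["post_mean_logtau"]["combined"].p_by_chrom
        p_old = age_group_contrast(
            table, parameters={"post_mean_logtau": "old_greater"}
        )["post_mean_logtau"]["combined"].p_by_chrom
        assert (p_young < 0.05).all()
        assert (p_old > 0.9).all()
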