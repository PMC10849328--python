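"""IBS clustering, CMH association, genomic control and permutations."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency, kstest, spearmanr

import gamescan as gs
from gamescan.assoc import (
    choose_best_k,
    cmh_from_calls,
    cmh_test,
    complete_linkage,
    genomic_control,
    group_allele_frequencies,
    ibs_distance,
    informative_samples,
    ld_r2,
    permutation_p,
    select_k,
)
from gamescan.filters import frequency_filters
from gamescan.sim import PopulationSpec, SimConfig
from gamescan.types import MISSING

import _reference as ref
from conftest import make_calls


class TestIBS:
    def test_identical_zero(self):
        calls = make_calls([[0, 1, 2], [0, 1, 2]])
        d = ibs_distance(calls)
        assert d[0, 1] == 0.0

    def test_opposite_homozygotes_one(self):
        calls = make_calls([[0, 0], [2, 2]])
        assert ibs_distance(calls)[0, 1] == 1.0

    def test_half_shared(self):
        # per-site shares (1, 0) -> mean share 0.5 -> distance 0.5
        calls = make_calls([[0, 2], [0, 0]])
        assert ibs_distance(calls)[0, 1] == 0.5

    def test_missing_sites_skipped(self):
        calls = make_calls([[0, 2, MISSING], [0, MISSING, 2]])
        assert ibs_distance(calls)[0, 1] == 0.0

    def test_no_cocalled_pair_errors(self):
        calls = make_calls([[0, MISSING], [MISSING, 2]])
        with pytest.raises(ValueError, match="no co-called"):
            ibs_distance(calls)

    def test_symmetric_unit_range(self, null_cohort):
        _, _, _, calls = null_cohort
        d = ibs_distance(calls.take_samples(np.arange(20)))
        np.testing.assert_allclose(d, d.T)
        assert np.all((d >= 0) & (d <= 1))
        assert np.all(np.diag(d) == 0)


class TestCompleteLinkage:
    def test_trivial_cuts(self):
        rng = np.random.default_rng(0)
        x = rng.random((6, 6))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        assert len(set(complete_linkage(d, 6))) == 6
        assert set(complete_linkage(d, 1)) == {1}
        with pytest.raises(ValueError):
            complete_linkage(d, 7)

    def test_two_tight_pairs_brute_force(self):
        # brute force over all 2-partitions of 4 points minimises the
        # complete-linkage criterion (max intra-cluster distance)
        d = np.array(
            [
                [0.0, 0.1, 0.9, 0.8],
                [0.1, 0.0, 0.85, 0.95],
                [0.9, 0.85, 0.0, 0.05],
                [0.8, 0.95, 0.05, 0.0],
            ]
        )
        got = complete_linkage(d, 2)
        assert got[0] == got[1] and got[2] == got[3] and got[0] != got[2]

        import itertools

        def crit(labels):
            worst = 0.0
            for c in set(labels):
                idx = [i for i, l in enumerate(labels) if l == c]
                for i, j in itertools.combinations(idx, 2):
                    worst = max(worst, d[i, j])
            return worst

        best = min(
            (labels for labels in itertools.product([1, 2], repeat=4)
             if len(set(labels)) == 2),
            key=crit,
        )
        assert crit(tuple(got)) == crit(best)


class TestCMH:
    def test_k1_is_scaled_pearson(self):
        # single stratum: CMH = ((T-1)/T) * Pearson chi2 (hypergeometric
        # variance), an exact identity
        rng = np.random.default_rng(7)
        for _ in range(100):
            t = rng.integers(1, 50, size=(2, 2))
            chi2, _ = cmh_test(t[None])
            pearson = chi2_contingency(t, correction=False).statistic
            T = t.sum()
            assert chi2 == pytest.approx((T - 1) / T * pearson, rel=1e-10)

    def test_identical_case_control_zero(self):
        tables = np.array([[[10, 20], [10, 20]], [[5, 5], [5, 5]]])
        chi2, p = cmh_test(tables)
        assert chi2 == 0.0 and p == 1.0

    def test_hand_oracle_random_strata(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            k = rng.integers(1, 5)
            tables = rng.integers(0, 30, size=(k, 2, 2))
            chi2, _ = cmh_test(tables)
            want = ref.ref_cmh(tables)
            if np.isnan(want):
                assert np.isnan(chi2)
            else:
                assert chi2 == pytest.approx(want, rel=1e-12)

    def test_against_r_mantelhaen(self):
        # independent oracle: R's mantelhaen.test without continuity correction
        tables = np.array(
            [[[12, 18], [7, 23]], [[30, 10], [22, 18]], [[3, 9], [5, 7]]]
        )
        chi2, p = cmh_test(tables)
        rscript = textwrap.dedent(
            """
            x <- array(c(12,7,18,23, 30,22,10,18, 3,5,9,7), dim=c(2,2,3))
            r <- mantelhaen.test(x, correct=FALSE)
            cat(sprintf("%.12f %.12g", r$statistic, r$p.value))
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, check=True
        )
        r_chi2, r_p = map(float, out.stdout.split())
        assert chi2 == pytest.approx(r_chi2, rel=1e-9)
        assert p == pytest.approx(r_p, rel=1e-9)

    def test_allele_label_swap_invariance(self):
        rng = np.random.default_rng(3)
        tables = rng.integers(1, 25, size=(3, 2, 2))
        chi2, _ = cmh_test(tables)
        swapped, _ = cmh_test(tables[:, :, ::-1])
        assert chi2 == pytest.approx(swapped, rel=1e-12)

    def test_all_strata_degenerate_nan(self):
        chi2, p = cmh_test(np.array([[[5, 0], [7, 0]]]))  # zero margin
        assert np.isnan(chi2) and np.isnan(p)

    def test_vectorised_matches_tables(self, null_cohort):
        _, samples, _, calls = null_cohort
        case = (samples["group"] == "gamecock").to_numpy()
        strata = np.tile([1, 2], 55)
        chi2, _ = cmh_from_calls(calls, case, strata)
        # rebuild the stacked tables per variant by hand for a few variants
        for j in [0, 17, 400]:
            tabs = []
            for c in (1, 2):
                members = strata == c
                col = calls.dosage[members, j]
                cc = case[members]
                ok = col != MISSING
                a = int(col[cc & ok].sum())
                n1 = int(2 * (cc & ok).sum())
                m1 = int(col[ok].sum())
                tt = int(2 * ok.sum())
                tabs.append([[a, n1 - a], [m1 - a, (tt - n1) - (m1 - a)]])
            want = ref.ref_cmh(np.array(tabs))
            if np.isnan(want):
                assert np.isnan(chi2[j])
            else:
                assert chi2[j] == pytest.approx(want, rel=1e-9)


class TestGenomicControl:
    def test_lambda_one_at_chi2_median(self):
        chi2 = np.full(5, 0.4549364231)
        lam, p = genomic_control(chi2)
        assert lam == 1.0

    def test_recovers_inflation_factor(self):
        # chi2 drawn as 2.61 * chi2(1): lambda estimates 2.61
        rng = np.random.default_rng(0)
        chi2 = 2.61 * rng.chisquare(1, size=1_000_000)
        lam, _ = genomic_control(chi2)
        assert lam == pytest.approx(2.61, abs=0.02)

    def test_floored_at_one(self):
        rng = np.random.default_rng(1)
        chi2 = 0.5 * rng.chisquare(1, size=100_000)
        lam, p = genomic_control(chi2)
        assert lam == 1.0
        # never deflates: p unchanged from raw
        from scipy.stats import chi2 as chi2_dist

        np.testing.assert_allclose(p, chi2_dist.sf(chi2, 1))

    def test_adjusted_p_never_smaller(self):
        rng = np.random.default_rng(2)
        chi2 = 3.0 * rng.chisquare(1, size=10_000)
        from scipy.stats import chi2 as chi2_dist

        lam, p_adj = genomic_control(chi2)
        assert lam > 1
        assert np.all(p_adj >= chi2_dist.sf(chi2, 1) - 1e-15)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            genomic_control(np.array([np.nan]))


class TestSelectK:
    def test_null_lambda_near_one(self, null_cohort):
        _, samples, _, calls = null_cohort
        case = (samples["group"] == "gamecock").to_numpy()
        keep = np.where(frequency_filters(calls, "maf"))[0]
        sel = select_k(calls, case, range(1, 5), variant_index=keep)
        lams = sel.table["lam"].to_numpy()
        assert np.all((lams >= 0.9) & (lams <= 1.1))

    def test_stratification_removes_confounding(self):
        # phenotype confounded with two demes: lambda(K=2) < lambda(K=1)
        cfg = SimConfig(
            n_variants=1200,
            chrom_length_bp=1_200_000,
            populations=(
                PopulationSpec("a", "gamecock", 40, 0.15),
                PopulationSpec("a", "nongame", 10, 0.15),
                PopulationSpec("b", "gamecock", 10, 0.15),
                PopulationSpec("b", "nongame", 40, 0.15),
            ),
            selected_locus=None,
            missing_rate=0.0,
            seed=17,
        )
        samples, _, calls = gs.simulate_cohort(cfg)
        case = (samples["group"] == "gamecock").to_numpy()
        keep = np.where(frequency_filters(calls, "maf"))[0]
        sel = select_k(calls, case, [1, 2], variant_index=keep)
        t = sel.table.set_index("k")["lam"]
        assert t[2] < t[1]
        assert t[1] > 1.5  # confounding inflates the unstratified scan

    def test_tie_breaks(self):
        table = pd.DataFrame(
            {"k": [4, 5, 2], "lam": [2.612, 2.608, 5.24],
             "informative_samples": [100, 90, 110]}
        )
        # 2.612 and 2.608 tie at 2 decimals; larger informative count wins
        assert choose_best_k(table) == 4
        table.loc[0, "informative_samples"] = 90  # full tie -> smaller K
        assert choose_best_k(table) == 4
        table.loc[0, "lam"] = 2.62  # no tie -> smallest lambda
        assert choose_best_k(table) == 5
        table["lam"] = [np.nan, np.nan, 3.0]  # undefined rows excluded
        assert choose_best_k(table) == 2

    def test_informative_samples_counts_mixed_strata_only(self):
        assignment = np.array([1, 1, 1, 2, 2, 3])
        case = np.array([True, False, False, True, True, True])
        # stratum 1 mixed (3 samples), stratum 2 pure cases, stratum 3 pure
        assert informative_samples(assignment, case) == 3


class TestPermutations:
    def test_seeded_determinism(self, null_cohort):
        _, samples, _, calls = null_cohort
        case = (samples["group"] == "gamecock").to_numpy()
        sub = calls.take_variants(np.arange(50))
        strata = np.ones(len(samples), dtype=int)
        p1, o1 = permutation_p(sub, case, strata, n_perm=200, seed=5)
        p2, o2 = permutation_p(sub, case, strata, n_perm=200, seed=5)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(o1, o2)

    def test_add_one_floor(self):
        # minimum attainable p is 1/(n_perm+1), just below 1e-4 at 10,000
        assert 1 / 10_001 < 1e-4
        # an overwhelming effect beats every permutation
        dos = np.zeros((40, 1), dtype=np.int8)
        dos[:20] = 2
        calls = make_calls(dos)
        case = np.zeros(40, dtype=bool)
        case[:20] = True
        p, obs = permutation_p(calls, case, np.ones(40, dtype=int), n_perm=99, seed=0)
        assert p[0] == pytest.approx(1 / 100)

    def test_null_uniform_and_rank_concordant(self, null_cohort):
        _, samples, _, calls = null_cohort
        case = (samples["group"] == "gamecock").to_numpy()
        keep = np.where(frequency_filters(calls, "maf"))[0]
        strata = np.ones(len(samples), dtype=int)
        p_mid, obs = permutation_p(
            calls, case, strata, n_perm=1000, seed=9, variant_index=keep, ties="midp"
        )
        p_perm, _ = permutation_p(
            calls, case, strata, n_perm=1000, seed=9, variant_index=keep
        )
        chi2, p_raw = cmh_from_calls(calls, case, strata, variant_index=keep)
        # mid-p version approximately uniform under exchangeability; the
        # tie-counting default is valid but conservative (mean >= 1/2)
        assert kstest(p_mid, "uniform").statistic < 0.05
        assert p_perm.mean() >= 0.5 - 2 / np.sqrt(len(p_perm))
        # analytic and permutation p rank-concordant
        rho = spearmanr(p_perm, p_raw).statistic
        assert rho > 0.99

    def test_max_t_is_conservative(self, null_cohort):
        _, samples, _, calls = null_cohort
        case = (samples["group"] == "gamecock").to_numpy()
        sub = calls.take_variants(np.arange(120))
        strata = np.ones(len(samples), dtype=int)
        p_point, _ = permutation_p(sub, case, strata, n_perm=300, seed=2)
        p_maxt, _ = permutation_p(sub, case, strata, n_perm=300, seed=2, max_t=True)
        ok = np.isfinite(p_point) & np.isfinite(p_maxt)
        assert ok.any()
        assert np.all(p_maxt[ok] >= p_point[ok] - 1e-12)

    def test_rejects_bad_n_perm(self, null_cohort):
        _, samples, _, calls = null_cohort
        case = (samples["group"] == "gamecock").to_numpy()
        with pytest.raises(ValueError):
            permutation_p(calls, case, np.ones(len(samples), dtype=int), n_perm=0)


class TestLdR2:
    def test_identical_one(self):
        assert ld_r2([0, 1, 2, 0], [0, 1, 2, 0]) == pytest.approx(1.0)

    def test_perfect_negative_one(self):
        assert ld_r2([0, 1, 2, 0], [2, 1, 0, 2]) == pytest.approx(1.0)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, size=1000)
        y = rng.integers(0, 3, size=1000)
        assert ld_r2(x, y) < 0.01

    def test_monomorphic_nan(self):
        assert np.isnan(ld_r2([1, 1, 1], [0, 1, 2]))

    def test_missing_pairs_dropped(self):
        x = np.array([0, 1, 2, MISSING, 2])
        y = np.array([0, 1, 2, 2, MISSING])
        assert ld_r2(x, y) == pytest.approx(1.0)


class TestGroupFrequencies:
    def test_hand_counts(self):
        # 48 diploids, alt count 86 of 96 alleles -> 0.8958...
        dos = np.zeros((48, 1), dtype=np.int8)
        dos[:38] = 2
        dos[38:48] = 1
        assert int(dos.sum()) == 86
        samples = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(48)],
             "group": "gamecock", "population": "p"}
        )
        f = group_allele_frequencies(make_calls(dos), samples)
        assert f["gamecock"][0] == pytest.approx(86 / 96)
        assert round(100 * f["gamecock"][0], 1) == 89.6

    def test_all_hom_ref_zero(self):
        samples = pd.DataFrame(
            {"sample_id": ["a", "b"], "group": "nongame", "population": "p"}
        )
        f = group_allele_frequencies(make_calls([[0], [0]]), samples)
        assert f["nongame"][0] == 0.0

    def test_zero_called_is_nan(self):
        samples = pd.DataFrame(
            {"sample_id": ["a"], "group": "nongame", "population": "p"}
        )
        f = group_allele_frequencies(make_calls([[MISSING]]), samples)
        assert np.isnan(f["nongame"][0])

    def test_simulated_locus_frequencies(self, default_cohort):
        cfg, samples, variants, calls = default_cohort
        from gamescan.sim import selected_variant_index

        si = selected_variant_index(cfg, variants)
        f = group_allele_frequencies(calls, samples)
        se_g = np.sqrt(0.895 * 0.105 / 96)
        se_n = np.sqrt(0.037 * 0.963 / 124)
        assert abs(f["gamecock"][si] - 0.895) < 3 * se_g + 0.02
        assert abs(f["nongame"][si] - 0.037) < 3 * se_n + 0.02
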