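"""Windowed selection statistics against hand calculations and naive
reference implementations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gamescan as gs
from gamescan.scans import (
    WindowSpec,
    allele_counts,
    hudson_fst_sites,
    hudson_fst_windows,
    iter_windows,
    pbs_from_fst,
    pbs_windows,
    pixy_pi,
    windowed_heterozygosity,
)
from gamescan.sim import PopulationSpec, SimConfig
from gamescan.types import MISSING

import _reference as ref
from conftest import make_calls, make_variants


class TestWindows:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(1, 5000),
        size=st.integers(1, 1200),
        step=st.integers(1, 1200),
    )
    def test_window_count_formula(self, n, size, step):
        step = min(step, size)
        spans = iter_windows(n, WindowSpec(size, step))
        full = [s for s in spans if not s[2]]
        expected_full = (n - size) // step + 1 if n >= size else 0
        assert len(full) == expected_full
        # coverage: last window ends at n; spans ordered and within bounds
        assert spans[-1][1] == n
        starts = [s for s, _, _ in spans]
        assert starts == sorted(starts)
        assert len(spans) - len(full) <= 1  # at most one trailing short window

    def test_bp_spans_non_decreasing(self):
        variants = make_variants(95)
        counts = (np.full(95, 20), np.full(95, 5))
        df = hudson_fst_windows(variants, counts, counts, WindowSpec(30, 10))
        assert (df["start_bp"].diff().dropna() >= 0).all()
        assert (df["end_bp"].diff().dropna() >= 0).all()
        # full windows start at 0,10,...,60; the trailing short one at 70
        assert bool(df["partial"].iloc[-1]) and df["n_variants"].iloc[-1] == 25


class TestAlleleCounts:
    def test_direct_count(self):
        calls = make_calls([[0], [1], [2], [MISSING]])
        n, a = allele_counts(calls)
        assert (n[0], a[0]) == (6, 3)

    def test_all_missing(self):
        calls = make_calls([[MISSING], [MISSING]])
        n, a = allele_counts(calls)
        assert (n[0], a[0]) == (0, 0)

    def test_matches_simulated_frequency(self, default_cohort):
        cfg, samples, variants, calls = default_cohort
        game = np.where((samples["group"] == "gamecock").to_numpy())[0]
        n, a = allele_counts(calls, game)
        ok = n > 0
        assert np.all(a[ok] <= n[ok])


class TestHudsonFst:
    def test_hand_single_site(self):
        # p1 = p2 = 0.5, n1 = n2 = 10: N = -2 * 0.25/9, D = 0.5
        counts = (np.array([10]), np.array([5]))
        num, den, valid = hudson_fst_sites(counts, counts)
        assert num[0] == pytest.approx(-2 * 0.25 / 9)
        assert den[0] == pytest.approx(0.5)
        df = hudson_fst_windows(make_variants(1), counts, counts, WindowSpec(1, 1))
        assert df["value"][0] == pytest.approx(-0.1111, abs=1e-4)

    def test_fixed_difference_is_one(self):
        n = np.full(50, 200)
        df = hudson_fst_windows(
            make_variants(50), (n, n.copy()), (n, np.zeros(50, dtype=int)),
            WindowSpec(50, 50),
        )
        assert df["value"][0] == pytest.approx(1.0)

    def test_null_simulation_near_zero(self):
        # two samples of one panmictic deme: estimator unbiased around 0
        cfg = SimConfig(
            n_variants=1000, chrom_length_bp=1_000_000,
            populations=(PopulationSpec("pop", "gamecock", 50, 0.1),
                         PopulationSpec("pop", "nongame", 50, 0.1)),
            selected_locus=None, missing_rate=0.0, seed=21,
        )
        samples, variants, calls = gs.simulate_cohort(cfg)
        a = allele_counts(calls, np.arange(50))
        b = allele_counts(calls, np.arange(50, 100))
        df = hudson_fst_windows(variants, a, b, WindowSpec(1000, 1000))
        assert abs(df["value"][0]) < 0.01

    def test_depends_only_on_counts(self):
        # same (n, a) from different genotype configurations: same FST
        c1 = make_calls([[1], [1], [0], [2]])  # n=8, a=4
        c2 = make_calls([[2], [2], [0], [0]])  # n=8, a=4
        other = (np.array([8]), np.array([1]))
        v = make_variants(1)
        w = WindowSpec(1, 1)
        f1 = hudson_fst_windows(v, allele_counts(c1), other, w)["value"][0]
        f2 = hudson_fst_windows(v, allele_counts(c2), other, w)["value"][0]
        assert f1 == f2

    def test_empty_denominator_is_nan(self):
        # both pops fixed ref: D = 0 -> undefined, not 0
        counts = (np.array([10]), np.array([0]))
        df = hudson_fst_windows(make_variants(1), counts, counts, WindowSpec(1, 1))
        assert np.isnan(df["value"][0])


class TestPBS:
    def test_closed_form(self):
        assert pbs_from_fst(0.5, 0.5, 0.0) == pytest.approx(-np.log(0.5), abs=1e-9)
        assert pbs_from_fst(0.0, 0.0, 0.0) == 0.0

    def test_negative_fst_passes_unclipped(self):
        val = pbs_from_fst(-0.1, 0.0, 0.0)
        assert val == pytest.approx(-np.log(1.1) / 2)

    def test_contrast_symmetry(self, default_cohort):
        cfg, samples, variants, calls = default_cohort
        g = {
            name: np.where(((samples["population"] == p) & (samples["group"] == grp)).to_numpy())[0]
            for name, (p, grp) in {
                "f": ("japan", "gamecock"),
                "c1": ("japan", "nongame"),
                "c2": ("ethiopia", "nongame"),
            }.items()
        }
        cf, c1, c2 = (allele_counts(calls, g[k]) for k in ("f", "c1", "c2"))
        w = WindowSpec(100, 50)
        a = pbs_windows(variants, cf, c1, c2, w)["value"]
        b = pbs_windows(variants, cf, c2, c1, w)["value"]
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_branch_identity_columns(self, default_cohort):
        cfg, samples, variants, calls = default_cohort
        idx = np.arange(20)
        cf = allele_counts(calls, idx)
        c1 = allele_counts(calls, np.arange(20, 40))
        c2 = allele_counts(calls, np.arange(40, 60))
        df = pbs_windows(variants, cf, c1, c2, WindowSpec(200, 100))
        np.testing.assert_allclose(
            df["t_focal_c1"], -np.log(1 - np.minimum(df["fst_focal_c1"], 1 - 1e-6))
        )
        np.testing.assert_allclose(
            df["value"],
            (df["t_focal_c1"] + df["t_focal_c2"] - df["t_c1_c2"]) / 2,
        )


class TestHeterozygosity:
    def test_all_het(self):
        calls = make_calls(np.ones((4, 10), dtype=np.int8))
        df = windowed_heterozygosity(calls, np.arange(4), make_variants(10), WindowSpec(10, 10))
        assert df["value"][0] == 1.0

    def test_hand_fraction(self):
        # 20 called genotypes: 5 hets -> 0.25
        dos = np.array([[0] * 10 + [1] * 5 + [2] * 5]).reshape(20, 1)
        calls = make_calls(dos)
        df = windowed_heterozygosity(calls, np.arange(20), make_variants(1), WindowSpec(1, 1))
        assert df["value"][0] == 0.25

    def test_missing_excluded_from_denominator(self):
        calls = make_calls([[1], [MISSING], [0], [MISSING]])
        df = windowed_heterozygosity(calls, np.arange(4), make_variants(1), WindowSpec(1, 1))
        assert df["value"][0] == 0.5

    def test_gamecock_dip_at_selected_locus(self, default_cohort):
        cfg, samples, variants, calls = default_cohort
        from gamescan.sim import block_span

        lo, hi = block_span(cfg)
        game = np.where((samples["group"] == "gamecock").to_numpy())[0]
        nong = np.where((samples["group"] == "nongame").to_numpy())[0]
        w = WindowSpec(50, 10)
        hg = windowed_heterozygosity(calls, game, variants, w)
        hn = windowed_heterozygosity(calls, nong, variants, w)
        gmin = hg.loc[hg["value"].idxmin()]
        assert gmin["start_bp"] <= hi and gmin["end_bp"] >= lo
        # nongame birds show no comparable dip in the same window
        same = hn.loc[hg["value"].idxmin(), "value"]
        assert same > 1.5 * gmin["value"]


class TestPi:
    def toy(self):
        # site 0 invariant (both called); site 1: 0/0 and 1/1; site 2: one
        # genotype missing, the other 0/1
        dos = np.array([[0, 0, MISSING], [0, 2, 1]], dtype=np.int8)
        variants = make_variants(3)
        variants.loc[0, "alt"] = "."
        return make_calls(dos), variants

    def test_hand_toy(self):
        calls, variants = self.toy()
        res = pixy_pi(calls, np.arange(2), variants)
        assert res.pi == pytest.approx(5 / 13)
        assert (res.diffs, res.comps) == (5, 13)

    def test_all_invariant_zero(self):
        calls = make_calls(np.zeros((3, 5), dtype=np.int8))
        res = pixy_pi(calls, np.arange(3), make_variants(5, alt="."))
        assert res.pi == 0.0

    def test_invariant_sites_scale_denominator(self):
        # doubling invariant sites (4 alleles each, comps 6) grows the
        # denominator while the numerator is fixed
        base_dos = np.array([[0, 2], [0, 0]], dtype=np.int8)

        def with_invariants(k):
            dos = np.concatenate(
                [base_dos, np.zeros((2, k), dtype=np.int8)], axis=1
            )
            v = make_variants(2 + k)
            v.loc[2:, "alt"] = "."
            return pixy_pi(make_calls(dos), np.arange(2), v)

        r1 = with_invariants(4)
        r2 = with_invariants(10)
        assert r1.pi == pytest.approx(r1.diffs / (r1.comps))
        assert r2.comps == r1.comps + 6 * 6
        assert r2.pi < r1.pi

    def test_partition_additivity(self, default_cohort):
        cfg, samples, variants, calls = default_cohort
        idx = np.arange(20)
        whole = pixy_pi(calls, idx, variants)
        half = (variants["pos"] <= variants["pos"].median()).to_numpy()
        a = pixy_pi(calls.take_variants(np.where(half)[0]), idx,
                    variants[half].reset_index(drop=True))
        b = pixy_pi(calls.take_variants(np.where(~half)[0]), idx,
                    variants[~half].reset_index(drop=True))
        combined = (a.diffs + b.diffs) / (a.comps + b.comps)
        assert whole.pi == pytest.approx(combined, rel=1e-12)
        assert whole.pi >= 0


class TestReferenceEquivalence:
    """All four windowed statistics against the naive per-site reference on
    random small matrices, to 1e-10 relative."""

    def _random_case(self, rng):
        n_var = rng.integers(5, 30)
        sizes = rng.integers(3, 12, size=3)
        dosage = rng.integers(0, 3, size=(int(sizes.sum()), n_var)).astype(np.int8)
        miss = rng.random(dosage.shape) < 0.15
        dosage[miss] = MISSING
        return dosage, sizes, n_var

    def test_fifty_random_matrices(self):
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(50):
            dosage, sizes, n_var = self._random_case(rng)
            calls = make_calls(dosage)
            variants = make_variants(n_var)
            i1 = np.arange(sizes[0])
            i2 = np.arange(sizes[0], sizes[0] + sizes[1])
            i3 = np.arange(sizes[0] + sizes[1], sizes.sum())
            cf = allele_counts(calls, i1)
            c1 = allele_counts(calls, i2)
            c2 = allele_counts(calls, i3)
            size = int(rng.integers(2, n_var + 1))
            step = int(rng.integers(1, size + 1))
            spec = WindowSpec(size, step)
            spans = iter_windows(n_var, spec)

            fst = hudson_fst_windows(variants, cf, c1, spec)["value"].to_numpy()
            pbs = pbs_windows(variants, cf, c1, c2, spec)["value"].to_numpy()
            het = windowed_heterozygosity(calls, i1, variants, spec)["value"].to_numpy()
            for w, (s, e, _) in enumerate(spans):
                r_fst = ref.ref_fst_window(cf, c1, s, e)
                r_pbs = ref.ref_pbs_window(cf, c1, c2, s, e)
                r_het = ref.ref_het_window(dosage[i1], s, e)
                for got, want in ((fst[w], r_fst), (pbs[w], r_pbs), (het[w], r_het)):
                    if np.isnan(want):
                        assert np.isnan(got)
                    else:
                        assert got == pytest.approx(want, rel=1e-10, abs=1e-12)
                        checked += 1
            r_pi = ref.ref_pi(dosage[i2])
            got_pi = pixy_pi(calls, i2, variants).pi
            if np.isnan(r_pi):
                assert np.isnan(got_pi)
            else:
                assert got_pi == pytest.approx(r_pi, rel=1e-10)
        assert checked > 100
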