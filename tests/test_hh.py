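import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hhmap.hh import (
    build_hh,
    find_dhsnps,
    genotyping_error_reliability,
    pairwise_rchh,
    pool_comparison_test,
    rca_expected_length,
    shared_rchh_scan,
    significant_rchhs,
    RepresentativeRCHH,
)
from hhmap.model import Call, HHMapError

from conftest import HET, HOM_ALT, HOM_REF, MISSING, flat_pedigree, make_matrix, make_panel, random_matrix


# ---------------------------------------------------------------- oracles
def _hom(c):
    return c in (HOM_REF, HOM_ALT)


def oracle_dhsnps(calls_a, calls_b):
    """Independent per-marker scan for discordant homozygotes."""
    return [
        i
        for i in range(len(calls_a))
        if _hom(calls_a[i]) and _hom(calls_b[i]) and calls_a[i] != calls_b[i]
    ]


def oracle_rchh(calls_a, calls_b, cm, cutoff):
    """Enumerate maximal dhSNP-free intervals by exhaustive (i, j) checking.

    Uses the fact that dhSNPs are themselves compSNPs: an interval [i, j] of
    compSNPs with no dhSNP inside is maximal iff the nearest compSNP outside
    each end (if any) is a dhSNP.
    """
    n = len(calls_a)
    dh = set(oracle_dhsnps(calls_a, calls_b))
    comp = [i for i in range(n) if _hom(calls_a[i]) and _hom(calls_b[i])]
    out = []
    for ai, i in enumerate(comp):
        for bj in range(ai, len(comp)):
            j = comp[bj]
            if any(d in dh for d in range(i, j + 1)):
                continue
            left_ok = ai == 0 or comp[ai - 1] in dh
            right_ok = bj == len(comp) - 1 or comp[bj + 1] in dh
            if left_ok and right_ok and cm[j] - cm[i] >= cutoff:
                out.append((i, j))
    return sorted(out)


def oracle_norm_sf(z):
    """Upper-tail standard normal probability via erfc (independent of scipy)."""
    return 0.5 * math.erfc(z / math.sqrt(2.0))


# ---------------------------------------------------------------- build_hh
class TestBuildHH:
    def test_all_het_is_empty(self):
        panel = make_panel({"1": 4, "2": 2})
        m = make_matrix(panel, {"a": [HET] * 6})
        hh = build_hh(m, "a")
        assert hh.n_markers() == 0
        assert all(len(v) == 0 for v in hh.indices.values())

    def test_retains_hom_only(self):
        panel = make_panel({"1": 4})
        m = make_matrix(panel, {"a": [HOM_REF, HET, HOM_ALT, MISSING]})
        hh = build_hh(m, "a")
        assert list(hh.indices["1"]) == [0, 2]
        assert list(hh.alleles["1"]) == ["A", "G"]

    def test_unknown_id(self):
        panel = make_panel({"1": 1})
        m = make_matrix(panel, {"a": [HOM_REF]})
        with pytest.raises(KeyError):
            build_hh(m, "zzz")

    def test_size_matches_recount_on_random_individuals(self, rng):
        # oracle: direct recount of homozygous calls
        panel = make_panel({"1": 40, "2": 20})
        matrix = random_matrix(rng, panel, 100)
        for sid in matrix.sample_ids:
            hh = build_hh(matrix, sid)
            expected = int(np.isin(matrix.row(sid), [HOM_REF, HOM_ALT]).sum())
            assert hh.n_markers() == expected


# ---------------------------------------------------------------- dhSNPs
class TestFindDhsnps:
    def test_identical_rows_empty(self):
        panel = make_panel({"1": 5})
        row = [HOM_REF, HET, HOM_ALT, MISSING, HOM_REF]
        m = make_matrix(panel, {"a": row, "b": row})
        assert len(find_dhsnps(m, "a", "b", "1")) == 0

    def test_single_discordant_marker(self):
        panel = make_panel({"1": 3})
        m = make_matrix(
            panel,
            {"a": [HET, HOM_REF, HET], "b": [HET, HOM_ALT, HET]},
        )
        assert list(find_dhsnps(m, "a", "b", "1")) == [1]

    def test_matches_bruteforce_and_symmetric(self, rng):
        panel = make_panel({"1": 30})
        matrix = random_matrix(rng, panel, 40)
        ids = matrix.sample_ids
        for _ in range(200):
            a, b = rng.choice(ids, size=2, replace=False)
            got = list(find_dhsnps(matrix, a, b, "1"))
            assert got == oracle_dhsnps(list(matrix.row(a)), list(matrix.row(b)))
            assert got == list(find_dhsnps(matrix, b, a, "1"))


# ---------------------------------------------------------------- pairwise RCHH
class TestPairwiseRCHH:
    def test_identical_homozygous_pair_whole_chromosome(self):
        panel = make_panel({"1": 51})  # 0..50 cM
        row = [HOM_REF] * 51
        m = make_matrix(panel, {"a": row, "b": row})
        (r,) = pairwise_rchh(m, "a", "b", 7.0)
        assert (r.start_idx, r.end_idx) == (0, 50)
        assert r.length_cm == 50.0
        assert r.n_compsnp == 51

    def test_single_mid_dhsnp_splits_in_two(self):
        panel = make_panel({"1": 51})
        a = [HOM_REF] * 51
        b = [HOM_REF] * 51
        b[25] = HOM_ALT
        m = make_matrix(panel, {"a": a, "b": b})
        regions = pairwise_rchh(m, "a", "b", 7.0)
        assert [(r.start_idx, r.end_idx) for r in regions] == [(0, 24), (26, 50)]
        assert all(abs(r.length_cm - 24.0) < 1e-12 for r in regions)

    def test_short_chromosome_empty(self):
        panel = make_panel({"1": 1})
        m = make_matrix(panel, {"a": [HOM_REF], "b": [HOM_REF]})
        assert pairwise_rchh(m, "a", "b", 7.0) == []

    def test_cutoff_must_be_positive(self):
        panel = make_panel({"1": 2})
        m = make_matrix(panel, {"a": [0, 0], "b": [0, 0]})
        with pytest.raises(HHMapError):
            pairwise_rchh(m, "a", "b", 0.0)

    def test_matches_bruteforce_enumerator(self, rng):
        panel = make_panel({"1": 100})
        for _ in range(100):
            matrix = random_matrix(rng, panel, 2, missing_rate=0.15)
            a, b = matrix.sample_ids
            cutoff = float(rng.uniform(2.0, 15.0))
            got = [
                (r.start_idx, r.end_idx)
                for r in pairwise_rchh(matrix, a, b, cutoff)
            ]
            want = oracle_rchh(
                list(matrix.row(a)), list(matrix.row(b)), panel.cm, cutoff
            )
            assert got == want

    def test_boundary_soundness_random(self, rng):
        # no dhSNP strictly inside; length >= cutoff; symmetric; disjoint
        panel = make_panel({"1": 80})
        for _ in range(30):
            matrix = random_matrix(rng, panel, 2, missing_rate=0.1)
            a, b = matrix.sample_ids
            regions = pairwise_rchh(matrix, a, b, 5.0)
            dh = set(find_dhsnps(matrix, a, b, "1"))
            prev_end = -1
            for r in regions:
                assert r.length_cm >= 5.0
                assert not any(r.start_idx <= d <= r.end_idx for d in dh)
                assert r.start_idx > prev_end
                prev_end = r.end_idx
            flipped = pairwise_rchh(matrix, b, a, 5.0)
            assert [(r.start_idx, r.end_idx) for r in regions] == [
                (r.start_idx, r.end_idx) for r in flipped
            ]

    def test_cutoff_monotonicity(self, rng):
        panel = make_panel({"1": 60})
        matrix = random_matrix(rng, panel, 2)
        a, b = matrix.sample_ids
        counts = [len(pairwise_rchh(matrix, a, b, c)) for c in (1.0, 4.0, 8.0, 16.0)]
        assert counts == sorted(counts, reverse=True)

    def test_truncation_by_injected_error(self):
        # an injected opposite homozygote splits a region into two intervals
        # whose union is the original minus the error marker
        panel = make_panel({"1": 51})
        a = [HOM_REF] * 51
        b = [HOM_REF] * 51
        m = make_matrix(panel, {"a": a, "b": b})
        (orig,) = pairwise_rchh(m, "a", "b", 5.0)
        b_err = list(b)
        b_err[17] = HOM_ALT
        m2 = make_matrix(panel, {"a": a, "b": b_err})
        parts = pairwise_rchh(m2, "a", "b", 5.0)
        covered = set()
        for r in parts:
            covered.update(range(r.start_idx, r.end_idx + 1))
        assert covered == set(range(orig.start_idx, orig.end_idx + 1)) - {17}


# ---------------------------------------------------------------- pool test
class TestPoolComparison:
    def test_equal_proportions(self):
        z, p, nl = pool_comparison_test(3, 6, 5, 10)
        assert z == 0.0
        assert p == 0.5

    def test_eleven_eleven_vs_seventeen_twentysix(self):
        z, p, nl = pool_comparison_test(11, 11, 17, 26)
        assert z == pytest.approx(2.2431, abs=5e-5)
        assert p == pytest.approx(oracle_norm_sf(z), abs=1e-12)
        assert p == pytest.approx(0.01244, abs=5e-6)

    def test_threshold_consistency_with_stated_p(self):
        # -log10(0.06) = 1.2218...: the 1.2 threshold corresponds to p = 0.06
        assert -math.log10(0.06) == pytest.approx(1.2218, abs=1e-4)
        assert round(10 ** -1.2, 2) == 0.06

    def test_degenerate_pooled_proportion(self):
        assert pool_comparison_test(0, 5, 0, 9)[:2] == (0.0, 0.5)
        assert pool_comparison_test(5, 5, 9, 9)[:2] == (0.0, 0.5)

    def test_empty_pool_rejected(self):
        with pytest.raises(HHMapError):
            pool_comparison_test(0, 0, 1, 2)

    def test_matches_oracle_on_random_counts(self, rng):
        for _ in range(1000):
            n1 = int(rng.integers(1, 40))
            n2 = int(rng.integers(1, 40))
            k1 = int(rng.integers(0, n1 + 1))
            k2 = int(rng.integers(0, n2 + 1))
            z, p, nl = pool_comparison_test(k1, n1, k2, n2)
            p_hat = (k1 + k2) / (n1 + n2)
            if p_hat in (0.0, 1.0):
                assert (z, p) == (0.0, 0.5)
                continue
            se = math.sqrt(p_hat * (1 - p_hat) * (1 / n1 + 1 / n2))
            z_o = (k1 / n1 - k2 / n2) / se
            assert abs(p - oracle_norm_sf(z_o)) < 1e-10
            assert nl == pytest.approx(-math.log10(p))

    def test_p_decreases_as_k1_increases(self):
        ps = [pool_comparison_test(k1, 10, 2, 20)[1] for k1 in range(0, 10)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    @given(
        st.integers(1, 30).flatmap(
            lambda n1: st.tuples(
                st.integers(0, n1),
                st.just(n1),
                st.integers(1, 30).flatmap(
                    lambda n2: st.tuples(st.integers(0, n2), st.just(n2))
                ),
            )
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_output_domain(self, args):
        k1, n1, (k2, n2) = args
        z, p, nl = pool_comparison_test(k1, n1, k2, n2)
        assert 0.0 < p < 1.0 or p == 0.5
        assert nl == pytest.approx(-math.log10(p))


# ---------------------------------------------------------------- filtering
def _rep(neg_log10_p, start_idx=0):
    return RepresentativeRCHH(
        family_id="f",
        chrom="1",
        start_idx=start_idx,
        end_idx=start_idx + 1,
        start_bp=1,
        end_bp=2,
        start_marker="rs1",
        end_marker="rs2",
        length_cm=10.0,
        patient_sharers=("a", "b"),
        k1=2,
        n1=2,
        k2=0,
        n2=2,
        z=0.0,
        p_value=None if neg_log10_p is None else 10 ** -neg_log10_p,
        neg_log10_p=neg_log10_p,
    )


class TestSignificant:
    def test_fixture_threshold_12_keeps_all_rows(self):
        from hhmap.fixtures import load_fixtures

        t2 = load_fixtures().table2
        reps = [_rep(v, i) for i, v in enumerate(t2["neg_log10_p"])]
        kept = significant_rchhs(reps, 1.2)
        assert len(kept) == len(t2) == 106  # the table lists only significant rows

    def test_fixture_threshold_19(self):
        from hhmap.fixtures import load_fixtures

        t2 = load_fixtures().table2
        reps = [_rep(v, i) for i, v in enumerate(t2["neg_log10_p"])]
        kept = significant_rchhs(reps, 1.9)
        assert [r.neg_log10_p for r in kept] == [1.96]

    def test_infinite_threshold_empty(self):
        assert significant_rchhs([_rep(3.0)], math.inf) == []

    def test_null_p_dropped(self):
        assert significant_rchhs([_rep(None)], 0.0) == []


# ---------------------------------------------------------------- scan
class TestSharedScan:
    def _separated_cohort(self):
        panel = make_panel({"1": 51})
        pat = [HOM_REF] * 51
        ctl = [HOM_REF] * 51
        ctl[25] = HOM_ALT
        calls = {f"p{i}": pat for i in range(3)}
        calls.update({f"c{i}": ctl for i in range(3)})
        matrix = make_matrix(panel, calls)
        ped = flat_pedigree(matrix.sample_ids, affected={"p0", "p1", "p2"})
        return matrix, ped

    def test_constructed_separation(self):
        matrix, ped = self._separated_cohort()
        reps = shared_rchh_scan(matrix, ped, "FAM1", 7.0, 1.0)
        assert len(reps) == 1
        r = reps[0]
        assert (r.k1, r.n1, r.k2, r.n2) == (3, 3, 0, 3)
        assert (r.start_idx, r.end_idx) == (0, 50)
        assert r.neg_log10_p > 1.2

    def test_report_row_shape(self):
        from hhmap.pipeline import format_rep_row

        matrix, ped = self._separated_cohort()
        (r,) = shared_rchh_scan(matrix, ped, "FAM1", 7.0, 1.0)
        row = format_rep_row(r)
        assert row[1] == "3 out of 3"
        assert row[2] == "0 out of 3"
        assert row[3] == "1"
        assert row[4] == f"{r.start_bp}-{r.end_bp}"
        assert row[5] == "rs1_0-rs1_50"
        assert float(row[6]) == pytest.approx(r.neg_log10_p, abs=1e-3)

    def test_empty_control_pool_yields_null_p(self):
        panel = make_panel({"1": 51})
        row = [HOM_REF] * 51
        matrix = make_matrix(panel, {"p0": row, "p1": row})
        ped = flat_pedigree(["p0", "p1"], affected={"p0", "p1"})
        reps = shared_rchh_scan(matrix, ped, "FAM1", 7.0, 1.0)
        assert len(reps) == 1
        assert reps[0].n2 == 0
        assert reps[0].p_value is None and reps[0].neg_log10_p is None

    def test_needs_two_genotyped_affected(self):
        panel = make_panel({"1": 10})
        matrix = make_matrix(panel, {"p0": [HOM_REF] * 10})
        ped = flat_pedigree(["p0"], affected={"p0"})
        with pytest.raises(HHMapError, match="need >= 2"):
            shared_rchh_scan(matrix, ped, "FAM1")

    def test_recovers_implant_on_synthetic_family(self):
        from hhmap.simulate import SimulationConfig, simulate_cohort

        cfg = SimulationConfig(seed=1)
        panel, matrix, ped, truth = simulate_cohort(cfg)
        reps = shared_rchh_scan(matrix, ped, cfg.family_id, 7.0, 1.0)
        top = max(reps, key=lambda r: (r.neg_log10_p or 0, r.k1))
        assert top.chrom == truth.implant_chrom
        assert top.start_bp <= truth.implant_end_bp
        assert truth.implant_start_bp <= top.end_bp


# ---------------------------------------------------------------- reliability
class TestReliability:
    def _two_sample_one_marker(self):
        panel = make_panel({"1": 1})
        return make_matrix(panel, {"a": [HOM_REF], "b": [HOM_REF]})

    def test_zero_epsilon(self):
        m = self._two_sample_one_marker()
        res = genotyping_error_reliability(m, ("1", 0, 0), ["a", "b"], 0.0, 1000, seed=1)
        assert res.probability == 0.0
        assert res.reliable is True

    @pytest.mark.parametrize("eps", [0.01, 0.1])
    def test_closed_form_single_marker(self, eps):
        # dhSNP needs exactly one member flipped to the opposite homozygote
        # while the other keeps the same homozygous call: P = eps * (1 - eps)
        m = self._two_sample_one_marker()
        n = 100_000
        res = genotyping_error_reliability(m, ("1", 0, 0), ["a", "b"], eps, n, seed=7)
        expected = eps * (1 - eps)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(res.probability - expected) <= 3 * se

    def test_reliable_flag_threshold(self):
        m = self._two_sample_one_marker()
        res = genotyping_error_reliability(m, ("1", 0, 0), ["a", "b"], 0.1, 2000, seed=3)
        assert res.reliable is (res.probability < 0.001)

    def test_preexisting_dhsnp_pairs_excluded(self):
        panel = make_panel({"1": 1})
        m = make_matrix(panel, {"a": [HOM_REF], "b": [HOM_ALT]})
        res = genotyping_error_reliability(m, ("1", 0, 0), ["a", "b"], 0.5, 500, seed=2)
        assert res.probability == 0.0

    def test_epsilon_out_of_range(self):
        m = self._two_sample_one_marker()
        with pytest.raises(HHMapError):
            genotyping_error_reliability(m, ("1", 0, 0), ["a", "b"], 1.5, 10)

    def test_seeded_reproducibility(self):
        m = self._two_sample_one_marker()
        r1 = genotyping_error_reliability(m, ("1", 0, 0), ["a", "b"], 0.2, 5000, seed=9)
        r2 = genotyping_error_reliability(m, ("1", 0, 0), ["a", "b"], 0.2, 5000, seed=9)
        assert r1.probability == r2.probability


# ---------------------------------------------------------------- RCA length
class TestRcaExpectedLength:
    @pytest.mark.parametrize(
        "m,n,expected",
        [(1, 0, 1.0), (1, 1, 0.75), (2, 0, 0.5), (3, 2, 0.125), (2, 2, 0.25)],
    )
    def test_piecewise_values(self, m, n, expected):
        assert rca_expected_length(m, n) == expected

    def test_n_greater_than_m_rejected(self):
        with pytest.raises(HHMapError):
            rca_expected_length(1, 2)

    def test_m_zero_rejected(self):
        with pytest.raises(HHMapError):
            rca_expected_length(0, 0)

    @given(st.integers(1, 40), st.integers(0, 40))
    @settings(max_examples=200, deadline=None)
    def test_branches(self, m, extra):
        n = min(m, extra)
        v = rca_expected_length(m, n)
        if n == 0:
            assert v == 2.0 ** (-m + 1)
        elif m == 1 and n == 1:
            assert v == 0.75
        else:
            assert v == 2.0 ** (-m - n + 2)
        assert 0 < v <= 1.0
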