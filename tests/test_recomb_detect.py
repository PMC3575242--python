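import numpy as np
import pytest
from scipy import stats

from pokeyrec import recomb_detect as rd
from pokeyrec.core_io import strip_columns
from pokeyrec.synthetic_data import (
    SimConfig,
    pool_to_alignment,
    simulate_parent_pools,
    simulate_recombinants,
)
from .conftest import make_aln


# ---------------------------------------------------------------------------
# independent oracles


def rm_oracle(binary_rows: np.ndarray) -> int:
    """Weighted-interval-scheduling DP over four-gamete-incompatible site
    pairs (independent of the production greedy + reduction route)."""
    n, K = binary_rows.shape
    intervals = []
    for i in range(K):
        for j in range(i + 1, K):
            gametes = {(int(a), int(b)) for a, b in zip(binary_rows[:, i], binary_rows[:, j])}
            if len(gametes) == 4:
                intervals.append((i, j))
    if not intervals:
        return 0
    intervals.sort(key=lambda iv: iv[1])
    ends = [iv[1] for iv in intervals]
    best = [0] * (len(intervals) + 1)
    import bisect

    for t, (i, j) in enumerate(intervals, start=1):
        # latest interval ending at or before this one's start (open intervals
        # may share an endpoint)
        k = bisect.bisect_right(ends, i, hi=t - 1)
        best[t] = max(best[t - 1], best[k] + 1)
    return best[-1]


def random_binary_alignment(rng, n=8, K=15):
    rows = rng.integers(0, 2, size=(n, K))
    # ensure every column is truly biallelic to keep site indexing aligned
    for j in range(K):
        if len(set(rows[:, j])) == 1:
            rows[rng.integers(0, n), j] ^= 1
    residues = np.where(rows == 0, b"A", b"G").astype("S1")
    aln = make_aln({f"s{i}": residues[i].tobytes().decode() for i in range(n)})
    return aln, rows


# ---------------------------------------------------------------------------
# phi test


class TestPhi:
    def test_tree_like_data_has_zero_statistic(self):
        # perfectly nested (compatible) informative sites
        rows = {
            "a": "AAAA", "b": "AAAA", "c": "GAAA", "d": "GGAA",
            "e": "GGGA", "f": "GGGG",
        }
        r = rd.phi_test(make_aln(rows), window_w=100, n_perm=200, seed=0)
        assert r.testable and r.phi_stat == 0.0

    def test_identical_sequences_not_testable(self):
        r = rd.phi_test(make_aln({"a": "ACGT" * 5, "b": "ACGT" * 5}), seed=0)
        assert not r.testable and r.p_value is None

    def test_power_on_mosaics_and_control_on_nulls(self, mosaic_scenario):
        aln, _, _ = mosaic_scenario
        r = rd.phi_test(aln, n_perm=1000, seed=1)
        assert r.p_value < 0.01
        rejections = 0
        for seed in range(20):
            pool, _ = simulate_parent_pools(SimConfig(seed=3000 + seed))
            rn = rd.phi_test(pool_to_alignment(pool), n_perm=400, seed=seed)
            if rn.testable and rn.p_value < 0.05:
                rejections += 1
        assert rejections <= 3  # type-I control at the nominal level


# ---------------------------------------------------------------------------
# maximum chi-square


class TestMaxChi:
    def test_perfect_association_chi2_equals_table_total(self):
        # 100 matches / 0 mismatches vs 0 / 100: chi2 = N = 200
        assert rd._chi2_2x2(np.array([0]), np.array([100]), 100)[0] == pytest.approx(200.0)

    def test_scan_finds_planted_junction(self):
        cfg = SimConfig(n_parents=7, alleles_per_parent=2, seed=11)
        pool, truth = simulate_parent_pools(cfg)
        rec, _ = simulate_recombinants(pool, truth, [("P1_a2", "P2_a2", [700])], seed=12)
        keep = {f"P{p}_a1": pool[f"P{p}_a1"] for p in range(1, 8)}
        keep.update(rec)
        calls = rd.maxchi_scan(pool_to_alignment(keep), n_perm=2000, seed=5)
        rec_id = next(iter(rec))
        covering = [
            c for c in calls
            if rec_id in c.seq_pair and c.interval[0] <= 700 <= c.interval[1]
        ]
        assert covering, [(c.seq_pair, c.interval) for c in calls]

    def test_needs_three_sequences(self):
        with pytest.raises(ValueError):
            rd.maxchi_scan(make_aln({"a": "ACGT", "b": "ACGA"}))

    def test_identical_sequences_produce_no_calls(self):
        aln = make_aln({k: "ACGT" * 60 for k in "abc"})
        assert rd.maxchi_scan(aln, n_perm=100, seed=0) == []

    def test_statistic_invariant_to_nucleotide_relabeling(self):
        cfg = SimConfig(n_parents=5, L=600, seed=21, alleles_per_parent=1)
        pool, truth = simulate_parent_pools(cfg)
        rec, _ = simulate_recombinants(pool, truth, [("P1_a1", "P2_a1", [300])], seed=2)
        pool = {**pool, **rec}
        relabel = str.maketrans("ACGT", "CGTA")
        pool2 = {k: v.translate(relabel) for k, v in pool.items()}
        c1 = rd.maxchi_scan(pool_to_alignment(pool), half_widths=(40,), n_perm=500, seed=3)
        c2 = rd.maxchi_scan(pool_to_alignment(pool2), half_widths=(40,), n_perm=500, seed=3)
        assert [(c.seq_pair, c.interval, round(c.chi2, 9)) for c in c1] == [
            (c.seq_pair, c.interval, round(c.chi2, 9)) for c in c2
        ]

    def test_null_p_values_are_uniform(self):
        """KS check of the Monte Carlo p-value machinery on null data."""
        h, n_perm = 30, 1500
        ps = []
        for seed in range(150):
            cfg = SimConfig(n_parents=5, L=1000, seed=10_000 + seed,
                            alleles_per_parent=1, within_group_theta=0.0)
            pool, _ = simulate_parent_pools(cfg)
            m = strip_columns(pool_to_alignment(pool)).matrix()
            seg = np.flatnonzero((m != m[0]).any(axis=0))
            K = seg.size
            if K < 2 * h + 20:
                continue
            dpos = np.flatnonzero(m[0, seg] != m[1, seg])
            if dpos.size < 2:
                continue
            profile = rd._cut_chi2_profile(dpos, K, h)
            obs = float(profile.max())
            null = rd._PlacementNull([(0, K)], [dpos.size], K, (h,), seed=seed)
            null.ensure(n_perm)
            ps.append((1 + (null.maxima[h] >= obs - 1e-9).sum()) / (1 + n_perm))
        assert len(ps) >= 100
        assert stats.kstest(ps, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# event merging


def call(pair, interval, h=70, step=1):
    return rd.BreakpointCall(
        seq_pair=pair, interval=interval, chi2=10.0, p_value=0.01,
        half_width=h, step_index=step, cut=sum(interval) // 2,
    )


class TestMergeCalls:
    def test_identical_intervals_become_one_event(self):
        calls = [call((f"x{i}", f"y{i}"), (592, 607)) for i in range(5)]
        events = rd.merge_calls(calls)
        assert len(events) == 1
        assert events[0].label == "I"
        assert events[0].interval == (592, 607)

    def test_overlapping_but_distinct_intervals_stay_separate(self):
        events = rd.merge_calls([call(("a", "b"), (815, 856)), call(("c", "d"), (825, 856))])
        assert [e.interval for e in events] == [(815, 856), (825, 856)]
        assert [e.label for e in events] == ["I", "II"]

    def test_empty_input(self):
        assert rd.merge_calls([]) == []

    def test_merging_is_order_independent_and_bounded(self):
        calls = [
            call(("a", "b"), (100, 120)),
            call(("c", "d"), (100, 120)),
            call(("e", "f"), (300, 330)),
        ]
        fwd = rd.merge_calls(calls)
        rev = rd.merge_calls(list(reversed(calls)))
        assert [e.interval for e in fwd] == [e.interval for e in rev]
        assert len(fwd) <= len(calls)

    def test_jaccard_rule_unions_near_identical_intervals(self):
        events = rd.merge_calls(
            [call(("a", "b"), (100, 200)), call(("c", "d"), (105, 200))],
            rule="jaccard", jaccard_threshold=0.9,
        )
        assert len(events) == 1
        assert events[0].interval == (100, 200)

    def test_roman_labels(self):
        assert [rd.roman(k) for k in (1, 4, 7, 9, 14)] == ["I", "IV", "VII", "IX", "XIV"]


# ---------------------------------------------------------------------------
# Rm and Rh


class TestRm:
    def test_four_gametes_on_two_sites(self):
        aln = make_aln({"a": "AA", "b": "AG", "c": "GA", "d": "GG"})
        r = rd.hudson_kaplan_rm(aln)
        assert r.rm == 1
        assert r.chosen_disjoint_set == [(1, 2)]

    def test_tree_like_data_has_rm_zero(self):
        rows = {"a": "AAAA", "b": "GAAA", "c": "GGAA", "d": "GGGA"}
        assert rd.hudson_kaplan_rm(make_aln(rows)).rm == 0

    def test_matches_scheduling_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(150):
            aln, rows = random_binary_alignment(rng)
            assert rd.hudson_kaplan_rm(aln).rm == rm_oracle(rows)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(9)
        aln, _ = random_binary_alignment(rng)
        rev = make_aln({r.id: r.residues for r in reversed(aln.records)})
        assert rd.hudson_kaplan_rm(aln).rm == rd.hudson_kaplan_rm(rev).rm


class TestRh:
    def test_four_haplotypes_two_sites_local_bound(self):
        aln = make_aln({"a": "AA", "b": "AG", "c": "GA", "d": "GG"})
        r = rd.haplotype_bound_rh(aln)
        assert r.rh == 1
        assert r.dp_trace == [(1, 2, 1)]

    def test_identical_sequences_give_zero(self):
        aln = make_aln({"a": "ACGT" * 3, "b": "ACGT" * 3})
        assert rd.haplotype_bound_rh(aln).rh == 0

    def test_rh_dominates_rm_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(150):
            aln, _ = random_binary_alignment(rng)
            assert rd.haplotype_bound_rh(aln).rh >= rd.hudson_kaplan_rm(aln).rm

    def test_column_order_invariance_of_both_bounds(self):
        rng = np.random.default_rng(13)
        aln, rows = random_binary_alignment(rng)
        # reversing columns mirrors intervals; the bounds are unchanged
        rev = make_aln({r.id: r.residues[::-1] for r in aln.records})
        assert rd.hudson_kaplan_rm(aln).rm == rd.hudson_kaplan_rm(rev).rm
        assert rd.haplotype_bound_rh(aln).rh == rd.haplotype_bound_rh(rev).rh


# ---------------------------------------------------------------------------
# fragment scan


class TestFragmentScan:
    def test_duplicated_segment_data_yields_no_breakpoints(self):
        # both halves generated by the same process: no incongruence signal
        cfg = SimConfig(n_parents=4, L=400, seed=3, alleles_per_parent=2)
        pool, _ = simulate_parent_pools(cfg)
        doubled = {k: v + v for k, v in pool.items()}
        assert rd.fragment_scan(pool_to_alignment(doubled)) == []

    def test_too_short_alignment_returns_empty_with_warning(self):
        aln = make_aln({"a": "ACGT", "b": "ACGA", "c": "GCGT"})
        with pytest.warns(UserWarning):
            assert rd.fragment_scan(aln) == []

    def test_recovers_planted_double_breakpoint(self):
        cfg = SimConfig(n_parents=5, L=1450, d=0.08, alleles_per_parent=2, seed=100)
        pool, truth = simulate_parent_pools(cfg)
        rec, _ = simulate_recombinants(
            pool, truth, [("P1_a1", "P2_a1", [500, 900])], n_copies=2, seed=0
        )
        bps = rd.fragment_scan(pool_to_alignment({**pool, **rec}))
        assert len(bps) == 2
        assert abs(bps[0] - 500) <= 30 and abs(bps[1] - 900) <= 30

    def test_null_and_recovery_rates(self):
        """Recombination-free data stays unsplit in >= 90% of runs; a
        donor-swapped middle segment (d = 0.08) is recovered within
        +-30 bp in >= 80%."""
        from pokeyrec import evaluation as ev

        out = ev.fragment_scan_rates(n_runs=50, seed=8)
        assert out["null_empty_rate"] >= 0.90, out
        assert out["recovery_rate"] >= 0.80, out

    def test_deterministic(self):
        cfg = SimConfig(n_parents=5, L=800, seed=5)
        pool, _ = simulate_parent_pools(cfg)
        aln = pool_to_alignment(pool)
        assert rd.fragment_scan(aln) == rd.fragment_scan(aln)
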