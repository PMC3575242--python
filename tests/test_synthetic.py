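import numpy as np
import pytest

from pokeyrec import diversity as div
from pokeyrec.synthetic_data import (
    ConfigError,
    SimConfig,
    breakpoint_recovery_scenario,
    inject_pcr_chimeras,
    pool_to_alignment,
    sample_isolates,
    simulate_parent_pools,
    simulate_recombinants,
)


class TestParentPools:
    def test_zero_rates_give_identical_sequences(self):
        cfg = SimConfig(n_parents=3, L=300, d=1e-9, within_group_theta=0.0, seed=1)
        pool, truth = simulate_parent_pools(cfg)
        assert len(set(pool.values())) <= 2  # d ~ 0: at most rare stray hits
        cfg0 = SimConfig(n_parents=3, L=300, d=1e-12, within_group_theta=0.0, seed=1)
        pool0, _ = simulate_parent_pools(cfg0)
        assert len(set(pool0.values())) == 1

    def test_all_invariant_limit(self):
        with pytest.raises(ConfigError):
            # d cannot be realized when every site is invariant
            SimConfig(p_inv=0.99, d=0.06)

    def test_fixed_seed_reproducible(self):
        cfg = SimConfig(seed=42, L=500)
        a, ta = simulate_parent_pools(cfg)
        b, tb = simulate_parent_pools(cfg)
        assert a == b
        assert ta.to_frame().equals(tb.to_frame())

    def test_pooled_diversity_in_expected_band(self):
        # study conditions: 5 lineages, L=1450, d=0.06, alpha=0.8423, p_inv=0.633
        pis = []
        for seed in range(5):
            cfg = SimConfig(seed=7 + seed)
            pool, _ = simulate_parent_pools(cfg)
            pis.append(div.nucleotide_diversity(pool_to_alignment(pool)))
        assert 0.03 <= float(np.mean(pis)) <= 0.07

    def test_inter_parent_distance_within_20pct_of_target(self):
        cfg = SimConfig(seed=3, within_group_theta=0.0, alleles_per_parent=1)
        pool, _ = simulate_parent_pools(cfg)
        m = pool_to_alignment(pool).matrix()
        ds = [
            (m[i] != m[j]).mean()
            for i in range(len(pool))
            for j in range(i + 1, len(pool))
        ]
        assert abs(np.mean(ds) - cfg.d) <= 0.2 * cfg.d

    def test_region_rate_multiplier_shifts_diversity(self):
        ratios = []
        for seed in range(8):
            cfg = SimConfig(
                L=900, seed=seed, rate_regions=((451, 900, 10.0),),
                within_group_theta=0.0, alleles_per_parent=1,
            )
            pool, _ = simulate_parent_pools(cfg)
            aln = pool_to_alignment(pool)
            left = aln.take_columns(np.arange(0, 450))
            right = aln.take_columns(np.arange(450, 900))
            pi_l = div.nucleotide_diversity(left)
            pi_r = div.nucleotide_diversity(right)
            if pi_l > 0:
                ratios.append(pi_r / pi_l)
        assert 5 <= float(np.mean(ratios)) <= 20


class TestRecombinants:
    def test_single_breakpoint_is_exact_splice(self):
        cfg = SimConfig(n_parents=2, L=400, seed=5, alleles_per_parent=1)
        pool, truth = simulate_parent_pools(cfg)
        rec, rt = simulate_recombinants(pool, truth, [("P1_a1", "P2_a1", [200])], seed=1)
        (rid, seq), = rec.items()
        assert seq[:200] == pool["P1_a1"][:200]
        assert seq[200:] == pool["P2_a1"][200:]
        assert rt[rid].breakpoints() == [200]

    def test_empty_event_list_is_identity(self):
        cfg = SimConfig(n_parents=2, L=200, seed=5)
        pool, truth = simulate_parent_pools(cfg)
        rec, rt = simulate_recombinants(pool, truth, [], seed=1)
        assert rec == {}

    def test_nested_events_resolve_to_three_donor_segments(self):
        # group-a style history: c originates from d x i, then a from h x c
        cfg = SimConfig(n_parents=4, L=600, seed=9, alleles_per_parent=1)
        pool, truth = simulate_parent_pools(cfg)
        c_pool, c_truth = simulate_recombinants(
            pool, truth, [("P1_a1", "P2_a1", [300])], seed=1
        )
        merged_pool = {**pool, **c_pool}
        merged_truth = truth.merged(c_truth)
        cid = next(iter(c_pool))
        a_pool, a_truth = simulate_recombinants(
            merged_pool, merged_truth, [("P3_a1", cid, [150])], seed=2
        )
        aid = next(iter(a_pool))
        segs = a_truth[aid].segments
        assert [s.donor for s in segs] == ["P3", "P1", "P2"]
        assert [s.start for s in segs] == [1, 151, 301]

    def test_bad_breakpoint_rejected(self):
        cfg = SimConfig(n_parents=2, L=200, seed=5)
        pool, truth = simulate_parent_pools(cfg)
        with pytest.raises(ConfigError):
            simulate_recombinants(pool, truth, [("P1", "P2", [200])], seed=1)

    def test_truth_segments_tile_sequence(self, mosaic_scenario):
        aln, truth, _ = mosaic_scenario
        for sid in aln.ids:
            segs = truth[sid].segments
            assert segs[0].start == 1 and segs[-1].end == aln.length
            for a, b in zip(segs[:-1], segs[1:]):
                assert b.start == a.end + 1


class TestChimeras:
    def test_rate_zero_is_identity(self):
        cfg = SimConfig(n_parents=2, L=200, seed=5)
        pool, truth = simulate_parent_pools(cfg)
        out, ot = inject_pcr_chimeras(pool, truth, rate=0.0, seed=1)
        assert out == dict(pool)
        assert not any(t.chimera for _, t in ot.items())

    def test_rate_one_flags_everything(self):
        cfg = SimConfig(n_parents=2, L=200, seed=5, alleles_per_parent=1)
        pool, truth = simulate_parent_pools(cfg)
        out, ot = inject_pcr_chimeras(pool, truth, rate=1.0, seed=1)
        assert all(t.chimera for _, t in ot.items())

    def test_bad_rate_rejected(self):
        cfg = SimConfig(n_parents=2, L=200, seed=5)
        pool, truth = simulate_parent_pools(cfg)
        with pytest.raises(ConfigError):
            inject_pcr_chimeras(pool, truth, rate=1.5, seed=1)


class TestIsolateSampling:
    def test_single_allele_isolate_yields_identical_clones(self):
        cfg = SimConfig(n_parents=3, L=200, seed=5)
        pool, truth = simulate_parent_pools(cfg)
        out, ot = sample_isolates(
            pool, truth, n_isolates=1, alleles_per_isolate=(1, 1),
            clones_per_isolate=(12, 12), seed=2,
        )
        assert len(out) == 12
        assert len(set(out.values())) == 1
        assert all(t.isolate == "ISO1" for _, t in ot.items())

    def test_undersampling_of_many_alleles(self):
        # 5 alleles, 12 clones with replacement: sometimes < 5 recovered
        cfg = SimConfig(n_parents=5, L=200, seed=5, alleles_per_parent=1)
        pool, truth = simulate_parent_pools(cfg)
        missed = 0
        for seed in range(30):
            out, _ = sample_isolates(
                pool, truth, n_isolates=1, alleles_per_isolate=(5, 5),
                clones_per_isolate=(12, 12), seed=seed,
            )
            missed += len(set(out.values())) < 5
        # P(all 5 seen in 12 draws) ~ 0.72, so some misses are expected
        assert 0 < missed < 30

    def test_too_many_alleles_requested(self):
        cfg = SimConfig(n_parents=2, L=200, seed=5, alleles_per_parent=1)
        pool, truth = simulate_parent_pools(cfg)
        with pytest.raises(ConfigError):
            sample_isolates(pool, truth, 1, alleles_per_isolate=(1, 5))


class TestRecoveryScenario:
    def test_scenario_is_reproducible_and_truthful(self):
        a1, bp1 = breakpoint_recovery_scenario(seed=5)
        a2, bp2 = breakpoint_recovery_scenario(seed=5)
        assert bp1 == bp2
        assert a1 == a2
        null, bp_null = breakpoint_recovery_scenario(seed=5, recombinant=False)
        assert bp_null is None and null.n == a1.n - 1
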