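"""Validation experiments: oracle cross-checks and parameter-recovery rates.

Each function runs a self-contained seeded experiment against the package's
own synthetic data and returns plain numbers, so the same code backs the
acceptance tests and the reproduction script.  Brute-force oracles here are
deliberately written as different algorithms from the production routines
they check (pairwise loops instead of matrix code; weighted interval
scheduling instead of greedy reduction).
"""

from __future__ import annotations

import bisect
from dataclasses import replace

import numpy as np

from . import diversity as div
from . import phylo
from . import recomb_detect as rd
from . import rflp
from .core_io import Alignment, SequenceRecord
from .synthetic_data import (
    SimConfig,
    breakpoint_recovery_scenario,
    default_mosaic_scenario,
    inject_pcr_chimeras,
    sample_isolates,
    simulate_parent_pools,
)

__all__ = [
    "pi_theta_oracle_errors",
    "rm_oracle_mismatches",
    "rh_rm_violations",
    "breakpoint_recovery_rates",
    "maxchi_false_call_rate",
    "assignment_accuracy",
    "fragment_scan_rates",
    "phi_rates",
    "rflp_conformation_count",
    "rflp_screen_summary",
]


def _random_alignment(rng: np.random.Generator, n: int, L: int) -> Alignment:
    m = rng.choice(list("ACGT"), size=(n, L))
    return Alignment([SequenceRecord(f"s{i}", "".join(m[i])) for i in range(n)])


# ---------------------------------------------------------------------------
# brute-force oracles


def _pi_oracle(aln: Alignment) -> float:
    m = aln.matrix()
    n, L = m.shape
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += sum(1 for k in range(L) if m[i, k] != m[j, k])
    return total / (n * (n - 1) / 2) / L


def _theta_oracle(aln: Alignment) -> float:
    m = aln.matrix()
    n, L = m.shape
    S = sum(1 for k in range(L) if len({m[i, k] for i in range(n)}) > 1)
    return S / sum(1.0 / k for k in range(1, n)) / L


def _rm_oracle(aln: Alignment) -> int:
    """Maximum disjoint four-gamete-incompatible intervals by weighted
    interval scheduling (dynamic programming over right endpoints)."""
    m = aln.matrix()
    n, L = m.shape
    sites = [j for j in range(L) if len({m[i, j] for i in range(n)}) == 2]
    intervals = []
    for a in range(len(sites)):
        for b in range(a + 1, len(sites)):
            ja, jb = sites[a], sites[b]
            gam = {(m[i, ja], m[i, jb]) for i in range(n)}
            if len(gam) == 4:
                intervals.append((a, b))
    if not intervals:
        return 0
    intervals.sort(key=lambda iv: iv[1])
    ends = [iv[1] for iv in intervals]
    best = [0] * (len(intervals) + 1)
    for t, (i, j) in enumerate(intervals, start=1):
        k = bisect.bisect_right(ends, i, hi=t - 1)
        best[t] = max(best[t - 1], best[k] + 1)
    return best[-1]


# ---------------------------------------------------------------------------
# oracle agreement experiments


def pi_theta_oracle_errors(n_instances: int = 500, seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    err_pi = err_theta = 0.0
    for _ in range(n_instances):
        aln = _random_alignment(rng, int(rng.integers(3, 9)), int(rng.integers(10, 51)))
        err_pi = max(err_pi, abs(div.nucleotide_diversity(aln) - _pi_oracle(aln)))
        err_theta = max(err_theta, abs(div.watterson_theta(aln) - _theta_oracle(aln)))
    return {"pi_max_abs_error": err_pi, "theta_max_abs_error": err_theta,
            "n": n_instances}


def _random_binary_alignment(rng, n=8, K=15) -> Alignment:
    rows = rng.integers(0, 2, size=(n, K))
    for j in range(K):
        if len(set(rows[:, j])) == 1:
            rows[rng.integers(0, n), j] ^= 1
    residues = np.where(rows == 0, b"A", b"G").astype("S1")
    return Alignment(
        [SequenceRecord(f"s{i}", residues[i].tobytes().decode()) for i in range(n)]
    )


def rm_oracle_mismatches(n_instances: int = 500, seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    bad = 0
    for _ in range(n_instances):
        aln = _random_binary_alignment(rng)
        if rd.hudson_kaplan_rm(aln).rm != _rm_oracle(aln):
            bad += 1
    return {"mismatches": bad, "n": n_instances}


def rh_rm_violations(n_instances: int = 500, seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    bad = 0
    for _ in range(n_instances):
        aln = _random_binary_alignment(rng)
        if rd.haplotype_bound_rh(aln).rh < rd.hudson_kaplan_rm(aln).rm:
            bad += 1
    return {"violations": bad, "n": n_instances}


# ---------------------------------------------------------------------------
# detection calibration experiments


def breakpoint_recovery_rates(
    n_runs: int = 100,
    seed: int = 0,
    half_widths=(70, 80, 90, 100),
    n_perm: int = 10_000,
    alpha: float = 0.05,
) -> dict:
    """Fraction of runs in which a significant max chi-square call's interval
    covers the planted breakpoint, per half-width."""
    hits = {h: 0 for h in half_widths}
    for r in range(n_runs):
        aln, bp = breakpoint_recovery_scenario(seed=seed * 1_000_003 + r)
        calls = rd.maxchi_scan(
            aln, half_widths=half_widths, n_perm=n_perm, alpha=alpha, seed=seed + r
        )
        for h in half_widths:
            if any(
                c.half_width == h and c.interval[0] <= bp <= c.interval[1]
                for c in calls
            ):
                hits[h] += 1
    return {h: hits[h] / n_runs for h in half_widths} | {"n": n_runs}


def maxchi_false_call_rate(
    n_runs: int = 100, seed: int = 0, n_perm: int = 10_000, alpha: float = 0.05
) -> dict:
    """Fraction of recombination-free runs yielding any significant call."""
    false = 0
    for r in range(n_runs):
        aln, _ = breakpoint_recovery_scenario(
            seed=seed * 1_000_003 + r, recombinant=False
        )
        if rd.maxchi_scan(aln, n_perm=n_perm, alpha=alpha, seed=seed + r):
            false += 1
    return {"rate": false / n_runs, "n": n_runs}


def assignment_accuracy(n_scenarios: int = 10, seed: int = 0) -> dict:
    """Fraction of mosaics whose per-fragment nearest-group donors match the
    planted donor pair, over default mosaic scenarios (fragments delimited
    by each mosaic's true breakpoint)."""
    ok = tot = 0
    for s in range(n_scenarios):
        aln, truth, groups = default_mosaic_scenario(seed=seed * 7919 + s)
        for sid in aln.ids:
            segs = truth[sid].segments
            if len(segs) != 2:
                continue
            tot += 1
            dms = []
            for span in phylo.fragment_spans([segs[0].end], aln.length):
                lo, hi = span
                idx = np.flatnonzero(
                    (aln.column_map >= lo) & (aln.column_map <= hi)
                )
                dms.append((span, phylo.pairwise_distances(aln.take_columns(idx))))
            a = phylo.assign_parents(sid, dms, groups)
            ok += a.best_donors() == [segs[0].donor, segs[1].donor]
    return {"accuracy": ok / tot if tot else float("nan"), "n": tot}


def fragment_scan_rates(n_runs: int = 50, seed: int = 0) -> dict:
    """Null empty-set rate (d=0.06) and planted double-breakpoint recovery
    within +-30 bp (d=0.08, donor-swapped middle segment)."""
    from .synthetic_data import simulate_recombinants

    empty = 0
    for r in range(n_runs):
        cfg = SimConfig(alleles_per_parent=2, seed=seed * 4_007 + r)
        pool, _ = simulate_parent_pools(cfg)
        aln = Alignment([SequenceRecord(k, v) for k, v in pool.items()])
        if not rd.fragment_scan(aln):
            empty += 1
    hit = 0
    for r in range(n_runs):
        cfg = SimConfig(d=0.08, alleles_per_parent=2, seed=seed * 9_001 + r)
        pool, truth = simulate_parent_pools(cfg)
        rec, _ = simulate_recombinants(
            pool, truth, [("P1_a1", "P2_a1", [500, 900])], n_copies=2, seed=seed + r
        )
        aln = Alignment(
            [SequenceRecord(k, v) for k, v in {**pool, **rec}.items()]
        )
        bps = rd.fragment_scan(aln)
        if len(bps) == 2 and abs(bps[0] - 500) <= 30 and abs(bps[1] - 900) <= 30:
            hit += 1
    return {"null_empty_rate": empty / n_runs, "recovery_rate": hit / n_runs,
            "n": n_runs}


def phi_rates(n_runs: int = 30, seed: int = 0, n_perm: int = 1000) -> dict:
    """Power on default mosaic scenarios (p < 0.01) and rejection rate on
    recombination-free data (p < 0.05)."""
    power = 0
    for r in range(n_runs):
        aln, _, _ = default_mosaic_scenario(seed=seed * 31 + r)
        res = rd.phi_test(aln, n_perm=n_perm, seed=seed + r)
        power += res.testable and res.p_value < 0.01
    null_rej = 0
    for r in range(n_runs):
        pool, _ = simulate_parent_pools(SimConfig(seed=seed * 37 + r))
        aln = Alignment([SequenceRecord(k, v) for k, v in pool.items()])
        res = rd.phi_test(aln, n_perm=n_perm, seed=seed + r)
        null_rej += bool(res.testable and res.p_value < 0.05)
    return {"power": power / n_runs, "null_rejection_rate": null_rej / n_runs,
            "n": n_runs}


# ---------------------------------------------------------------------------
# RFLP experiments


def rflp_conformation_count(seed: int = 0, co_migration_bp: int = 40) -> dict:
    """Distinct, pairwise gel-distinguishable haplotype codes over all eight
    cut-presence patterns of the synthetic default amplicon."""
    import itertools

    profiles = []
    codes = set()
    for bits in itertools.product([False, True], repeat=3):
        prof = rflp.digest(rflp.synthetic_amplicon(sites=bits, seed=seed))
        codes.add(rflp.haplotype_code(prof, co_migration_bp=co_migration_bp).code)
        profiles.append(prof)
    distinguishable_pairs = sum(
        rflp.distinguishable(a.fragments, b.fragments, co_migration_bp)
        for a, b in itertools.combinations(profiles, 2)
    )
    all_distinct = distinguishable_pairs == len(profiles) * (len(profiles) - 1) // 2
    return {"n_codes": len(codes), "all_distinguishable": all_distinct}


def rflp_screen_summary(
    seed: int = 0,
    n_isolates: int = 41,
    chimera_rate: float = 0.0,
) -> dict:
    """In-silico PCR-RFLP screen of a synthetic isolate panel.

    Allele templates are the eight synthetic amplicons embedded in flanking
    sequence; isolates carry 1-5 alleles with the strong skew toward one or
    two that real screens show; clones are sampled 10-12 deep and digested.
    """
    rng = np.random.default_rng(seed)
    templates = {}
    truth_entries = {}
    from .synthetic_data import Segment, SeqTruth, SimTruth

    import itertools

    for k, bits in enumerate(itertools.product([False, True], repeat=3), start=1):
        tpl = rflp.synthetic_amplicon(sites=bits, seed=seed + k)
        padded = "".join(rng.choice(list("ACGT"), size=60)) + tpl + "".join(
            rng.choice(list("ACGT"), size=60)
        )
        templates[f"allele{k}"] = padded
        truth_entries[f"allele{k}"] = SeqTruth(
            segments=[Segment(f"allele{k}", 1, len(padded))]
        )
    truth = SimTruth(len(next(iter(templates.values()))), truth_entries)
    clones, clone_truth = sample_isolates(
        templates, truth, n_isolates=n_isolates,
        alleles_per_isolate=(1, 5), clones_per_isolate=(10, 12),
        seed=seed, allele_count_probs=(0.50, 0.32, 0.10, 0.05, 0.03),
    )
    if chimera_rate > 0:
        clones, clone_truth = inject_pcr_chimeras(
            clones, clone_truth, rate=chimera_rate, seed=seed + 1
        )
    by_isolate: dict[str, list[int]] = {}
    for sid, seq in clones.items():
        amps = rflp.in_silico_pcr(seq)
        if not amps:
            continue
        code = rflp.haplotype_code(rflp.digest(amps[0])).code
        by_isolate.setdefault(clone_truth[sid].isolate, []).append(code)
    out = rflp.isolate_summary(by_isolate)
    return {
        "mean": out["mean"], "sd": out["sd"], "max": out["max"],
        "n_isolates": out["n_isolates"],
    }
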