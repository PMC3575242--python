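"""Synthetic mosaic-sequence generator with full ground truth.

Emulates a set of divergent parental transposon lineages, mosaic
recombinants spliced from them at known breakpoints, per-isolate clone
sampling, and PCR-chimera artifacts, so every downstream stage (diversity,
breakpoint detection, fragment trees, RFLP) can be validated against a
truth record.

The substitution process is a jump process with among-site rate
heterogeneity: a site is invariant with probability ``p_inv``, otherwise its
relative rate is drawn from a 4-category discretized gamma with shape
``alpha``; substitution events follow a Kimura-style kernel with
transition/transversion bias ``kappa``.  Defaults target the study
conditions of the real data: L = 1450 bp, pooled diversity around
pi = 0.05, alpha = 0.8423, 63.3% invariant sites, parental divergence
d = 0.06.  Parental lineages radiate from a single root (star topology);
branch lengths are calibrated numerically so the realized mean inter-parent
distance matches ``d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, special

from .core_io import Alignment, SequenceRecord

__all__ = [
    "ConfigError",
    "SimConfig",
    "Segment",
    "SeqTruth",
    "SimTruth",
    "simulate_parent_pools",
    "simulate_recombinants",
    "inject_pcr_chimeras",
    "sample_isolates",
    "pool_to_alignment",
    "default_mosaic_scenario",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class ConfigError(ValueError):
    """Raised when a simulation configuration cannot be realized."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the parental-pool simulation.

    d is the target expected pairwise divergence between parental lineages
    (substitutions/site, p-distance scale); within_group_theta the expected
    pairwise divergence between alleles of the same lineage.
    """

    n_parents: int = 5
    L: int = 1450
    d: float = 0.06
    alpha: float = 0.8423
    p_inv: float = 0.633
    within_group_theta: float = 0.008
    alleles_per_parent: int = 3
    kappa: float = 2.0
    seed: int = 0
    indel_rate: float = 0.0
    # optional per-region rate multipliers (1-based inclusive intervals),
    # e.g. ((330, 956, 10.0),) makes the second exon evolve 10x faster
    rate_regions: tuple[tuple[int, int, float], ...] = ()

    def __post_init__(self) -> None:
        if not (0 < self.d < 0.75):
            raise ConfigError("d must be in (0, 0.75)")
        if self.alpha <= 0:
            raise ConfigError("alpha must be > 0")
        if not (0 <= self.p_inv < 1):
            raise ConfigError("p_inv must be in [0, 1)")
        if self.L <= 0 or self.n_parents < 1 or self.alleles_per_parent < 1:
            raise ConfigError("L, n_parents and alleles_per_parent must be positive")
        if self.d >= 0.75 * (1 - self.p_inv):
            raise ConfigError(
                "target divergence d is not realizable: saturation bound is "
                f"0.75*(1-p_inv) = {0.75 * (1 - self.p_inv):.3f}"
            )


@dataclass(frozen=True)
class Segment:
    """One donor segment of a sequence: 1-based inclusive bounds."""

    donor: str
    start: int
    end: int


@dataclass
class SeqTruth:
    segments: list[Segment]
    chimera: bool = False
    isolate: str | None = None

    def breakpoints(self) -> list[int]:
        """Positions after which the donor changes (end of each non-last segment)."""
        return [s.end for s in self.segments[:-1]]


class SimTruth:
    """Mapping sequence id -> :class:`SeqTruth`, with tiling validation."""

    def __init__(self, L: int, entries: Mapping[str, SeqTruth] | None = None):
        self.L = L
        self._entries: dict[str, SeqTruth] = dict(entries or {})
        for sid, t in self._entries.items():
            self._validate(sid, t)

    def _validate(self, sid: str, t: SeqTruth) -> None:
        pos = 1
        for seg in t.segments:
            if seg.start != pos or seg.end < seg.start:
                raise ValueError(f"truth segments for {sid!r} do not tile [1, {self.L}]")
            pos = seg.end + 1
        if pos != self.L + 1:
            raise ValueError(f"truth segments for {sid!r} do not tile [1, {self.L}]")

    def add(self, sid: str, truth: SeqTruth) -> None:
        self._validate(sid, truth)
        self._entries[sid] = truth

    def __getitem__(self, sid: str) -> SeqTruth:
        return self._entries[sid]

    def __contains__(self, sid: str) -> bool:
        return sid in self._entries

    def __iter__(self):
        return iter(self._entries)

    def items(self):
        return self._entries.items()

    def merged(self, other: "SimTruth") -> "SimTruth":
        if other.L != self.L:
            raise ValueError("cannot merge truths of different lengths")
        out = dict(self._entries)
        out.update(other._entries)
        return SimTruth(self.L, out)

    def to_frame(self):
        import pandas as pd

        rows = []
        for sid, t in self._entries.items():
            for k, seg in enumerate(t.segments):
                rows.append(
                    {
                        "seq_id": sid,
                        "segment_index": k,
                        "donor": seg.donor,
                        "start": seg.start,
                        "end": seg.end,
                        "chimera": t.chimera,
                        "isolate": t.isolate or "",
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# rate heterogeneity and branch-length calibration


def discrete_gamma_rates(alpha: float, k: int = 4) -> np.ndarray:
    """Mean relative rates of k equal-probability gamma categories (mean 1)."""
    # category boundaries of gamma(shape=alpha, scale=1/alpha)
    probs = np.arange(0, k + 1) / k
    bounds = special.gammaincinv(alpha, np.clip(probs, 0, 1 - 1e-12)) / alpha
    bounds[-1] = np.inf
    # partial expectations via the regularized incomplete gamma of shape alpha+1
    upper = special.gammainc(alpha + 1, np.where(np.isinf(bounds), 1e12, bounds) * alpha)
    rates = k * np.diff(upper)
    return rates / rates.mean() * 1.0


def _site_rates(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-site relative rates: 0 w.p. p_inv, else a gamma-category rate.

    Rates are normalized so the mean over all sites is 1; branch lengths are
    then expected substitutions per site.
    """
    cats = discrete_gamma_rates(cfg.alpha)
    rates = np.zeros(cfg.L)
    variable = rng.random(cfg.L) >= cfg.p_inv
    if variable.any():
        rates[variable] = rng.choice(cats, size=int(variable.sum()))
    for lo, hi, mult in cfg.rate_regions:
        rates[lo - 1 : hi] *= mult
    if rates.any():
        rates /= rates.mean()
    return rates


def _expected_p_distance(tau: float, rates: np.ndarray) -> float:
    """Expected pairwise p-distance for path length tau (JC-style correction)."""
    return float(np.mean(0.75 * (1.0 - np.exp(-4.0 / 3.0 * tau * rates))))


def _calibrate_branch(target_d: float, rates: np.ndarray) -> float:
    """Half-path branch length t so that E[p-distance at path 2t] = target_d."""
    ceiling = 0.75 * float(np.mean(rates > 0))
    if target_d >= ceiling:
        raise ConfigError(
            f"divergence {target_d} exceeds the saturation ceiling {ceiling:.3f} "
            "for these site rates"
        )
    f = lambda t: _expected_p_distance(2 * t, rates) - target_d
    return optimize.brentq(f, 0.0, 50.0)


def _mutate(seq: np.ndarray, t: float, rates: np.ndarray, kappa: float,
            rng: np.random.Generator) -> np.ndarray:
    """Evolve a (L,) uint8 base-index array along a branch of length t."""
    out = seq.copy()
    n_events = rng.poisson(t * rates)
    remaining = n_events.copy()
    # transition partner: A<->G (0<->2), C<->T (1<->3)
    while (active := remaining > 0).any():
        idx = np.flatnonzero(active)
        cur = out[idx]
        u = rng.random(idx.size)
        p_ts = kappa / (kappa + 2.0)
        is_ts = u < p_ts
        new = np.where(is_ts, cur ^ 2, 0)
        # transversion: pick one of the two bases of opposite purine/pyrimidine class
        tv_pick = (rng.random(idx.size) < 0.5).astype(np.uint8)
        # classes: purines {0,2}=A,G ; pyrimidines {1,3}=C,T
        other_class = np.where(cur % 2 == 0, 1, 0)  # target class parity
        tv_base = (other_class + 2 * tv_pick).astype(np.uint8)
        new = np.where(is_ts, new, tv_base).astype(np.uint8)
        out[idx] = new
        remaining[idx] -= 1
    return out


def _indices_to_str(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# operations


def simulate_parent_pools(cfg: SimConfig) -> tuple[dict[str, str], SimTruth]:
    """Generate allele pools for ``n_parents`` divergent lineages.

    A random root radiates to each parent along a calibrated branch; within
    each parent, ``alleles_per_parent`` alleles radiate again at the
    (smaller) within-lineage branch length.  Returns ``(pool, truth)`` where
    pool maps allele id (``P1_a1`` ...) to its sequence and every truth
    entry is a single full-length segment labelled with the parent lineage.
    """
    rng = np.random.default_rng(cfg.seed)
    rates = _site_rates(cfg, rng)
    root = rng.integers(0, 4, size=cfg.L).astype(np.uint8)
    t_between = _calibrate_branch(cfg.d, rates) if cfg.d > 0 else 0.0
    t_within = (
        _calibrate_branch(cfg.within_group_theta, rates)
        if cfg.within_group_theta > 0
        else 0.0
    )
    pool: dict[str, str] = {}
    truth = SimTruth(cfg.L)
    for p in range(1, cfg.n_parents + 1):
        parent = _mutate(root, t_between, rates, cfg.kappa, rng)
        lineage = f"P{p}"
        for a in range(1, cfg.alleles_per_parent + 1):
            allele = _mutate(parent, t_within, rates, cfg.kappa, rng)
            sid = f"{lineage}_a{a}"
            pool[sid] = _indices_to_str(allele)
            truth.add(sid, SeqTruth(segments=[Segment(lineage, 1, cfg.L)]))
    return pool, truth


def _spliced_segments(
    donor_truths: Sequence[SeqTruth], bounds: Sequence[tuple[int, int]]
) -> list[Segment]:
    """Segments of a splice, resolved through recombinant donors."""
    segs: list[Segment] = []
    pos = 1
    for truth, (lo, hi) in zip(donor_truths, bounds):
        for seg in truth.segments:
            s, e = max(seg.start, lo), min(seg.end, hi)
            if s > e:
                continue
            length = e - s + 1
            if segs and segs[-1].donor == seg.donor:
                segs[-1] = Segment(seg.donor, segs[-1].start, segs[-1].end + length)
            else:
                segs.append(Segment(seg.donor, pos, pos + length - 1))
            pos = segs[-1].end + 1
    return segs


def simulate_recombinants(
    pool: Mapping[str, str],
    truth: SimTruth,
    events: Sequence[tuple[str, str, Sequence[int]]],
    n_copies: int = 1,
    seed: int = 0,
    post_mutation: float = 0.0,
) -> tuple[dict[str, str], SimTruth]:
    """Splice mosaic recombinants from donor alleles at given breakpoints.

    Each event is ``(donor_a, donor_b, breakpoints)`` where the donors are
    either lineage names (``P1`` — an allele is drawn at random from that
    lineage) or explicit sequence ids already in ``pool`` (which may
    themselves be recombinants: their truth segments are inherited, so
    nested events resolve to ultimate donors).  A breakpoint at position b
    means the splice switches donors after column b.  With
    ``post_mutation`` = 0 the splice is exact.
    """
    rng = np.random.default_rng(seed)
    L = truth.L
    by_lineage: dict[str, list[str]] = {}
    for sid in pool:
        lineage = truth[sid].segments[0].donor if len(truth[sid].segments) == 1 else None
        if lineage:
            by_lineage.setdefault(lineage, []).append(sid)

    def pick(donor: str) -> str:
        if donor in pool:
            return donor
        if donor in by_lineage:
            return str(rng.choice(by_lineage[donor]))
        raise ConfigError(f"unknown donor {donor!r}")

    out_pool: dict[str, str] = {}
    out_truth = SimTruth(L)
    counter = 0
    for ev_i, (da, db, breakpoints) in enumerate(events, start=1):
        bps = list(breakpoints)
        if any(not (1 <= b < L) for b in bps) or bps != sorted(set(bps)):
            raise ConfigError(
                f"breakpoints {bps} must be strictly increasing within [1, {L - 1}]"
            )
        for _ in range(n_copies):
            counter += 1
            ida, idb = pick(da), pick(db)
            bounds = []
            donors = []
            edges = [0] + bps + [L]
            for k in range(len(edges) - 1):
                lo, hi = edges[k] + 1, edges[k + 1]
                src = ida if k % 2 == 0 else idb
                bounds.append((lo, hi))
                donors.append(src)
            residues = "".join(pool[src][lo - 1 : hi] for src, (lo, hi) in zip(donors, bounds))
            if post_mutation > 0:
                arr = np.frombuffer(residues.encode(), dtype="S1")
                idx_map = {b: i for i, b in enumerate(_BASES)}
                as_idx = np.array([idx_map[b] for b in arr], dtype=np.uint8)
                as_idx = _mutate(as_idx, post_mutation, np.ones(L), 2.0, rng)
                residues = _indices_to_str(as_idx)
            sid = f"R{ev_i}_{counter}"
            out_pool[sid] = residues
            out_truth.add(
                sid,
                SeqTruth(segments=_spliced_segments([truth[s] for s in donors], bounds)),
            )
    return out_pool, out_truth


def inject_pcr_chimeras(
    pool: Mapping[str, str],
    truth: SimTruth,
    rate: float,
    seed: int = 0,
) -> tuple[dict[str, str], SimTruth]:
    """Replace each molecule, with probability ``rate``, by a single-crossover
    chimera of two randomly chosen distinct templates (uniform crossover
    position), flagged in the truth record.  ``rate`` = 0 is the identity.
    """
    if not (0 <= rate <= 1):
        raise ConfigError("chimera rate must be in [0, 1]")
    ids = list(pool)
    if rate > 0 and len(set(pool.values())) < 2:
        raise ConfigError("need >= 2 distinct template sequences for chimeras")
    rng = np.random.default_rng(seed)
    L = truth.L
    out_pool: dict[str, str] = {}
    out_truth = SimTruth(L)
    for sid in ids:
        if rate > 0 and rng.random() < rate:
            a, b = rng.choice(len(ids), size=2, replace=False)
            ta, tb = ids[int(a)], ids[int(b)]
            x = int(rng.integers(1, L))  # switch after column x
            residues = pool[ta][:x] + pool[tb][x:]
            segs = _spliced_segments([truth[ta], truth[tb]], [(1, x), (x + 1, L)])
            out_pool[sid] = residues
            out_truth.add(sid, SeqTruth(segments=segs, chimera=True,
                                        isolate=truth[sid].isolate))
        else:
            out_pool[sid] = pool[sid]
            t = truth[sid]
            out_truth.add(sid, SeqTruth(list(t.segments), t.chimera, t.isolate))
    return out_pool, out_truth


def sample_isolates(
    pool: Mapping[str, str],
    truth: SimTruth,
    n_isolates: int,
    alleles_per_isolate: tuple[int, int] = (1, 5),
    clones_per_isolate: tuple[int, int] = (10, 12),
    seed: int = 0,
    allele_count_probs: Sequence[float] | None = None,
) -> tuple[dict[str, str], SimTruth]:
    """Emulate per-isolate cloning: each isolate carries 1-5 distinct
    underlying alleles; clones are drawn with replacement from them
    (so deep-coalescence style under-sampling of rare alleles occurs).

    ``allele_count_probs``, when given, weights the allele counts
    lo..hi (real screens are strongly skewed toward one or two alleles
    per isolate); default is uniform.  Clone ids are ``ISO<i>_<c>``; the
    truth records the source isolate.
    """
    lo_a, hi_a = alleles_per_isolate
    lo_c, hi_c = clones_per_isolate
    if lo_c < 1:
        raise ConfigError("clones_per_isolate must be >= 1")
    if allele_count_probs is not None and len(allele_count_probs) != hi_a - lo_a + 1:
        raise ConfigError("allele_count_probs must cover lo..hi allele counts")
    ids = list(pool)
    if hi_a > len(ids):
        raise ConfigError(
            f"alleles_per_isolate max {hi_a} exceeds the {len(ids)} available alleles"
        )
    rng = np.random.default_rng(seed)
    out_pool: dict[str, str] = {}
    out_truth = SimTruth(truth.L)
    for i in range(1, n_isolates + 1):
        if allele_count_probs is not None:
            k = lo_a + int(rng.choice(hi_a - lo_a + 1, p=allele_count_probs))
        else:
            k = int(rng.integers(lo_a, hi_a + 1))
        alleles = [ids[int(j)] for j in rng.choice(len(ids), size=k, replace=False)]
        n_clones = int(rng.integers(lo_c, hi_c + 1))
        iso = f"ISO{i}"
        for c in range(1, n_clones + 1):
            src = alleles[int(rng.integers(0, k))]
            sid = f"{iso}_{c}"
            out_pool[sid] = pool[src]
            t = truth[src]
            out_truth.add(sid, SeqTruth(list(t.segments), t.chimera, isolate=iso))
    return out_pool, out_truth


# ---------------------------------------------------------------------------
# conveniences


def pool_to_alignment(pool: Mapping[str, str]) -> Alignment:
    """Gap-free simulated sequences are trivially aligned; wrap them."""
    return Alignment([SequenceRecord(sid, seq) for sid, seq in pool.items()])


def breakpoint_recovery_scenario(
    seed: int,
    n_parents: int = 7,
    recombinant: bool = True,
    bp_range: tuple[int, int] = (600, 850),
    cfg: SimConfig | None = None,
) -> tuple[Alignment, int | None]:
    """One replicate of the single-breakpoint detection experiment.

    Seven divergent lineages give the alignment enough segregating sites
    (~240) for the largest detection half-window (100 segregating sites per
    side) to fit; the mosaic is spliced from clone a2 of two lineages while
    the alignment carries clones a1/a3, so the recombinant is compared with
    relatives of its donors rather than the donors themselves — as in a
    clone-sampled dataset.  The breakpoint is planted in the central region
    where all half-windows can reach it.  With ``recombinant=False`` the
    recombination-free version of the same alignment is returned (for
    false-positive calibration).

    Returns (alignment, planted breakpoint position or None).
    """
    cfg = replace(cfg if cfg is not None else SimConfig(), seed=seed,
                  n_parents=n_parents, alleles_per_parent=3)
    rng = np.random.default_rng(seed + 1)
    bp = int(rng.integers(bp_range[0], bp_range[1] + 1))
    pool, truth = simulate_parent_pools(cfg)
    keep = {f"P{p}_a1": pool[f"P{p}_a1"] for p in range(1, n_parents + 1)}
    keep["P1_a3"] = pool["P1_a3"]
    keep["P2_a3"] = pool["P2_a3"]
    if not recombinant:
        return pool_to_alignment(keep), None
    rec, _ = simulate_recombinants(
        pool, truth, [("P1_a2", "P2_a2", [bp])], seed=seed + 2
    )
    keep.update(rec)
    return pool_to_alignment(keep), bp


def default_mosaic_scenario(
    seed: int,
    cfg: SimConfig | None = None,
    n_mosaics: int = 10,
    bp_margin: float = 0.2,
) -> tuple[Alignment, SimTruth, dict[str, str]]:
    """The default end-to-end scenario: parental pools plus ``n_mosaics``
    single-breakpoint recombinants between random distinct lineages, with
    breakpoints uniform in the central (1 - 2*bp_margin) of the sequence.

    Returns (alignment of all sequences, truth, group map lineage labels for
    every sequence: parents get their lineage, mosaics 'recombinant').
    """
    cfg = replace(cfg if cfg is not None else SimConfig(), seed=seed)
    rng = np.random.default_rng(seed + 1)
    pool, truth = simulate_parent_pools(cfg)
    events = []
    lo = int(cfg.L * bp_margin)
    hi = int(cfg.L * (1 - bp_margin))
    for _ in range(n_mosaics):
        a, b = rng.choice(cfg.n_parents, size=2, replace=False) + 1
        bp = int(rng.integers(lo, hi + 1))
        events.append((f"P{int(a)}", f"P{int(b)}", [bp]))
    rec_pool, rec_truth = simulate_recombinants(pool, truth, events, seed=seed + 2)
    all_pool = {**pool, **rec_pool}
    all_truth = truth.merged(rec_truth)
    groups = {}
    for sid in all_pool:
        t = all_truth[sid]
        groups[sid] = t.segments[0].donor if len(t.segments) == 1 else "recombinant"
    return pool_to_alignment(all_pool), all_truth, groups
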