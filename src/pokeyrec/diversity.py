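"""Nucleotide diversity and similarity statistics, per region and overall.

pi is the average pairwise proportion of differing sites, theta_w the
Watterson estimator S / (a_{n-1} L); both are reported per site on the
gap/ambiguity-stripped columns (complete deletion by default, per-pair
deletion available because legacy software totals on full-length sequences
may have used it).  The population recombination rate combines two
coalescent estimates: R = theta_LAM * r_LAM = (4 Ne mu)(c / mu) = 4 Ne c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import (
    Alignment,
    AlignmentError,
    InputError,
    PartitionMap,
    extract_partition,
    strip_columns,
)

__all__ = [
    "DiversitySummary",
    "RateEstimates",
    "pairwise_difference_matrix",
    "nucleotide_diversity",
    "watterson_theta",
    "segregating_sites",
    "mean_similarity",
    "summarize",
    "partition_diversity",
    "recombination_rate",
]


@dataclass(frozen=True)
class DiversitySummary:
    region: str
    n: int
    L_used: int
    S: int
    pi: float
    theta_w: float
    mean_similarity: float  # percent


@dataclass(frozen=True)
class RateEstimates:
    """R = theta_LAM * r_LAM = 4 Ne c (per site per generation)."""

    theta_lam: float
    r_lam: float
    R: float
    interpretation: str = "4Nec per site per generation"


def _stripped(aln: Alignment) -> Alignment:
    return strip_columns(aln)


def pairwise_difference_matrix(aln: Alignment) -> np.ndarray:
    """(n, n) matrix of raw counts of differing sites (complete deletion)."""
    m = _stripped(aln).matrix()
    n = m.shape[0]
    d = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        d[i, i + 1 :] = (m[i + 1 :] != m[i]).sum(axis=1)
    return d + d.T


def nucleotide_diversity(aln: Alignment, per_pair_deletion: bool = False) -> float:
    """pi = [2 / (n (n-1))] * sum_{i<j} d_ij / L_used."""
    if aln.n < 2:
        raise InputError("nucleotide diversity needs >= 2 sequences")
    if not per_pair_deletion:
        s = _stripped(aln)
        d = pairwise_difference_matrix(s)
        iu = np.triu_indices(s.n, k=1)
        return float(d[iu].mean() / s.length)
    # per-pair deletion: each pair compared over its own gap/ambiguity-free sites
    m = aln.matrix()
    valid = (m == b"A") | (m == b"C") | (m == b"G") | (m == b"T")
    vals = []
    for i in range(aln.n):
        for j in range(i + 1, aln.n):
            ok = valid[i] & valid[j]
            L = int(ok.sum())
            if L == 0:
                raise AlignmentError(f"pair ({i},{j}) shares no comparable sites")
            vals.append((m[i, ok] != m[j, ok]).sum() / L)
    return float(np.mean(vals))


def segregating_sites(aln: Alignment) -> int:
    m = _stripped(aln).matrix()
    return int((m != m[0]).any(axis=0).sum())


def watterson_theta(aln: Alignment) -> float:
    """theta_w = S / (a_{n-1} * L_used), a_{n-1} = sum_{k=1}^{n-1} 1/k."""
    if aln.n < 2:
        raise InputError("Watterson's estimator needs >= 2 sequences")
    s = _stripped(aln)
    a = np.sum(1.0 / np.arange(1, s.n))
    return float(segregating_sites(s) / (a * s.length))


def mean_similarity(aln: Alignment) -> float:
    """Mean pairwise identity in percent: 100 * (1 - mean p-distance)."""
    s = _stripped(aln)
    d = pairwise_difference_matrix(s)
    iu = np.triu_indices(s.n, k=1)
    return float(100.0 * (1.0 - d[iu].mean() / s.length))


def summarize(aln: Alignment, region: str = "total") -> DiversitySummary:
    s = _stripped(aln)
    return DiversitySummary(
        region=region,
        n=s.n,
        L_used=s.length,
        S=segregating_sites(s),
        pi=nucleotide_diversity(s),
        theta_w=watterson_theta(s),
        mean_similarity=mean_similarity(s),
    )


def partition_diversity(
    aln: Alignment, part: PartitionMap, warn=None
) -> list[DiversitySummary]:
    """One summary per region, plus total-coding / total-noncoding / total rows.

    Empty regions (all columns stripped) are skipped with a warning callback.
    """
    out: list[DiversitySummary] = []

    def region_aln(names) -> Alignment | None:
        subs = []
        for nm in names:
            if nm not in part.regions:
                continue
            try:
                subs.append(extract_partition(aln, part, nm))
            except AlignmentError:
                if warn:
                    warn(f"region {nm!r} empty after stripping; skipped")
        if not subs:
            return None
        from .core_io import concat_alignments

        return concat_alignments(subs)

    coding = [nm for nm in part.coding if nm in part.regions]
    noncoding = [nm for nm in part.noncoding if nm in part.regions]
    total_coding = region_aln(coding)
    if total_coding is not None:
        out.append(summarize(total_coding, "coding_total"))
    for nm in coding:
        try:
            out.append(summarize(extract_partition(aln, part, nm), nm))
        except AlignmentError:
            if warn:
                warn(f"region {nm!r} empty after stripping; skipped")
    total_nc = region_aln(noncoding)
    if total_nc is not None:
        out.append(summarize(total_nc, "noncoding_total"))
    for nm in noncoding:
        try:
            out.append(summarize(extract_partition(aln, part, nm), nm))
        except AlignmentError:
            if warn:
                warn(f"region {nm!r} empty after stripping; skipped")
    out.append(summarize(aln, "total"))
    return out


def summaries_to_frame(summaries: list[DiversitySummary]):
    """Table-1-shaped report: pi/theta to 3 decimals, similarity to 1."""
    import pandas as pd

    df = pd.DataFrame([s.__dict__ for s in summaries]).set_index("region")
    disp = df.copy()
    disp["pi"] = disp["pi"].round(3)
    disp["theta_w"] = disp["theta_w"].round(3)
    disp["mean_similarity"] = disp["mean_similarity"].round(1)
    return disp


def recombination_rate(theta_lam: float, r_lam: float) -> RateEstimates:
    """Combine coalescent estimates into R = theta_LAM * r_LAM = 4 Ne c."""
    if theta_lam < 0 or r_lam < 0:
        raise InputError("rate estimates must be non-negative")
    return RateEstimates(theta_lam=theta_lam, r_lam=r_lam, R=theta_lam * r_lam)
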