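"""In-silico PCR-RFLP haplotyping.

The screen amplifies the 3' end of the element together with the flanking
28S sequence (an ~1600 bp product) and digests it with a three-enzyme panel
whose diagnostic sites sit around 380, 790 and 1080 bp.  Presence/absence of
the three cuts gives a 3-bit code rendered as haplotypes 1-8; a recombinant
(or PCR-chimeric) allele carries the left-of-crossover bits of one template
and the right-of-crossover bits of the other, which is what makes the panel
sensitive to mosaic alleles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .core_io import InputError

__all__ = [
    "Primer",
    "EnzymeSpec",
    "Amplicon",
    "DigestProfile",
    "RflpHaplotype",
    "DEFAULT_ENZYMES",
    "DEFAULT_WINDOWS",
    "POK5026F",
    "PRIMER_28SR",
    "iupac_match_positions",
    "in_silico_pcr",
    "digest",
    "haplotype_code",
    "gel_pattern",
    "distinguishable",
    "isolate_summary",
    "synthetic_amplicon",
]


@dataclass(frozen=True)
class Primer:
    """A PCR primer, written 5'->3'; the 3'-terminal ``exact_3prime`` bases
    must match exactly even when ``max_mismatch`` > 0."""

    name: str
    sequence: str
    max_mismatch: int = 0
    exact_3prime: int = 5

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq or set(seq) - set(ambiguous_dna_values):
            raise InputError(f"primer {self.name!r} is not IUPAC DNA")
        if self.max_mismatch < 0:
            raise InputError("max_mismatch must be >= 0")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class EnzymeSpec:
    """Restriction enzyme: IUPAC recognition pattern and cut offset.

    ``cut_offset`` counts bases from the start of the pattern to the cut
    (e.g. TTT^AAA -> offset 3).
    """

    name: str
    pattern: str
    cut_offset: int

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        if len(pat) < 4:
            raise InputError("recognition pattern must be >= 4 bases")
        if set(pat) - set(ambiguous_dna_values):
            raise InputError(f"pattern for {self.name!r} is not IUPAC DNA")
        if not (0 <= self.cut_offset <= len(pat)):
            raise InputError("cut offset must lie within the pattern")
        object.__setattr__(self, "pattern", pat)


# standard recognition sequences (editable defaults; the study names the
# enzymes, the sites are the canonical ones)
DEFAULT_ENZYMES = (
    EnzymeSpec("DraI", "TTTAAA", 3),
    EnzymeSpec("BspHI", "TCATGA", 1),
    EnzymeSpec("BstEII", "GGTNACC", 1),
)

# diagnostic windows: +/- 25 bp around the nominal 380 / 790 / 1080 bp cuts
DEFAULT_WINDOWS = ((355, 405), (765, 815), (1055, 1105))

POK5026F = Primer("Pok5026F", "TCGAACCTGCAGCCGGACGAATTTGCAG")
PRIMER_28SR = Primer("28SR", "TCCATTCGTGCGCGTCACTAATTAGATGAC")


@dataclass(frozen=True)
class Amplicon:
    """PCR product: template span (1-based inclusive) and its sequence."""

    sequence: str
    start: int
    end: int

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DigestProfile:
    amplicon_length: int
    cuts: dict[str, list[int]]  # enzyme name -> 1-based cut positions
    fragments: list[int]  # descending

    def __post_init__(self) -> None:
        if sum(self.fragments) != self.amplicon_length:
            raise ValueError("fragment lengths must sum to the amplicon length")


@dataclass(frozen=True)
class RflpHaplotype:
    code: int  # 1..8
    bits: tuple[int, int, int]  # cut presence per enzyme, panel order
    bands: tuple[int, ...]  # gel-binned band sizes, descending


def _iupac_sets(pattern: str) -> list[frozenset[bytes]]:
    return [
        frozenset(c.encode() for c in ambiguous_dna_values[ch]) for ch in pattern
    ]


def iupac_match_positions(
    template: str,
    pattern: str,
    max_mismatch: int = 0,
    exact_left: int = 0,
    exact_right: int = 0,
) -> list[int]:
    """0-based start positions where ``pattern`` matches ``template`` with
    at most ``max_mismatch`` mismatches; positions within ``exact_left`` /
    ``exact_right`` of the pattern ends must match exactly."""
    t = np.frombuffer(template.upper().encode(), dtype="S1")
    k = len(pattern)
    if len(t) < k:
        return []
    sets = _iupac_sets(pattern)
    n_windows = len(t) - k + 1
    mismatches = np.zeros(n_windows, dtype=np.int32)
    hard = np.zeros(n_windows, dtype=bool)
    for off, allowed in enumerate(sets):
        col = t[off : off + n_windows]
        ok = np.isin(col, list(allowed))
        mismatches += ~ok
        if off < exact_left or off >= k - exact_right:
            hard |= ~ok
    return [int(i) for i in np.flatnonzero((mismatches <= max_mismatch) & ~hard)]


def in_silico_pcr(
    template: str,
    fwd: Primer = POK5026F,
    rev: Primer = PRIMER_28SR,
    size_window: tuple[int, int] = (300, 5000),
) -> list[Amplicon]:
    """All products of a forward match and a downstream reverse-complement
    match of the reverse primer, within ``size_window``.

    The amplicon runs from the first base of the forward-primer match to the
    last base of the reverse match, inclusive.  No pair found -> empty list.
    """
    template = template.upper()
    f_hits = iupac_match_positions(
        template, fwd.sequence, fwd.max_mismatch, exact_right=fwd.exact_3prime
    )
    rc = str(Seq(rev.sequence).reverse_complement())
    # the reverse primer's 3' end maps to the LEFT end of its revcomp
    r_hits = iupac_match_positions(
        template, rc, rev.max_mismatch, exact_left=rev.exact_3prime
    )
    out = []
    for f in f_hits:
        for r in r_hits:
            end = r + len(rc)  # exclusive
            length = end - f
            if size_window[0] <= length <= size_window[1]:
                out.append(Amplicon(template[f:end], start=f + 1, end=end))
    return out


def digest(
    amplicon: str | Amplicon, enzymes: Sequence[EnzymeSpec] = DEFAULT_ENZYMES
) -> DigestProfile:
    """Cut positions and fragment lengths of a complete digest.

    All recognition-pattern matches cut at pattern start + offset; for
    non-palindromic patterns the reverse-complement orientation is scanned
    too (palindromes are handled once).  Total length is conserved.
    """
    seq = amplicon.sequence if isinstance(amplicon, Amplicon) else amplicon
    L = len(seq)
    cuts: dict[str, list[int]] = {}
    for enz in enzymes:
        hits = {
            start + enz.cut_offset for start in iupac_match_positions(seq, enz.pattern)
        }
        rc = str(Seq(enz.pattern).reverse_complement())
        if rc != enz.pattern:
            k = len(enz.pattern)
            hits |= {
                start + (k - enz.cut_offset)
                for start in iupac_match_positions(seq, rc)
            }
        cuts[enz.name] = sorted(c for c in hits if 0 < c < L)
    all_cuts = sorted({c for v in cuts.values() for c in v})
    edges = [0, *all_cuts, L]
    fragments = sorted(
        (edges[i + 1] - edges[i] for i in range(len(edges) - 1)), reverse=True
    )
    return DigestProfile(amplicon_length=L, cuts=cuts, fragments=fragments)


def haplotype_code(
    profile: DigestProfile,
    diagnostic_windows: Sequence[tuple[int, int]] = DEFAULT_WINDOWS,
    enzyme_order: Sequence[str] = ("DraI", "BspHI", "BstEII"),
    co_migration_bp: int = 40,
    log=None,
) -> RflpHaplotype:
    """3-bit cut-presence code over the diagnostic windows, rendered 1-8.

    Bit k is set iff enzyme k cuts within window k (first enzyme = most
    significant bit); code = 1 + binary value, so no cuts -> 1 and all
    three cuts -> 8.  Cuts outside every window are logged and ignored.
    """
    for a, b in zip(diagnostic_windows, diagnostic_windows[1:]):
        if a[1] >= b[0]:
            raise InputError("diagnostic windows must be non-overlapping and sorted")
    bits = []
    for (lo, hi), enz in zip(diagnostic_windows, enzyme_order):
        positions = profile.cuts.get(enz, [])
        inside = [c for c in positions if lo <= c <= hi]
        outside = [c for c in positions if not (lo <= c <= hi)]
        if outside and log:
            log(f"{enz} cut(s) at {outside} outside the diagnostic window; ignored")
        bits.append(1 if inside else 0)
    code = 1 + (bits[0] << 2 | bits[1] << 1 | bits[2])
    return RflpHaplotype(
        code=code,
        bits=(bits[0], bits[1], bits[2]),
        bands=gel_pattern(profile.fragments, co_migration_bp),
    )


def gel_pattern(fragments: Sequence[int], co_migration_bp: int = 40) -> tuple[int, ...]:
    """Collapse fragments closer than ``co_migration_bp`` into single bands
    (models a 3% agarose gel); bands reported descending as the rounded mean
    of their co-migrating fragments."""
    if not fragments:
        raise InputError("no fragments to display")
    sizes = sorted(fragments, reverse=True)
    bands: list[list[int]] = [[sizes[0]]]
    for f in sizes[1:]:
        if bands[-1][-1] - f <= co_migration_bp:
            bands[-1].append(f)
        else:
            bands.append([f])
    return tuple(int(round(float(np.mean(b)))) for b in bands)


def distinguishable(
    fragments_a: Sequence[int],
    fragments_b: Sequence[int],
    co_migration_bp: int = 40,
) -> bool:
    """Two digests are distinguishable iff their banded patterns differ
    (different band count, or some band off by more than the co-migration
    threshold)."""
    pa = gel_pattern(fragments_a, co_migration_bp)
    pb = gel_pattern(fragments_b, co_migration_bp)
    if len(pa) != len(pb):
        return True
    return any(abs(x - y) > co_migration_bp for x, y in zip(pa, pb))


def isolate_summary(
    haplotypes_by_isolate: Mapping[str, Iterable[int]],
) -> dict:
    """Distinct-haplotype counts per isolate plus a frequency table.

    Returns mean / sample SD / max of distinct haplotypes per isolate and,
    per haplotype, the percentage of isolates in which it occurs.
    """
    if not haplotypes_by_isolate:
        raise InputError("need at least one isolate")
    counts = {}
    freq: dict[int, int] = {}
    for iso, haps in haplotypes_by_isolate.items():
        distinct = set(haps)
        if not distinct:
            warnings.warn(f"isolate {iso!r} has no haplotypes; counted as 0")
        counts[iso] = len(distinct)
        for h in distinct:
            freq[h] = freq.get(h, 0) + 1
    vals = np.array(list(counts.values()), dtype=float)
    n_iso = len(counts)
    sd = float(vals.std(ddof=1)) if n_iso > 1 else 0.0
    return {
        "n_isolates": n_iso,
        "counts": counts,
        "mean": float(vals.mean()),
        "sd": sd,
        "max": int(vals.max()),
        "haplotype_percent": {h: 100.0 * c / n_iso for h, c in sorted(freq.items())},
    }


# ---------------------------------------------------------------------------
# synthetic default amplicon


def synthetic_amplicon(
    sites: tuple[bool, bool, bool] = (True, True, True),
    length: int = 1600,
    cut_positions: tuple[int, int, int] = (380, 790, 1080),
    enzymes: Sequence[EnzymeSpec] = DEFAULT_ENZYMES,
    seed: int = 0,
    with_primers: bool = True,
) -> str:
    """A synthetic stand-in for the screen's amplicon (the real amplicon
    sequence is not available): random background, free of stray recognition
    sites, with each enzyme's site planted (or not, per ``sites``) so its
    cut falls at the nominal position; primer sequences at the ends when
    ``with_primers``.
    """
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    for _ in range(200):
        seq = list(rng.choice(list(bases), size=length))
        if with_primers:
            fwd = POK5026F.sequence
            seq[: len(fwd)] = list(fwd)
            rc = str(Seq(PRIMER_28SR.sequence).reverse_complement())
            seq[length - len(rc) :] = list(rc)
        for present, cut_at, enz in zip(sites, cut_positions, enzymes):
            if present:
                pat = enz.pattern.replace("N", "A")
                start = cut_at - enz.cut_offset  # 0-based pattern start
                seq[start : start + len(pat)] = list(pat)
        s = "".join(seq)
        prof = digest(s, enzymes)
        expected = {
            enz.name: ([cut_at] if present else [])
            for present, cut_at, enz in zip(sites, cut_positions, enzymes)
        }
        if {k: v for k, v in prof.cuts.items()} == expected:
            return s
    raise RuntimeError("failed to construct a clean synthetic amplicon")
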