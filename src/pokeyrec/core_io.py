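"""Alignment I/O, column filtering and partition handling.

The analyses downstream (diversity statistics, recombination detection,
fragment dendrograms) all operate on a rectangular nucleotide alignment from
which ambiguous sites and indel columns have been removed, while breakpoints
and partition boundaries are reported in the coordinates of the *source*
alignment.  The :class:`Alignment` container therefore carries, for every
current column, its 1-based coordinate in the source alignment
(``column_map``), so that positions survive any amount of column stripping
and sub-setting.

Coordinates are 1-based and inclusive throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "AlignmentError",
    "InputError",
    "SequenceRecord",
    "Alignment",
    "PartitionMap",
    "read_alignment",
    "write_alignment",
    "strip_columns",
    "extract_partition",
    "concat_alignments",
    "translate_ungapped",
    "aa_polymorphism_table",
    "read_partition_map",
]

DNA_UNAMBIGUOUS = frozenset("ACGT")
# full IUPAC nucleotide alphabet plus gap
DNA_IUPAC = frozenset("ACGTRYSWKMBDHVN-")


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged rows, empty column set...)."""


class InputError(ValueError):
    """Raised for invalid user inputs (duplicate ids, unknown regions...)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single named aligned sequence.

    ``id`` follows the isolate_colony naming convention used for cloned
    alleles (e.g. ``PX2-QC-8_28``); ``taxon_tag`` is a free-text species /
    hybrid / ploidy label and may be empty.
    """

    id: str
    residues: str
    taxon_tag: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("sequence id must be non-empty")
        bad = set(self.residues.upper()) - DNA_IUPAC
        if bad:
            raise InputError(
                f"sequence {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


class Alignment:
    """Rectangular set of named sequences with a source-coordinate map.

    Parameters
    ----------
    records:
        Equal-length :class:`SequenceRecord` objects, order preserved.
    column_map:
        For each current column, its 1-based coordinate in the source
        alignment.  Defaults to the identity map.
    """

    def __init__(
        self,
        records: Sequence[SequenceRecord],
        column_map: Sequence[int] | None = None,
    ) -> None:
        records = list(records)
        if not records:
            raise AlignmentError("alignment needs at least one sequence")
        L = len(records[0])
        if L == 0:
            raise AlignmentError("alignment length must be > 0")
        for r in records:
            if len(r) != L:
                raise AlignmentError(
                    f"ragged alignment: {r.id!r} has length {len(r)}, expected {L}"
                )
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate sequence ids: {dupes}")
        if column_map is None:
            column_map = np.arange(1, L + 1)
        column_map = np.asarray(column_map, dtype=np.int64)
        if column_map.shape != (L,):
            raise AlignmentError("column_map length must equal alignment length")
        if L > 1 and not np.all(np.diff(column_map) > 0):
            raise AlignmentError("column_map must be strictly increasing")
        self.records: list[SequenceRecord] = records
        self.column_map: np.ndarray = column_map
        # residues as a (n, L) array of single characters for fast column ops
        self._matrix = np.frombuffer(
            "".join(r.residues for r in records).encode("ascii"), dtype="S1"
        ).reshape(len(records), L)

    # -- basic accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return self._matrix.shape[1]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def matrix(self) -> np.ndarray:
        """(n, L) array of bytes; read-only view."""
        return self._matrix

    def sequence(self, seq_id: str) -> str:
        for r in self.records:
            if r.id == seq_id:
                return r.residues
        raise InputError(f"unknown sequence id {seq_id!r}")

    def take_columns(self, idx: np.ndarray) -> "Alignment":
        """Sub-alignment of the given current-column indices (0-based)."""
        idx = np.asarray(idx, dtype=np.int64)
        if idx.size == 0:
            raise AlignmentError("selection leaves an empty alignment")
        sub = self._matrix[:, idx]
        recs = [
            SequenceRecord(r.id, sub[i].tobytes().decode("ascii"), r.taxon_tag)
            for i, r in enumerate(self.records)
        ]
        return Alignment(recs, self.column_map[idx])

    def take_sequences(self, ids: Iterable[str]) -> "Alignment":
        wanted = list(ids)
        by_id = {r.id: r for r in self.records}
        missing = [i for i in wanted if i not in by_id]
        if missing:
            raise InputError(f"unknown sequence ids: {missing}")
        return Alignment([by_id[i] for i in wanted], self.column_map.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return (
            self.ids == other.ids
            and np.array_equal(self.column_map, other.column_map)
            and all(a.residues == b.residues for a, b in zip(self.records, other.records))
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"Alignment(n={self.n}, L={self.length})"


@dataclass
class PartitionMap:
    """Named regions of the source alignment (1-based inclusive intervals).

    ``frames`` gives, for coding regions, the 0-based offset of the first
    complete codon (a partial leading exon may start mid-codon).
    """

    regions: Mapping[str, list[tuple[int, int]]]
    frames: Mapping[str, int] = field(default_factory=dict)
    coding: Sequence[str] = ("exon1", "exon2")
    noncoding: Sequence[str] = ("intron", "ncr3")

    def __post_init__(self) -> None:
        for name, ivals in self.regions.items():
            for lo, hi in ivals:
                if lo < 1 or hi < lo:
                    raise InputError(f"bad interval ({lo}, {hi}) in region {name!r}")

    def region_names(self) -> list[str]:
        return list(self.regions)

    def columns(self, region: str) -> np.ndarray:
        """All 1-based source columns of a region, in order."""
        if region not in self.regions:
            raise InputError(f"unknown region {region!r}")
        cols = [np.arange(lo, hi + 1) for lo, hi in self.regions[region]]
        return np.concatenate(cols)


# ---------------------------------------------------------------------------
# I/O


def read_alignment(path: str | Path, fmt: str = "fasta") -> Alignment:
    """Read an aligned FASTA (default) or relaxed PHYLIP file.

    Order is preserved, lowercase is normalized to uppercase, and the
    column map is the identity (source coordinates = file coordinates).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if fmt == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
    elif fmt in ("phylip", "phylip-relaxed"):
        records = list(SeqIO.parse(str(path), "phylip-relaxed"))
    else:
        raise InputError(f"unsupported alignment format {fmt!r}")
    if not records:
        raise InputError(f"empty alignment file: {path}")
    recs = [SequenceRecord(r.id, str(r.seq)) for r in records]
    return Alignment(recs)


def write_alignment(aln: Alignment, path: str | Path, fmt: str = "fasta") -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in aln.records
    ]
    AlignIO.write(AlignIO.MultipleSeqAlignment(bio), str(path), fmt)


def read_partition_map(path: str | Path) -> PartitionMap:
    """Read a ``region  start  end  [frame]`` whitespace-separated table."""
    regions: dict[str, list[tuple[int, int]]] = {}
    frames: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) not in (3, 4):
            raise InputError(f"bad partition line: {line!r}")
        name, lo, hi = parts[0], int(parts[1]), int(parts[2])
        regions.setdefault(name, []).append((lo, hi))
        if len(parts) == 4:
            frames[name] = int(parts[3])
    return PartitionMap(regions=regions, frames=frames)


# ---------------------------------------------------------------------------
# Column filtering and partition extraction


def strip_columns(
    aln: Alignment,
    drop_gap_cols: bool = True,
    drop_ambiguous_cols: bool = True,
) -> Alignment:
    """Remove columns containing gaps and/or ambiguity codes.

    Any IUPAC code other than A/C/G/T in any row removes the whole column
    (conservative: ambiguous sites and indels generate spurious
    recombination signal, so they are excluded before any detection).
    Idempotent; the surviving columns keep their source coordinates.
    """
    m = aln.matrix()
    keep = np.ones(aln.length, dtype=bool)
    if drop_gap_cols:
        keep &= ~(m == b"-").any(axis=0)
    if drop_ambiguous_cols:
        acgt = (m == b"A") | (m == b"C") | (m == b"G") | (m == b"T")
        if drop_gap_cols:
            keep &= acgt.all(axis=0)
        else:
            keep &= (acgt | (m == b"-")).all(axis=0)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise AlignmentError("all columns removed by stripping")
    if idx.size == aln.length:
        return aln
    return aln.take_columns(idx)


def extract_partition(aln: Alignment, part: PartitionMap, region: str) -> Alignment:
    """Sub-alignment of the surviving columns of one named region.

    Region coordinates are source coordinates; columns already removed by
    stripping are simply absent from the result.
    """
    wanted = part.columns(region)
    mask = np.isin(aln.column_map, wanted)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise AlignmentError(f"region {region!r} has no surviving columns")
    return aln.take_columns(idx)


def concat_alignments(parts: Sequence[Alignment]) -> Alignment:
    """Column-wise concatenation (same sequence ids, disjoint column maps)."""
    if not parts:
        raise InputError("nothing to concatenate")
    ids = parts[0].ids
    for p in parts:
        if p.ids != ids:
            raise InputError("alignments to concatenate must share sequence ids")
    cols = np.concatenate([p.column_map for p in parts])
    order = np.argsort(cols)
    mats = np.concatenate([p.matrix() for p in parts], axis=1)[:, order]
    recs = [
        SequenceRecord(ids[i], mats[i].tobytes().decode("ascii"), parts[0].records[i].taxon_tag)
        for i in range(len(ids))
    ]
    return Alignment(recs, cols[order])


# ---------------------------------------------------------------------------
# Translation and amino-acid polymorphism


def translate_ungapped(nt: str, frame_offset: int = 0) -> str:
    """Translate a gap-free nucleotide string (standard code, '*' = stop)."""
    s = nt[frame_offset:]
    s = s[: len(s) - len(s) % 3]
    if not s:
        return ""
    return str(Seq(s).translate())


def _coding_alignment(aln: Alignment, part: PartitionMap) -> tuple[Alignment, int]:
    """Concatenated coding regions (gaps retained) and the frame offset."""
    cols = []
    for name in part.coding:
        if name in part.regions:
            cols.append(part.columns(name))
    if not cols:
        raise InputError("no coding regions defined")
    wanted = np.concatenate(cols)
    mask = np.isin(aln.column_map, wanted)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise InputError("coding regions have no columns in this alignment")
    first = part.coding[0]
    frame = part.frames.get(first, 0)
    return aln.take_columns(idx), frame


def aa_polymorphism_table(aln: Alignment, part: PartitionMap):
    """Per-codon-position amino-acid counts plus frameshift flags.

    Codons are read on the *aligned* coding columns so that homologous codon
    positions line up across sequences; codons containing a gap are skipped,
    so per-position counts may sum to fewer than n.  A sequence is flagged
    frameshifted when its ungapped coding length differs from the modal
    ungapped length by a non-multiple of 3.  Internal stops are reported as
    '*' counts, not errors (pseudogenized copies are expected).

    Returns ``(table, flags)`` where ``table`` is a pandas DataFrame indexed
    by 1-based amino-acid position with one column per observed residue, and
    ``flags`` maps sequence id -> bool.
    """
    import pandas as pd
    from collections import Counter

    coding, frame = _coding_alignment(aln, part)
    ungapped = {r.id: len(r.residues.replace("-", "")) for r in coding.records}
    lengths = Counter(ungapped.values())
    if set(lengths) == {0}:
        raise InputError("coding regions are empty in every sequence")
    modal = lengths.most_common(1)[0][0]
    flags = {sid: (l - modal) % 3 != 0 for sid, l in ungapped.items()}

    n_codons = (coding.length - frame) // 3
    counts: list[Counter] = [Counter() for _ in range(n_codons)]
    for r in coding.records:
        s = r.residues[frame:]
        for k in range(n_codons):
            codon = s[3 * k : 3 * k + 3]
            if "-" in codon or len(codon) < 3:
                continue
            if set(codon) - DNA_UNAMBIGUOUS:
                continue
            counts[k][translate_ungapped(codon)] += 1
    residues = sorted({aa for c in counts for aa in c})
    table = pd.DataFrame(
        [[c.get(aa, 0) for aa in residues] for c in counts],
        index=pd.RangeIndex(1, n_codons + 1, name="aa_position"),
        columns=residues,
    )
    return table, flags


def unique_protein_count(aln: Alignment, part: PartitionMap) -> int:
    """Number of distinct translated coding sequences (gaps removed first)."""
    coding, frame = _coding_alignment(aln, part)
    seen = {
        translate_ungapped(r.residues.replace("-", ""), frame) for r in coding.records
    }
    return len(seen)
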