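"""Distance matrices, neighbor-joining fragment dendrograms and
parental-donor assignment for recombinant sequences.

A mosaic sequence clusters with a different parental group in trees built
from different fragments of the alignment; the nearest-group distances per
fragment therefore identify the probable donor pair (reported in the
``"h : c"`` style, with ``"h or i"`` alternatives when donors are
statistically indistinguishable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import skbio
from skbio.tree import TreeNode, nj as _skbio_nj

from .core_io import Alignment, InputError, strip_columns

__all__ = [
    "DistanceMatrix",
    "GroupMap",
    "ParentalAssignment",
    "pairwise_distances",
    "nj_tree",
    "tree_to_newick",
    "newick_to_tree",
    "fragment_spans",
    "fragment_trees",
    "assign_parents",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with a model tag.

    ``saturated`` lists label pairs where the model correction diverged
    (its entries fall back to the p-distance).
    """

    labels: list[str]
    matrix: np.ndarray
    model: str = "p"
    saturated: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise InputError("distance matrix shape does not match labels")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
            raise InputError("distance matrix must be symmetric with zero diagonal")
        if not np.all(np.isfinite(m)) or (m < 0).any():
            raise InputError("distances must be finite and non-negative")
        self.matrix = m

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.matrix[i, j])


GroupMap = Mapping[str, str]  # sequence id -> group label ("a".."i" or "ungrouped")


def pairwise_distances(aln: Alignment, model: str = "p") -> DistanceMatrix:
    """p, JC69 or K2P distances on the gap/ambiguity-stripped columns.

    JC69: d = -(3/4) ln(1 - 4p/3).  K2P: d = -(1/2) ln((1-2P-Q) sqrt(1-2Q))
    with P, Q the transition / transversion proportions.  Saturated pairs
    (logarithm of a non-positive argument) keep their p-distance and are
    flagged.
    """
    if model not in ("p", "JC69", "K2P"):
        raise InputError(f"unknown distance model {model!r}")
    s = strip_columns(aln)
    m = s.matrix()
    n, L = m.shape
    # purine/pyrimidine classes for transition/transversion partitioning
    is_purine = (m == b"A") | (m == b"G")
    D = np.zeros((n, n))
    saturated: list[tuple[str, str]] = []
    for i in range(n):
        diff = m[i + 1 :] != m[i]
        p = diff.sum(axis=1) / L
        if model == "p":
            D[i, i + 1 :] = p
        elif model == "JC69":
            arg = 1 - 4 * p / 3
            d = np.where(arg > 0, -0.75 * np.log(np.maximum(arg, 1e-300)), np.nan)
            for k, j in enumerate(range(i + 1, n)):
                if np.isnan(d[k]):
                    saturated.append((s.ids[i], s.ids[j]))
                    d[k] = p[k]
            D[i, i + 1 :] = d
        else:  # K2P
            ts = (diff & (is_purine[i + 1 :] == is_purine[i])).sum(axis=1) / L
            tv = p - ts
            arg1 = 1 - 2 * ts - tv
            arg2 = 1 - 2 * tv
            ok = (arg1 > 0) & (arg2 > 0)
            d = np.where(
                ok,
                -0.5 * np.log(np.maximum(arg1, 1e-300))
                - 0.25 * np.log(np.maximum(arg2, 1e-300)),
                np.nan,
            )
            for k, j in enumerate(range(i + 1, n)):
                if np.isnan(d[k]):
                    saturated.append((s.ids[i], s.ids[j]))
                    d[k] = p[k]
            D[i, i + 1 :] = d
    D = D + D.T
    if saturated:
        warnings.warn(
            f"{len(saturated)} saturated pair(s) under {model}; p-distance used for them"
        )
    return DistanceMatrix(labels=list(s.ids), matrix=D, model=model, saturated=saturated)


def nj_tree(D: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; deterministic via lowest-label ordering.

    Negative branch lengths are clamped to zero.  On additive distances the
    generating topology and branch lengths are recovered exactly.
    """
    if len(D.labels) < 3:
        raise InputError("neighbor joining needs >= 3 taxa")
    order = np.argsort(np.asarray(D.labels, dtype=object))
    labels = [D.labels[i] for i in order]
    mat = D.matrix[np.ix_(order, order)]
    dm = skbio.DistanceMatrix(mat, ids=labels)
    return _skbio_nj(dm, neg_as_zero=True)


def tree_to_newick(tree: TreeNode) -> str:
    import io

    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def newick_to_tree(newick: str) -> TreeNode:
    return TreeNode.read([newick])


def fragment_spans(breakpoints: Sequence[int], L_source: int) -> list[tuple[int, int]]:
    """Source-coordinate spans delimited by breakpoints: a breakpoint at b
    ends a fragment at column b (inclusive); e.g. [540, 820] on 1450 columns
    gives (1, 540), (541, 820), (821, 1450)."""
    bps = sorted(set(int(b) for b in breakpoints))
    if any(not (1 <= b < L_source) for b in bps):
        raise InputError(f"breakpoints must lie within [1, {L_source - 1}]")
    edges = [0] + bps + [L_source]
    return [(edges[k] + 1, edges[k + 1]) for k in range(len(edges) - 1)]


def _span_alignment(aln: Alignment, span: tuple[int, int]) -> Alignment | None:
    lo, hi = span
    idx = np.flatnonzero((aln.column_map >= lo) & (aln.column_map <= hi))
    if idx.size == 0:
        return None
    return aln.take_columns(idx)


def _n_variable(aln: Alignment) -> int:
    m = aln.matrix()
    return int((m != m[0]).any(axis=0).sum())


def fragment_trees(
    aln: Alignment,
    breakpoints: Sequence[int],
    model: str = "p",
    min_variable_sites: int = 3,
) -> list[tuple[tuple[int, int], TreeNode | None]]:
    """One NJ tree per inter-breakpoint fragment (source coordinates).

    Fragments with fewer than ``min_variable_sites`` variable columns are
    returned with a None tree (and a warning) rather than a spurious tree.
    """
    L_source = int(aln.column_map[-1])
    out: list[tuple[tuple[int, int], TreeNode | None]] = []
    for span in fragment_spans(breakpoints, L_source):
        sub = _span_alignment(aln, span)
        if sub is None or _n_variable(sub) < min_variable_sites:
            warnings.warn(f"fragment {span} has < {min_variable_sites} variable sites; skipped")
            out.append((span, None))
            continue
        out.append((span, nj_tree(pairwise_distances(sub, model))))
    return out


@dataclass
class ParentalAssignment:
    """Per-fragment nearest donor group(s) for one recombinant sequence."""

    recombinant: str
    fragments: list[tuple[int, int]]
    donors: list[list[str]]  # per fragment, best group first then tied alternatives
    margins: list[float]  # second-best minus best mean distance
    assignment: str  # e.g. "h : c" or "h or i : c"

    def best_donors(self) -> list[str]:
        return [d[0] for d in self.donors]


def assign_parents(
    recomb_id: str,
    fragment_dms: Sequence[tuple[tuple[int, int], DistanceMatrix]],
    groups: GroupMap,
    tie_tolerance: float = 0.10,
    exclude_labels: Sequence[str] = ("ungrouped", "recombinant"),
) -> ParentalAssignment:
    """Nearest-group donor per fragment, with tie reporting.

    For each fragment, the donor is the group (never the recombinant's own
    singleton, nor ``exclude_labels``) minimizing the mean distance to the
    recombinant; groups whose mean distance is within ``tie_tolerance`` of
    the best (relative) are listed as alternatives ("h or i").
    """
    donors: list[list[str]] = []
    margins: list[float] = []
    spans: list[tuple[int, int]] = []
    for span, dm in fragment_dms:
        if recomb_id not in dm.labels:
            raise InputError(f"{recomb_id!r} absent from fragment {span} matrix")
        by_group: dict[str, list[float]] = {}
        for other in dm.labels:
            if other == recomb_id:
                continue
            g = groups.get(other, "ungrouped")
            if g in exclude_labels:
                continue
            by_group.setdefault(g, []).append(dm.value(recomb_id, other))
        own = groups.get(recomb_id)
        if own in by_group and not by_group[own]:
            del by_group[own]
        if not by_group:
            raise InputError(f"no candidate donor groups for {recomb_id!r}")
        means = sorted(((float(np.mean(v)), g) for g, v in by_group.items()))
        best_d, _ = means[0]
        tol = best_d * tie_tolerance
        tied = [g for d, g in means if d - best_d <= tol]
        margin = means[1][0] - best_d if len(means) > 1 else 0.0
        donors.append(tied)
        margins.append(max(margin, 0.0))
        spans.append(span)
    text = " : ".join(" or ".join(d) for d in donors)
    return ParentalAssignment(
        recombinant=recomb_id,
        fragments=spans,
        donors=donors,
        margins=margins,
        assignment=text,
    )
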