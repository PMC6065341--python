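"""Group-wise multiple sequence alignment.

The coding loci (rbcL, matK) align globally; the length-variable spacers
(trnH-psbA, ITS) are partitioned by family, order, or curated groups of
closely related orders, aligned independently per group, and the group
blocks are then placed block-diagonally ('?' elsewhere) so that columns
from different groups are never treated as homologous.

The aligner is a generic progressive profile aligner: k-mer distances feed
a neighbor-joining guide tree, and profiles are merged by affine-gap
(Gotoh) profile-profile Needleman-Wunsch in guide-tree post-order.  It is
not a re-implementation of any particular published aligner; externally
produced alignments can be imported through ``seqio`` instead.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .phylo import Clade, DistanceMatrix, SupportTree, nj_tree
from .seqio import LocusAlignment, SpecimenRecord

logger = logging.getLogger(__name__)

NEG_INF = -1e30


@dataclass(frozen=True)
class AlignmentScoring:
    """Match/mismatch and affine gap parameters for profile alignment."""

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0


@dataclass
class AlignmentGroupingPlan:
    locus_name: str
    grouping_level: str  # global | family | order | custom
    groups: dict[str, set[str]]

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def plan_groups(
    metadata: Sequence[SpecimenRecord],
    locus_name: str,
    grouping_level: str = "global",
    overrides: Mapping[str, Sequence[str]] | None = None,
    specimens_with_data: set[str] | None = None,
) -> AlignmentGroupingPlan:
    """Partition specimens with data for a locus into alignment groups.

    ``overrides`` maps a merged group name to the families/orders it
    absorbs (the "closely related orders" case); any family/order not named
    in an override keeps its own group.
    """
    if grouping_level not in ("global", "family", "order", "custom"):
        raise ValueError(f"unknown grouping_level {grouping_level!r}")
    records = [
        r for r in metadata
        if specimens_with_data is None or r.specimen_id in specimens_with_data
    ]
    if grouping_level == "global":
        groups = {"all": {r.specimen_id for r in records}}
        return AlignmentGroupingPlan(locus_name, grouping_level, groups)

    key_attr = "family" if grouping_level == "family" else "order"
    known_keys = {getattr(r, key_attr) for r in records}
    merged_into: dict[str, str] = {}
    if overrides:
        for merged_name, members in overrides.items():
            for member in members:
                if member not in known_keys:
                    raise ValueError(
                        f"override group {merged_name!r} references unknown "
                        f"{key_attr} {member!r}"
                    )
                merged_into[member] = merged_name
    groups: dict[str, set[str]] = {}
    for r in records:
        key = getattr(r, key_attr)
        gid = merged_into.get(key, key)
        groups.setdefault(gid, set()).add(r.specimen_id)
    logger.info("%s grouping for %s: %d group(s)", grouping_level, locus_name, len(groups))
    return AlignmentGroupingPlan(locus_name, grouping_level, groups)


# ---------------------------------------------------------------------------
# k-mer guide distances


def kmer_distance(seq_a: str, seq_b: str, k: int = 6) -> float:
    """Dissimilarity in [0, 1]: 1 - shared k-mers / smaller k-mer multiset."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if len(seq_a) < k or len(seq_b) < k:
        logger.warning("sequence shorter than k=%d; distance set to 1", k)
        return 1.0
    ca = Counter(seq_a[i : i + k] for i in range(len(seq_a) - k + 1))
    cb = Counter(seq_b[i : i + k] for i in range(len(seq_b) - k + 1))
    shared = sum(min(ca[m], cb[m]) for m in ca.keys() & cb.keys())
    smaller = min(sum(ca.values()), sum(cb.values()))
    return 1.0 - shared / smaller


def _guide_tree(sequences: Mapping[str, str], k: int = 6) -> Clade:
    ids = list(sequences)
    n = len(ids)
    if n == 1:
        return Clade(name=ids[0])
    if n == 2:
        return Clade(children=[Clade(name=ids[0]), Clade(name=ids[1])])
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = kmer_distance(sequences[ids[i]], sequences[ids[j]], k)
    dm = DistanceMatrix(ids, D, "kmer", np.zeros_like(D, bool), np.zeros_like(D, bool))
    return nj_tree(dm).root


# ---------------------------------------------------------------------------
# Profile-profile alignment (Gotoh affine gaps)


class _Profile:
    """An in-progress alignment: row ids plus an (n_rows, width) char array."""

    __slots__ = ("ids", "chars")

    def __init__(self, ids: list[str], chars: np.ndarray):
        self.ids = ids
        self.chars = chars  # dtype '<U1'

    @classmethod
    def from_sequence(cls, sid: str, seq: str) -> "_Profile":
        return cls([sid], np.array([list(seq)], dtype="<U1"))

    @property
    def width(self) -> int:
        return self.chars.shape[1]


def _column_scores(a: _Profile, b: _Profile, scoring: AlignmentScoring) -> np.ndarray:
    """Expected pairwise substitution score between every column pair.

    Characters are compared literally (ambiguity codes score as mismatch
    unless identical); pairs involving a gap contribute 0 and the score is
    averaged over all row pairs, keeping it commensurate with gap costs.
    """
    alphabet = sorted(set(a.chars.ravel()) | set(b.chars.ravel()) - {"-"})
    alphabet = [c for c in alphabet if c != "-"]
    idx = {c: i for i, c in enumerate(alphabet)}
    A = len(alphabet)

    def counts(p: _Profile) -> np.ndarray:
        out = np.zeros((p.width, A), dtype=np.float64)
        for c, i in idx.items():
            out[:, i] = (p.chars == c).sum(axis=0)
        return out

    S = np.full((A, A), scoring.mismatch)
    np.fill_diagonal(S, scoring.match)
    ca, cb = counts(a), counts(b)
    denom = a.chars.shape[0] * b.chars.shape[0]
    return (ca @ S @ cb.T) / denom


def _align_profiles(a: _Profile, b: _Profile, scoring: AlignmentScoring) -> _Profile:
    S = _column_scores(a, b, scoring)
    la, lb = a.width, b.width
    go, ge = scoring.gap_open, scoring.gap_extend
    M = np.full((la + 1, lb + 1), NEG_INF)
    Ix = np.full((la + 1, lb + 1), NEG_INF)  # gap in b (consume a column)
    Iy = np.full((la + 1, lb + 1), NEG_INF)  # gap in a (consume b column)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        Ix[i, 0] = go + (i - 1) * ge
    for j in range(1, lb + 1):
        Iy[0, j] = go + (j - 1) * ge
    for i in range(1, la + 1):
        prev_best = np.maximum(np.maximum(M[i - 1, :-1], Ix[i - 1, :-1]), Iy[i - 1, :-1])
        M[i, 1:] = S[i - 1, :] + prev_best
        Ix[i, :] = np.maximum(M[i - 1, :] + go, Ix[i - 1, :] + ge)
        # Iy within-row recurrence, vectorised with a running maximum:
        # Iy[i,j] = max_{k<j} M[i,k] + go + (j-1-k)*ge
        u = M[i, :-1] + go - np.arange(lb) * ge
        Iy[i, 1:] = np.maximum.accumulate(u) + np.arange(lb) * ge
    # traceback
    out_a: list[np.ndarray] = []
    out_b: list[np.ndarray] = []
    gap_a = np.full(a.chars.shape[0], "-", dtype="<U1")
    gap_b = np.full(b.chars.shape[0], "-", dtype="<U1")
    i, j = la, lb
    state = int(np.argmax([M[i, j], Ix[i, j], Iy[i, j]]))
    while i > 0 or j > 0:
        if state == 0:
            out_a.append(a.chars[:, i - 1])
            out_b.append(b.chars[:, j - 1])
            prev = [M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev)) if (i, j) != (0, 0) else 0
        elif state == 1:
            out_a.append(a.chars[:, i - 1])
            out_b.append(gap_b)
            state = 1 if Ix[i, j] == Ix[i - 1, j] + ge else 0
            i -= 1
        else:
            out_a.append(gap_a)
            out_b.append(b.chars[:, j - 1])
            state = 2 if Iy[i, j] == Iy[i, j - 1] + ge else 0
            j -= 1
    cols_a = np.stack(out_a[::-1], axis=1) if out_a else np.empty((a.chars.shape[0], 0), "<U1")
    cols_b = np.stack(out_b[::-1], axis=1) if out_b else np.empty((b.chars.shape[0], 0), "<U1")
    return _Profile(a.ids + b.ids, np.vstack([cols_a, cols_b]))


def pairwise_align_score(seq_a: str, seq_b: str, scoring: AlignmentScoring | None = None) -> float:
    """Optimal global affine-gap alignment score for a sequence pair."""
    scoring = scoring or AlignmentScoring()
    a = _Profile.from_sequence("a", seq_a)
    b = _Profile.from_sequence("b", seq_b)
    merged = _align_profiles(a, b, scoring)
    return _sp_score(merged.chars[0], merged.chars[1], scoring)


def _sp_score(row_a: np.ndarray, row_b: np.ndarray, scoring: AlignmentScoring) -> float:
    score = 0.0
    in_gap = False
    for ca, cb in zip(row_a, row_b):
        if ca == "-" or cb == "-":
            score += scoring.gap_extend if in_gap else scoring.gap_open
            in_gap = True
        else:
            score += scoring.match if ca == cb else scoring.mismatch
            in_gap = False
    return score


def progressive_align(
    sequences: Mapping[str, str],
    guide_tree: Clade | SupportTree | None = None,
    scoring: AlignmentScoring | None = None,
    locus_name: str = "locus",
) -> LocusAlignment:
    """Progressive multiple alignment following a guide tree.

    Profiles are merged in guide-tree post-order; ungapping any output row
    returns its input sequence unchanged.
    """
    scoring = scoring or AlignmentScoring()
    if not sequences:
        return LocusAlignment(locus_name, {})
    if len(sequences) == 1:
        (sid, seq), = sequences.items()
        return LocusAlignment(locus_name, {sid: seq})
    root = guide_tree.root if isinstance(guide_tree, SupportTree) else guide_tree
    if root is None:
        root = _guide_tree(sequences)
    tree_tips = set(SupportTree._collect_tips(root))
    if tree_tips != set(sequences):
        raise ValueError("guide tree tips do not match sequence IDs")

    def merge(node: Clade) -> _Profile:
        if node.is_leaf:
            return _Profile.from_sequence(node.name, sequences[node.name])
        prof = merge(node.children[0])
        for child in node.children[1:]:
            prof = _align_profiles(prof, merge(child), scoring)
        return prof

    prof = merge(root)
    rows = {sid: "".join(prof.chars[i]) for i, sid in enumerate(prof.ids)}
    # keep input order for readability
    ordered = {sid: rows[sid] for sid in sequences}
    return LocusAlignment(locus_name, ordered)


# ---------------------------------------------------------------------------
# Group-wise alignment with block-diagonal merge


@dataclass
class GroupedAlignment:
    locus_name: str
    blocks: dict[str, LocusAlignment]
    merged: LocusAlignment
    block_spans: dict[str, tuple[int, int]] = field(default_factory=dict)  # 0-based half-open


def align_locus(
    sequences: Mapping[str, str],
    plan: AlignmentGroupingPlan,
    scoring: AlignmentScoring | None = None,
) -> GroupedAlignment:
    """Align each group independently, then merge block-diagonally.

    Cross-group columns are non-homologous: in the merged matrix each
    group's rows carry '?' outside the group's own column block.
    """
    planned = set().union(*plan.groups.values()) if plan.groups else set()
    unplanned = set(sequences) - planned
    if unplanned:
        raise ValueError(f"plan does not cover sequences: {', '.join(sorted(unplanned))}")
    blocks: dict[str, LocusAlignment] = {}
    for gid in sorted(plan.groups):
        members = {s: sequences[s] for s in sorted(plan.groups[gid]) if s in sequences}
        if members:
            blocks[gid] = progressive_align(members, scoring=scoring, locus_name=plan.locus_name)
    total = sum(b.width for b in blocks.values())
    merged_rows: dict[str, str] = {}
    spans: dict[str, tuple[int, int]] = {}
    offset = 0
    for gid, block in blocks.items():
        spans[gid] = (offset, offset + block.width)
        offset += block.width
    for gid, block in blocks.items():
        lo, hi = spans[gid]
        for sid, row in block.rows.items():
            merged_rows[sid] = "?" * lo + row + "?" * (total - hi)
    return GroupedAlignment(
        locus_name=plan.locus_name,
        blocks=blocks,
        merged=LocusAlignment(plan.locus_name, merged_rows),
        block_spans=spans,
    )
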