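"""Desk-scale tree inference: model-corrected distances, neighbor joining,
and nonparametric bootstrap support.

The tree container (:class:`SupportTree`) is deliberately engine-agnostic:
the resolution criterion downstream only ever asks "which bipartitions does
this tree contain, and with what support?", so externally computed ML trees
imported from Newick are interchangeable with the built-in NJ engine.

Distances use pairwise deletion: a site counts for a pair only when both
rows carry an unambiguous base (A/C/G/T).  Saturated distances (a log
argument that is not positive) are flagged, never silently clamped, and
block tree building with an explicit error.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
DISTANCE_MODELS = ("p-distance", "JC69", "K80")


# ---------------------------------------------------------------------------
# Tree container


@dataclass
class Clade:
    """A node of a (possibly multifurcating) phylogeny."""

    name: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class SupportTree:
    """Unrooted phylogeny whose internal edges may carry bootstrap support
    percentages in [0, 100]; an edge without a value is distinct from 0."""

    def __init__(self, root: Clade):
        self.root = root
        self._tips = tuple(self._collect_tips(root))
        if len(set(self._tips)) != len(self._tips):
            dupes = sorted({t for t in self._tips if self._tips.count(t) > 1})
            raise ValueError(f"duplicate tip labels: {', '.join(dupes)}")

    @staticmethod
    def _collect_tips(node: Clade) -> list[str]:
        if node.is_leaf:
            return [node.name or ""]
        out: list[str] = []
        for c in node.children:
            out.extend(SupportTree._collect_tips(c))
        return out

    @property
    def tip_names(self) -> tuple[str, ...]:
        return self._tips

    def __len__(self) -> int:
        return len(self._tips)

    # -- bipartitions -----------------------------------------------------

    def bipartitions(self) -> dict[frozenset, float | None]:
        """Map each non-trivial split of the unrooted topology to its support.

        Keys are normalised to the side *not* containing the reference tip
        (the lexicographically smallest label), so the same unrooted split
        always hashes identically regardless of rooting.  Trivial splits
        (single tip on either side) are omitted.  When a split is reachable
        from two root-adjacent edges, a present support value wins over an
        absent one.
        """
        taxa = frozenset(self._tips)
        ref = min(taxa)
        n = len(taxa)
        out: dict[frozenset, float | None] = {}

        def walk(node: Clade) -> frozenset:
            if node.is_leaf:
                return frozenset((node.name,))
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 2 <= len(below) <= n - 2:
                key = below if ref not in below else taxa - below
                if key not in out or out[key] is None:
                    out[key] = node.support
            return below

        walk(self.root)
        return out

    # -- Newick -----------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "SupportTree":
        depth = 0
        for pos, ch in enumerate(text):
            depth += ch == "("
            depth -= ch == ")"
            if depth < 0:
                raise ValueError(f"unbalanced parentheses at position {pos}")
        if depth != 0:
            raise ValueError(f"unbalanced parentheses: {depth} unclosed '(' at end of input")
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )

        def convert(dnode) -> Clade:
            if dnode.is_leaf():
                name = dnode.taxon.label if dnode.taxon else dnode.label
                return Clade(name=name, length=dnode.edge.length)
            support = None
            if dnode.label is not None:
                try:
                    support = float(dnode.label)
                except ValueError:
                    support = None
            return Clade(
                length=dnode.edge.length,
                support=support,
                children=[convert(c) for c in dnode.child_nodes()],
            )

        return cls(convert(dtree.seed_node))

    @classmethod
    def read(cls, path: str | Path) -> "SupportTree":
        return cls.from_newick(Path(path).read_text())

    def to_newick(self) -> str:
        def fmt(node: Clade) -> str:
            if node.is_leaf:
                core = node.name or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = "" if node.support is None else _fmt_num(node.support)
                core = f"({inner}){label}"
            if node.length is not None:
                core += f":{_fmt_num(node.length)}"
            return core

        return fmt(self.root) + ";"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def _fmt_num(x: float) -> str:
    return repr(round(float(x), 10)).rstrip("0").rstrip(".") or "0"


def read_newick(path: str | Path) -> SupportTree:
    return SupportTree.read(path)


def write_newick(tree: SupportTree, path: str | Path) -> None:
    tree.write(path)


def import_tree(newick_path: str | Path, metadata: Sequence) -> SupportTree:
    """Load an externally computed tree, validating tips against metadata."""
    tree = SupportTree.read(newick_path)
    known = {r.specimen_id for r in metadata}
    unmatched = sorted(set(tree.tip_names) - known)
    if unmatched:
        raise ValueError(f"tree tips not in metadata: {', '.join(unmatched)}")
    return tree


# ---------------------------------------------------------------------------
# Distances


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    model: str
    undefined: np.ndarray  # bool mask: no valid sites for the pair
    saturated: np.ndarray  # bool mask: log argument <= 0

    def flagged_pairs(self) -> list[tuple[str, str]]:
        bad = np.argwhere(np.triu(self.undefined | self.saturated, k=1))
        return [(self.labels[i], self.labels[j]) for i, j in bad]


def encode_rows(rows: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    """Encode aligned rows as an (n, L) int8 matrix; A/C/G/T -> 0..3, any
    gap, unknown or ambiguity code -> -1 (excluded by pairwise deletion)."""
    labels = list(rows)
    if not labels:
        return [], np.zeros((0, 0), dtype=np.int8)
    table = np.full(256, -1, dtype=np.int8)
    for ch, code in _CODE.items():
        table[ord(ch)] = code
        table[ord(ch.lower())] = code
    mats = [table[np.frombuffer(rows[l].encode("ascii"), dtype=np.uint8)] for l in labels]
    return labels, np.vstack(mats)


def _pair_counts(
    X: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pair counts of valid sites, matches and transitions, optionally
    with per-column multiplicities (bootstrap weights)."""
    n, L = X.shape
    w = np.ones(L, dtype=np.float32) if weights is None else weights.astype(np.float32)
    onehot = [(X == b).astype(np.float32) for b in range(4)]
    valid = (X >= 0).astype(np.float32)
    valid_pairs = (valid * w) @ valid.T
    matches = np.zeros((n, n), dtype=np.float32)
    for h in onehot:
        matches += (h * w) @ h.T
    # transitions: A<->G and C<->T
    ag = (onehot[0] * w) @ onehot[2].T
    ct = (onehot[1] * w) @ onehot[3].T
    transitions = ag + ag.T + ct + ct.T
    return valid_pairs, matches, transitions


def distances_from_counts(
    valid: np.ndarray, matches: np.ndarray, transitions: np.ndarray, model: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if model not in DISTANCE_MODELS:
        raise ValueError(f"unknown distance model {model!r}; choose from {DISTANCE_MODELS}")
    valid = valid.astype(np.float64)
    matches = matches.astype(np.float64)
    transitions = transitions.astype(np.float64)
    undefined = valid <= 0
    safe_valid = np.where(undefined, 1.0, valid)
    p = (valid - matches) / safe_valid
    saturated = np.zeros_like(undefined)
    with np.errstate(divide="ignore", invalid="ignore"):
        if model == "p-distance":
            d = p
        elif model == "JC69":
            arg = 1.0 - 4.0 * p / 3.0
            saturated = arg <= 0
            d = -0.75 * np.log(np.where(saturated, 1.0, arg))
        else:  # K80
            P = transitions / safe_valid
            Q = p - P  # transversion proportion
            a1 = 1.0 - 2.0 * P - Q
            a2 = 1.0 - 2.0 * Q
            saturated = (a1 <= 0) | (a2 <= 0)
            d = 0.5 * np.log(1.0 / np.where(saturated, 1.0, a1)) + 0.25 * np.log(
                1.0 / np.where(saturated, 1.0, a2)
            )
    d = np.where(undefined | saturated, np.nan, d)
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(undefined, False)
    np.fill_diagonal(saturated, False)
    return d.astype(np.float64), undefined, saturated


def distance_matrix(rows: Mapping[str, str], model: str = "K80") -> DistanceMatrix:
    """Model-corrected pairwise distances with pairwise deletion."""
    labels, X = encode_rows(rows)
    valid, matches, ts = _pair_counts(X)
    d, undef, sat = distances_from_counts(valid, matches, ts, model)
    return DistanceMatrix(labels=labels, values=d, model=model, undefined=undef, saturated=sat)


def pairwise_distance(seq_a: str, seq_b: str, model: str = "K80") -> float:
    """Distance between two aligned rows; NaN when undefined or saturated."""
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned rows must have equal width")
    dm = distance_matrix({"a": seq_a, "b": seq_b}, model=model)
    return float(dm.values[0, 1])


# ---------------------------------------------------------------------------
# Neighbor joining


def _nj_core(D: np.ndarray) -> tuple[list[tuple[int, int, float, float, int]], list[tuple[int, float]]]:
    """Saitou–Nei neighbor joining on a distance matrix.

    Returns the merge list ``(i_id, j_id, len_i, len_j, new_id)`` plus the
    final join (the ids and edge lengths meeting at the unresolved root).
    Ties in the Q-matrix are broken toward the lowest (row, column) index
    pair in the current active ordering, making the result deterministic.
    Negative branch lengths are clamped to zero (deficit logged).
    """
    n0 = D.shape[0]
    if n0 < 2:
        return [], [(0, 0.0)] if n0 == 1 else []
    D = D.astype(np.float64).copy()
    active = list(range(n0))  # node ids, in insertion order
    next_id = n0
    merges: list[tuple[int, int, float, float, int]] = []
    clamp_deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal clamp_deficit
        if x < 0:
            clamp_deficit += -x
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        flat = Q[iu]
        k = int(np.argmin(flat))  # first minimum in row-major upper-triangle order
        i, j = int(iu[0][k]), int(iu[1][k])
        li_raw = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        li = clamp(li_raw)
        lj = clamp(D[i, j] - li_raw)
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        newD = np.empty((m - 1, m - 1))
        newD[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        newD[: m - 2, m - 2] = dnew[keep]
        newD[m - 2, : m - 2] = dnew[keep]
        newD[m - 2, m - 2] = 0.0
        merges.append((active[i], active[j], li, lj, next_id))
        active = [active[x] for x in keep] + [next_id]
        next_id += 1
        D = newD

    if len(active) == 3:
        d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
        l0 = clamp(0.5 * (d01 + d02 - d12))
        l1 = clamp(0.5 * (d01 + d12 - d02))
        l2 = clamp(0.5 * (d02 + d12 - d01))
        final = [(active[0], l0), (active[1], l1), (active[2], l2)]
    elif len(active) == 2:
        half = clamp(0.5 * D[0, 1])
        final = [(active[0], half), (active[1], half)]
    else:
        final = [(active[0], 0.0)]
    if clamp_deficit > 0:
        logger.debug("NJ clamped negative branch lengths; total deficit %.6g", clamp_deficit)
    return merges, final


def _build_clade_tree(
    labels: Sequence[str],
    merges: list[tuple[int, int, float, float, int]],
    final: list[tuple[int, float]],
) -> Clade:
    nodes: dict[int, Clade] = {i: Clade(name=l) for i, l in enumerate(labels)}
    for i_id, j_id, li, lj, new_id in merges:
        nodes[i_id].length = li
        nodes[j_id].length = lj
        nodes[new_id] = Clade(children=[nodes[i_id], nodes[j_id]])
    root = Clade()
    for node_id, length in final:
        nodes[node_id].length = length
        root.children.append(nodes[node_id])
    return root


def nj_tree(dm: DistanceMatrix) -> SupportTree:
    """Neighbor-joining tree (no supports) from a distance matrix."""
    if len(dm.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    bad = dm.flagged_pairs()
    if bad:
        pairs = "; ".join(f"{a}~{b}" for a, b in bad[:10])
        raise ValueError(
            f"distance matrix has {len(bad)} undefined/saturated entr(ies): {pairs}"
        )
    merges, final = _nj_core(dm.values)
    return SupportTree(_build_clade_tree(dm.labels, merges, final))


def _nj_split_masks(D: np.ndarray, n_tips: int) -> set[int]:
    """Non-trivial splits of the NJ tree as normalised tip bitmasks."""
    merges, final = _nj_core(D)
    masks: dict[int, int] = {i: 1 << i for i in range(n_tips)}
    full = (1 << n_tips) - 1
    out: set[int] = set()
    for i_id, j_id, _li, _lj, new_id in merges:
        m = masks[i_id] | masks[j_id]
        masks[new_id] = m
        norm = (full ^ m) if (m & 1) else m
        if 2 <= bin(norm).count("1") <= n_tips - 2:
            out.add(norm)
    return out


def prune_undefined_rows(
    rows: Mapping[str, str], model: str = "K80"
) -> tuple[dict[str, str], list[str]]:
    """Iteratively drop the rows responsible for undefined or saturated
    pairwise distances (typically specimens whose only recovered locus is
    group-aligned, leaving zero shared sites with other groups).  Returns
    the reduced row mapping and the dropped labels."""
    labels, X = encode_rows(rows)
    valid, matches, ts = _pair_counts(X)
    _d, undef, sat = distances_from_counts(valid, matches, ts, model)
    bad = undef | sat
    dropped: list[str] = []
    while bad.any():
        i = int(bad.sum(axis=1).argmax())
        dropped.append(labels[i])
        keep = [j for j in range(len(labels)) if j != i]
        labels = [labels[j] for j in keep]
        bad = bad[np.ix_(keep, keep)]
    if dropped:
        logger.info("dropped %d row(s) with undefined distances: %s",
                    len(dropped), ", ".join(dropped))
    return {l: rows[l] for l in labels}, dropped


# ---------------------------------------------------------------------------
# Bootstrap


@dataclass
class BootstrapReport:
    n_replicates: int
    n_redrawn: int


def bootstrap_tree(
    supermatrix,
    model: str = "K80",
    n_replicates: int = 100,
    seed: int | None = None,
    max_redraws_factor: int = 10,
) -> tuple[SupportTree, BootstrapReport]:
    """NJ tree with nonparametric bootstrap supports.

    Columns are resampled with replacement *within each partition
    independently*, so every replicate preserves the per-locus site counts.
    Support on each internal edge of the tree built from the original
    columns is the percentage of replicates whose NJ tree contains the same
    bipartition.  A replicate producing an undefined/saturated distance is
    redrawn (counted in the report).  Fully deterministic for a fixed seed.
    """
    rows: Mapping[str, str] = supermatrix.rows
    partitions = getattr(supermatrix, "partitions", None)
    labels, X = encode_rows(rows)
    n, L = X.shape
    if n < 3:
        raise ValueError("bootstrap needs at least 3 rows")
    if not partitions:
        partitions = [("all", 1, L)]

    valid, matches, ts = _pair_counts(X)
    d, undef, sat = distances_from_counts(valid, matches, ts, model)
    dm = DistanceMatrix(labels, d, model, undef, sat)
    main = nj_tree(dm)
    if n_replicates == 0:
        return main, BootstrapReport(0, 0)

    rng = np.random.default_rng(seed)
    spans = [(s - 1, e) for (_name, s, e) in partitions]
    counts: dict[int, int] = {}
    n_redrawn = 0
    max_attempts = n_replicates * max_redraws_factor
    done = attempts = 0
    while done < n_replicates:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"bootstrap exceeded {max_attempts} attempts; "
                f"{n_redrawn} replicates had undefined distances"
            )
        attempts += 1
        w = np.zeros(L, dtype=np.float32)
        for lo, hi in spans:
            idx = rng.integers(lo, hi, size=hi - lo)
            w += np.bincount(idx, minlength=L).astype(np.float32)
        v, m, t = _pair_counts(X, w)
        dr, un, sa = distances_from_counts(v, m, t, model)
        if (un | sa).any():
            n_redrawn += 1
            continue
        for mask in _nj_split_masks(dr, n):
            counts[mask] = counts.get(mask, 0) + 1
        done += 1

    full = (1 << n) - 1
    index = {lab: i for i, lab in enumerate(labels)}

    def annotate(node: Clade) -> int:
        if node.is_leaf:
            return 1 << index[node.name]
        m = 0
        for c in node.children:
            m |= annotate(c)
        if node is not main.root:
            norm = (full ^ m) if (m & 1) else m
            if 2 <= bin(norm).count("1") <= n - 2:
                node.support = 100.0 * counts.get(norm, 0) / n_replicates
        return m

    annotate(main.root)
    return SupportTree(main.root), BootstrapReport(n_replicates, n_redrawn)
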