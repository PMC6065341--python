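"""Shared fixtures: small synthetic communities and pipeline runs reused
across test modules (session-scoped where they are expensive)."""

from __future__ import annotations

import random
from dataclasses import replace

import pytest

from barcodetree import CommunitySpec, HybridizationSpec, pipeline
from barcodetree import simulate as sim


@pytest.fixture(scope="session")
def clean_bundle(tmp_path_factory):
    """End-to-end pipeline on a 50-species community with no hybridization,
    full recovery, four full-length loci and 100 bootstrap replicates."""
    cfg = pipeline.merge_config({
        "seed": 1,
        "simulate": {"n_singleton_genera": 38, "n_pairs": 6, "recovery": 1.0},
        "tree": {"bootstrap": 100},
    })
    out = tmp_path_factory.mktemp("clean_run")
    return pipeline.run_pipeline(cfg, out)


@pytest.fixture(scope="session")
def capture_dataset():
    """Community with three two-species genera, all forced into plastid
    capture (nuclear genealogy untouched), full-length loci, no missing
    data."""
    spec = replace(
        CommunitySpec.small(n_singleton_genera=6, n_pairs=3), singleton_fraction=0.0
    )
    hyb = HybridizationSpec(p_capture=1.0, p_nuclear_share=0.0)
    models = [replace(m, recovery_prob=1.0) for m in sim.default_locus_models()]
    return sim.simulate_dataset(spec, models, hyb, seed=1)


def random_binary_tree(labels: list[str], rng: random.Random):
    """Random rooted binary tree over labels as nested tuples with branch
    lengths: leaf = (label, length), internal = ((left, right), length)."""

    def build(labs):
        if len(labs) == 1:
            return (labs[0], round(rng.uniform(0.1, 1.0), 6))
        k = rng.randint(1, len(labs) - 1)
        left, right = labs[:k], labs[k:]
        return ((build(left), build(right)), round(rng.uniform(0.1, 1.0), 6))

    labs = labels[:]
    rng.shuffle(labs)
    return build(labs)


def tree_distances(node) -> dict:
    """Additive tip-to-tip path lengths of a nested-tuple tree, computed by
    straightforward recursion (independent of any package tree code)."""
    dists: dict[tuple[str, str], float] = {}

    def walk(n) -> dict[str, float]:
        content, length = n
        if isinstance(content, str):
            return {content: length}
        left, right = content
        dl, dr = walk(left), walk(right)
        for a, da in dl.items():
            for b, db in dr.items():
                key = (a, b) if a < b else (b, a)
                dists[key] = da + db
        return {t: d + length for part in (dl, dr) for t, d in part.items()}

    walk(node)
    return dists


def tree_splits(node, labels: list[str]) -> set[frozenset]:
    """Non-trivial bipartitions of a nested-tuple tree, normalised to the
    side not containing the smallest label."""
    taxa = frozenset(labels)
    ref = min(taxa)
    out: set[frozenset] = set()

    def walk(n) -> frozenset:
        content, _length = n
        if isinstance(content, str):
            return frozenset((content,))
        left, right = content
        below = walk(left) | walk(right)
        if 2 <= len(below) <= len(taxa) - 2:
            out.add(below if ref not in below else taxa - below)
        return below

    walk(node)
    return out
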