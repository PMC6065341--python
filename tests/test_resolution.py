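"""The monophyly-with-support criterion and its aggregation tables."""

import random

import dendropy
import pandas as pd
import pytest

from barcodetree.phylo import SupportTree
from barcodetree.resolution import (
    ResolutionConfig,
    aggregate,
    combination_sweep,
    count_cells,
    is_exclusive_clade,
    resolve_genera,
    resolve_species,
    species_per_genus_class,
    threshold_sweep,
)
from barcodetree.seqio import SpecimenRecord


def _rec(sid, species, genus=None, fam="F1", lf="herbaceous", clade="angiosperm"):
    genus = genus or species.split()[0]
    return SpecimenRecord(sid, species, genus, fam, "O1", lf, clade)


# ---------------------------------------------------------------------------
# is_exclusive_clade


def test_exclusive_clade_basic():
    t = SupportTree.from_newick("((a1:1,a2:1)90:1,(b1:1,b2:1)80:1);")
    assert is_exclusive_clade(t, {"a1", "a2"}) == (True, 90.0)
    assert is_exclusive_clade(t, {"a1", "b1"}) == (False, None)
    assert is_exclusive_clade(t, {"a1"}) == (True, None)  # single tip: trivial


def test_exclusive_clade_all_but_one_has_no_support():
    t = SupportTree.from_newick("((a:1,b:1)90:1,(c:1,d:1)80:1);")
    mono, support = is_exclusive_clade(t, {"a", "b", "c"})
    assert mono and support is None


def test_exclusive_clade_unknown_tip_rejected():
    t = SupportTree.from_newick("((a,b),(c,d));")
    with pytest.raises(ValueError, match="zz"):
        is_exclusive_clade(t, {"a", "zz"})


def _random_support_tree(labels, rng):
    """Random binary tree over labels with random supports, as Newick."""
    nodes = [f"{l}:1" for l in labels]
    rng.shuffle(nodes)
    while len(nodes) > 2:
        a = nodes.pop(rng.randrange(len(nodes)))
        b = nodes.pop(rng.randrange(len(nodes)))
        nodes.append(f"({a},{b}){rng.randint(0, 100)}:1")
    return f"({nodes[0]},{nodes[1]});"


@pytest.mark.parametrize("seed", range(12))
def test_monophyly_matches_exhaustive_edge_enumeration(seed):
    """For every random species subset, the criterion's decision equals an
    exhaustive scan over all edges' bipartitions via an independent
    (dendropy) traversal of the same Newick."""
    rng = random.Random(seed)
    n = rng.randint(5, 12)
    labels = [f"t{i}" for i in range(n)]
    newick = _random_support_tree(labels, rng)
    tree = SupportTree.from_newick(newick)

    dtree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    taxa = frozenset(labels)
    edge_sides = set()
    for node in dtree.preorder_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        edge_sides.add(leaves)
        edge_sides.add(taxa - leaves)

    for _ in range(25):
        k = rng.randint(1, n)
        subset = frozenset(rng.sample(labels, k))
        mono, _support = is_exclusive_clade(tree, subset)
        assert mono == (subset in edge_sides), (newick, sorted(subset))


def test_rooting_invariance():
    """Decisions are identical under any rooting of the same unrooted
    topology."""
    rng = random.Random(3)
    labels = [f"t{i}" for i in range(8)]
    newick = _random_support_tree(labels, rng)
    base = SupportTree.from_newick(newick)
    subsets = [frozenset(rng.sample(labels, rng.randint(2, 6))) for _ in range(15)]
    base_calls = [is_exclusive_clade(base, s)[0] for s in subsets]

    dtree = dendropy.Tree.get(data=newick, schema="newick")
    for edge in list(dtree.preorder_edge_iter())[3:6]:
        if edge.head_node is dtree.seed_node or edge.head_node.is_leaf():
            continue
        dtree.reroot_at_edge(edge, update_bipartitions=False)
        rerooted = SupportTree.from_newick(dtree.as_string(schema="newick").strip())
        calls = [is_exclusive_clade(rerooted, s)[0] for s in subsets]
        assert calls == base_calls


# ---------------------------------------------------------------------------
# resolve_species / resolve_genera


def _four_species_tree(sup_a=90, sup_b=80):
    return SupportTree.from_newick(
        f"(((a1:1,a2:1){sup_a}:1,(b1:1,b2:1){sup_b}:1)70:1,((c1:1,c2:1)95:1,(d1:1,d2:1)40:1)60:1);"
    )


def _four_species_meta():
    return (
        [_rec(f"a{i}", "Aa x") for i in (1, 2)]
        + [_rec(f"b{i}", "Bb x", fam="F2") for i in (1, 2)]
        + [_rec(f"c{i}", "Cc x", fam="F2", lf="woody") for i in (1, 2)]
        + [_rec(f"d{i}", "Dd x", fam="F3", lf="woody") for i in (1, 2)]
    )


def test_support_threshold_is_strict():
    meta = _four_species_meta()
    df51 = resolve_species(_four_species_tree(sup_a=51), meta)
    df50 = resolve_species(_four_species_tree(sup_a=50), meta)
    assert bool(df51[df51.species == "Aa x"].resolved.iloc[0])
    assert not bool(df50[df50.species == "Aa x"].resolved.iloc[0])


def test_low_support_species_not_resolved():
    df = resolve_species(_four_species_tree(), _four_species_meta())
    by = df.set_index("species")
    assert bool(by.loc["Cc x", "resolved"])  # support 95
    assert not bool(by.loc["Dd x", "resolved"])  # monophyletic but support 40
    assert bool(by.loc["Dd x", "monophyletic"])


def test_non_monophyletic_species_not_resolved():
    # species split across two genera's clades
    t = SupportTree.from_newick("((a1:1,b1:1)99:1,(a2:1,b2:1)99:1);")
    meta = [_rec("a1", "Aa x"), _rec("a2", "Aa x"), _rec("b1", "Bb y"), _rec("b2", "Bb y")]
    df = resolve_species(t, meta)
    assert not df.resolved.any()


def test_singleton_policy():
    t = SupportTree.from_newick("((a1:1,a2:1)90:1,(b1:1,c1:1)10:1);")
    meta = [_rec("a1", "Aa x"), _rec("a2", "Aa x"), _rec("b1", "Bb y"), _rec("c1", "Cc z")]
    resolved = resolve_species(t, meta, ResolutionConfig(singleton_policy="resolved"))
    excluded = resolve_species(t, meta, ResolutionConfig(singleton_policy="excluded"))
    assert resolved.set_index("species").loc["Bb y", "resolved"]
    assert not excluded.set_index("species").loc["Bb y", "resolved"]
    r_table = aggregate(resolved, meta)
    e_table = aggregate(excluded, meta)
    assert r_table.rate("overall", "all") == 100.0
    assert e_table.rate("overall", "all") == pytest.approx(33.33)


def test_species_without_data_not_assessable():
    t = SupportTree.from_newick("((a1:1,a2:1)90:1,(b1:1,b2:1)80:1);")
    meta = _four_species_meta()  # c*, d* not in tree
    df = resolve_species(t, meta)
    by = df.set_index("species")
    assert not by.loc["Cc x", "assessable"]
    table = aggregate(df, meta)
    sel = table.rates[(table.rates.grouping == "overall")]
    assert sel.total.iloc[0] == 2  # only assessable species in denominator


def test_resolve_genera_monotypic_and_sister_species():
    t = SupportTree.from_newick(
        "(((a1:1,a2:1)90:1,(a3:1,a4:1)85:1)80:1,((b1:1,b2:1)95:1,(c1:1,c2:1)70:1)60:1);"
    )
    meta = (
        [_rec(f"a{i}", "Aa x") for i in (1, 2)]
        + [_rec(f"a{i}", "Aa y") for i in (3, 4)]
        + [_rec(f"b{i}", "Bb z", fam="F2") for i in (1, 2)]
        + [_rec(f"c{i}", "Cc w", fam="F2") for i in (1, 2)]
    )
    df = resolve_genera(t, meta).set_index("genus")
    assert bool(df.loc["Aa", "resolved"])  # two sister species under support 80
    assert bool(df.loc["Bb", "resolved"])  # monotypic genus


# ---------------------------------------------------------------------------
# Aggregation


def test_sg_class_capped_at_five():
    meta = [_rec(f"s{i}", f"Gg sp{i}", genus="Gg") for i in range(7)]
    classes = species_per_genus_class(meta)
    assert all(c == 5 for c in classes.values())


def test_life_form_difference_arithmetic():
    """Aggregation reproduces the rate-difference arithmetic of stratified
    tables: 92.62% vs 65.63% -> 26.99 points; 97.66% vs 74.24% -> 23.42."""

    def build(n_herb, k_herb, n_woody, k_woody):
        rows = []
        meta = []
        for i in range(n_herb):
            sp = f"H{i} x"
            meta.append(_rec(f"h{i}", sp, genus=f"H{i}"))
            rows.append({"species": sp, "n_individuals": 2, "assessable": True,
                         "monophyletic": True, "support": 99.0, "resolved": i < k_herb})
        for i in range(n_woody):
            sp = f"W{i} x"
            meta.append(_rec(f"w{i}", sp, genus=f"W{i}", lf="woody"))
            rows.append({"species": sp, "n_individuals": 2, "assessable": True,
                         "monophyletic": True, "support": 99.0, "resolved": i < k_woody})
        return aggregate(pd.DataFrame(rows), meta, combination="X")

    matk_like = build(122, 113, 64, 42)  # 92.62% vs 65.63%
    assert matk_like.rate("life_form", "herbaceous") == 92.62
    assert matk_like.rate("life_form", "woody") == 65.63
    assert matk_like.life_form_differences.difference.iloc[0] == 26.99

    rmpi_like = build(128, 125, 66, 49)  # 97.66% vs 74.24%
    assert rmpi_like.life_form_differences.difference.iloc[0] == 23.42


def test_all_resolved_gives_100_everywhere():
    meta = _four_species_meta()
    rows = pd.DataFrame([
        {"species": s, "n_individuals": 2, "assessable": True,
         "monophyletic": True, "support": 99.0, "resolved": True}
        for s in sorted({r.species for r in meta})
    ])
    table = aggregate(rows, meta)
    assert all(p == 100.0 for p in table.rates.pct)


def test_empty_stratum_absent_not_zero():
    meta = [_rec("a1", "Aa x"), _rec("a2", "Aa x")]  # no woody, no gymnosperm
    rows = pd.DataFrame([{"species": "Aa x", "n_individuals": 2, "assessable": True,
                          "monophyletic": True, "support": 99.0, "resolved": True}])
    table = aggregate(rows, meta)
    assert table.rate("life_form", "woody") is None
    assert table.rate("clade", "gymnosperm") is None


def test_gymnosperm_monotypic_genera_all_resolved():
    """Six gymnosperm species in six monotypic genera, each exclusively
    clustered with support over the threshold, score 6/6."""
    tips = [f"g{i}_1:1,g{i}_2:1" for i in range(6)]
    newick = "(" + ",".join(f"({t}){80 + i}:1" for i, t in enumerate(tips)) + ");"
    t = SupportTree.from_newick(newick)
    meta = [
        _rec(f"g{i}_{j}", f"G{i} x", genus=f"G{i}", fam=f"GF{i % 3}", lf="woody", clade="gymnosperm")
        for i in range(6)
        for j in (1, 2)
    ]
    table = aggregate(resolve_species(t, meta), meta)
    sel = table.rates[(table.rates.grouping == "clade") & (table.rates.stratum == "gymnosperm")]
    assert sel.resolved.iloc[0] == 6 and sel.total.iloc[0] == 6
    assert sel.pct.iloc[0] == 100.0


def test_threshold_monotonicity():
    t = _four_species_tree()
    meta = _four_species_meta()
    sweep = threshold_sweep(t, meta, thresholds=list(range(0, 101, 10)))
    pcts = sweep.pct.tolist()
    assert all(a >= b for a, b in zip(pcts, pcts[1:]))


def test_count_cells_shape(clean_bundle):
    cells = count_cells(clean_bundle.tables)
    assert set(cells.columns) == {"barcode", "sg_class", "resolved", "total"}
    assert cells.barcode.nunique() == 8
    assert ((cells.resolved >= 0) & (cells.resolved <= cells.total)).all()


def test_combination_sweep_skips_missing(caplog):
    meta = _four_species_meta()
    trees = {"R": _four_species_tree()}
    with caplog.at_level("WARNING"):
        tables = combination_sweep(trees, meta)
    assert list(tables) == ["R"]
    assert any("RMPI" in r.message for r in caplog.records)
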