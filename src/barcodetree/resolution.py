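"""Species discrimination by tree-based monophyly with bootstrap support.

A species is *resolved* on a tree when all of its sampled individuals form
an exclusive clade (equivalently: some edge of the unrooted tree separates
exactly those tips from everything else) whose support strictly exceeds
the threshold (default 50%).  Working with edge bipartitions of the
unrooted topology makes the decision independent of any arbitrary rooting.

Species sampled once are trivially exclusive; whether they count as
resolved is a policy switch (``singleton_policy``), because rate
denominators change materially when a community holds many singletons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .phylo import SupportTree
from .seqio import COMBINATIONS, SpecimenRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResolutionConfig:
    """Support threshold is a strict inequality: support must be *over*
    the threshold for a species to count as resolved."""

    support_threshold: float = 50.0
    singleton_policy: str = "resolved"  # resolved | excluded

    def __post_init__(self) -> None:
        if not 0.0 <= self.support_threshold <= 100.0:
            raise ValueError("support_threshold must be in [0, 100]")
        if self.singleton_policy not in ("resolved", "excluded"):
            raise ValueError("singleton_policy must be 'resolved' or 'excluded'")


def is_exclusive_clade(
    tree: SupportTree, tipset: Iterable[str]
) -> tuple[bool, float | None]:
    """Does some edge of the unrooted tree separate exactly ``tipset``?

    Returns ``(exclusive, support)``.  Support is absent (None) for
    trivial tipsets: a single tip, all tips, or all-but-one tip, none of
    which correspond to an internal edge.
    """
    tipset = frozenset(tipset)
    taxa = frozenset(tree.tip_names)
    unknown = tipset - taxa
    if unknown:
        raise ValueError(f"tips not in tree: {', '.join(sorted(unknown))}")
    if not tipset:
        raise ValueError("tipset must be non-empty")
    n = len(taxa)
    if len(tipset) in (1, n):
        return True, None
    if len(tipset) == n - 1:
        # complement is a single tip: always an (external) edge, no support
        return True, None
    splits = tree.bipartitions()
    ref = min(taxa)
    key = tipset if ref not in tipset else taxa - tipset
    if key in splits:
        return True, splits[key]
    return False, None


@dataclass
class SpeciesResolution:
    species: str
    n_individuals: int
    assessable: bool
    monophyletic: bool
    support: float | None
    resolved: bool


def _resolve_tipsets(
    tree: SupportTree,
    tipsets: Mapping[str, frozenset],
    config: ResolutionConfig,
) -> list[SpeciesResolution]:
    out: list[SpeciesResolution] = []
    for name in sorted(tipsets):
        tips = tipsets[name]
        if not tips:
            out.append(SpeciesResolution(name, 0, False, False, None, False))
            continue
        mono, support = is_exclusive_clade(tree, tips)
        if len(tips) == 1:
            resolved = config.singleton_policy == "resolved"
        else:
            resolved = mono and support is not None and support > config.support_threshold
        out.append(SpeciesResolution(name, len(tips), True, mono, support, resolved))
    return out


def resolve_species(
    tree: SupportTree,
    metadata: Sequence[SpecimenRecord],
    config: ResolutionConfig | None = None,
) -> pd.DataFrame:
    """Per-species monophyly/support/resolved flags for one tree.

    Species whose specimens are all absent from the tree (no data for this
    barcode combination) are recorded as not assessable and never enter a
    rate denominator.
    """
    config = config or ResolutionConfig()
    tree_tips = set(tree.tip_names)
    by_specimen = {r.specimen_id: r for r in metadata}
    stray = sorted(tree_tips - set(by_specimen))
    if stray:
        raise ValueError(f"tree tips without metadata: {', '.join(stray)}")
    tipsets: dict[str, frozenset] = {}
    for species in sorted({r.species for r in metadata}):
        tips = frozenset(
            r.specimen_id for r in metadata if r.species == species and r.specimen_id in tree_tips
        )
        tipsets[species] = tips
    rows = _resolve_tipsets(tree, tipsets, config)
    df = pd.DataFrame([r.__dict__ for r in rows])
    n_dropped = int((~df["assessable"]).sum())
    if n_dropped:
        logger.info("%d species not assessable on this tree (no data)", n_dropped)
    return df


def resolve_genera(
    tree: SupportTree,
    metadata: Sequence[SpecimenRecord],
    config: ResolutionConfig | None = None,
) -> pd.DataFrame:
    """Genus-level analogue of :func:`resolve_species`."""
    config = config or ResolutionConfig()
    tree_tips = set(tree.tip_names)
    tipsets = {
        genus: frozenset(
            r.specimen_id for r in metadata if r.genus == genus and r.specimen_id in tree_tips
        )
        for genus in sorted({r.genus for r in metadata})
    }
    rows = _resolve_tipsets(tree, tipsets, config)
    df = pd.DataFrame([r.__dict__ for r in rows]).rename(columns={"species": "genus"})
    return df


# ---------------------------------------------------------------------------
# Aggregation


def species_per_genus_class(metadata: Sequence[SpecimenRecord], cap: int = 5) -> dict[str, int]:
    """Number of sampled congeneric species for each species, capped for
    reporting (class 5 holds 'five or more')."""
    genus_species: dict[str, set[str]] = {}
    for r in metadata:
        genus_species.setdefault(r.genus, set()).add(r.species)
    out: dict[str, int] = {}
    for genus, spp in genus_species.items():
        cls = min(len(spp), cap)
        for sp in spp:
            out[sp] = cls
    return out


def _round2(x: float) -> float:
    """Round to 2 decimals with ties away from zero (printed-table
    convention), not banker's rounding."""
    return float(Decimal(x).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _rate(sub: pd.DataFrame) -> tuple[int, int, float | None]:
    assessable = sub[sub["assessable"]]
    total = len(assessable)
    resolved = int(assessable["resolved"].sum())
    pct = _round2(100.0 * resolved / total) if total else None
    return resolved, total, pct


@dataclass
class ResolutionTable:
    """Aggregated resolution rates for one (combination, tree) analysis."""

    combination: str
    per_species: pd.DataFrame
    rates: pd.DataFrame  # columns: grouping, stratum, resolved, total, pct
    life_form_differences: pd.DataFrame = field(default_factory=pd.DataFrame)

    def rate(self, grouping: str, stratum: str) -> float | None:
        sel = self.rates[(self.rates["grouping"] == grouping) & (self.rates["stratum"] == stratum)]
        if sel.empty:
            return None
        val = sel["pct"].iloc[0]
        return None if pd.isna(val) else float(val)


def aggregate(
    per_species: pd.DataFrame,
    metadata: Sequence[SpecimenRecord],
    combination: str = "",
) -> ResolutionTable:
    """Aggregate per-species flags into the study's stratified rate table:
    overall, by major clade, by life form, by species-per-genus class, and
    by genus; plus the herbaceous-woody rate difference."""
    attrs = {}
    for r in metadata:
        attrs.setdefault(r.species, (r.clade, r.life_form, r.genus))
    sg_class = species_per_genus_class(metadata)
    df = per_species.copy()
    df["clade"] = df["species"].map(lambda s: attrs[s][0])
    df["life_form"] = df["species"].map(lambda s: attrs[s][1])
    df["genus"] = df["species"].map(lambda s: attrs[s][2])
    df["sg_class"] = df["species"].map(sg_class)

    rows = []

    def add(grouping: str, stratum: str, sub: pd.DataFrame) -> None:
        resolved, total, pct = _rate(sub)
        rows.append({
            "grouping": grouping, "stratum": str(stratum),
            "resolved": resolved, "total": total, "pct": pct,
        })

    add("overall", "all", df)
    for clade in ("angiosperm", "gymnosperm"):
        sub = df[df["clade"] == clade]
        if not sub.empty:
            add("clade", clade, sub)
    for lf in ("herbaceous", "woody"):
        sub = df[df["life_form"] == lf]
        if not sub.empty:
            add("life_form", lf, sub)
    for cls in range(1, 6):
        sub = df[df["sg_class"] == cls]
        if not sub.empty:
            add("sg_class", cls, sub)
    for genus in sorted(df["genus"].unique()):
        add("genus", genus, df[df["genus"] == genus])

    rates = pd.DataFrame(rows)
    herb = rates[(rates["grouping"] == "life_form") & (rates["stratum"] == "herbaceous")]
    woody = rates[(rates["grouping"] == "life_form") & (rates["stratum"] == "woody")]
    diffs = pd.DataFrame(columns=["combination", "herbaceous_pct", "woody_pct", "difference"])
    if not herb.empty and not woody.empty and herb["pct"].notna().all() and woody["pct"].notna().all():
        h, w = float(herb["pct"].iloc[0]), float(woody["pct"].iloc[0])
        diffs = pd.DataFrame([{
            "combination": combination,
            "herbaceous_pct": h,
            "woody_pct": w,
            "difference": round(h - w, 2),
        }])
    return ResolutionTable(combination, df, rates, diffs)


def combination_sweep(
    trees: Mapping[str, SupportTree],
    metadata: Sequence[SpecimenRecord],
    config: ResolutionConfig | None = None,
    combinations: Sequence[str] = COMBINATIONS,
) -> dict[str, ResolutionTable]:
    """Run the resolution criterion for every barcode combination with an
    available tree; missing combinations are skipped with a warning."""
    config = config or ResolutionConfig()
    out: dict[str, ResolutionTable] = {}
    for combo in combinations:
        if combo not in trees:
            logger.warning("no tree for combination %s; skipped", combo)
            continue
        per_species = resolve_species(trees[combo], metadata, config)
        out[combo] = aggregate(per_species, metadata, combination=combo)
    return out


def count_cells(
    tables: Mapping[str, ResolutionTable]
) -> pd.DataFrame:
    """Resolved/total counts per (barcode, species-per-genus class) — input
    for the Poisson GLM layer."""
    rows = []
    for combo, table in tables.items():
        for cls in range(1, 6):
            sel = table.rates[
                (table.rates["grouping"] == "sg_class") & (table.rates["stratum"] == str(cls))
            ]
            if sel.empty:
                continue
            rows.append({
                "barcode": combo,
                "sg_class": cls,
                "resolved": int(sel["resolved"].iloc[0]),
                "total": int(sel["total"].iloc[0]),
            })
    return pd.DataFrame(rows)


def threshold_sweep(
    tree: SupportTree,
    metadata: Sequence[SpecimenRecord],
    thresholds: Sequence[float],
    singleton_policy: str = "resolved",
) -> pd.DataFrame:
    """Overall resolution rate as a function of the support threshold."""
    rows = []
    for t in thresholds:
        cfg = ResolutionConfig(support_threshold=t, singleton_policy=singleton_policy)
        table = aggregate(resolve_species(tree, metadata, cfg), metadata)
        rows.append({"threshold": t, "pct": table.rate("overall", "all")})
    return pd.DataFrame(rows)
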