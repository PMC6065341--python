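"""Synthetic multilocus barcode communities.

Generates datasets with the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without any sequence download:

* a nested taxonomy (species in genera in families in orders) whose
  genus-size distribution, singleton fraction and per-species individual
  counts emulate a real forest-dynamics-plot collection;
* two ultrametric genealogies per replicate — one shared by the three
  plastid loci (rbcL, matK, trnH-psbA), reflecting chloroplast linkage,
  and an independent one for nuclear ITS — built from fixed divergence
  depth tiers (family > genus > species > within-species) rather than a
  parameterised coalescent;
* optional plastid-capture / nuclear haplotype-sharing events between
  congeneric species pairs, which collapse the pair onto one within-
  species clade of the affected genealogy and are recorded as per-species
  "expected resolvable" truth flags;
* Kimura two-parameter sequence evolution along the genealogy with a
  per-locus rate scalar and a branch-rate multiplier (< 1) on woody
  lineages, emulating the slower substitution rates of woody plants;
* per-locus recovery failure (a specimen yields a sequence with the
  locus's recovery probability).

All randomness flows from the single seed handed to each entry point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .phylo import Clade, SupportTree
from .seqio import SpecimenRecord, write_fasta, write_specimen_table

logger = logging.getLogger(__name__)

PLASTID_LOCI = ("rbcL", "matK", "trnH-psbA")
NUCLEAR_LOCI = ("ITS",)


@dataclass(frozen=True)
class CommunitySpec:
    """Structure of the simulated community.

    ``genus_size_distribution`` maps species-per-genus class (1..5) to the
    number of genera in that class; ``depth_params`` are divergence depths
    in expected substitutions per site at the base locus rate.
    """

    genus_size_distribution: dict[int, int]
    n_families: int = 64
    n_gymnosperm_families: int = 3
    individuals_min: int = 2
    individuals_max: int = 6
    individuals_geometric_ratio: float = 0.4
    singleton_fraction: float = 19 / 201
    woody_genus_prob: float = 0.36
    rate_multiplier_woody: float = 0.5
    depth_family: float = 0.30
    depth_genus: float = 0.10
    depth_species: float = 0.03
    depth_within: float = 0.003
    depth_jitter: float = 0.2

    def __post_init__(self) -> None:
        for cls, count in self.genus_size_distribution.items():
            if count < 0:
                raise ValueError(f"genus_size_distribution[{cls}] is negative ({count})")
            if cls < 1:
                raise ValueError(f"genus_size_distribution has class {cls} < 1")
        if not 0 < self.rate_multiplier_woody <= 1:
            raise ValueError("rate_multiplier_woody must be in (0, 1]")
        if not (self.depth_family > self.depth_genus > self.depth_species > self.depth_within > 0):
            raise ValueError("depths must satisfy family > genus > species > within-species > 0")
        if not 0 <= self.singleton_fraction <= 1:
            raise ValueError("singleton_fraction must be in [0, 1]")
        if not 1 <= self.individuals_min <= self.individuals_max:
            raise ValueError("need 1 <= individuals_min <= individuals_max")

    @property
    def n_species(self) -> int:
        return sum(cls * n for cls, n in self.genus_size_distribution.items())

    @property
    def n_genera(self) -> int:
        return sum(self.genus_size_distribution.values())

    @classmethod
    def plot_default(cls) -> "CommunitySpec":
        """Community shaped like a subalpine forest-dynamics-plot survey:
        201 species in 135 genera and 64 families (mean S/G 1.49), with
        ~19 singleton species and two-to-six individuals otherwise."""
        return cls(genus_size_distribution={1: 100, 2: 18, 3: 7, 4: 6, 5: 4})

    @classmethod
    def small(cls, n_singleton_genera: int = 38, n_pairs: int = 6) -> "CommunitySpec":
        """Desk-scale community (default 50 species) for fast end-to-end runs."""
        return cls(
            genus_size_distribution={1: n_singleton_genera, 2: n_pairs},
            n_families=16,
            n_gymnosperm_families=1,
            singleton_fraction=0.1,
        )


@dataclass(frozen=True)
class LocusModel:
    """Per-locus simulation model (K80 with transition/transversion ratio
    kappa, relative rate scalar, and sequence recovery probability)."""

    locus_name: str
    length: int
    kappa: float = 2.0
    rate_scalar: float = 1.0
    recovery_prob: float = 1.0
    plastid: bool = True

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("length must be > 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if not 0 <= self.recovery_prob <= 1:
            raise ValueError("recovery_prob must be in [0, 1]")


def default_locus_models(length_scale: float = 1.0) -> list[LocusModel]:
    """The four standard plant barcodes with recovery probabilities set to
    the sequencing-success rates typical of plot-scale surveys (rbcL
    0.9874, trnH-psbA and matK 0.9202, ITS 0.8950) and relative rates
    increasing from the conservative coding loci to the spacers."""
    def L(x: int) -> int:
        return max(10, int(round(x * length_scale)))

    return [
        LocusModel("rbcL", L(552), rate_scalar=1.0, recovery_prob=0.9874, plastid=True),
        LocusModel("matK", L(750), rate_scalar=1.5, recovery_prob=0.9202, plastid=True),
        LocusModel("trnH-psbA", L(450), rate_scalar=2.0, recovery_prob=0.9202, plastid=True),
        LocusModel("ITS", L(600), rate_scalar=2.5, recovery_prob=0.8950, plastid=False),
    ]


@dataclass(frozen=True)
class HybridizationSpec:
    """Probabilities that a congeneric species pair shares haplotypes:
    ``p_capture`` for the plastid genealogy (plastid capture following
    hybridization), ``p_nuclear_share`` for the nuclear genealogy."""

    p_capture: float = 0.0
    p_nuclear_share: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.p_capture <= 1 or not 0 <= self.p_nuclear_share <= 1:
            raise ValueError("capture/share probabilities must be in [0, 1]")


@dataclass
class SimulatedDataset:
    metadata: list[SpecimenRecord]
    sequences: dict[str, dict[str, str]]  # locus -> {specimen_id: seq}
    truth: "pd.DataFrame"
    plastid_tree: SupportTree
    nuclear_tree: SupportTree
    capture_events: list[tuple[str, str, str]]  # (genome, species_a, species_b)


# ---------------------------------------------------------------------------
# Taxonomy


def simulate_taxonomy(spec: CommunitySpec, seed: int) -> list[SpecimenRecord]:
    """Draw a nested taxonomy and per-species individual counts.

    Deterministic for a fixed seed.  Genera are assigned round-robin to
    families; the first ``n_gymnosperm_families`` families are gymnosperm
    (woody, monotypic genera only, matching how conifers enter a plot
    survey), the rest angiosperm.  Individual counts follow a truncated
    geometric on [individuals_min, individuals_max] except for a
    ``singleton_fraction`` of species sampled once.
    """
    rng = np.random.default_rng(seed)
    genera: list[int] = []  # species count per genus
    for cls in sorted(spec.genus_size_distribution):
        genera.extend([cls] * spec.genus_size_distribution[cls])
    if spec.n_gymnosperm_families > 0:
        # move some monotypic genera to the front for the gymnosperm families
        n_gymno_genera = min(2 * spec.n_gymnosperm_families, genera.count(1))
        ones = [i for i, g in enumerate(genera) if g == 1][:n_gymno_genera]
        rest = [g for i, g in enumerate(genera) if i not in ones]
        genera = [1] * n_gymno_genera + rest
    else:
        n_gymno_genera = 0

    n_angio_families = spec.n_families - spec.n_gymnosperm_families
    if n_angio_families < 1:
        raise ValueError("n_families must exceed n_gymnosperm_families")

    # truncated geometric weights for individuals per species
    ks = np.arange(spec.individuals_min, spec.individuals_max + 1)
    w = spec.individuals_geometric_ratio ** (ks - spec.individuals_min)
    w = w / w.sum()

    records: list[SpecimenRecord] = []
    species_counter = 0
    for gi, n_sp in enumerate(genera):
        gymno = gi < n_gymno_genera
        if gymno:
            family_i = gi % spec.n_gymnosperm_families
            family = f"GymFam{family_i + 1:02d}"
            order = f"GymOrder{family_i // 2 + 1:02d}"
            clade, life_form = "gymnosperm", "woody"
        else:
            family_i = (gi - n_gymno_genera) % n_angio_families
            family = f"Fam{family_i + 1:02d}"
            order = f"Order{family_i // 3 + 1:02d}"
            clade = "angiosperm"
            life_form = "woody" if rng.random() < spec.woody_genus_prob else "herbaceous"
        genus = f"Genus{gi + 1:03d}"
        for si in range(n_sp):
            species_counter += 1
            species = f"{genus} species{si + 1}"
            if rng.random() < spec.singleton_fraction:
                n_ind = 1
            else:
                n_ind = int(rng.choice(ks, p=w))
            for ii in range(n_ind):
                records.append(SpecimenRecord(
                    specimen_id=f"sp{species_counter:04d}_{ii + 1}",
                    species=species,
                    genus=genus,
                    family=family,
                    order=order,
                    life_form=life_form,
                    clade=clade,
                ))
    logger.info(
        "simulated taxonomy: %d specimens, %d species, %d genera",
        len(records), species_counter, len(genera),
    )
    return records


# ---------------------------------------------------------------------------
# Genealogies


def _jitter(rng: np.random.Generator, depth: float, frac: float) -> float:
    return depth * (1.0 + frac * (2.0 * rng.random() - 1.0))


def simulate_genealogies(
    taxonomy: Sequence[SpecimenRecord],
    spec: CommunitySpec,
    hyb: HybridizationSpec | None = None,
    seed: int = 0,
) -> tuple[SupportTree, SupportTree, list[tuple[str, str, str]], "pd.DataFrame"]:
    """Build the shared plastid genealogy and the independent nuclear
    genealogy over all specimens, with optional haplotype-sharing events.

    Both trees are ultrametric in time units: tips at time 0, splits at (jittered)
    family/genus/species depths, individuals coalescing at the within-
    species depth.  A capture event between congeneric species collapses
    the pair onto a single within-species clade of the affected genealogy,
    so their tips intermingle; the event is skipped (and logged) for
    genera with a single species.  Woody lineages have all branch lengths
    below the genus node scaled by ``rate_multiplier_woody``.

    Returns (plastid_tree, nuclear_tree, capture_events, truth) where
    truth holds per-species expected-resolvable flags per genome class.
    """
    import pandas as pd

    hyb = hyb or HybridizationSpec()
    rng = np.random.default_rng(seed)

    # organise taxonomy
    families: dict[str, dict[str, dict[str, list[str]]]] = {}
    species_meta: dict[str, SpecimenRecord] = {}
    for r in taxonomy:
        families.setdefault(r.family, {}).setdefault(r.genus, {}).setdefault(r.species, []).append(
            r.specimen_id
        )
        species_meta.setdefault(r.species, r)

    # choose sharing events per genome
    events: list[tuple[str, str, str]] = []
    shared_pairs = {"plastid": [], "nuclear": []}
    for genome, p in (("plastid", hyb.p_capture), ("nuclear", hyb.p_nuclear_share)):
        if p <= 0:
            continue
        for family in sorted(families):
            for genus in sorted(families[family]):
                spp = sorted(families[family][genus])
                if rng.random() >= p:
                    continue
                if len(spp) < 2:
                    logger.info(
                        "capture event requested in monotypic genus %s; skipped", genus
                    )
                    continue
                # haplotype sharing only disrupts the criterion for species
                # with >= 2 sampled individuals (singletons are trivially
                # exclusive whatever their haplotype)
                eligible = [s for s in spp if len(families[family][genus][s]) >= 2]
                if len(eligible) < 2:
                    logger.info(
                        "capture event in genus %s needs two multi-individual "
                        "species; skipped", genus,
                    )
                    continue
                pair = list(rng.choice(len(eligible), size=2, replace=False))
                a, b = eligible[pair[0]], eligible[pair[1]]
                shared_pairs[genome].append((a, b))
                events.append((genome, a, b))

    def build(genome: str, tree_seed: int) -> SupportTree:
        trng = np.random.default_rng(tree_seed)
        merged_into: dict[str, str] = {}
        for a, b in shared_pairs[genome]:
            merged_into[b] = a  # b's tips join a's within-species clade
        root = Clade()
        root_depth = 1.2 * spec.depth_family
        for family in sorted(families):
            fam_depth = _jitter(trng, spec.depth_family, spec.depth_jitter / 2)
            fam_node = Clade(length=None)
            for genus in sorted(families[family]):
                gen_depth = min(_jitter(trng, spec.depth_genus, spec.depth_jitter), fam_depth * 0.9)
                gen_node = Clade()
                woody = species_meta[sorted(families[family][genus])[0]].life_form == "woody"
                rate = spec.rate_multiplier_woody if woody else 1.0
                # group species tips, applying within-genus haplotype sharing:
                # each group is a host species plus any species captured into it
                groups: dict[str, list[tuple[str, list[str]]]] = {}
                for sp in sorted(families[family][genus]):
                    target = merged_into.get(sp, sp)
                    groups.setdefault(target, []).append((sp, families[family][genus][sp]))
                for gname in sorted(groups):
                    sp_depth = min(
                        _jitter(trng, spec.depth_species, spec.depth_jitter), gen_depth * 0.9
                    )
                    within = min(spec.depth_within, sp_depth * 0.5)
                    members = groups[gname]
                    if len(members) == 1:
                        tips = list(members[0][1])
                        trng.shuffle(tips)
                        clade, top = _star_clade(tips, within, rate)
                    else:
                        # captured species: its tips attach inside the host's
                        # clade, interleaved so neither species is exclusive
                        tip_lists = [list(t) for _sp, t in members]
                        for t in tip_lists:
                            trng.shuffle(t)
                        clade, top = _caterpillar_clade(tip_lists, within, sp_depth, rate)
                    clade.length = (gen_depth - top) * rate
                    gen_node.children.append(clade)
                gen_node.length = (fam_depth - gen_depth) * rate
                fam_node.children.append(gen_node)
            fam_node.length = root_depth - fam_depth
            root.children.append(fam_node)
        return SupportTree(_flatten_unaries(root))

    s1, s2 = rng.integers(0, 2**31 - 1, size=2)
    plastid_tree = build("plastid", int(s1))
    nuclear_tree = build("nuclear", int(s2))

    all_species = sorted(species_meta)
    unres = {g: set() for g in ("plastid", "nuclear")}
    for genome, a, b in events:
        unres[genome].update((a, b))
    truth = pd.DataFrame({
        "species": all_species,
        "resolvable_plastid": [s not in unres["plastid"] for s in all_species],
        "resolvable_nuclear": [s not in unres["nuclear"] for s in all_species],
    })
    return plastid_tree, nuclear_tree, events, truth


def _star_clade(tips: list[str], within: float, rate: float) -> tuple[Clade, float]:
    """A species clade: tips coalescing at the within-species depth.
    Returns the clade and the depth of its top node."""
    if len(tips) == 1:
        return Clade(name=tips[0]), 0.0
    node = Clade(children=[Clade(name=t, length=within * rate) for t in tips])
    return node, within


def _caterpillar_clade(
    tip_lists: list[list[str]], within: float, sp_depth: float, rate: float
) -> tuple[Clade, float]:
    """A shared-haplotype clade for a capture event: the member species'
    tips are interleaved along an ultrametric caterpillar, so no species'
    tips are separated by any single edge of the genealogy.  Coalescence
    depths spread from the within-species depth up toward the species
    depth — introgressed haplotype lineages diverged at intermediate
    times, which also gives tree inference real signal against either
    species' exclusivity."""
    order: list[str] = []
    i = 0
    lists = [list(t) for t in tip_lists]
    while any(lists):
        src = lists[i % len(lists)]
        if src:
            order.append(src.pop(0))
        i += 1
    m = len(order)
    if m == 1:
        return Clade(name=order[0]), 0.0
    top_depth = max(within, 0.8 * sp_depth)
    depths = list(np.linspace(within, top_depth, m - 1)) if m > 2 else [top_depth]
    node = Clade(children=[
        Clade(name=order[0], length=depths[0] * rate),
        Clade(name=order[1], length=depths[0] * rate),
    ])
    top = depths[0]
    for k in range(2, m):
        d = depths[k - 1]
        node = Clade(children=[
            Clade(name=order[k], length=d * rate),
            node,
        ])
        node.children[1].length = (d - top) * rate
        top = d
    return node, top


def _flatten_unaries(node: Clade) -> Clade:
    """Collapse single-child chains, summing branch lengths."""
    while len(node.children) == 1 and not node.is_leaf:
        child = node.children[0]
        if node.length is not None and child.length is not None:
            child.length += node.length
        elif node.length is not None:
            child.length = node.length
        node = child
    node.children = [_flatten_unaries(c) for c in node.children]
    return node


# ---------------------------------------------------------------------------
# Sequence evolution (K80)


def k80_expected_distance(t: float, kappa: float) -> float:
    """Closed-form expected K80 distance equals the branch length under the
    normalised rate matrix; exposed for Monte-Carlo checks."""
    return t


def _k80_step_probs(t: float, kappa: float) -> tuple[float, float, float]:
    """(stay, transition, each-transversion) probabilities after expected
    ``t`` substitutions/site under K80 with ts/tv rate ratio kappa."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    e1 = np.exp(-4.0 * t / (kappa + 2.0))
    e2 = np.exp(-2.0 * t * (kappa + 1.0) / (kappa + 2.0))
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # each of the two transversions
    return float(p_same), float(p_ts), float(p_tv)


def simulate_sequences(
    genealogy: SupportTree,
    model: LocusModel,
    seed: int,
) -> dict[str, str]:
    """Evolve one locus along the genealogy under K80 and apply recovery.

    Branch lengths are multiplied by ``model.rate_scalar``.  Each tip is
    retained with probability ``model.recovery_prob``.  Deterministic for
    a fixed seed.
    """
    rng = np.random.default_rng(seed)
    L = model.length
    alphabet = np.array(list("ACGT"))
    root_seq = rng.integers(0, 4, size=L, dtype=np.int8)
    out: dict[str, str] = {}

    def evolve(seq: np.ndarray, t: float) -> np.ndarray:
        if t <= 0:
            return seq.copy()
        p_same, p_ts, p_tv = _k80_step_probs(t * model.rate_scalar, model.kappa)
        u = rng.random(L)
        child = seq.copy()
        ts_mask = (u >= p_same) & (u < p_same + p_ts)
        tv1_mask = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)
        tv2_mask = u >= p_same + p_ts + p_tv
        child[ts_mask] ^= 2  # A<->G, C<->T
        child[tv1_mask] ^= 1  # purine<->pyrimidine
        child[tv2_mask] ^= 3  # the other transversion
        return child

    def walk(node: Clade, seq: np.ndarray) -> None:
        for child in node.children:
            cseq = evolve(seq, child.length or 0.0)
            if child.is_leaf:
                if rng.random() < model.recovery_prob:
                    out[child.name] = "".join(alphabet[cseq])
            else:
                walk(child, cseq)

    walk(genealogy.root, root_seq)
    return out


# ---------------------------------------------------------------------------
# Whole datasets


def simulate_dataset(
    spec: CommunitySpec,
    locus_models: Sequence[LocusModel] | None = None,
    hyb: HybridizationSpec | None = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Taxonomy + genealogies + per-locus sequences + truth flags, all
    derived from a single seed."""
    locus_models = list(locus_models) if locus_models is not None else default_locus_models()
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=2 + len(locus_models))
    taxonomy = simulate_taxonomy(spec, int(sub[0]))
    plastid_tree, nuclear_tree, events, truth = simulate_genealogies(
        taxonomy, spec, hyb, int(sub[1])
    )
    sequences: dict[str, dict[str, str]] = {}
    for i, model in enumerate(locus_models):
        tree = plastid_tree if model.plastid else nuclear_tree
        sequences[model.locus_name] = simulate_sequences(tree, model, int(sub[2 + i]))
    return SimulatedDataset(
        metadata=taxonomy,
        sequences=sequences,
        truth=truth,
        plastid_tree=plastid_tree,
        nuclear_tree=nuclear_tree,
        capture_events=events,
    )


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Write metadata TSV, per-locus FASTA, truth TSV and both genealogies."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_specimen_table(ds.metadata, outdir / "metadata.tsv")
    for locus, recs in ds.sequences.items():
        write_fasta(recs, outdir / f"{locus}.fasta")
    ds.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    ds.plastid_tree.write(outdir / "plastid_genealogy.nwk")
    ds.nuclear_tree.write(outdir / "nuclear_genealogy.nwk")
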