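"""End-to-end orchestration: simulate or load data, align per grouping
plan, build per-combination supermatrices and bootstrap trees, apply the
resolution criterion, and run the statistical layer, writing every stage
artifact plus a manifest for reproducibility checks."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import msa, phylo, resolution, seqio, simulate, stats

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for configuration problems detected before any compute."""


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": None,
    "loci": ["rbcL", "matK", "trnH-psbA", "ITS"],
    "combinations": list(seqio.COMBINATIONS),
    "simulate": None,  # or {"n_singleton_genera":..., "n_pairs":..., "length_scale":..., "p_capture":..., "p_nuclear_share":...}
    "inputs": None,  # or {"metadata": path, "fasta": {locus: path}}
    "alignment": {"grouping": {"rbcL": "global", "matK": "global", "trnH-psbA": "family", "ITS": "family"}, "overrides": {}},
    "tree": {"engine": "nj", "model": "K80", "bootstrap": 100, "import": {}},
    "resolution": {"support_threshold": 50.0, "singleton_policy": "resolved"},
    "stats": {"adjustment": "bonferroni", "family": "poisson"},
}


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: Mapping[str, Any]) -> dict[str, Any]:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, Mapping) and isinstance(cfg.get(key), Mapping):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def validate_config(cfg: Mapping[str, Any]) -> None:
    if cfg.get("simulate") is None and cfg.get("inputs") is None:
        raise ConfigError("config must provide either 'simulate' or 'inputs'")
    stochastic = cfg.get("simulate") is not None or (
        cfg.get("tree", {}).get("engine") == "nj" and cfg.get("tree", {}).get("bootstrap", 0) > 0
    )
    if stochastic and cfg.get("seed") is None:
        raise ConfigError("seed is mandatory when any stochastic stage is enabled")
    for combo in cfg.get("combinations", []):
        loci = seqio.combination_loci(combo)
        missing = [l for l in loci if l not in cfg["loci"]]
        if missing:
            raise ConfigError(f"combination {combo} needs loci not configured: {missing}")
    inputs = cfg.get("inputs")
    if inputs is not None:
        meta = Path(inputs["metadata"])
        if not meta.exists():
            raise ConfigError(f"metadata file not found: {meta}")
        for locus in cfg["loci"]:
            fasta = inputs.get("fasta", {}).get(locus)
            if fasta is None:
                raise ConfigError(f"no FASTA configured for locus {locus}")
            if not Path(fasta).exists():
                raise ConfigError(f"FASTA for {locus} not found: {fasta}")


@dataclass
class ResultBundle:
    outdir: Path
    metadata: list
    alignments: dict[str, seqio.LocusAlignment]
    supermatrices: dict[str, seqio.Supermatrix]
    trees: dict[str, phylo.SupportTree]
    tables: dict[str, resolution.ResolutionTable]
    count_cells: pd.DataFrame
    stats_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict[str, Any] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: Mapping[str, Any], outdir: str | Path) -> ResultBundle:
    """Run every stage per the validated config; idempotent for a fixed
    config and seed (byte-identical artifacts on re-run)."""
    validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg.get("seed")

    # --- stage: data ---------------------------------------------------
    if cfg.get("simulate") is not None:
        sim = dict(cfg["simulate"])
        if sim.get("genus_size_distribution"):
            dist = {int(k): int(v) for k, v in sim["genus_size_distribution"].items()}
            spec = simulate.CommunitySpec(
                genus_size_distribution=dist,
                n_families=int(sim.get("n_families", 16)),
                n_gymnosperm_families=int(sim.get("n_gymnosperm_families", 1)),
                singleton_fraction=float(sim.get("singleton_fraction", 0.1)),
            )
        else:
            spec = simulate.CommunitySpec.small(
                n_singleton_genera=int(sim.get("n_singleton_genera", 38)),
                n_pairs=int(sim.get("n_pairs", 6)),
            )
        hyb = simulate.HybridizationSpec(
            p_capture=float(sim.get("p_capture", 0.0)),
            p_nuclear_share=float(sim.get("p_nuclear_share", 0.0)),
        )
        models = [
            m for m in simulate.default_locus_models(float(sim.get("length_scale", 1.0)))
            if m.locus_name in cfg["loci"]
        ]
        if sim.get("recovery") is not None:
            from dataclasses import replace as _rep
            models = [_rep(m, recovery_prob=float(sim["recovery"])) for m in models]
        ds = simulate.simulate_dataset(spec, models, hyb, seed=int(seed))
        simdir = outdir / "simulated"
        simulate.write_dataset(ds, simdir)
        metadata = ds.metadata
        raw = ds.sequences
    else:
        metadata, _summary = seqio.read_specimen_table(cfg["inputs"]["metadata"])
        raw = {
            locus: seqio.read_fasta(cfg["inputs"]["fasta"][locus]) for locus in cfg["loci"]
        }
    logger.info("stage data: %d specimens, loci %s", len(metadata), list(raw))

    # --- stage: alignment ----------------------------------------------
    alignments: dict[str, seqio.LocusAlignment] = {}
    aln_dir = outdir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    grouping_cfg = cfg["alignment"]["grouping"]
    overrides = cfg["alignment"].get("overrides") or {}
    for locus, seqs in raw.items():
        plan = msa.plan_groups(
            metadata,
            locus,
            grouping_cfg.get(locus, "global"),
            overrides=overrides.get(locus),
            specimens_with_data=set(seqs),
        )
        grouped = msa.align_locus(seqs, plan)
        alignments[locus] = grouped.merged
        seqio.write_fasta(grouped.merged.rows, aln_dir / f"{locus}.aln.fasta")
    logger.info("stage align: widths %s", {l: a.width for l, a in alignments.items()})

    # --- stage: supermatrices + trees ----------------------------------
    trees: dict[str, phylo.SupportTree] = {}
    supermatrices: dict[str, seqio.Supermatrix] = {}
    tree_dir = outdir / "trees"
    tree_dir.mkdir(exist_ok=True)
    tree_cfg = cfg["tree"]
    for combo in cfg["combinations"]:
        sm = seqio.build_supermatrix(list(alignments.values()), combo)
        supermatrices[combo] = sm
        seqio.write_supermatrix(
            sm, outdir / f"supermatrix_{combo}.fasta", outdir / f"partitions_{combo}.txt"
        )
        imported = tree_cfg.get("import", {}).get(combo)
        if tree_cfg.get("engine") == "import" or imported:
            if not imported:
                raise ConfigError(f"engine=import but no tree path for {combo}")
            trees[combo] = phylo.import_tree(imported, metadata)
        else:
            pruned_rows, dropped = phylo.prune_undefined_rows(
                sm.rows, tree_cfg.get("model", "K80")
            )
            if dropped:
                logger.info(
                    "combination %s: dropped %d specimen(s) with no usable "
                    "overlap: %s", combo, len(dropped), ", ".join(dropped),
                )
                sm = seqio.Supermatrix(sm.combination, pruned_rows, sm.partitions)
                supermatrices[combo] = sm
            tree, report = phylo.bootstrap_tree(
                sm,
                model=tree_cfg.get("model", "K80"),
                n_replicates=int(tree_cfg.get("bootstrap", 100)),
                seed=_combo_seed(seed, combo),
            )
            if report.n_redrawn:
                logger.info("combination %s: %d bootstrap replicates redrawn", combo, report.n_redrawn)
            trees[combo] = tree
        trees[combo].write(tree_dir / f"{combo}.nwk")
    logger.info("stage tree: built %d trees", len(trees))

    # --- stage: resolution ----------------------------------------------
    res_cfg = resolution.ResolutionConfig(
        support_threshold=float(cfg["resolution"]["support_threshold"]),
        singleton_policy=cfg["resolution"]["singleton_policy"],
    )
    tables = resolution.combination_sweep(trees, metadata, res_cfg, cfg["combinations"])
    res_dir = outdir / "resolution"
    res_dir.mkdir(exist_ok=True)
    for combo, table in tables.items():
        table.rates.to_csv(res_dir / f"rates_{combo}.tsv", sep="\t", index=False)
        table.per_species.to_csv(res_dir / f"species_{combo}.tsv", sep="\t", index=False)
    cells = resolution.count_cells(tables)
    cells.to_csv(outdir / "count_cells.tsv", sep="\t", index=False)

    # --- stage: stats ----------------------------------------------------
    stats_tables: dict[str, pd.DataFrame] = {}
    family = cfg["stats"].get("family", "poisson")
    nonempty = cells[cells["total"] > 0] if not cells.empty else cells
    if not nonempty.empty and nonempty["sg_class"].nunique() > 1 and nonempty["barcode"].nunique() > 1:
        dev = stats.analysis_of_deviance(nonempty, family=family)
        stats_tables["deviance"] = pd.DataFrame([t.__dict__ for t in dev])
        stats_tables["contrasts"] = stats.contrasts_by_barcode(
            nonempty, adjustment=cfg["stats"].get("adjustment", "bonferroni"), family=family
        )
        for name, df in stats_tables.items():
            df.to_csv(outdir / f"stats_{name}.tsv", sep="\t", index=False)

    bundle = ResultBundle(
        outdir=outdir,
        metadata=metadata,
        alignments=alignments,
        supermatrices=supermatrices,
        trees=trees,
        tables=tables,
        count_cells=cells,
        stats_tables=stats_tables,
    )
    report_tables(bundle)

    # --- manifest --------------------------------------------------------
    files = sorted(p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    bundle.manifest = manifest
    return bundle


def _combo_seed(seed: int | None, combo: str) -> int | None:
    if seed is None:
        return None
    h = hashlib.sha256(f"{seed}:{combo}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def report_tables(bundle: ResultBundle) -> dict[str, pd.DataFrame]:
    """Summary grids: combination x species-per-genus class, combination x
    life form, combination x {species, genus} rates.  Absent strata render
    as missing values, never as 0."""
    combos = list(bundle.tables)
    grids: dict[str, pd.DataFrame] = {}

    def grid(grouping: str, strata: Sequence[str]) -> pd.DataFrame:
        data = {}
        for s in strata:
            data[s] = [bundle.tables[c].rate(grouping, s) for c in combos]
        return pd.DataFrame(data, index=combos)

    grids["by_sg_class"] = grid("sg_class", [str(i) for i in range(1, 6)])
    grids["by_life_form"] = grid("life_form", ["herbaceous", "woody"])
    grids["by_clade"] = grid("clade", ["angiosperm", "gymnosperm"])
    overall = pd.DataFrame(
        {"species_pct": [bundle.tables[c].rate("overall", "all") for c in combos]},
        index=combos,
    )
    grids["overall"] = overall
    for name, df in grids.items():
        df.to_csv(bundle.outdir / f"report_{name}.tsv", sep="\t")
    return grids
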