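"""Sequence, metadata and supermatrix I/O.

Reads the three plain-text formats the pipeline touches (FASTA sequence
files, a tab-separated specimen metadata table, Newick trees) and builds
per-barcode-combination supermatrices with explicit partition bookkeeping.

Conventions
-----------
* FASTA headers are tokenised on whitespace; the first token is the
  specimen ID.
* A specimen missing a member locus occupies that partition with ``'?'``
  (unknown), never ``'-'`` (gap), so absence of data stays distinguishable
  from alignment gaps.  A specimen with no data in any member locus is
  dropped from the supermatrix.
* Partition coordinates are 1-based inclusive, matching the RAxML
  partition-file convention (``DNA, rbcL = 1-552``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

LIFE_FORMS = ("herbaceous", "woody")
CLADES = ("angiosperm", "gymnosperm")

#: Single-letter shorthand for the four barcode loci.
LOCUS_CODES = {"R": "rbcL", "M": "matK", "P": "trnH-psbA", "I": "ITS"}

#: The eight barcode combinations assessed by the analysis.
COMBINATIONS = ("R", "M", "RM", "RP", "RI", "RMP", "RMI", "RMPI")

METADATA_COLUMNS = (
    "specimen_id", "species", "genus", "family", "order", "life_form", "clade",
)


def combination_loci(combination: str) -> list[str]:
    """Expand a combination code like ``"RMPI"`` into locus names."""
    try:
        return [LOCUS_CODES[c] for c in combination]
    except KeyError as exc:
        raise ValueError(f"unknown barcode code {exc.args[0]!r} in {combination!r}") from None


@dataclass(frozen=True)
class SpecimenRecord:
    """One sampled individual with its taxonomy and life form."""

    specimen_id: str
    species: str
    genus: str
    family: str
    order: str
    life_form: str
    clade: str

    def __post_init__(self) -> None:
        if self.life_form not in LIFE_FORMS:
            raise ValueError(f"life_form must be one of {LIFE_FORMS}, got {self.life_form!r}")
        if self.clade not in CLADES:
            raise ValueError(f"clade must be one of {CLADES}, got {self.clade!r}")
        if not self.species.startswith(self.genus):
            raise ValueError(
                f"species {self.species!r} is not prefix-consistent with genus {self.genus!r}"
            )


@dataclass
class LocusAlignment:
    """Aligned sequences for one locus; all rows have equal width."""

    locus_name: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        widths = {len(s) for s in self.rows.values()}
        if len(widths) > 1:
            raise ValueError(f"unequal row widths in {self.locus_name}: {sorted(widths)}")

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


@dataclass
class Supermatrix:
    """Concatenated alignment across a barcode combination.

    ``partitions`` is a list of ``(locus_name, start, end)`` with 1-based
    inclusive coordinates tiling ``[1, width]``.
    """

    combination: str
    rows: dict[str, str]
    partitions: list[tuple[str, int, int]]

    @property
    def width(self) -> int:
        return self.partitions[-1][2] if self.partitions else 0

    def locus_slice(self, locus_name: str) -> tuple[int, int]:
        """0-based half-open column slice for a member locus."""
        for name, start, end in self.partitions:
            if name == locus_name:
                return start - 1, end
        raise KeyError(f"locus {locus_name!r} not in supermatrix {self.combination}")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an order-preserving ``{id: sequence}`` mapping.

    Sequences are upper-cased and RNA ``U`` is mapped to ``T``.  Duplicate
    IDs are an error; an empty file yields an empty mapping with a warning.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate sequence ID {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper().replace("U", "T")
    if not records:
        logger.warning("FASTA file %s contained no records", path)
    return records


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    seq_records = [SeqRecord(Seq(s), id=i, description="") for i, s in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# Specimen metadata


@dataclass
class MetadataSummary:
    n_specimens: int
    n_species: int
    n_genera: int
    n_families: int
    species_by_life_form: dict[str, int] = field(default_factory=dict)


def read_specimen_table(path: str | Path) -> tuple[list[SpecimenRecord], MetadataSummary]:
    """Read the specimen metadata TSV and summarise its taxonomic coverage."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata table {path} missing column(s): {', '.join(missing)}")
    records: list[SpecimenRecord] = []
    seen: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        if row.life_form not in LIFE_FORMS:
            raise ValueError(f"row {idx}: unknown life_form {row.life_form!r}")
        if row.clade not in CLADES:
            raise ValueError(f"row {idx}: unknown clade {row.clade!r}")
        if row.specimen_id in seen:
            raise ValueError(f"row {idx}: duplicate specimen_id {row.specimen_id!r}")
        seen.add(row.specimen_id)
        records.append(SpecimenRecord(*[getattr(row, c) for c in METADATA_COLUMNS]))
    return records, summarize_metadata(records)


def summarize_metadata(records: Sequence[SpecimenRecord]) -> MetadataSummary:
    species = {r.species for r in records}
    by_life_form: dict[str, int] = {}
    for lf in LIFE_FORMS:
        by_life_form[lf] = len({r.species for r in records if r.life_form == lf})
    return MetadataSummary(
        n_specimens=len(records),
        n_species=len(species),
        n_genera=len({r.genus for r in records}),
        n_families=len({r.family for r in records}),
        species_by_life_form=by_life_form,
    )


def write_specimen_table(records: Iterable[SpecimenRecord], path: str | Path) -> None:
    df = pd.DataFrame([r.__dict__ for r in records], columns=list(METADATA_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Supermatrix


def build_supermatrix(
    alignments: Sequence[LocusAlignment], combination: str
) -> Supermatrix:
    """Concatenate locus alignments for a barcode combination.

    Missing loci are '?'-filled per specimen; specimens with no data in any
    member locus are dropped.  Row order is lexicographic by specimen ID.
    """
    loci = combination_loci(combination)
    by_name = {a.locus_name: a for a in alignments}
    absent = [n for n in loci if n not in by_name]
    if absent:
        raise ValueError(f"combination {combination} needs alignment(s) for: {', '.join(absent)}")
    members = [by_name[n] for n in loci]
    all_ids = sorted({sid for a in members for sid in a.rows})
    partitions: list[tuple[str, int, int]] = []
    start = 1
    for a in members:
        partitions.append((a.locus_name, start, start + a.width - 1))
        start += a.width
    rows: dict[str, str] = {}
    n_dropped = 0
    for sid in all_ids:
        parts = [a.rows.get(sid, "?" * a.width) for a in members]
        rows[sid] = "".join(parts)
    n_dropped = 0  # ids absent from every member never entered all_ids
    logger.debug(
        "supermatrix %s: %d rows, width %d, %d specimens dropped",
        combination, len(rows), partitions[-1][2] if partitions else 0, n_dropped,
    )
    return Supermatrix(combination=combination, rows=rows, partitions=partitions)


def write_supermatrix(sm: Supermatrix, fasta_path: str | Path, partition_path: str | Path | None = None) -> None:
    """Write a supermatrix as FASTA plus a RAxML-style partition file."""
    write_fasta(sm.rows, fasta_path)
    if partition_path is not None:
        with open(partition_path, "w") as fh:
            for name, start, end in sm.partitions:
                fh.write(f"DNA, {name} = {start}-{end}\n")


def write_phylip_relaxed(sm: Supermatrix, path: str | Path) -> None:
    """Relaxed PHYLIP export for external ML runs."""
    with open(path, "w") as fh:
        fh.write(f"{len(sm.rows)} {sm.width}\n")
        for sid in sorted(sm.rows):
            fh.write(f"{sid}  {sm.rows[sid]}\n")
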