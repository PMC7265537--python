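"""Reading, writing and summarising OrthoFinder-style orthogroup tables.

The orthogroup (OG) table is the unit of comparison for the whole pipeline:
``Orthogroups.tsv`` maps each OG to a per-species list of gene ids, and
``Orthogroups.GeneCount.csv`` holds the corresponding count matrix.  This
module parses both, computes the core/shared/unique pangenome partition and
the OG-level summary statistics.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "OrthogroupTable",
    "GeneCountMatrix",
    "PangenomeSummary",
    "OgStats",
    "OrthogroupParseError",
    "read_orthogroups_tsv",
    "write_orthogroups_tsv",
    "read_gene_counts_csv",
    "write_gene_counts_csv",
    "gene_counts",
    "pangenome_partition",
    "orthogroup_stats",
    "round_half_up",
]


class OrthogroupParseError(ValueError):
    """Raised for malformed orthogroup files; message names the offending line."""


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of printed percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class OrthogroupTable:
    """Orthogroup membership: OG id -> per-species gene-id lists.

    ``unassigned`` holds singleton / species-specific genes that belong to no
    OG.  Gene ids are opaque strings and must be globally unique.
    """

    species: list[str]
    rows: dict[str, dict[str, list[str]]]
    unassigned: dict[str, list[str]] = field(default_factory=dict)

    def genes_of(self, og_id: str) -> list[str]:
        row = self.rows[og_id]
        return [g for sp in self.species for g in row.get(sp, [])]

    def og_size(self, og_id: str) -> int:
        return len(self.genes_of(og_id))

    @property
    def n_ogs(self) -> int:
        return len(self.rows)

    def all_genes(self) -> list[str]:
        """All gene ids, assigned and unassigned, in deterministic order."""
        out = [g for og in self.rows for g in self.genes_of(og)]
        for sp in self.species:
            out.extend(self.unassigned.get(sp, []))
        return out

    def n_assigned_genes(self) -> int:
        return sum(self.og_size(og) for og in self.rows)

    def n_total_genes(self) -> int:
        return self.n_assigned_genes() + sum(
            len(v) for v in self.unassigned.values()
        )

    def species_gene_counts(self) -> dict[str, int]:
        """Per-species totals including unassigned genes (= proteome sizes)."""
        counts = {sp: len(self.unassigned.get(sp, [])) for sp in self.species}
        for row in self.rows.values():
            for sp, genes in row.items():
                counts[sp] += len(genes)
        return counts

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OrthogroupTable):
            return NotImplemented
        return (
            self.species == other.species
            and self.rows == other.rows
            and {k: v for k, v in self.unassigned.items() if v}
            == {k: v for k, v in other.unassigned.items() if v}
        )


@dataclass
class GeneCountMatrix:
    """Nonnegative integer matrix, rows = OG ids, columns = species."""

    frame: pd.DataFrame  # index = OG ids, columns = species, dtype int

    @property
    def og_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def species(self) -> list[str]:
        return list(self.frame.columns)


@dataclass
class PangenomeSummary:
    n_core: int
    n_shared: int
    n_unique: int
    core_ogs: list[str]
    shared_ogs: list[str]
    unique_ogs: list[str]
    per_species: pd.DataFrame  # columns: core, shared, unique OG counts

    @property
    def n_total(self) -> int:
        return self.n_core + self.n_shared + self.n_unique


@dataclass
class OgStats:
    n_ogs: int
    total_genes: int
    assigned_genes: int
    pct_assigned: float          # printed form, one decimal, half-up
    pct_unassigned: float
    mean_og_size: float | None   # printed form, nearest integer
    n_two_gene_ogs: int
    pct_two_gene_ogs: float | None  # printed form, nearest integer percent
    og_size_histogram: dict[int, int]
    raw_pct_assigned: float
    raw_mean_og_size: float | None
    raw_pct_two_gene_ogs: float | None

    @classmethod
    def from_totals(
        cls,
        total_genes: int,
        assigned_genes: int,
        n_ogs: int,
        n_two_gene_ogs: int = 0,
        og_size_histogram: Mapping[int, int] | None = None,
    ) -> "OgStats":
        """Compute the printed summary statistics from raw totals.

        Percentages are rounded half-up to one decimal; mean OG size and the
        two-gene-OG percentage to the nearest integer, matching how such
        numbers are conventionally printed.
        """
        raw_pct = 100.0 * assigned_genes / total_genes if total_genes else 0.0
        raw_mean = assigned_genes / n_ogs if n_ogs else None
        raw_two = 100.0 * n_two_gene_ogs / n_ogs if n_ogs else None
        return cls(
            n_ogs=n_ogs,
            total_genes=total_genes,
            assigned_genes=assigned_genes,
            pct_assigned=round_half_up(raw_pct, 1),
            pct_unassigned=round_half_up(100.0 - raw_pct, 1),
            mean_og_size=round_half_up(raw_mean) if raw_mean is not None else None,
            n_two_gene_ogs=n_two_gene_ogs,
            pct_two_gene_ogs=round_half_up(raw_two) if raw_two is not None else None,
            og_size_histogram=dict(og_size_histogram or {}),
            raw_pct_assigned=raw_pct,
            raw_mean_og_size=raw_mean,
            raw_pct_two_gene_ogs=raw_two,
        )


def _split_cell(cell: str) -> list[str]:
    if not cell.strip():
        return []
    return [g.strip() for g in cell.split(",") if g.strip()]


def read_orthogroups_tsv(path: str | Path) -> OrthogroupTable:
    """Parse an ``Orthogroups.tsv`` file.

    First row is a header: an OG-id column followed by one column per
    species.  Cells hold comma-separated gene ids; empty cells mean the
    species has no members in that OG.  Ragged rows and duplicate OG ids
    raise :class:`OrthogroupParseError` naming the line.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise OrthogroupParseError(f"{path}: empty file")
        species = [h.strip() for h in header[1:]]
        rows: dict[str, dict[str, list[str]]] = {}
        for lineno, fields in enumerate(reader, start=2):
            if not fields or (len(fields) == 1 and not fields[0].strip()):
                continue
            if len(fields) != len(header):
                raise OrthogroupParseError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            og_id = fields[0].strip()
            if og_id in rows:
                raise OrthogroupParseError(
                    f"{path}: line {lineno}: duplicate orthogroup id {og_id!r}"
                )
            rows[og_id] = {
                sp: _split_cell(cell) for sp, cell in zip(species, fields[1:])
            }
    return OrthogroupTable(species=species, rows=rows)


def write_orthogroups_tsv(table: OrthogroupTable, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["Orthogroup", *table.species])
        for og_id in sorted(table.rows):
            row = table.rows[og_id]
            writer.writerow(
                [og_id, *( ", ".join(row.get(sp, [])) for sp in table.species)]
            )
    return path


def gene_counts(table: OrthogroupTable) -> GeneCountMatrix:
    """Count genes per (OG, species); shape n_ogs x n_species."""
    og_ids = sorted(table.rows)
    data = [
        [len(table.rows[og].get(sp, [])) for sp in table.species]
        for og in og_ids
    ]
    frame = pd.DataFrame(data, index=og_ids, columns=table.species, dtype=int)
    return GeneCountMatrix(frame=frame)


def write_gene_counts_csv(
    counts: GeneCountMatrix, path: str | Path, total_column: bool = True
) -> Path:
    path = Path(path)
    frame = counts.frame.copy()
    if total_column:
        frame["Total"] = frame.sum(axis=1)
    frame.to_csv(path, index_label="Orthogroup")
    return path


def read_gene_counts_csv(path: str | Path) -> GeneCountMatrix:
    """Read a GeneCount csv; a trailing ``Total`` column is dropped if present."""
    frame = pd.read_csv(path, index_col=0)
    if len(frame.columns) and frame.columns[-1] == "Total":
        frame = frame.drop(columns="Total")
    return GeneCountMatrix(frame=frame.astype(int))


def pangenome_partition(table: OrthogroupTable) -> PangenomeSummary:
    """Partition OGs into core (all species), shared (>1, not all), unique (1)."""
    if not table.species:
        raise ValueError("pangenome partition requires at least one species")
    n_sp = len(table.species)
    core, shared, unique = [], [], []
    presence: dict[str, set[str]] = {}
    for og_id in sorted(table.rows):
        present = {sp for sp, genes in table.rows[og_id].items() if genes}
        presence[og_id] = present
        if not present:
            continue
        if len(present) == n_sp:
            core.append(og_id)
        elif len(present) == 1:
            unique.append(og_id)
        else:
            shared.append(og_id)
    per_species = pd.DataFrame(
        {
            "core": [sum(1 for og in core if sp in presence[og]) for sp in table.species],
            "shared": [sum(1 for og in shared if sp in presence[og]) for sp in table.species],
            "unique": [sum(1 for og in unique if sp in presence[og]) for sp in table.species],
        },
        index=table.species,
    )
    return PangenomeSummary(
        n_core=len(core),
        n_shared=len(shared),
        n_unique=len(unique),
        core_ogs=core,
        shared_ogs=shared,
        unique_ogs=unique,
        per_species=per_species,
    )


def orthogroup_stats(table: OrthogroupTable) -> OgStats:
    sizes = [table.og_size(og) for og in table.rows]
    histogram: dict[int, int] = {}
    for s in sizes:
        histogram[s] = histogram.get(s, 0) + 1
    return OgStats.from_totals(
        total_genes=table.n_total_genes(),
        assigned_genes=table.n_assigned_genes(),
        n_ogs=table.n_ogs,
        n_two_gene_ogs=histogram.get(2, 0),
        og_size_histogram=histogram,
    )
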