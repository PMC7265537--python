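"""Two-step KO annotation: per-gene assignments plus orthogroup consensus.

Step one (M1) loads direct gene -> K-number maps, one TSV per species.
Step two (M2) propagates the modal K number of each orthogroup to its
unannotated members; direct annotations are never overwritten, so the
effective annotation set is a superset of the direct one.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .orthogroup_io import OrthogroupTable, round_half_up

__all__ = [
    "AnnotationMap",
    "EfficiencyReport",
    "AnnotationConflictError",
    "KoParseError",
    "load_gene_ko_tsv",
    "propagate_ko",
    "efficiency",
    "category_counts",
]

_K_RE = re.compile(r"^K\d{5}$")

DIRECT = "direct"
PROPAGATED = "propagated"


class KoParseError(ValueError):
    pass


class AnnotationConflictError(ValueError):
    pass


@dataclass
class AnnotationMap:
    """Gene-level K assignments with provenance.

    ``direct`` holds first-round assignments; ``og_consensus`` the modal K per
    OG (absent when the OG has no annotated member); ``effective`` maps every
    annotated gene to ``(K, provenance)`` where provenance is ``direct`` or
    ``propagated``.
    """

    direct: dict[str, str] = field(default_factory=dict)
    og_consensus: dict[str, str] = field(default_factory=dict)
    effective: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.effective and self.direct:
            self.effective = {g: (k, DIRECT) for g, k in self.direct.items()}

    def effective_k(self, gene: str) -> str | None:
        entry = self.effective.get(gene)
        return entry[0] if entry else None

    @property
    def n_direct(self) -> int:
        return len(self.direct)

    @property
    def n_effective(self) -> int:
        return len(self.effective)


def load_gene_ko_tsv(paths: Iterable[str | Path]) -> AnnotationMap:
    """Load per-species two-column TSVs (gene id, K number) into one map.

    K numbers must match ``K`` + five digits. Duplicate rows with identical K
    are deduplicated; conflicting duplicates raise
    :class:`AnnotationConflictError`.
    """
    direct: dict[str, str] = {}
    for path in paths:
        path = Path(path)
        with path.open(newline="") as fh:
            for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
                if not row or (len(row) == 1 and not row[0].strip()):
                    continue
                if len(row) < 2:
                    raise KoParseError(
                        f"{path}: line {lineno}: expected 2 columns, got {len(row)}"
                    )
                gene, k = row[0].strip(), row[1].strip()
                if not _K_RE.match(k):
                    raise KoParseError(
                        f"{path}: line {lineno}: malformed K number {k!r}"
                    )
                if gene in direct and direct[gene] != k:
                    raise AnnotationConflictError(
                        f"{path}: line {lineno}: gene {gene!r} maps to both "
                        f"{direct[gene]} and {k}"
                    )
                direct[gene] = k
    return AnnotationMap(direct=direct)


def _modal_k(ks: Iterable[str]) -> str | None:
    counts = Counter(ks)
    if not counts:
        return None
    best = max(counts.values())
    # deterministic tie-break: lexicographically smallest K among the modes
    return min(k for k, c in counts.items() if c == best)


def propagate_ko(
    table: OrthogroupTable,
    annotation: AnnotationMap,
    level: str = "gene",
) -> AnnotationMap:
    """Fill annotation gaps with each OG's consensus (modal) K number.

    ``level="gene"`` counts every directly annotated gene when taking the
    mode; ``level="species"`` counts each (species, K) combination once.
    Direct annotations are preserved; only unannotated genes of an OG with at
    least one direct annotation receive the consensus, flagged ``propagated``.
    Unassigned genes are untouched. Idempotent.
    """
    if level not in ("gene", "species"):
        raise ValueError(f"unknown consensus level {level!r}")
    direct = annotation.direct
    consensus: dict[str, str] = {}
    effective: dict[str, tuple[str, str]] = {g: (k, DIRECT) for g, k in direct.items()}
    for og_id in sorted(table.rows):
        row = table.rows[og_id]
        if level == "gene":
            ks = [direct[g] for sp in table.species for g in row.get(sp, []) if g in direct]
        else:
            ks = []
            for sp in table.species:
                sp_ks = {direct[g] for g in row.get(sp, []) if g in direct}
                ks.extend(sorted(sp_ks))
        k = _modal_k(ks)
        if k is None:
            continue
        consensus[og_id] = k
        for sp in table.species:
            for g in row.get(sp, []):
                if g not in effective:
                    effective[g] = (k, PROPAGATED)
    return AnnotationMap(direct=dict(direct), og_consensus=consensus, effective=effective)


@dataclass
class EfficiencyReport:
    n_genes: int
    n_direct: int
    n_effective: int
    efficiency_direct: float    # percent of all genes with a direct K
    efficiency_effective: float  # percent with any effective K

    def as_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "n_direct": self.n_direct,
            "n_effective": self.n_effective,
            "efficiency_direct": self.efficiency_direct,
            "efficiency_effective": self.efficiency_effective,
        }


def efficiency(
    direct: AnnotationMap, propagated: AnnotationMap, table: OrthogroupTable
) -> EfficiencyReport:
    """Mapping efficiency before (M1) and after (M2) consensus propagation.

    Denominator is every gene in the analysis, assigned to an OG or not.
    """
    genes = table.all_genes()
    n = len(genes)
    n_direct = sum(1 for g in genes if g in direct.direct)
    n_eff = sum(1 for g in genes if g in propagated.effective)
    return EfficiencyReport(
        n_genes=n,
        n_direct=n_direct,
        n_effective=n_eff,
        efficiency_direct=round_half_up(100.0 * n_direct / n, 1) if n else 0.0,
        efficiency_effective=round_half_up(100.0 * n_eff / n, 1) if n else 0.0,
    )


def category_counts(
    annotation: AnnotationMap,
    table: OrthogroupTable,
    ko_to_pathways: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Per-species, per-pathway counts of effectively annotated genes.

    A K number belonging to several pathways contributes once to each; K
    numbers absent from the map are tallied under ``unmapped``.
    """
    gene_species: dict[str, str] = {}
    for og_id, row in table.rows.items():
        for sp, genes in row.items():
            for g in genes:
                gene_species[g] = sp
    for sp, genes in table.unassigned.items():
        for g in genes:
            gene_species[g] = sp

    counts: dict[str, Counter] = {sp: Counter() for sp in table.species}
    categories: set[str] = set()
    for gene, (k, _prov) in annotation.effective.items():
        sp = gene_species.get(gene)
        if sp is None:
            continue
        paths = list(ko_to_pathways.get(k, [])) or ["unmapped"]
        for cat in paths:
            counts[sp][cat] += 1
            categories.add(cat)
    cols = sorted(categories)
    frame = pd.DataFrame(
        [[counts[sp].get(cat, 0) for cat in cols] for sp in table.species],
        index=table.species,
        columns=cols,
        dtype=int,
    )
    return frame
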