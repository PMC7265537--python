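"""Compound-level metabolic networks from K numbers via ko -> rn -> cpd maps.

Each annotated gene contributes, for every reaction of its K number, the
complete set of unordered compound pairs of that reaction; edge weights count
gene-backed reactions so paralog abundance is reflected in edge width.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "KoReactionCompoundMap",
    "MetabolicNetwork",
    "build_network",
    "node_abundance_vector",
    "edge_abundance_vector",
    "export_edge_list",
    "read_edge_list",
    "read_ko_map",
    "write_ko_map",
]


@dataclass
class KoReactionCompoundMap:
    """KEGG-style mapping: K number -> reactions -> participating compounds."""

    ko_to_rn: dict[str, frozenset[str]]
    rn_to_cpds: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        missing = {
            rn for rns in self.ko_to_rn.values() for rn in rns
        } - set(self.rn_to_cpds)
        if missing:
            raise ValueError(
                f"reactions referenced but not defined: {sorted(missing)[:5]}"
            )
        empty = [rn for rn, cpds in self.rn_to_cpds.items() if not cpds]
        if empty:
            raise ValueError(f"reactions with no compounds: {empty[:5]}")


@dataclass
class MetabolicNetwork:
    """Weighted undirected graph on compound nodes for one species."""

    species: str
    nodes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], int] = field(default_factory=dict)  # sorted pair
    unmapped_k: dict[str, int] = field(default_factory=dict)

    def node_abundance(self, cpd: str) -> int:
        return sum(w for (a, b), w in self.edges.items() if cpd in (a, b))

    def node_abundances(self) -> dict[str, int]:
        out = {c: 0 for c in self.nodes}
        for (a, b), w in self.edges.items():
            out[a] += w
            out[b] += w
        return out

    @property
    def total_edge_weight(self) -> int:
        return sum(self.edges.values())


def build_network(
    species: str,
    k_numbers: Iterable[str],
    ko_map: KoReactionCompoundMap,
) -> MetabolicNetwork:
    """Expand a (multiset) K-number list into a weighted compound graph.

    Per gene, per reaction: every unordered compound pair gets weight +1;
    single-compound reactions add an isolated node. K numbers absent from the
    map are tallied in ``unmapped_k`` rather than raising.
    """
    net = MetabolicNetwork(species=species)
    for k in k_numbers:
        rns = ko_map.ko_to_rn.get(k)
        if rns is None:
            net.unmapped_k[k] = net.unmapped_k.get(k, 0) + 1
            continue
        for rn in sorted(rns):
            cpds = sorted(ko_map.rn_to_cpds[rn])
            net.nodes.update(cpds)
            for a, b in combinations(cpds, 2):
                net.edges[(a, b)] = net.edges.get((a, b), 0) + 1
    return net


def node_abundance_vector(
    network: MetabolicNetwork, cpd_universe: Sequence[str]
) -> np.ndarray:
    """Node-abundance vector over a fixed compound ordering (zero outside)."""
    missing = network.nodes - set(cpd_universe)
    if missing:
        raise ValueError(
            f"universe missing network nodes: {sorted(missing)[:5]}"
        )
    ab = network.node_abundances()
    return np.array([ab.get(c, 0) for c in cpd_universe], dtype=float)


def edge_abundance_vector(
    network: MetabolicNetwork, edge_universe: Sequence[tuple[str, str]]
) -> np.ndarray:
    """Edge-weight vector over a fixed unordered-pair ordering (option)."""
    missing = set(network.edges) - set(edge_universe)
    if missing:
        raise ValueError(f"universe missing network edges: {sorted(missing)[:5]}")
    return np.array([network.edges.get(e, 0) for e in edge_universe], dtype=float)


def export_edge_list(network: MetabolicNetwork, path: str | Path) -> Path:
    """Write a TSV edge list (source, target, weight), sorted by pair."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["source", "target", "weight"])
        for (a, b) in sorted(network.edges):
            writer.writerow([a, b, network.edges[(a, b)]])
        for node in sorted(network.nodes - {c for e in network.edges for c in e}):
            writer.writerow([node, "", 0])  # isolated single-compound reaction
    return path


def read_edge_list(path: str | Path, species: str = "") -> MetabolicNetwork:
    net = MetabolicNetwork(species=species)
    with Path(path).open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)  # header
        for row in reader:
            a, b, w = row[0], row[1], int(row[2])
            if not b:
                net.nodes.add(a)
                continue
            net.nodes.update((a, b))
            key = (a, b) if a <= b else (b, a)
            net.edges[key] = net.edges.get(key, 0) + w
    return net


def write_ko_map(ko_map: KoReactionCompoundMap, directory: str | Path) -> tuple[Path, Path]:
    """Write ``ko2rn.tsv`` and ``rn2cpd.tsv`` (one pair per line)."""
    directory = Path(directory)
    ko2rn = directory / "ko2rn.tsv"
    rn2cpd = directory / "rn2cpd.tsv"
    with ko2rn.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for k in sorted(ko_map.ko_to_rn):
            for rn in sorted(ko_map.ko_to_rn[k]):
                w.writerow([k, rn])
    with rn2cpd.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for rn in sorted(ko_map.rn_to_cpds):
            for cpd in sorted(ko_map.rn_to_cpds[rn]):
                w.writerow([rn, cpd])
    return ko2rn, rn2cpd


def read_ko_map(ko2rn_path: str | Path, rn2cpd_path: str | Path) -> KoReactionCompoundMap:
    ko_to_rn: dict[str, set[str]] = {}
    rn_to_cpds: dict[str, set[str]] = {}
    with Path(ko2rn_path).open(newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if row:
                ko_to_rn.setdefault(row[0], set()).add(row[1])
    with Path(rn2cpd_path).open(newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if row:
                rn_to_cpds.setdefault(row[0], set()).add(row[1])
    return KoReactionCompoundMap(
        ko_to_rn={k: frozenset(v) for k, v in ko_to_rn.items()},
        rn_to_cpds={k: frozenset(v) for k, v in rn_to_cpds.items()},
    )
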