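"""Synthetic genome-reduction fixtures: tree, gene content, annotation, ko map.

Generates everything the downstream analysis consumes, with the statistical
structure it assumes: a rooted binary species tree; category-structured gene
content where designated reduced ("PPE") lineages lose soluble-pathway genes
at an elevated rate and informational-gene loss accelerates as a lineage's
proteome shrinks; partial direct KO annotation; and a consistent
ko -> reaction -> compound map.

The loss process is gene-wise Poisson thinning along branches: a gene present
at a parent survives a branch of length L with probability exp(-r*L), where
r = base_loss_rate times the category's PPE multiplier on branches whose
descendant tips are all PPE (1 elsewhere), and, for informational categories,
times (1 + lambda * (1 - P_parent/P_root)) with P the lineage's surviving
non-informational gene count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ko_annotation import AnnotationMap
from .metabolic_network import KoReactionCompoundMap, read_ko_map, write_ko_map
from .orthogroup_io import (
    GeneCountMatrix,
    OrthogroupTable,
    gene_counts,
    read_gene_counts_csv,
    read_orthogroups_tsv,
    write_gene_counts_csv,
    write_orthogroups_tsv,
)
from .trees import PhyloTree, TreeNode, read_newick, write_newick

__all__ = [
    "CategorySpec",
    "ScenarioConfig",
    "FixtureBundle",
    "simulate_species_tree",
    "simulate_gene_content",
    "emit_fixture_files",
    "load_fixture_files",
    "bqh_pch_scenario",
]

SOLUBILITIES = ("soluble", "insoluble", "informational", "neutral")


@dataclass
class CategorySpec:
    """One KEGG-pathway-like functional category of orthogroups."""

    category_id: str
    n_ogs: int
    solubility: str
    ppe_loss_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.solubility not in SOLUBILITIES:
            raise ValueError(f"unknown solubility {self.solubility!r}")
        if self.n_ogs < 0 or self.ppe_loss_multiplier < 0:
            raise ValueError("category sizes and multipliers must be >= 0")


@dataclass
class ScenarioConfig:
    n_species: int
    n_ppe: int
    categories: list[CategorySpec]
    base_loss_rate: float
    annotation_fraction: float
    seed: int
    info_coupling: float = 0.0      # lambda in the proteome-size feedback
    annotation_noise: float = 0.0   # probability an annotation gets a wrong K
    n_unassigned_per_species: int = 0

    def __post_init__(self) -> None:
        if not self.n_ppe < self.n_species:
            raise ValueError("n_ppe must be smaller than n_species")
        if not 0.0 <= self.annotation_fraction <= 1.0:
            raise ValueError("annotation_fraction must lie in [0, 1]")
        if not 0.0 <= self.annotation_noise <= 1.0:
            raise ValueError("annotation_noise must lie in [0, 1]")
        if self.base_loss_rate < 0 or self.info_coupling < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class FixtureBundle:
    """Everything one simulated scenario produces, plus ground-truth bookkeeping."""

    species_tree: PhyloTree
    orthogroups: OrthogroupTable
    gene_counts: GeneCountMatrix
    annotations: AnnotationMap
    ko_map: KoReactionCompoundMap
    ko_to_pathways: dict[str, list[str]]
    proteome_sizes: dict[str, int]
    ppe_species: list[str] = field(default_factory=list)
    og_category: dict[str, str] = field(default_factory=dict)
    og_k: dict[str, str] = field(default_factory=dict)
    true_category_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    config: ScenarioConfig | None = None


def simulate_species_tree(n_species: int, seed: int) -> PhyloTree:
    """Random rooted binary tree with exponential branch lengths.

    Built by repeatedly joining two random lineages; deterministic for a
    fixed seed, with strictly positive branch lengths and tips labeled
    sp01..spNN.
    """
    if n_species < 3:
        raise ValueError("need at least 3 species")
    rng = np.random.default_rng(seed)
    width = max(2, len(str(n_species)))
    lineages = [TreeNode(label=f"sp{i + 1:0{width}d}") for i in range(n_species)]
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        parent = TreeNode()
        for child in (lineages[i], lineages[j]):
            child.length = float(rng.exponential(0.1) + 0.05)
            parent.add_child(child)
        lineages = [n for k, n in enumerate(lineages) if k not in (i, j)]
        lineages.append(parent)
    return PhyloTree(root=lineages[0], rooted=True)


def _ppe_tips(tree: PhyloTree, n_ppe: int) -> list[str]:
    # first n_ppe tips in the tree's own traversal order: contiguous tips
    # share recent ancestry, so PPE lineages get PPE-exclusive branches
    return [t.label for t in tree.tips()][:n_ppe]


def _branch_multiplier_flags(tree: PhyloTree, ppe: set[str]) -> dict[int, bool]:
    """id(node) -> True when every descendant tip of the branch is PPE."""
    flags: dict[int, bool] = {}
    tipsets: dict[int, set[str]] = {}
    for node in tree.postorder():
        if node.is_tip:
            tipsets[id(node)] = {node.label}
        else:
            tipsets[id(node)] = set().union(*(tipsets[id(c)] for c in node.children))
        flags[id(node)] = tipsets[id(node)] <= ppe
    return flags


def simulate_gene_content(tree: PhyloTree, config: ScenarioConfig) -> FixtureBundle:
    """Simulate category-structured gene loss along the tree.

    Two passes: non-informational categories first (tracking surviving gene
    counts per lineage), then informational categories whose loss rate is
    scaled by the proteome-size feedback. One ancestral gene per (OG,
    species-lineage); OGs left with a single surviving gene migrate to the
    unassigned pool, and OGs lost everywhere vanish.
    """
    tips = tree.tips()
    if len(tips) < config.n_ppe + 1:
        raise ValueError("tree must have more tips than n_ppe")
    rng = np.random.default_rng(config.seed)
    ppe = set(_ppe_tips(tree, config.n_ppe))
    ppe_flag = _branch_multiplier_flags(tree, ppe)

    # stable OG / K / category bookkeeping
    og_category: dict[str, str] = {}
    og_k: dict[str, str] = {}
    og_ids: list[str] = []
    counter = 0
    for cat in config.categories:
        for _ in range(cat.n_ogs):
            og_id = f"OG{counter:07d}"
            og_ids.append(og_id)
            og_category[og_id] = cat.category_id
            og_k[og_id] = f"K{counter + 1:05d}"
            counter += 1
    cat_by_id = {c.category_id: c for c in config.categories}

    non_info = [og for og in og_ids if cat_by_id[og_category[og]].solubility != "informational"]
    info = [og for og in og_ids if cat_by_id[og_category[og]].solubility == "informational"]
    p_root = max(len(non_info), 1)

    presence: dict[str, dict[int, bool]] = {}  # og -> id(node) -> present
    surviving_non_info: dict[int, int] = {id(tree.root): len(non_info)}

    def survives(rate: float, length: float) -> bool:
        if rate <= 0:
            return True
        return bool(rng.random() < np.exp(-rate * length))

    def preorder(node: TreeNode):
        yield node
        for c in node.children:
            yield from preorder(c)

    order = [n for n in preorder(tree.root)]

    # pass 1: everything except informational categories
    for og in non_info:
        cat = cat_by_id[og_category[og]]
        pres = {id(tree.root): True}
        for node in order:
            if node is tree.root:
                continue
            if not pres[id(node.parent)]:
                pres[id(node)] = False
                continue
            mult = cat.ppe_loss_multiplier if ppe_flag[id(node)] else 1.0
            pres[id(node)] = survives(config.base_loss_rate * mult, node.length)
        presence[og] = pres
    for node in order:
        if node is tree.root:
            continue
        surviving_non_info[id(node)] = sum(
            1 for og in non_info if presence[og][id(node)]
        )

    # pass 2: informational categories with proteome-size feedback
    for og in info:
        cat = cat_by_id[og_category[og]]
        pres = {id(tree.root): True}
        for node in order:
            if node is tree.root:
                continue
            if not pres[id(node.parent)]:
                pres[id(node)] = False
                continue
            mult = cat.ppe_loss_multiplier if ppe_flag[id(node)] else 1.0
            feedback = 1.0 + config.info_coupling * (
                1.0 - surviving_non_info[id(node.parent)] / p_root
            )
            pres[id(node)] = survives(
                config.base_loss_rate * mult * feedback, node.length
            )
        presence[og] = pres

    species = sorted(t.label for t in tips)
    tip_by_label = {t.label: t for t in tips}
    rows: dict[str, dict[str, list[str]]] = {}
    unassigned: dict[str, list[str]] = {sp: [] for sp in species}
    true_counts: dict[str, dict[str, int]] = {
        sp: {c.category_id: 0 for c in config.categories} for sp in species
    }
    surviving_genes: dict[str, list[str]] = {}
    for og in og_ids:
        members = {
            sp: [f"{og}_{sp}"]
            for sp in species
            if presence[og][id(tip_by_label[sp])]
        }
        total = sum(len(v) for v in members.values())
        for sp in members:
            true_counts[sp][og_category[og]] += 1
        if total == 0:
            continue
        surviving_genes[og] = [g for sp in sorted(members) for g in members[sp]]
        if total == 1:
            (sp,) = members
            unassigned[sp].extend(members[sp])
            continue
        rows[og] = {sp: members.get(sp, []) for sp in species}
    # species-specific singleton genes: Poisson-distributed around the
    # configured mean, independent of the tree (mirrors the unassigned,
    # species-specific fraction real proteomes carry)
    for sp in species:
        n_orphans = (
            int(rng.poisson(config.n_unassigned_per_species))
            if config.n_unassigned_per_species > 0
            else 0
        )
        for i in range(n_orphans):
            unassigned[sp].append(f"{sp}_orphan{i:04d}")

    table = OrthogroupTable(species=species, rows=rows, unassigned=unassigned)

    # partial direct annotation (gene gets its OG's K with prob f; optional noise)
    all_ks = sorted(set(og_k.values()))
    direct: dict[str, str] = {}
    for og in og_ids:
        for gene in surviving_genes.get(og, []):
            if rng.random() >= config.annotation_fraction:
                continue
            k = og_k[og]
            if config.annotation_noise > 0 and rng.random() < config.annotation_noise:
                others = [x for x in all_ks if x != k]
                if others:
                    k = others[int(rng.integers(len(others)))]
            direct[gene] = k

    ko_map, ko_to_pathways = _simulate_ko_map(config, og_ids, og_k, og_category, rng)
    return FixtureBundle(
        species_tree=tree,
        orthogroups=table,
        gene_counts=gene_counts(table),
        annotations=AnnotationMap(direct=direct),
        ko_map=ko_map,
        ko_to_pathways=ko_to_pathways,
        proteome_sizes=table.species_gene_counts(),
        ppe_species=sorted(ppe),
        og_category=og_category,
        og_k=og_k,
        true_category_counts=true_counts,
        config=config,
    )


def _simulate_ko_map(
    config: ScenarioConfig,
    og_ids: list[str],
    og_k: dict[str, str],
    og_category: dict[str, str],
    rng: np.random.Generator,
) -> tuple[KoReactionCompoundMap, dict[str, list[str]]]:
    """One or two reactions per K, 2-4 compounds per reaction from a shared pool."""
    n_compounds = max(20, len(og_ids))
    pool = [f"C{i + 1:05d}" for i in range(n_compounds)]
    ko_to_rn: dict[str, frozenset[str]] = {}
    rn_to_cpds: dict[str, frozenset[str]] = {}
    rn_counter = 0
    for og in og_ids:
        k = og_k[og]
        rns = []
        for _ in range(int(rng.integers(1, 3))):
            rn_counter += 1
            rn = f"R{rn_counter:05d}"
            size = int(rng.integers(2, 5))
            cpds = rng.choice(n_compounds, size=size, replace=False)
            rn_to_cpds[rn] = frozenset(pool[i] for i in cpds)
            rns.append(rn)
        ko_to_rn[k] = frozenset(rns)
    ko_to_pathways = {og_k[og]: [og_category[og]] for og in og_ids}
    return KoReactionCompoundMap(ko_to_rn=ko_to_rn, rn_to_cpds=rn_to_cpds), ko_to_pathways


def emit_fixture_files(bundle: FixtureBundle, directory: str | Path) -> dict[str, Path]:
    """Write the bundle as the plain-text files the I/O modules consume.

    Deterministic layout and ordering: byte-identical output for identical
    bundles. Round-tripping through :func:`load_fixture_files` reproduces
    the tables exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["orthogroups"] = write_orthogroups_tsv(
        bundle.orthogroups, directory / "Orthogroups.tsv"
    )
    paths["gene_counts"] = write_gene_counts_csv(
        bundle.gene_counts, directory / "Orthogroups.GeneCount.csv"
    )
    table = bundle.orthogroups
    gene_species = {
        g: sp for og in table.rows for sp in table.species for g in table.rows[og].get(sp, [])
    }
    for sp in table.species:
        for g in table.unassigned.get(sp, []):
            gene_species[g] = sp
    for sp in table.species:
        p = directory / f"{sp}.gene2ko.tsv"
        with p.open("w") as fh:
            for gene in sorted(g for g, s in gene_species.items() if s == sp):
                k = bundle.annotations.direct.get(gene)
                if k is not None:
                    fh.write(f"{gene}\t{k}\n")
        paths[f"gene2ko:{sp}"] = p
    p = directory / "unassigned_genes.tsv"
    with p.open("w") as fh:
        for sp in table.species:
            for gene in table.unassigned.get(sp, []):
                fh.write(f"{sp}\t{gene}\n")
    paths["unassigned"] = p
    paths["ko2rn"], paths["rn2cpd"] = write_ko_map(bundle.ko_map, directory)
    p = directory / "ko2pathway.tsv"
    with p.open("w") as fh:
        for k in sorted(bundle.ko_to_pathways):
            for cat in sorted(bundle.ko_to_pathways[k]):
                fh.write(f"{k}\t{cat}\n")
    paths["ko2pathway"] = p
    paths["tree"] = write_newick(bundle.species_tree, directory / "species_tree.nwk")
    p = directory / "proteome_sizes.tsv"
    with p.open("w") as fh:
        for sp in table.species:
            fh.write(f"{sp}\t{bundle.proteome_sizes[sp]}\n")
    paths["proteome_sizes"] = p
    return paths


def load_fixture_files(directory: str | Path) -> FixtureBundle:
    """Read the files written by :func:`emit_fixture_files` back into a bundle."""
    directory = Path(directory)
    table = read_orthogroups_tsv(directory / "Orthogroups.tsv")
    # unassigned genes are recoverable from the annotation files only if
    # annotated; proteome sizes are authoritative for totals
    from .ko_annotation import load_gene_ko_tsv

    annotations = load_gene_ko_tsv(
        sorted(directory.glob("*.gene2ko.tsv"))
    )
    ko_map = read_ko_map(directory / "ko2rn.tsv", directory / "rn2cpd.tsv")
    ko_to_pathways: dict[str, list[str]] = {}
    with (directory / "ko2pathway.tsv").open() as fh:
        for line in fh:
            if line.strip():
                k, cat = line.rstrip("\n").split("\t")
                ko_to_pathways.setdefault(k, []).append(cat)
    proteome_sizes: dict[str, int] = {}
    with (directory / "proteome_sizes.tsv").open() as fh:
        for line in fh:
            if line.strip():
                sp, n = line.split("\t")
                proteome_sizes[sp] = int(n)
    unassigned_path = directory / "unassigned_genes.tsv"
    if unassigned_path.exists():
        with unassigned_path.open() as fh:
            for line in fh:
                if line.strip():
                    sp, gene = line.rstrip("\n").split("\t")
                    table.unassigned.setdefault(sp, []).append(gene)
    return FixtureBundle(
        species_tree=read_newick(directory / "species_tree.nwk"),
        orthogroups=table,
        gene_counts=read_gene_counts_csv(directory / "Orthogroups.GeneCount.csv"),
        annotations=annotations,
        ko_map=ko_map,
        ko_to_pathways=ko_to_pathways,
        proteome_sizes=proteome_sizes,
    )


def bqh_pch_scenario(
    n_species: int = 16,
    n_ppe: int = 7,
    seed: int = 0,
    og_per_category: int = 120,
) -> ScenarioConfig:
    """Default scenario: soluble and informational categories reduced in PPEs.

    Effect sizes are illustrative (no calibrated loss rates exist). The low
    base rate keeps non-PPE gene content nearly constant (so insoluble
    categories stay decoupled from proteome size), the large PPE multipliers
    concentrate loss in the reduced lineages, and the Poisson orphan-gene
    noise gives proteome sizes tree-independent variation; together these
    separate soluble/informational from insoluble categories reliably in the
    screen at 16 species.
    """
    categories = [
        CategorySpec("KO00220", og_per_category, "soluble", 1500.0),
        CategorySpec("KO00300", og_per_category, "soluble", 1500.0),
        CategorySpec("KO00400", og_per_category, "soluble", 1500.0),
        CategorySpec("KO00906", og_per_category, "soluble", 1500.0),
        CategorySpec("KO00061", og_per_category, "insoluble", 1.0),
        CategorySpec("KO00100", og_per_category, "insoluble", 1.0),
        CategorySpec("KO01040", og_per_category, "insoluble", 1.0),
        CategorySpec("KO03400", og_per_category, "informational", 1500.0),
        CategorySpec("KO03030", og_per_category, "informational", 1500.0),
        CategorySpec("KO09100", og_per_category, "neutral", 1.0),
    ]
    return ScenarioConfig(
        n_species=n_species,
        n_ppe=n_ppe,
        categories=categories,
        base_loss_rate=0.01,
        annotation_fraction=0.6,
        seed=seed,
        info_coupling=3.0,
        n_unassigned_per_species=400,
    )
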