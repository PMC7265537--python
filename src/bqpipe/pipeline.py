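"""End-to-end orchestration: simulate -> annotate -> networks -> distances ->
NJ trees -> congruence -> PIC screen -> report.

Every stage writes plain-text artifacts (TSV / Newick / PHYLIP) under the
output directory and records its summary numbers in a JSON manifest, so each
stage is independently inspectable and a re-run with the same config and
seed is byte-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ko_annotation import category_counts, efficiency, load_gene_ko_tsv, propagate_ko
from .metabolic_network import build_network, export_edge_list
from .network_distance import MEASURES, distance_matrix, write_phylip_lower
from .orthogroup_io import orthogroup_stats, pangenome_partition
from .pic_screen import branch_length_correlation, category_screen
from .synthetic_data import (
    FixtureBundle,
    ScenarioConfig,
    bqh_pch_scenario,
    emit_fixture_files,
    simulate_gene_content,
    simulate_species_tree,
)
from .trees import neighbor_join, shared_split_fraction, write_newick

log = logging.getLogger("bqpipe")

__all__ = ["RunManifest", "run_pipeline", "report"]

STAGES = (
    "simulate",
    "annotate",
    "network",
    "distances",
    "njtree",
    "congruence",
    "pic",
)


@dataclass
class RunManifest:
    seed: int
    version: str
    config: dict
    outputs: dict[str, dict[str, str]] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    digests: dict[str, str] = field(default_factory=dict)

    def record(self, stage: str, paths: dict[str, Path]) -> None:
        self.outputs[stage] = {k: str(p) for k, p in paths.items()}
        for key, p in paths.items():
            self.digests[f"{stage}:{key}"] = hashlib.sha256(
                Path(p).read_bytes()
            ).hexdigest()

    @property
    def completed_stages(self) -> list[str]:
        return [s for s in STAGES if s in self.outputs]

    def save(self, path: Path) -> Path:
        def coerce(obj):
            if isinstance(obj, np.integer):
                return int(obj)
            if isinstance(obj, (np.floating, np.bool_)):
                return obj.item()
            raise TypeError(f"not JSON serializable: {type(obj)}")

        path.write_text(
            json.dumps(asdict(self), indent=2, sort_keys=True, default=coerce) + "\n"
        )
        return path


def run_pipeline(
    out_dir: str | Path,
    seed: int = 0,
    scenario: ScenarioConfig | None = None,
) -> RunManifest:
    """Run the whole analysis on a simulated genome-reduction scenario.

    A single seed is fanned out to independent per-stage substreams
    (tree and gene content get distinct children of the seed sequence), so
    stages are reproducible in isolation.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    tree_seed, content_seed = (int(c.generate_state(1)[0]) for c in ss.spawn(2))
    if scenario is None:
        scenario = bqh_pch_scenario(seed=content_seed)
    manifest = RunManifest(
        seed=seed,
        version=__version__,
        config={**asdict(scenario), "out_dir": str(out)},
    )

    # --- simulate -----------------------------------------------------------
    log.info("stage simulate: %d species, %d PPE", scenario.n_species, scenario.n_ppe)
    tree = simulate_species_tree(scenario.n_species, tree_seed)
    bundle = simulate_gene_content(tree, scenario)
    fixture_dir = out / "fixture"
    manifest.record("simulate", emit_fixture_files(bundle, fixture_dir))
    summary = pangenome_partition(bundle.orthogroups)
    stats = orthogroup_stats(bundle.orthogroups)
    manifest.summary["pangenome"] = {
        "n_core": summary.n_core,
        "n_shared": summary.n_shared,
        "n_unique": summary.n_unique,
        "n_ogs": stats.n_ogs,
        "total_genes": stats.total_genes,
        "pct_assigned": stats.pct_assigned,
    }

    # --- annotate -----------------------------------------------------------
    table = bundle.orthogroups
    direct = load_gene_ko_tsv(sorted(fixture_dir.glob("*.gene2ko.tsv")))
    effective = propagate_ko(table, direct)
    eff = efficiency(direct, effective, table)
    counts = category_counts(effective, table, bundle.ko_to_pathways)
    paths: dict[str, Path] = {}
    p = out / "effective_annotations.tsv"
    with p.open("w") as fh:
        fh.write("gene\tK\tprovenance\n")
        for gene in sorted(effective.effective):
            k, prov = effective.effective[gene]
            fh.write(f"{gene}\t{k}\t{prov}\n")
    paths["effective_annotations"] = p
    p = out / "og_consensus.tsv"
    with p.open("w") as fh:
        fh.write("orthogroup\tK\n")
        for og in sorted(effective.og_consensus):
            fh.write(f"{og}\t{effective.og_consensus[og]}\n")
    paths["og_consensus"] = p
    p = out / "category_counts.tsv"
    counts.to_csv(p, sep="\t", index_label="species")
    paths["category_counts"] = p
    manifest.record("annotate", paths)
    manifest.summary["efficiency"] = eff.as_dict()

    # --- network ------------------------------------------------------------
    species_ks: dict[str, list[str]] = {sp: [] for sp in table.species}
    gene_species = {
        g: sp for og in table.rows for sp in table.species for g in table.rows[og].get(sp, [])
    }
    for sp in table.species:
        for g in table.unassigned.get(sp, []):
            gene_species[g] = sp
    for gene in sorted(effective.effective):
        sp = gene_species.get(gene)
        if sp is not None:
            species_ks[sp].append(effective.effective[gene][0])
    networks = [
        build_network(sp, species_ks[sp], bundle.ko_map) for sp in table.species
    ]
    net_dir = out / "networks"
    net_dir.mkdir(exist_ok=True)
    paths = {
        sp: export_edge_list(net, net_dir / f"{sp}.edges.tsv")
        for sp, net in zip(table.species, networks)
    }
    manifest.record("network", paths)
    manifest.summary["network"] = {
        sp: {"n_nodes": len(net.nodes), "total_edge_weight": net.total_edge_weight}
        for sp, net in zip(table.species, networks)
    }

    # --- distances / njtree / congruence ------------------------------------
    dist_paths: dict[str, Path] = {}
    tree_paths: dict[str, Path] = {}
    congruence: dict[str, dict] = {}
    for measure in MEASURES:
        dm = distance_matrix(networks, measure=measure)
        dist_paths[measure] = write_phylip_lower(
            dm, out / f"distance_{measure}.phy"
        )
        pd.DataFrame(dm.values, index=dm.labels, columns=dm.labels).to_csv(
            out / f"distance_{measure}.tsv", sep="\t"
        )
        if np.allclose(dm.values, 0):
            congruence[measure] = {"shared_pct": None, "degenerate": True}
            continue
        nj = neighbor_join(dm)
        tree_paths[measure] = write_newick(nj, out / f"njtree_{measure}.nwk")
        cmp_ = shared_split_fraction(nj, bundle.species_tree)
        congruence[measure] = {
            "shared_pct": cmp_.shared_pct,
            "rf_distance": cmp_.rf_distance,
            "n_shared": cmp_.n_shared,
            "degenerate": False,
        }
    manifest.record("distances", dist_paths)
    if tree_paths:
        manifest.record("njtree", tree_paths)
    else:
        manifest.outputs["njtree"] = {}
    manifest.outputs["congruence"] = {}
    manifest.summary["congruence"] = congruence

    # --- pic ----------------------------------------------------------------
    results = category_screen(bundle.species_tree, counts, bundle.proteome_sizes)
    p = out / "screen_results.tsv"
    with p.open("w") as fh:
        fh.write("category\tR\tp\tn_contrasts\tsignificant\tslope_reduction\tdegenerate\n")
        for res in results:
            sr = "" if res.slope_reduction is None else f"{res.slope_reduction:.3f}"
            fh.write(
                f"{res.category}\t{res.r:.6f}\t{res.p:.6g}\t{res.n_contrasts}\t"
                f"{int(res.significant)}\t{sr}\t{int(res.degenerate)}\n"
            )
    manifest.record("pic", {"screen_results": p})
    blc = branch_length_correlation(bundle.species_tree, bundle.proteome_sizes)
    n_sig = sum(r.significant for r in results)
    manifest.summary["screen"] = {
        "n_categories": len(results),
        "n_significant": n_sig,
        "significant_categories": sorted(r.category for r in results if r.significant),
        "branch_length_R": None if np.isnan(blc.r) else blc.r,
        "branch_length_p": None if np.isnan(blc.p) else blc.p,
    }

    manifest.save(out / "manifest.json")
    return manifest


def report(manifest: RunManifest, out_dir: str | Path | None = None) -> tuple[Path, Path]:
    """Write human-readable and machine-readable summaries of a finished run.

    Raises ValueError listing missing stages when the manifest is incomplete.
    """
    missing = [s for s in STAGES if s not in manifest.outputs]
    if missing:
        raise ValueError(f"manifest incomplete; missing stages: {missing}")
    out = Path(out_dir) if out_dir else Path(manifest.config["out_dir"])
    tsv = out / "summary.tsv"
    txt = out / "summary.txt"
    rows = []
    s = manifest.summary
    for key in ("n_core", "n_shared", "n_unique", "n_ogs", "total_genes", "pct_assigned"):
        rows.append(("pangenome", key, s["pangenome"][key]))
    for key, val in s["efficiency"].items():
        rows.append(("efficiency", key, val))
    for measure in MEASURES:
        rows.append(("congruence_pct", measure, s["congruence"][measure]["shared_pct"]))
    rows.append(("screen", "n_categories", s["screen"]["n_categories"]))
    rows.append(("screen", "n_significant", s["screen"]["n_significant"]))
    rows.append(("screen", "branch_length_R", s["screen"]["branch_length_R"]))
    with tsv.open("w") as fh:
        fh.write("section\tkey\tvalue\n")
        for sec, key, val in rows:
            fh.write(f"{sec}\t{key}\t{val}\n")
    cong = s["congruence"]
    lines = [
        f"bqpipe {manifest.version} run (seed={manifest.seed})",
        "",
        f"Pangenome: {s['pangenome']['n_core']} core / "
        f"{s['pangenome']['n_shared']} shared / {s['pangenome']['n_unique']} unique OGs "
        f"({s['pangenome']['pct_assigned']}% of genes assigned)",
        f"KO mapping efficiency: {s['efficiency']['efficiency_direct']}% direct -> "
        f"{s['efficiency']['efficiency_effective']}% after OG consensus",
        "",
        "Tree congruence with the species tree (% shared splits):",
    ]
    for measure in MEASURES:
        val = cong[measure]["shared_pct"]
        shown = "degenerate (identical networks)" if val is None else f"{val:.1f}%"
        lines.append(f"  {measure:>9}: {shown}")
    if cong["adcan"]["shared_pct"] is not None and cong["jaccard"]["shared_pct"] is not None:
        delta = cong["adcan"]["shared_pct"] - cong["jaccard"]["shared_pct"]
        lines.append(
            f"  Adkins-Canberra vs unweighted Jaccard: {delta:+.1f} percentage points"
        )
    lines += [
        "",
        f"PIC screen: {s['screen']['n_significant']} / {s['screen']['n_categories']} "
        "categories significant (R > 0.5, p < 0.05)",
        f"  significant: {', '.join(s['screen']['significant_categories']) or 'none'}",
    ]
    txt.write_text("\n".join(lines) + "\n")
    return txt, tsv
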