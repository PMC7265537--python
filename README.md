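# bqpipe

Comparative-genomics toolkit for studying genome reduction in microbial
eukaryotes. It takes OrthoFinder-style orthogroup tables plus per-gene KEGG
Orthology (KO) annotations and runs the full downstream analysis:

- **orthogroup_io** — parse `Orthogroups.tsv` / `Orthogroups.GeneCount.csv`,
  pangenome partition (core / shared / unique), orthogroup summary statistics.
- **ko_annotation** — two-step KO annotation: direct per-gene assignments
  plus orthogroup-consensus propagation (modal K number fills annotation
  gaps), with mapping-efficiency reporting and per-category gene counts.
- **metabolic_network** — compound-level metabolic networks from K numbers
  via a ko → reaction → compound map, with reaction-abundance edge weights.
- **network_distance** — unweighted/weighted Jaccard, Canberra and
  Adkins-Canberra distances; pairwise species distance matrices; PHYLIP
  lower-triangular export.
- **trees** — neighbor joining, Newick I/O, bipartition extraction,
  shared-split congruence (with Robinson-Foulds), root-to-tip branch lengths.
- **pic_screen** — phylogenetic independent contrasts, correlation through
  the origin, and the category-vs-proteome-size significance screen
  (R > 0.5, p < 0.05).
- **proteomic_constraint** — the mutation-rate / genome-information relation
  mu = k(2·Ne·s̄·π·P)⁻¹ and its inversions.
- **synthetic_data** — a genome-reduction simulator (species tree,
  category-structured gene loss along branches, partial annotation, ko map)
  so the whole pipeline is testable without any downloads.
- **pipeline** — end-to-end orchestration with a JSON run manifest and
  plain-text artifacts at every stage.

## CLI

Every stage is exposed as a `bqpipe` subcommand:

```sh
bqpipe simulate --n-species 16 --n-ppe 7 --seed 1 --out fixture/
bqpipe stats --orthogroups fixture/Orthogroups.tsv
bqpipe annotate --orthogroups fixture/Orthogroups.tsv \
    --gene2ko fixture/*.gene2ko.tsv --out annotated/
bqpipe njtree --matrix distance_adcan.phy --out njtree.nwk
bqpipe congruence --query njtree.nwk --reference fixture/species_tree.nwk
bqpipe pic --tree fixture/species_tree.nwk \
    --category-counts annotated/category_counts.tsv \
    --proteome-sizes fixture/proteome_sizes.tsv --out screen.tsv
bqpipe constraint --mu 5e-10 --k 1 --s_bar 0.01 --pi 0.001 --P 1e7  # prints Ne

bqpipe run --seed 1 --out-dir run/        # full simulate→screen pipeline
```

`bqpipe run` writes a `manifest.json`, per-stage TSV/Newick/PHYLIP artifacts,
and human/machine-readable summaries (`summary.txt`, `summary.tsv`) covering
the pangenome partition, mapping efficiency, the four distance measures'
tree congruence with the species tree, and the PIC screen results. Scenario
parameters can be supplied as a YAML file via `--config` (see
`ScenarioConfig` / `CategorySpec` in `bqpipe.synthetic_data`).

## Notes

- Distance matrices compare node sets (unweighted Jaccard) or
  node-abundance vectors over the union compound universe (weighted
  measures); edge-indexed vectors are available as an option.
- Adkins-Canberra normalizes by the count of positions nonzero in either
  vector (bounded in [0, 1]); a strict both-nonzero mode exists.
- Identical networks yield an all-zero distance matrix with no defined NJ
  topology; the pipeline flags this degenerate case instead of reporting
  congruence.
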