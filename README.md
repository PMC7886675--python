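# hidtree

Select a minimal set of genotype markers that distinguishes every accession
in a HapMap population, and package the result as a hierarchical decision
tree whose root-to-leaf paths are PCR-checkable identification recipes.

## The problem

A HapMap project genotypes hundreds of lines (accessions) of a species.
Before phenotyping or GWAS work, the accessions in hand must be verified —
seed stocks get propagated, heterozygous material segregates, and genotype
calls contain missing values. Homozygous genotypes at a variant marker are
stably inherited in self-pollinated species, so a marker whose homozygous
classes ("0/0" vs "1/1") split the population can discriminate accession
sets; a cascade of such markers can pin down an individual accession. Long
INDEL markers are particularly practical because the allele is visible as a
PCR product-size difference.

`hidtree` takes a plain-text genotype marker matrix (rows = markers,
columns = accessions, cells = VCF-style GT tokens `0/0`, `1/1`, `0/1`,
`./.`), or extracts one from a VCF, and builds the decision tree.

## The method

Every marker gets a **distinguishing score** over the accession set it is
asked to split. With `AN` accessions, `UN` missing calls, `HN` heterozygous
calls and homozygous class fractions `P_{i/i}`:

```
DS = (AN - UN - HN) / AN  ·  Σ_{i<j} P_{i/i} · P_{j/j}
```

For a bi-allelic marker this is `((AN-UN-HN)/AN) · P_{0/0} · P_{1/1}`,
maximal at **0.25** for a clean 50:50 split; with `TG` homozygous classes the
maximum is `(TG-1)/(2·TG)`. The builder greedily selects the highest-DS
usable marker, partitions the set by homozygous genotype — accessions with
heterozygous or missing calls are duplicated into **every** child, trading
redundancy for robustness — and recurses until subsets reach the significance
threshold (threshold 1 resolves individual accessions). Markers may be
globally excluded after first use (`--no-reuse`) or re-selected in other
branches (`--reuse`).

## Worked example

```
$ hidtree simulate --mode noisy --accessions 16 --markers 40 \
      --het-rate 0.2 --missing-rate 0.1 --seed 7 --out matrix.txt
INFO hidtree: simulated 40 x 16 matrix -> matrix.txt
$ hidtree build --matrix matrix.txt --subset-size 1 --no-reuse --outdir tree --dot tree.dot
INFO hidtree: tree: 16 marker nodes, 17 subsets, depth 5 -> tree
$ hidtree paths --tree tree --accession ACC003
path 1: (M029; 0/0) -> (M004; 0/0) -> (M002; 0/0) -> (M012; 0/0) -> (M001; 1/1)
```

The simulated population has the heterozygosity (0.2) and missingness (0.1)
levels typical of HapMap data. Sixteen markers suffice to resolve all 16
accessions; 17 leaves (one more than the accession count) means exactly one
accession was duplicated by a het/missing call on its decision path. The
printed path says: accession ACC003 is the one that is homozygous-reference
at markers M029, M004, M002 and M012 and homozygous-alternative at M001 —
five PCR assays identify it. `tree/` holds the three output files
(`HiDTree.txt`, the tree; `MarkerList.txt`, used markers with their 1-based
matrix row indices; `SubsetList.txt`, each leaf with its accessions and
path) and `tree.dot` is Graphviz input for visualization.

Starting from a VCF instead:

```
hidtree extract --vcf variants.vcf --type INDEL --min-indel-len 10 \
    --max-missing 0.2 --max-het 0.2 --min-ds 0.05 --out matrix.txt
```

## Library surface

```python
from hidtree import (
    read_genotype_matrix, extract_matrix, ExtractionConfig,   # input
    tally_marker, ds_score, rank_markers,                     # scoring
    build_tree, PartitionConfig,                              # partitioning
    write_outputs, path_to_accession, tree_stats, export_dot, # tree outputs
    perfect_matrix, noisy_matrix, SimulationSpec,             # simulation
)
```

See `docs/methods.md` for the model, parameter semantics, numerical choices
and known limitations.
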