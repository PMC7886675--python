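# Methods

## Model and assumptions

The package treats accession identification as recursive set partitioning
over a genotype marker matrix. The operative assumptions are those of the
underlying experimental setting:

* the species is self-pollinated, so a homozygous genotype at a marker is
  stably inherited and can anchor an identification assay;
* heterozygous calls are uninformative for stable discrimination (they
  segregate in offspring) unless explicitly promoted to their own class;
* missing calls carry no information;
* genotype calls in the matrix are accurate; the method has no error model
  for miscalled genotypes (a wrongly called marker must be removed upstream).

Markers are diploid GT tokens in the VCF convention. Phased separators `|`
are normalised to `/`; any `.` in an allele position makes the whole call
missing (so `./1` is missing, not heterozygous); `i/j` with `i != j` is
heterozygous for any allele pair, so multi-allelic markers are supported
throughout. Haploid tokens are rejected unless a lenient flag maps `i` to
`i/i`.

## Distinguishing score

For a marker over an accession subset with `AN` members, `UN` missing, `HN`
heterozygous and homozygous class counts `c_i` (total `T = AN - UN - HN`,
`TG` classes present):

```
DS = (AN - UN - HN)/AN · Σ_{i<j} P_{i/i} P_{j/j}
```

`P_{i/i} = c_i / T` by default ("homozygous" denominator): fractions always
sum to 1, the leading factor is the sole missing/het penalty, and the
bi-allelic identity `P_{0/0} + P_{1/1} = 1` holds in general, not only in the
clean case. The alternative convention `P_{i/i} = c_i / AN` ("all"
denominator) penalises missing/het calls a second time through the
fractions; it is available via the `denominator` switch on every scoring
entry point because the convention used by earlier C++ implementations of
this procedure is not documented. Markers with `TG < 2` score 0 (the
pairwise sum is empty — such a marker cannot partition anything). The
bi-allelic maximum is 0.25 at a clean 50:50 split; the `TG`-class maximum is
`(TG-1)/(2·TG)`.

### Exact ranking arithmetic

With integer tallies, `DS = (AN-UN-HN)(T² - Σc_i²) / (2·AN·d²)` for fraction
denominator `d`, a rational number. Marker ranking compares these exact
rationals (`fractions.Fraction`) rather than floats: two markers with
mathematically equal DS but different class-count orderings can otherwise
differ in the last float ulp, which would silently break the documented
tie-break (equal DS resolves to the lower matrix row index) and make tree
construction depend on summation order. Reported DS values are the float
image of the exact rational.

## Partitioning and tree construction

At each step the builder ranks all non-excluded markers by DS within the
current subset and selects the best *usable* one: at least two homozygous
classes present in the subset, and every prospective child strictly smaller
than the subset. Children are one per homozygous class, in ascending allele
order; accessions with heterozygous or missing calls at the selected marker
are duplicated into **every** child. Duplication trades output-size
parsimony for robustness: an accession is never lost to a bad call, and can
simply appear in several leaves (any one of its paths identifies it). A
subset at or below the significance threshold becomes a leaf; a subset no
marker can split (marker exhaustion under no-reuse, or all remaining markers
constant/heterozygous within it) becomes a leaf with a logged warning rather
than an error, so a complete tree is always emitted.

With reuse disabled, a marker selected anywhere is excluded from all later
selections, in construction order. Construction is depth-first with an
explicit work stack, parent before children, lowest-allele branch first;
leaf indices count left to right. All outputs are byte-deterministic.

Because a usable marker in plain mode has `TG ≥ 2`, every child is strictly
smaller than its parent automatically (a child could only equal the parent
if a single homozygous class held all homozygous calls); the explicit
child-size guard matters for degenerate configurations of the
heterozygote-as-class extension and is kept as a termination invariant:
recursion depth is bounded by the subset size.

### Heterozygote as a third class

For matrices from material where segregation is not a concern, the
`treat_het_as_class` switch promotes `0/1` to its own branch class, labelled
`2/2`. The resulting tree is a polytree (nodes may have three or more
branches) and heterozygous accessions are no longer duplicated. The label
`2/2` would collide with a genuine third allele, so this mode requires a
bi-allelic matrix and raises otherwise.

## VCF extraction

`extract_matrix` reproduces the usual matrix-preparation step: classify each
record (SNP: all alleles length 1; INDEL: any REF/ALT length difference;
symbolic, breakend and length-preserving multi-base alleles: OTHER), then
filter by variant type, minimum INDEL length, biallelic status, missing
rate, het rate and DS. Only the GT field is consulted; FILTER is honoured
only under `pass_only`. Defaults (`INDEL`, length ≥ 10, biallelic, missing ≤
0.2, het ≤ 0.2, DS ≥ 0.05) are package conventions chosen for PCR-friendly
panels — long INDELs give easily sized products, and 0.2 matches the
heterozygosity commonly reported for HapMap populations — not values from
any published pipeline; all are configurable. Multi-allelic records under
`biallelic_only` are dropped, not split, because splitting would renumber
allele indices relative to the called GTs. Parsing is delegated to pysam.

## Synthetic data

`perfect_matrix(M, N)` builds the analytic ground truth: `2^M` accessions
and one perfect bi-allelic marker per internal node of the perfect binary
tree down to depth `M-N-1` (`2^(M-N) - 1` markers, breadth-first row order).
Each marker's block is half `0/0`, half `1/1`; accessions outside the block
are filled with constant `0/0`. The constant fill makes each node's marker
the unique DS maximiser within its own block (outside markers are constant
there, deeper markers are less balanced), so greedy construction at
threshold `2^N` recovers the generating topology exactly — the
parameter-recovery fixture for tree construction.

`noisy_matrix` draws i.i.d. cells: missing with probability `missing_rate`,
heterozygous with `het_rate`, otherwise `0/0` with probability `hom_balance`
(default 0.5, the DS-optimal balance) and `1/1` otherwise. Defaults
`het_rate = 0.2` and `missing_rate = 0.1` reflect the heterozygosity level
reported for well-characterised HapMap populations and a moderate missing
rate. What the generator does **not** emulate: linkage between markers,
realistic allele-frequency spectra, population structure, and genotyping
error correlated by accession. Tests passing on these fixtures therefore
demonstrate the combinatorial and scoring behaviour of the method, not its
end-to-end performance on a real population, where linked markers make
greedy selection less efficient than the i.i.d. case suggests.

Simulation sizes used in the test suite (up to `M = 8`, i.e. 256 accessions
× 255 markers for the perfect-tree sweeps; 200 random ≤ 8×6 matrices for the
brute-force cross-check; 30–40 accessions × 80–120 markers for the noisy
regime) were chosen as the smallest scales at which every property being
checked is non-trivially exercised.

## Output files

* `HiDTree.txt` — versioned (`# HiDTree v1`), indented pre-order rendering,
  one node per line, branch lines prefixed `label -> `. Human-readable and
  machine-parseable; `read_hidtree` reconstructs an isomorphic tree, which
  is what the `paths` and `viz` subcommands consume. The layout is defined
  by this package (no prior art documents one).
* `MarkerList.txt` — used markers in first-use (pre-order) order with their
  original matrix row indices; 1-based by default (`--marker-index-base`)
  since marker numbers are conventionally quoted as 1-based row positions.
* `SubsetList.txt` — per leaf: index, accession list, and the path rendered
  as `marker:genotype` steps.
* DOT export — ellipses for marker nodes, boxes for subsets, edges labelled
  with the branch genotype; plain text, renderable with any Graphviz.

Newick is deliberately not offered: branch-labelled polytrees with
duplicated leaves do not map onto Newick semantics.

## Known limitations

* Greedy DS selection is not guaranteed minimal; no optimal marker-set
  search is attempted.
* No linkage modelling: two markers in perfect LD both look informative and
  can both be selected on different levels.
* The tie-break (lowest row index) is a convention; a different but equally
  valid convention in another implementation yields a different, equally
  correct tree, so node-level comparisons across tools can shift by a few
  nodes.
* Matrices are held in memory; the intended scale is ~10^3 markers × 10^2
  accessions.
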