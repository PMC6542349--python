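# Methods

## Scope and model

`markerselect` detects condition-specific marker genes in a normalized
expression matrix **X** (*n* genes × *s* samples) whose samples are grouped
into *t* sample types, each with at least two replicates.  The matrix is
taken as given: values must be non-negative, finite and comparable between
samples (log2 of RPKM/FPKM/TMM/RLE or size-factor-normalized counts, with a
pseudo-count of 1 added before the log).  The package never normalizes,
imputes or maps reads; `log2_pseudocount` and `filter_expressed` (drop genes
with positive values in fewer than two samples) are the only preprocessing
steps offered.

The core detector asks, per gene, whether the replicates of one type occupy
the entire top of the decreasingly sorted profile, all above an expression
cutoff, and scores specificity as the ratio of the next block's mean to the
top block's mean.  The second block is grown until every type it touches is
fully contained, so the score compares the candidate type against the
nearest *complete* group of competitors rather than a single runner-up
sample.  Because the profile is non-increasing, the score is guaranteed to
lie in [0, 1], and it is a ratio, so jointly rescaling the matrix and the
cutoff changes nothing.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| expression cutoff | 1 | minimum value (matrix scale) for every entry of the top replicate block; 1 matches common presence thresholds for log-scale RNA-seq units |
| SPM cutoff | 0.4 | inclusive selection threshold on the cosine specificity score |
| z cutoff | 1 | inclusive selection threshold on the per-type z-score |
| z-score sd | ddof = 1 | sample standard deviation; configurable |
| k-means runs | 100 | restarts averaged in the clustering benchmark |
| overlap draws | 1000 | random same-size sets in the enrichment z-test |

## Conventions the description leaves open

* **Ties.**  The decreasing sort is stable with ties broken by original
  sample index.  A candidate whose top block ties exactly with the next
  value of a different type passes on position and carries a
  `boundary_tie` flag in its `MarkerCall`.
* **Degenerate profiles.**  All-zero and constant profiles are skipped
  before sorting: a gene with identical expression everywhere carries no
  contrast, and under the positional tie rule it would otherwise be
  assigned, with score exactly 1, to whichever type happens to sort first —
  an artifact of sample ordering, not biology.
* **Singleton types.**  Types with one replicate trigger a warning (or an
  error with `strict=True`) but detection proceeds; the algorithm is
  well-defined for r = 1.  At least two distinct types are required —
  with one type there is nothing beyond the first cut-point to compare
  against.
* **Baselines on per-type means.**  SPM and z-score operate on length-*t*
  per-type mean profiles rather than per-sample profiles, putting all
  detectors on the same per-type ranking footing in the benchmarks.  SPM is
  the *length-normalized* dot product (cosine): the raw dot product is
  unbounded and incompatible with a fixed 0.4 threshold.

## Evaluation choices

* **PCA**: samples are observations, genes features; features are centered,
  not scaled (scaling available via a flag).  Component signs are fixed by
  making each component's largest-magnitude loading positive, so embeddings
  are reproducible and invariant to gene row order.
* **k-means**: one k-means++ seeding plus Lloyd iterations (tol 1e-6,
  max 300) per run, each run on its own RNG substream derived from the
  master seed.  k-means++ rather than uniform random-point seeding: with
  coincident replicate coordinates (noise-free data) uniform seeding can
  place two centroids on the same point and converge with a merged cluster,
  so even perfectly separable data would not score NMI = 1.
* **NMI** normalizes mutual information by the arithmetic mean of the two
  entropies (geometric/min/max variants selectable).  Purity is reported
  knowing its degenerate optimum (one cluster per sample scores 1); it is
  not symmetric in its arguments.
* **AUPRC** uses the non-interpolated step summation Σ ΔR·P with tied
  scores entering together.  When a gene universe is supplied, recall is
  counted against all gold genes in the universe, so gold genes a detector
  never listed cap its recall below 1; without a universe the ranking
  itself defines the denominator.  **AUROC** is the Mann–Whitney
  probability with ties counting 1/2; with a universe, unlisted genes enter
  tied at the least-specific end.
* **Overlap z-test**: one-sided (enrichment) upper-tail normal p-value for
  z = (observed − mean)/sd over 1,000 random same-size sets (sd with
  ddof = 1).  If the random distribution is degenerate (sd = 0) the p-value
  is reported as 0 or 1 with a warning.

## Synthetic data

The generator emulates the structure of small grouped transcriptome
studies: defaults of 5 types × 3 replicates, 10 planted markers per type
and 500 background genes, half housekeeping-like and half silent.  On the
log2 working scale, each marker gene draws a per-gene level ~
Normal(8, 1) — log-normal in raw units — expressed in its own type and set
to 0 elsewhere; housekeeping genes draw one level ~ Normal(4, 1) shared by
all samples; per-cell Gaussian noise (default sd 1) is added, optional
Bernoulli dropout zeroes cells independently of expression level, and
values are clipped at 0.  Everything is a deterministic function of the
seed.

What this does *not* emulate: library-size or gene-length biases,
mean–variance coupling, correlated gene modules, partially shared markers,
or expression-dependent dropout.  Passing tests on this generator therefore
demonstrate algorithmic correctness and qualitative behavior (planted
markers recovered perfectly without noise; recall degrading monotonically
with noise; marker-restricted clustering at least as good as full-matrix
clustering), not performance on any particular real dataset.

Problem sizes in the test-suite and acceptance runs (550–10,000 genes,
6–15 samples, 100 k-means restarts, 1,000 overlap draws, 20 seeds per noise
level) are chosen as the smallest sizes at which the measured quantities
are stable to well within the asserted tolerances.

## Known limitations

* With many replicates per type, the chance that all of them sort into the
  top block shrinks, so the detector is most useful in the few-replicate
  regime where pairwise differential expression lacks power.
* Detected markers are relative to the sample collection at hand: adding or
  removing a type changes the competition inside each sorted profile and
  may change every list.
* The score attaches no p-value; the overlap z-test and the ranked
  benchmarks provide the inferential layer instead.
* Gene-identifier mapping is a plain offline three-column lookup table;
  no live annotation-database queries.
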