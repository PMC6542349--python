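# markerselect

Detection of condition-specific marker genes from grouped RNA-seq and
scRNA-seq expression matrices, with the benchmark machinery to evaluate
marker detectors against each other.

## The problem

Given a normalized expression matrix **X** (*n* genes × *s* samples) whose
samples belong to *t* sample types (tissues, cell types, ...) with at least
two replicates each, which genes mark each type — i.e. are characteristically
high in one type and low everywhere else?  Pairwise differential-expression
testing scales quadratically in the number of types and lacks power at two
or three replicates; `markerselect` implements a fast, parameter-light
alternative (the MGFR replicate-block algorithm) alongside two classical
specificity scores and a random baseline.

## The algorithm

For each gene:

1. Sort its expression profile decreasingly across the *s* samples
   (ties break by original sample index, so results are deterministic).
2. Let *T* be the type of the highest value and *r* its replicate count.
   If the top *r* positions are all type *T* with every value ≥ a cutoff
   (default 1 on the matrix scale), the gene is a candidate marker of *T*;
   otherwise it is discarded.  This is **cut-point 1**.
3. Grow a second block from position *r* + 1: take as many values as the
   next type has replicates, and keep extending until every type inside the
   block has all of its replicates inside (**cut-point 2**; capped at the
   profile end).
4. Score specificity as

   *score* = mean(values between cut-points 1 and 2) / mean(values before cut-point 1)

   which lies in [0, 1]: **0 = perfectly type-exclusive, values near 1 = no
   contrast**.  Per-type lists are ranked ascending by score.

Baselines: **SPM**, the cosine between a gene's per-type mean profile and a
type's one-hot vector (selection at SPM ≥ 0.4), and the **z-score**
(x<sub>i</sub> − μ)/σ of per-type means (selection at z ≥ 1), plus a seeded
random detector that matches another detector's set sizes.

Evaluation: PCA (first two components) of the marker-restricted matrix →
k-means (k = t, 100 restarts) scored against the known labels with NMI,
purity and adjusted Rand index; gold-standard agreement via ranked
precision–recall (AUPRC), ROC (AUROC) and a 1,000-draw random-overlap
z-test.

## Worked example

Simulate a 5-type × 3-replicate dataset with 10 planted markers per type
over 200 background genes, detect markers, and benchmark:

```sh
markerselect simulate --seed 42 --noise-sd 1 --n-background 200 --out sim
markerselect detect --expression sim/expression.tsv \
    --annotation sim/annotation.tsv --out markers.tsv
head -4 markers.tsv
```

```
gene_id	sample_type	score	cut1	cut2	detector
M_T1_008	T1	0.023829	3	15	mgfr
M_T1_010	T1	0.028477	3	15	mgfr
M_T1_006	T1	0.030779	3	9	mgfr
```

`M_T1_008` is called a marker of type `T1`: its three highest values are
exactly the three `T1` replicates (`cut1 = 3`), and the mean of the
following block is 2.4 % of the top-block mean (`score 0.023829`, very
specific).  Evaluating MGFR against the planted gold standard and the SPM
baseline:

```sh
markerselect evaluate --expression sim/expression.tsv \
    --annotation sim/annotation.tsv --gold sim/gold.tsv \
    --detector mgfr --detector spm --seed 42 --out report.tsv
```

The report's clustering row shows mean NMI 0.9987 over 100 k-means restarts
on the 51 MGFR markers; every type's gold row has AUPRC = AUROC = 1.0 with
overlap p-values below 1e-48, while SPM selects far larger sets
(127–132 genes/type) with AUPRC 0.80 on `T2` — MGFR's ranking separates the
true markers more cleanly.

The same workflow is available as scikit-learn estimators:

```python
from markerselect import MGFRSelector
sel = MGFRSelector(cutoff=1.0).fit(X, y)   # X: samples x genes, y: type labels
sel.markers_      # per-type ranked MarkerCall lists
X_markers = sel.transform(X)               # restrict to the marker union
```

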