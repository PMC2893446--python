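# omiclink

Headless linked-view analysis of integrated omics studies: gene
expression, copy-number states (array CGH / SNP calls) and clinical data
— including censored survival — organized in one data manager, analyzed
with a combinatorial-data-analysis toolbox, and rendered as fully linked,
testable views exported to deterministic SVG.

It is aimed at translational researchers and methodologists who want the
*engine* of an interactive multi-omics explorer — linked brushing,
clustering/seriation/biclustering, gain/loss profiles along chromosomes,
eventcharts — as a scriptable, reproducible library rather than a GUI.

## What it computes

* **Distances & hierarchical clustering** — euclidean / manhattan /
  Pearson / Spearman (`d = 1 − r`), Lance–Williams agglomeration with
  single, complete, average and Ward linkage; dendrogram cutting.
* **k-means** with seeded restarts; **seriation** by first principal
  component, classical MDS, or exact optimal leaf ordering (the
  2^(n−1)-flip dynamic program).
* **Biclustering** — Cheng–Church δ-biclustering on the mean squared
  residue
  `H(I,J) = mean_{i,j} (a_ij − a_iJ − a_Ij + a_IJ)²`
  with multiple-node deletion (threshold α·H), single-node deletion,
  node addition and seeded masking; and exact **Bimax** enumeration of
  inclusion-maximal all-ones submatrices.
* **Cluster agreement** — confusion matrix, exact diagonal-maximizing
  sort via optimal assignment, adjusted Rand index.
* **Linking** — marker↔gene mapping by closed-interval overlap, and
  selection propagation (monotone, idempotent closure) across every
  registered dataset and result: the headless form of linked brushing.
* **Views** — heatmap with clinical annotation bars, dendrogram,
  barchart, histogram, eventchart (per-subject lines, terminal tick =
  observed event), correlation matrix, confusion plot, and a chromosome
  browser of per-marker gain/loss frequencies; every graphic is a scene
  of provenance-tagged primitives serialized to SVG byte-reproducibly.
* **Synthetic studies** — a seeded generator planting subgroup
  signatures, an additive bicluster, copy-number segments with exact
  carrier fractions, and exponential survival, with a full ground-truth
  record.

## Worked example

```python
from omiclink import compare
from omiclink.fixtures import StudyDesign, simulate_study
from omiclink.unsupervised import (pairwise_distance, hierarchical_cluster,
                                   cut_dendrogram, cc_biclusters)
from omiclink.views import aberration_frequencies

study = simulate_study(StudyDesign(seed=1))

D = pairwise_distance(study.expression, "euclidean", axis="columns")
part = cut_dendrogram(hierarchical_cluster(D, "average"), 2)
print("ARI vs planted groups:",
      compare.adjusted_rand(part.as_dict(), study.truth["group_of"]))

b = cc_biclusters(study.expression, delta=0.1, max_biclusters=1, seed=1)[0]
print("first bicluster:", b.shape, "MSR =", round(b.score, 4))

f = aberration_frequencies(study.states, study.marker_features, "1")
seg = study.truth["segments"][0]
print("gain fraction on planted segment:",
      f[f.marker.isin(seg["markers"])].gain.unique())
```

prints

```
ARI vs planted groups: 1.0
first bicluster: (25, 12) MSR = 0.06
gain fraction on planted segment: [0.5]
```

— the two planted patient groups are recovered perfectly from
expression alone; the first δ-bicluster is essentially the planted
20 × 15 additive block (plus a few accidental members) at a residue
well under δ; and every marker inside the planted chromosome-1 gain
segment shows a gain frequency of exactly 0.5 = 30 carriers / 60
samples.

The same pipeline is available from the shell:

```sh
omiclink simulate --seed 1 --out study/
omiclink cluster  --dir study/ --metric pearson --linkage average --out run/
omiclink report   --dir study/ --seed 1 --out report/   # all views as SVG
```

Every run directory contains a `manifest.json` (parameters, outputs,
warning count) sufficient to replay the run bit-identically.

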