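# fatph

Topological analysis of CT attenuation patches that separates left-atrium
**epicardial fat** tissue from **non-fat** tissue. Epicardial adipose tissue
falls in a characteristic Hounsfield-unit (HU) window (≈ −190 to −30 HU) and
forms smooth, connected blobs on CT, whereas the same window applied to
non-fat tissue picks up only scattered, fragmented pixels. Persistent
homology turns that difference into numbers: the filtration sweep of a fat
patch produces a *narrow* range of Betti numbers and persistence-diagram
points close to the diagonal (many short-lived features), while a non-fat
patch produces a *wide* Betti range and points far from the diagonal.

The package is aimed at researchers in quantitative cardiac imaging and
topological data analysis who need a small, fully tested reference pipeline —
and at anyone who wants estimator-style TDA building blocks that compose
with scikit-learn.

## Method

For a 2D patch of HU values the pipeline computes persistent homology in
dimensions 0 (connected components, β₀) and 1 (loops, β₁) over Z/2:

* **Cubical sublevel filtration** (default): one vertex per pixel at its HU
  value, edges between 4-adjacent pixels and squares on 2×2 blocks at the
  maximum of their vertices; the sublevel sets {HU ≤ t} are swept over all
  thresholds t.
* **Vietoris–Rips filtration**: pixels inside the HU window become a planar
  point cloud; a simplex enters when all pairwise distances are ≤ ε
  (distance/diameter convention — balls of radius ε/2 touch at distance ε),
  truncated at `eps_max`.

Diagrams are computed by standard boundary-matrix column reduction; for
large images a union-find fast path (Kruskal pairing for β₀, planar duality
for β₁) produces the identical diagram. From a diagram D the pipeline
derives Betti curves β_k(t) = #{(b, d) ∈ D_k : b ≤ t < d}, the per-group
Betti range (min, max over t), and diagonal statistics (persistence d − b,
L∞ diagonal distance (d − b)/2). Two groups are contrasted descriptively:
which group has the larger Betti-number range and which sits closer to the
diagonal.

Because no patient CT data are distributed, a seeded generator emulates the
study conditions: per group, 8 subjects × 36 patches of 32×32 HU values
(Gaussian texture; the fat group smooth and centered in the HU window, the
non-fat group rough and mostly outside it), concatenated 6×6 into one
192×192 patch per subject.

## Worked example

```python
from fatph import PipelineConfig, generate_cohort
from fatph.pipeline import analyze_cohorts

cfg = PipelineConfig(make_plots=False).with_seed(0)
fat, nonfat = generate_cohort(cfg.fat, cfg.nonfat)
report, _ = analyze_cohorts(fat, nonfat, cfg)
print(report.to_text())
```

prints

```
Group comparison of topological summaries

  fat: Betti range 0-258, mean persistence 16.95, median diagonal distance 5.258 (3857 intervals)
  nonfat: Betti range 0-4864, mean persistence 39.8, median diagonal distance 17.13 (32054 intervals)

  betti_max ordering: fat < nonfat
  betti_max difference: 4606
  larger betti_max: nonfat
  larger mean_persistence: nonfat
  larger median_diagonal_distance: nonfat
```

Reading: over the attenuation sweep the fat group's component count (β₀)
never exceeds 258, while the fragmented non-fat group reaches 4864 — the fat
Betti range is the narrow one, and its diagram points sit ~3× closer to the
diagonal. The full `run_pipeline` / `fatph run` entry point additionally
writes every intermediate artifact (patch CSVs + manifest, masks, point
clouds, diagram TSVs, Betti-curve CSVs, diagram/barcode plots, JSON report).

The same stages are available as scikit-learn transformers:

```python
from sklearn.pipeline import Pipeline
from fatph.transformers import CubicalPersistence, BettiCurveTransformer

features = Pipeline([
    ("ph", CubicalPersistence()),
    ("curve", BettiCurveTransformer(k=0, n_bins=64)),
]).fit_transform(list_of_patches)   # (n_samples, 64) Betti-curve features
```

## Command line

```
fatph generate --seed 0 --out cohort/          # synthetic cohorts + manifest
fatph mask --hu-lo -190 --hu-hi -30 patch.csv  # 0/1 window mask
fatph ph --backend cubical patch.csv           # persistence diagram TSV
fatph betti --dim 0 patch_diagram.tsv          # Betti curve CSV + range
fatph compare dg_fat.tsv dg_nonfat.tsv         # two-group report
fatph run --config cfg.yaml --seed 0           # full pipeline
```

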