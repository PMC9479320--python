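# Methods

## Problem and model

Epicardial adipose tissue on CT occupies a characteristic attenuation window
(fat ≈ −190 to −30 HU) and is spatially coherent; non-fat tissue contributes
only sparse, spatially independent pixels to that window. The package
quantifies this with persistent homology over Z/2 in dimensions 0
(components) and 1 (loops): a one-parameter family of nested complexes is
built from each patch, and the birth/death of homology classes across the
sweep is summarized as persistence diagrams, barcodes, Betti curves
β_k(t), per-group Betti ranges, and diagram-vs-diagonal statistics.

Two filtrations are implemented:

* **Cubical sublevel (default).** Vertex construction: one vertex per pixel
  at its HU value, edges between 4-adjacent pixels and squares on 2×2
  blocks, each at the maximum of its vertices; the parameter is the
  attenuation threshold t. This is the image-native realization of sweeping
  "all possible thresholds": β₀(t) counts connected regions of {HU ≤ t},
  driven by the local minima of the attenuation field. When a patch contains
  negative HU values the filtration axis is shifted so the minimum maps to
  0; the shift is recorded on the complex and diagram.
* **Vietoris–Rips.** In-window pixels become a planar point cloud
  ((x, y) = (column, row), 0-based, Euclidean metric); a simplex enters when
  all pairwise distances are ≤ ε, up to dimension 2, truncated at
  `eps_max`. The filtration is indexed by *distance* (diameter convention):
  balls of radius ε/2 around two points first intersect when their distance
  equals ε, so one unit of the axis is one pixel of separation. Triangles
  enter at the maximum of their edge lengths (flag complex).

## Persistence computation

`reduce_complex` is the standard column-reduction algorithm over Z/2 with
cells processed in (filtration value, dimension, id) order — the
deterministic tie-break — and columns held as integer bitmasks. Plain
reduction was chosen over twist/clearing optimizations: the complexes here
are small and clarity/testability dominate. Zero-persistence intervals are
retained internally (interval count per dimension then equals the positive
cell count) but excluded from reported diagrams by default (`keep_zero`
retains them); essential classes carry death = +∞, serialized as `inf` and
capped only for plotting.

`cubical_persistence` is an equivalent fast path for images, needed because
full-scale patches (192×192 ≈ 147k cells) are routine:

* dimension 0 by Kruskal-style union-find over pixels and 4-adjacency edges
  with the elder rule (the younger component dies at the merge value);
* dimension 1 by planar duality: a sublevel loop encloses a bounded
  component of the complement, so dim-1 intervals are read off a descending
  union-find sweep over the complement squares of the image padded with one
  +∞ border layer. Squares sharing an edge connect when the larger of the
  two shared pixels exceeds the threshold; squares sharing only a corner
  connect through that pixel. A complement component created (descending)
  at value d that merges into an older one at value b is exactly a loop
  born at b and filled at d.

Property tests assert that the two routes produce identical interval
multisets on random images, and both are checked against a third,
independent oracle: `betti_at` computes β₀ by union-find and β₁ as
(#edges − rank ∂₁) − rank ∂₂ by GF(2) elimination (for planar cubical
complexes the Euler formula β₁ = β₀ − (V − E + F) gives the same number and
is tested as an invariant).

Betti curves use the half-open convention β_k(t) = #{b ≤ t < d}. The
threshold grid for range summaries is the sorted distinct critical values
plus one value below the minimum, so the curve attains 0 at the start of
the sweep and the range (min, max) is invariant under grid refinement.

## Bottleneck distance

Finite off-diagonal points are matched between diagrams (L∞ cost) or
projected to the diagonal (cost = persistence/2); essential intervals must
match in count and are paired by sorted births. Two exact solvers: an
exhaustive matching enumerator (≤ 8 off-diagonal points per diagram) and a
binary search over the finite candidate set of costs with Hopcroft–Karp
feasibility on the augmented bipartite graph, used automatically for larger
diagrams and cross-checked against the enumerator on random small diagrams.
Stability (distance ≤ sup-norm perturbation of the image) is verified on
random nonnegative patches, where no axis shift interferes with the bound.

## Synthetic study conditions

The generator emulates the cohort the analysis assumes — per group
8 subjects × 36 patches of 32×32 HU — with a stationary Gaussian random
field, the simplest texture model with a tunable correlation length:

| group  | mean (HU) | sd (HU) | smoothing σ (px) |
|--------|-----------|---------|-------------------|
| fat    | −110      | 25      | 2.0               |
| nonfat | −10       | 45      | 0.0               |

Fat defaults place ≈99.8% of pixel mass inside the adipose window and the
smoothing produces large coherent blobs (few sublevel minima → narrow Betti
range); non-fat defaults leave ≈33% of pixels in-window with no spatial
correlation (many minima → wide range). Smoothing uses periodic boundaries
so the marginal sd can be restored exactly by dividing by the kernel's l2
norm; values are clipped to the valid CT range [−1024, 3071] HU. Per-patch
streams derive from `SeedSequence(base_seed, (group, subject, patch))`:
bit-reproducible, mutually independent. The emulated contrast reproduces
the *direction* of the group difference (narrower fat range, fat diagrams
closer to the diagonal); the absolute Betti values depend on texture
parameters no real-data measurement constrains, so passing tests support
the method's correctness and the qualitative contrast, not any quantitative
claim about patient CT. Real CT features the generator does not emulate:
anatomy-correlated structure, partial-volume edges, scanner noise spectra,
inter-patient variability.

## Pipeline defaults and open choices

* Per-subject patches are concatenated row-major 6×6 into one 192×192 patch
  and analyzed as a single unit (`concatenate=False` analyzes per patch);
  a square tiling keeps the point cloud compact and isotropic.
* Default backend is `cubical`. Under a Rips filtration on masked pixel
  clouds, max β₀ over the sweep equals the number of in-window pixels —
  larger for fat patches by construction — so the component-count contrast
  that separates the groups is a property of the attenuation sublevel
  filtration; the Rips backend remains available (default `eps_max` 10 px,
  bounding the O(n²) edge set) for small clouds and fixtures.
* The Betti range defaults to dimension 0 (component counts plausibly span
  the observed magnitudes; loop counts would not); `homology_dim`/`--dim`
  overrides. Diagram-diagonal statistics default to dimension 1, where
  "many small holes" is the discriminating signature.
* Group aggregation: Betti range is (min over subjects, max over subjects)
  of per-subject curves; diagonal statistics pool all subjects' intervals.
  Per-patient aggregation was the open alternative; pooling is reported
  because the group-level diagram is what the comparison plots.
* HU window endpoints are inclusive ([−190, −30] default), the standard
  fat-threshold convention.
* The comparison is descriptive (ranges, ordering, contrasts); no
  hypothesis test is attached.

## Numerical notes and limitations

* Filtration ties are broken by (value, dim, id); diagrams as multisets are
  unique regardless, and all TSV/CSV outputs are byte-deterministic under a
  fixed config + seed (floats printed with fixed `%.10g`).
* Degenerate inputs: empty masks yield empty clouds and empty diagrams (an
  empty cloud is an error for `vietoris_rips` itself); constant patches
  yield a single essential component; diagrams with no finite interval in a
  dimension report diagonal statistics as not-available rather than failing.
* Homology is computed only in dimensions 0 and 1; the data are planar.
  No α/witness complexes, no representative cycles, no Wasserstein
  distances, no cohomology.
* The generic reduction is quadratic in the worst case and intended for
  clouds of up to a few hundred points; large images must use the fast
  cubical path (the pipeline does this automatically).
* Test and acceptance problem sizes: oracle-equivalence sweeps use 50
  clouds of ≤ 12 points and 50 images of ≤ 8×8 (sizes where brute-force
  GF(2) ranks are exact and instant); the group-contrast check runs the
  full default conditions (2 × 288 patches) over 20 seeds.
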