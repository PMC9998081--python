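# Methods

## Problem and model

foldspot asks whether a per-residue feature — a binary indicator such as
"site under positive selection", or any numeric score — is spatially
clustered on a folded protein, and where. Residue positions are
represented by their CA coordinates; spatial structure enters only
through pairwise CA (or heavy-atom) distances, so all results are
invariant under rigid rotation and translation of the model.

### Neighbor weights

A spatial weights matrix `W` defines each residue's neighborhood:

- `binary_radius` (default): w_ij = 1 iff 0 < d(i,j) ≤ r. Default
  r = 8 Å on CA coordinates, a standard residue-contact convention; on an
  ideal α-helix this makes residues i±1..i±4 the neighbors of i.
- `knn`: w_ij = 1 iff j is among i's k nearest residues (ties broken by
  the lower residue index, for determinism). May be asymmetric.
- `decay`: w_ij = exp(−d(i,j)/λ), a continuous neighborhood.

Self-inclusion (diagonal 1) and row standardization (nonzero rows sum
to 1) are orthogonal switches. A residue with no neighbor inside the
radius keeps an all-zero row and triggers a warning rather than an
error: its statistic is 0 and its permutation p-value is 1, which is the
honest answer for an isolated point.

### Local statistics

**Getis-Ord (default).** For residue i,

    z_i = [Σ_j w_ij x_j − x̄ W_i] / (s · sqrt[(n Σ_j w_ij² − W_i²)/(n−1)])

with x̄ and s the mean and population standard deviation of x and
W_i = Σ_j w_ij. With self-inclusive weights this is the G\* variant
(sums include j = i); without, the G variant, where residue i is also
excluded from x̄ and s and n is replaced by n−1. On complete
self-inclusive weights the numerator and variance both vanish and z is
defined as 0.

**Local Moran.** I_i = (x_i − x̄)/m₂ · Σ_j w_ij (x_j − x̄) with
m₂ = Σ_k (x_k − x̄)²/n and the self-weight forced to zero. The identity
Σ_i I_i = S₀ · I_global (S₀ = Σ_ij w_ij) is asserted in the test suite
to 1e-9. By default Moran's I runs on row-standardized weights, G\* on
raw binary weights; both are switchable.

### Inference

Significance uses **conditional permutation**: for residue i the value
x_i stays fixed while the remaining values are permuted over the
remaining positions, and

    p_i = (1 + #{permutations with statistic ≥ observed}) / (1 + n_perm),

so p_i ≥ 1/(n_perm+1) and is never zero. Defaults: n_perm = 999,
seed = 42, one-sided "greater" (hotspot = high values clustering;
significant cold-spots are not flagged unless `alternative="two_sided"`
is chosen). The implementation exploits the fact that the permuted
feature is the same multiset, so x̄, s and m₂ are permutation-invariant
and only the weighted neighbor sum Σ_j w_ij x_j varies; each residue's
null draw therefore reduces to a matrix-vector product. Permuted
statistics equal to the observed one up to a relative 1e-9 round-off
count as exceedances — binary features generate many exact ties, and
dropping them would make p anti-conservative.

Multiple testing uses the Benjamini–Hochberg step-up rule
(q_(i) = min_{j≥i} m·p_(j)/j, capped at 1); a residue is flagged hot
when q ≤ rate **and** its statistic is positive. A zero-variance feature
is a hard error, not NaN: silent NaNs would poison the FDR step.

### Clustering

Clustering uses coordinates only (no feature values), on the CA
positions of the selected residues. Back-ends:

- **HDBSCAN** (default), delegated to scikit-learn, Euclidean metric,
  `min_cluster_size=5` by default. We set `allow_single_cluster=True`,
  deviating from the canonical HDBSCAN default, because the common input
  here is a hotspot selection forming one compact region — the useful
  answer is "one cluster", not "all noise". With fewer selected residues
  than `min_cluster_size` everything is noise by construction.
- **MCL**, implemented from scratch: add self-loops (1.0),
  column-normalize, then iterate {matrix power `expansion` (2),
  elementwise power `inflation` (2.0), column renormalization, pruning of
  entries < 1e-6} until the largest entry change drops below 1e-6 or 100
  iterations (non-convergence is flagged in the result's params, never
  raised). The contact graph connects selected residues within
  `mcl_radius` = 8 Å. Clusters are connected attractor sets of the
  converged matrix; a node attracted to several attractors joins the
  first by index.

Labels are renumbered by decreasing cluster size (ties: lowest member
residue index); −1 marks noise and unselected residues.

## Synthetic data

The generators produce the geometries the tests and the acceptance
script measure on:

- `make_helix(n)`: ideal CA helix, rise 1.5 Å/residue, twist 100°,
  radius 2.3 Å (α-helix-like dimensions). Deterministic.
- `make_two_blob(n1, n2, separation, seed)`: two isotropic Gaussian CA
  clouds, s.d. 2 Å — a desk-scale stand-in for two spatially distinct
  residue groups (default 20+20 points 50 Å apart).
- `make_two_chain(n, separation)`: two parallel strands (chains A, B)
  4 Å apart, CA+CB per residue, for interface and heavy-atom tests.
- `plant_feature(fold, center, radius)`: binary track, 1 within `radius`
  of the center residue's CA — a spatially contiguous signal of the kind
  produced by clustered substitutions.

These fixtures are geometrically clean: no missing residues, no altloc
disorder, no B-factor noise, no realistic backbone chemistry. Passing
tests therefore demonstrate the statistics, inference, clustering and
I/O contracts — not robustness to crystallographic artifacts, which real
PDB files can still exercise through the parser's policies (first-seen
altloc, MODEL 1 only, HETATM/hydrogen exclusion, hard error on missing
CA with an explicit first-atom fallback).

## Numerical and design choices

- Residue identity is the 0-based position in file order; author
  numbering and insertion codes are metadata (used in PDB output and
  defattr addressing only). Feature vectors are interpreted in this
  index space.
- PDB coordinates are written with 3 decimals, so one round trip
  quantizes coordinates to ≤ 5e-4 Å error and is idempotent afterwards.
- pLDDT outside [0, 100] warns and keeps the value, flagging the model's
  provenance — tolerating real-world files while surfacing the anomaly.
- The n = 5 enumeration check defines the exact p-value as count/total
  over all 4! conditional permutations (identity included), which is the
  quantity the (1+c)/(1+n_perm) Monte-Carlo estimator converges to.
- Scene rendering is deliberately display-free: the deterministic JSON
  document (embedded PDB text, resolved atom serials, per-residue hex
  colors via min–max normalization over the named palette) is the
  testable surface; WebGL/raster display belongs to external viewers.
  Palette names resolve through a small built-in table ("binary",
  "Set2", "Set2_r", "greys", "viridis"); the hex values are this
  package's own choices.
- Problem sizes in the test suite and acceptance script — 60–100-residue
  helices, 999 permutations, 50 null simulations, 10⁴ permutations
  against exact enumeration at n = 5 — were chosen as the smallest sizes
  at which the measured properties (FDR control, recovery, agreement
  with oracles) are stable and informative; the whole suite runs in
  seconds to minutes on one CPU.

## Known limitations

- PDB input only (no mmCIF); first MODEL only; no structure alignment,
  bond perception or protonation.
- Hotspot inference assumes exchangeability of the feature over residues
  under the null; features with strong sequence autocorrelation of
  non-spatial origin will inflate apparent spatial clustering.
- The G-variant statistic and two-sided testing are provided but less
  exercised than the G\*/one-sided default.
- MCL on large dense graphs is O(n³) per iteration; it is intended for
  selections (tens to hundreds of residues), not whole proteomes.
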