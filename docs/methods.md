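# Methods

## Data model

The unit of observation is a bacteriological sample from one subject (a
dam or one of her puppies) in one family at one time point, through one
matrix: rectal swab, meconium (a puppy's birth rectal swab, T0 only),
vaginal swab or mammary secretion (dams at T0/T2 only; colostrum and milk
are one category distinguished by the time point). Each isolate carries a
genus (canonicalized: whitespace collapsed, trailing "spp."/"sp." removed,
capitalized), an optional species string and a CFU growth class (low 1–10,
moderate 11–30, high ≥31 colonies per 10 µL; 0 is "no growth").

Growth class and species never enter the analysis: the *codified pattern*
of a sample is the binary vector over the genus universe with 1 where the
genus was isolated at least once. The universe is the sorted union of
genera over the **whole dataset** (not per family), so patterns are
comparable across families; a fixed external list can be supplied for
cross-dataset work. Samples in which nothing grew are kept as all-zero
rows — they are biologically real and must not crash the pipeline.

## Distances

The association of two patterns is the phi coefficient, i.e. the Pearson
correlation of the two 0/1 vectors, computed exactly from integer counts
of the 2×2 co-presence table. Shared absences count: genera never seen in
either sample's family still contribute to the d cell, exactly as Pearson
correlation on full patterns does.

The distance transform is d = (1 − φ)/2, the simplest affine map bounding
distances in [0, 1] with identical patterns at 0 and complementary ones at
1. Because it is affine and order-preserving, every rank-based downstream
result (heterogeneity orderings, rank-sum p-values, linkage topologies) is
unchanged under the alternative d = 1 − φ, which is exposed as an option
and asserted equivalent in the tests.

φ is undefined when a pattern is constant (all-zero or all-one row). The
default `constant_policy="neutral"` treats such pairs as unassociated
(φ = 0, hence d = 0.5) unless the two rows are identical (d = 0), and logs
the event; `"error"` aborts instead. Neutrality keeps sterile-looking
samples in the analysis without inventing association for them.

## Heterogeneity and the exact rank-sum test

Within-family heterogeneity at a time point is the arithmetic mean of the
C(n, 2) pairwise distances among the family's samples collected then; it
is undefined (and reported with its n) when n < 2. Two matrix-filter
presets exist: `all` (every matrix type) and `rectal_only`
(rectal + meconium), the latter removing any bias from mixing sampling
matrices. Dams' samples are pooled with the litter's by default; a flag
excludes them.

Each later time point's per-family heterogeneity values are compared with
the birth values by an unpaired two-sample Wilcoxon rank-sum test (the
family trajectories are arguably paired, but the dispersion values are
treated as independent group samples; a signed-rank variant is a possible
extension, not implemented). The null distribution is obtained by full
enumeration of all C(n_a+n_b, n_a) assignments of the observed pooled
mid-ranks to group A, so with ties the null is conditional on the observed
tie pattern. The two-sided p doubles the smaller tail and caps at 1.
Enumeration is used whenever C(n_a+n_b, n_a) ≤ 200 000 — the study-scale
6-vs-6 comparison (924 assignments, minimum two-sided p = 2/924) is always
exact — otherwise a tie-corrected, continuity-corrected normal
approximation takes over. Three comparisons are reported raw by default;
Holm adjustment is available behind a flag.

## Clustering

Per family, samples are agglomerated bottom-up with complete linkage
(inter-cluster distance = maximum member-pair distance), implemented as
the textbook cubic algorithm — family dendrograms have at most a few
dozen leaves, so clarity wins over asymptotics. Ties in the minimum
inter-cluster distance are broken by the lexicographically smallest pair
of cluster creation indices, making runs bit-reproducible (ties are
measure-zero for real data but common in small binary datasets). Heights
inherit the [0, 1] distance scale and are exported as ultrametric Newick
trees (leaf-to-root path length = root height). The cophenetic span of a
leaf set (`subtree_height`) quantifies the claim that day-60 samples join
at lower heights than birth samples.

## Ordination and polygon areas

Two-dimensional scaling is classical Torgerson MDS: B = −½·J·D⁽²⁾·J, with
coordinates the top-two positive eigenvectors scaled by √eigenvalue. Phi
distances need not be Euclidean, so negative eigenvalues can occur; they
are dropped without an additive-constant correction, and the reported
*goodness* is the share of positive-eigenvalue mass retained by the two
axes. Axis signs follow a deterministic convention (the largest-magnitude
entry of each column is positive). Ordination is run **per family**; the
dispersion of one time point's samples in the family's 2DS plane is the
convex-hull area of their coordinates (hulls are what drawn bounding
polygons enclose, and the hull is the canonical order-free reading; fewer
than three distinct non-collinear points give area 0). Per-family areas
are pooled across families per time point and T30/T60 are compared
against birth with the same exact rank-sum test. Areas from different
family ordinations share the [0, 1] distance scale but not a common
2D stress; goodness is reported alongside as the caveat.

## Synthetic generator

The generator emulates the emulated study's design: 6 families; litter
sizes uniform on 3–8; a 13-genus pool (the genera named for the study's
rectal, meconium, colostrum/milk and vaginal isolates); per family a
latent profile π_f with independent Bernoulli(ρ = 0.4) genus membership;
each sample observes π_f with independent per-genus flips at the
time point's rate ε_t. The convergent preset uses ε = 0.40 (T0), 0.30
(T2), 0.15 (T30), 0.10 (T60) — decaying noise is the minimal mechanism
that makes within-family heterogeneity shrink. Meconium additionally
drops truly-present genera with probability δ0 = 0.5, mimicking the
sparse enteric flora of birth samples (dropout, not a different profile,
is the simplest mechanism for that sparsity). Dams' vaginal and mammary
samples are generated from π_f at the birth-level rate ε_T0 at both T0
and T2, reflecting that these matrices stay noisy proxies of the family
profile. Growth classes are drawn uniformly (they carry no signal). An
optional `shared_core` forces chosen genera into every profile (the
near-ubiquitous coliform/enterococcal pattern); it is off by default.

The null preset holds ε constant at 0.25 (mid-range between the
convergent extremes) **and sets δ0 = 0**: with meconium dropout active,
T0 cells would be systematically more heterogeneous than later ones and
the preset would not be a null for the convergence test.

What the generator does *not* model: genus covariance (flips are
independent), abundance, environmental/kennel flora beyond the shared
pool, strain-level transmission, litter attrition. Passing power and
calibration checks on this generator therefore show that the statistics
behave correctly under the assumed noise model, not that real kennel
data satisfy that model.

Two samples of one family at rate ε disagree per genus with probability
2ε(1−ε); inverting the mean pairwise Hamming disagreement h̄ gives the
flip-rate estimator ε̂ = (1 − √(1 − 2h̄))/2, clipped to [0, 0.5]. The
recovery harness estimates from rectal/meconium samples with δ0 = 0
(other matrices deliberately carry ε_T0 noise at T2) and pools h̄ across
families before the single inversion: near ε = 0.4 the inversion is
almost flat in h̄, so inverting noisy per-family means first would bias
the estimate upward.

## Problem sizes and numerical conventions

The Monte-Carlo suites run at the study scale they characterize: 200
replicates for the power of the two convergence findings (T60
heterogeneity and T60 polygon area, both at p < 0.01), 500 replicates for
type-I error at α = 0.05, 200 for flip-rate recovery (tolerance 0.03 on
the median). The type-I band [0.02, 0.07] reflects the exact test's
attainable size at 6-vs-6 (46/924 ≈ 0.0498) plus ~2σ binomial noise at
500 replicates. Oracle equivalences are tested to 1e−12 (phi vs Pearson,
enumeration p, linkage heights) and 1e−9 (planar distance recovery by
MDS). Distance matrices are symmetrized and their diagonals zeroed after
a 1e−12 tolerance validation; MDS eigen-decomposition uses the symmetric
solver.

## Pipeline

`run_pipeline` executes, per matrix-filter preset (both by default):
encoding → distances → heterogeneity + birth comparisons → per-family
complete linkage + Newick → per-family 2DS + areas + area comparisons,
writing each stage artifact (presence TSV, distance CSV, heterogeneity
CSV, Newick, coordinates CSV, area CSV) so every stage is independently
inspectable, plus a JSON report embedding the configuration, package
version, input checksum and every p-value and area. Everything downstream
of the input file is deterministic; reruns differ only in the timestamp.
Degenerate events (constant patterns, undefined heterogeneity cells,
sub-3-point polygons) are logged, not fatal. Exit codes: 0 ok,
2 validation error, 3 stage failure.

## Known limitations

* Presence/absence at genus level discards abundance and species signal
  by design; the growth classes are carried but unused analytically.
* The unpaired rank-sum ignores the family pairing across time points
  (conservative when trajectories are consistent).
* Per-family ordinations are not Procrustes-aligned; areas are compared
  across families on the shared distance scale only.
* Negative-eigenvalue mass in the MDS is dropped, which can understate
  distances for strongly non-Euclidean inputs (monitored via goodness).
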