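# Methods

## Problem setting

A soft X-ray tomogram is a 3-D grid of linear-absorption-coefficient (LAC)
values; carbon/nitrogen-dense organelles are brighter than cytosol.  A
semantic mask marks every voxel of one organelle class without separating
individuals.  The tool converts (tomogram, semantic mask, morphology flag)
into an instance mask under two structural assumptions: organelle interiors
contain intensity maxima (one per sphere-like organelle, one per
constituent blob of a columnar one), and organelles of the modelled classes
are either sphere-like or chains of blobs along a gently bending axis.
Branched, looped or sheet-like shapes (mitochondrial loops, ER, Golgi) are
out of scope.

All computation is in voxel units on the (z, y, x) lattice; physical
distances enter only through the voxel size (default 35 nm isotropic, the
common sampling of whole-cell SXT reconstructions).

## Pipeline and parameters

Per 26-connected mask cluster, cropped with 2 voxels of padding:

* **Scale bank.**  Ten denoised copies of the crop, Gaussian kernels
  truncated to 3×3×3 and renormalized to unit sum, σ = 1…10 voxels.  The
  truncated kernel preserves constant fields, so LAC means are unbiased.
  σ outside 1…10 adds no usable scales at this kernel size: the 3³ support
  saturates towards a box mean well before σ = 10.
* **Candidate centres.**  A voxel is a local maximum when it is ≥ all 26
  in-grid neighbours and > at least one (plateaus yield no candidate, which
  keeps flat degenerate inputs finite).  Maxima are collected per scale and
  deduplicated by position, keeping the smallest σ.  Candidates off the
  mask are discarded.
* **Radius.**  The overlapping ratio a_r = V_m(r)/V_s(r) compares mask
  voxels within centre distance r (strict) against the discrete sphere
  volume (lattice count, mask-independent).  r scans from r_min = 1.5
  voxels (19-voxel discrete ball; smaller blobs are unresolvable) to half
  the crop diagonal in Δr = 0.5 steps; the scan stops at the first
  a_r < 0.8 and keeps the previous r.  On ragged masks a_r can be
  non-monotone; stopping at the first drop keeps the rule deterministic.
  For an isolated sphere of radius R the estimate converges to ≈1.08 R,
  for a blob inside a long cylinder to ≈1.23 R — a deliberate slight
  over-estimate that lets blobs tile their organelle.
* **Greedy selection.**  Candidates ranked by raw centre intensity
  (descending; ties by lexicographic centre) are kept when their centre is
  strictly farther than each kept blob's radius from its centre.
* **Columnar grouping.**  A candidate reference vector exists for a blob
  whose two nearest unassigned neighbours are near-collinear with it
  (|cos θ_adj| > cos 30°): the sum of the two centre-to-centre vectors when
  θ_adj ≤ 90°, the difference otherwise; the globally best |cos| nucleates
  an instance (ties to the lowest blob id).  Growth admits an unassigned
  blob when any vector to a member is within 30° of the reference axis
  (sign-insensitive) *and* shorter than the sum of the two blob radii,
  i.e. the probe spheres overlap.  The member set updates after each
  addition; the closure is order-independent.  The overlap reach is the
  package's reading of the growth rule: the alternative reach of one blob
  *diameter* per blob spans more than three inter-blob spacings once radii
  carry their systematic ≈1.2× over-estimate, and on touching-column
  fixtures its transitive closure provably swallows every column in
  contact — a regime incompatible with the method's published behaviour of
  occasional pairwise merges.  Nucleation repeats until no triplet
  qualifies; leftovers are K-Means-clustered on coordinates with
  K ∈ 1…min(8, n) chosen by the largest second difference of the
  within-cluster sum of squares (n ≤ 2 or zero variance force K = 1; with
  n = 3 the only interior K is 2).  K-Means uses a fixed seed and 10
  restarts for reproducibility.
* **Voxel assignment.**  Every mask voxel joins the blob minimising
  distance/radius (ties to the lower blob id) and takes its group's label,
  within its own cluster only.  Scores are scale-invariant under uniform
  radius rescaling.  A cluster with no surviving blob (flat intensity,
  all maxima screened out) becomes one instance anchored at its
  intensity-weighted centroid, preserving the partition invariant:
  instance support equals semantic support exactly, labels contiguous.

## Baselines

Connected-regions labeling assigns one label per 26-component.  The
watershed baseline floods negated (optionally σ = 1 Gaussian-smoothed)
intensity restricted to the mask, seeded from strict in-mask 26-maxima;
components without any seed fall back to one label each.  Plain local-maxima
seeding is intentionally simple — its over-segmentation of noisy tomograms
is the documented failure mode the blob-based tool is compared against.

## Synthetic benchmark

Real benchmark construction would attach manually isolated organelle
instances from experimental masks; those are not distributable, so the
generator produces parametric phantoms:

* **Spheres:** solid balls, radius uniform in 3–8 voxels (insulin-vesicle
  scale at 35 nm sampling), quadratic intensity falloff from a peak
  (uniform 0.35–0.45, the reported LAC scale of dense vesicles) to the
  0.10 background at the mask edge.  Quadratic falloff is the simplest
  smooth profile with a single strict interior maximum.
* **Columns:** chains of 3–7 equal-radius balls (radius uniform 3–5
  voxels, the mitochondrial tubule scale at 35 nm) along a polyline bending
  ≤ 10° per step, centres 1.5 radii apart — overlapping enough to form one
  smooth tube, spaced enough that each ball keeps its own interior maximum
  under max-compositing; per-ball peaks are drawn independently.

A dataset composites five phantoms in a 100³ volume: each new phantom is
placed so it touches the previously placed one (26-adjacency, random
contact point) with voxel overlap below 10% of either instance; overlap
voxels keep the later label.  Gaussian voxel noise (sd 0.01) is added last.
Everything derives from one integer seed through numpy's PCG64 generator.

What the phantoms do *not* emulate: reconstruction artifacts (missing
wedge, rings), ragged hand-segmented mask boundaries, intra-organelle
texture, and irregular real shapes.  Passing benchmarks therefore show that
the pipeline resolves touching, noise-perturbed, unimodal-per-blob
organelles — not that it reaches the same scores on experimental tomograms,
where ragged masks shrink radius estimates and irregular intensity adds
spurious blobs.

## Evaluation

Instances are matched one-to-one greedily by descending IoU computed from
the joint label histogram.  AP at threshold t is TP/(TP+FP+FN)·100 with TP
the matches of IoU ≥ t; mAP averages t = 0.50…0.95 (step 0.05).  The
score-free form is the standard AP for unscored segmentation masks — the
tool emits no per-instance confidences, so ranked-precision AP is
undefined.  Per-instance statistics are voxel volume and mean raw LAC;
conditions are compared with the two-sided, tie-corrected Mann-Whitney U
test, p-values reported raw (no multiplicity correction across the few
pairwise contrasts).

## Problem sizes and determinism

Benchmarks run 10 datasets per morphology (5 phantoms, 100³ voxels); the
property fuzz uses 100 datasets of 2–4 phantoms at 64³.  These sizes keep a
full validation run in the tens of seconds on one CPU while exercising
every contact-resolution code path; accuracy on the 100³ benchmark is
insensitive to the volume size because clusters are processed
independently.  All randomness (generator, K-Means, benchmark seeds)
derives from explicit integer seeds; repeated runs are bit-identical.

## Known limitations

* Merging of touching columnar instances whose axes happen to align within
  30° remains possible; it is the dominant error mode on the columnar
  benchmark (and of the method generally).
* The watershed baselines score zero on the columnar phantoms: every
  constituent ball carries its own interior maximum by construction, so
  watershed fragments each column into per-ball basins whose IoU with the
  whole-column truth is below 0.5.  On real smooth-tube mitochondria the
  smoothed watershed performs better; the bumpy-chain phantom is
  pessimistic for it.
* Radius estimation assumes locally convex mask geometry; deeply concave
  clusters can over-estimate radii.
* No sub-voxel refinement of centres or radii; no anisotropic scales.
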