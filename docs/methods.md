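# Methods

This note documents the models, conventions, numerical choices and
known limitations behind `gsirads`. It complements the README (what the
package does) and the API docstrings (how to call it).

## Geometry and conventions

All volumes are carried with a 4×4 voxel→world-mm affine in the RAS+
convention (world *x* grows toward the patient's right). Files in other
on-disk orientations are reoriented on load; keeping a single internal
convention removes an entire class of hemisphere-sign bugs. The voxel
volume is |det| of the affine's 3×3 block (mm³), which is invariant
under rotation and reduces to the product of spacings for axis-aligned
grids.

Masks are strictly binary after loading. When a mask has fractional
values (the usual situation after linear resampling or nonlinear
warping into the reference space), it is binarized at a threshold of
0.5 — the majority rule for linearly interpolated binary labels. The
threshold is exposed because there is no universal convention for
re-binarizing warped masks; any fixed threshold in (0, 1] leaves an
already-binary mask unchanged.

Grid compatibility between a patient mask and the atlas requires equal
shapes and affines agreeing elementwise within 1e-4 — tight enough to
catch a wrong resampling, loose enough to tolerate float32 headers.

Spatial normalization itself (native → reference deformation) is
deliberately out of scope: the package consumes masks already
resampled into the reference space by external registration tooling,
and likewise treats automated segmentation models as upstream producers
of mask files.

## Hemisphere features

The reference space is symmetric with the midsagittal plane at world
*x* = 0. Tumor voxels with center *x* < 0 count to the left hemisphere
and *x* > 0 to the right; centers within half a voxel of the midplane
belong to neither, since such voxels straddle the plane and any
assignment would be arbitrary. Laterality is the hemisphere with the
larger tumor volume; an exact volume tie — which occurs for genuinely
midline tumors — is assigned `right`, deterministically. The tie rule
itself is arbitrary but must be fixed and documented, because midline
tumors with near-equal hemisphere volumes are a real discordance mode
between raters.

A patient whose mask contains no focus of countable size (see below)
has laterality `none`. The laterality index (V_L − V_R)/(V_L + V_R) is
still defined whenever any tumor voxel falls in either hemisphere; it
is NaN only for a fully empty (or fully midplane) mask. Undefined
scalars are NaN throughout, never exceptions: empty masks are an
expected cohort occurrence (automated models occasionally detect no
tumor), and the pipeline must classify them, not crash on them.

## Multifocality

Connected components use 26-connectivity by default (the common
neuroimaging choice for lesion masks; 6 and 18 are available because
the convention is not universal). Components are sorted by volume with
size ties broken by scan order of the first voxel, making downstream
decisions deterministic. A tumor is multifocal when the second-largest
component has volume ≥ 0.1 mL and its minimum voxel-center distance
from the largest component is ≥ 5 mm; both comparisons are inclusive,
reading "minimum volume" and "minimum distance" as attained bounds.
The distance is a set distance (minimum over voxel pairs, computed via
a k-d tree), not a centroid distance — two lobes of a dumbbell-shaped
tumor have centroids far apart but distance zero.

The number of foci counts components of at least 0.1 mL
(configurable). A floor is applied because single-voxel speckle from
resampling would otherwise inflate the count; 0.1 mL matches the scale
the multifocality rule itself treats as meaningful. A consequence is
the invariant: zero countable foci ⇔ laterality `none`.

## Location profiles and resectability

The per-patient overlap percentage is tumor-relative: 100 × |tumor ∩
structure| / |tumor|. Parcel percentages therefore sum to ≤ 100 (tumor
voxels outside every parcel are allowed); a structure is involved when
any tumor voxel overlaps it. The structure-relative alternative
(fraction of the parcel occupied) answers a different question and is
not what a surgical report needs.

Expected resectability masks the resection probability map with the
tumor and sums: ERV = Σ p(v)·v_voxel. ERTV = V_norm − ERV and
RI = ERV / V_norm use the reference-space (normalized) volume, because
the resection probability map lives in reference space; mixing native
volume into the ratio would silently conflate brain-size differences
with resectability. ERV is monotone in the map and RI ∈ [0, 1] by
construction.

## Cohort maps and permutation FDR

The tumor probability map is the voxel-wise mean of binary masks, so
every value is exactly k/n. For paired two-rater comparison, the
observed voxel-wise difference Δ(v) is the mean over patients of
(a_i − b_i)(v) ∈ {−1, 0, +1}. The null of exchangeable raters is
realized by independently swapping each patient's (a, b) pair with
probability ½ per permutation — a per-patient sign flip of the paired
difference. The per-voxel FDR is the empirical exceedance ratio

    FDR(v) = mean_perm #{u : |Δ_perm(u)| ≥ |Δ_obs(v)|}
             ───────────────────────────────────────────
                   #{u : |Δ_obs(u)| ≥ |Δ_obs(v)|}

clipped to [0, 1]: a Storey-style plug-in estimator without π₀
correction, the simplest estimator consistent with a permutation-based
FDR. Voxels with zero incidence under both raters are excluded from
the comparison by default (their difference is structurally zero and
would dilute the denominator); they are reported with FDR 1. The
estimator is seed-reproducible and invariant under exchanging the two
rater lists.

## Agreement statistics

- **Concordance** — trace over total of the paired contingency table.
- **McNemar (2×2)** — exact form throughout, because discordant counts
  in practice range from a handful to hundreds: odds ratio b/c on the
  discordant cells, p-value from the exact binomial test of b in b + c
  at ½, and CI by mapping the Clopper–Pearson interval on b/(b + c)
  through p/(1 − p).
- **Ordinal ratings, two related raters** — the Friedman rank statistic
  for k = 2 treatments with tie correction collapses algebraically to
  the sign chi-square (P − N)²/(P + N), df 1, where P and N count pairs
  with A > B and A < B; ties drop out. The test suite verifies this
  identity against the textbook rank computation.
- **TOST** — for proportions observed on the same n patients: normal Z
  statistics against ±bound with SE from the two marginal proportions,
  and the 90% interval d ± 1.6449·SE, so that equivalence at α = 0.05
  holds exactly when the interval lies inside (−bound, +bound). (Such
  equivalence intervals are sometimes labeled "95% CI" in clinical
  reports; the interval reported here is the 90% interval that the
  TOST decision rule actually uses.) For paired means: one-sample t
  statistics against ±bound, df = n − 1; zero-variance input
  degenerates to an exact comparison of the mean against the bounds.
- **ICC** — one-way random-effects, single measurement
  (MSB − MSW)/(MSB + MSW) for k = 2, CI from F-distribution bounds on
  MSB/MSW; cross-checked against an independent implementation in the
  test suite.
- **Bland–Altman** — bias = mean(x − y), its 95% CI from the standard
  error of the mean, limits of agreement bias ± 1.96·sd.
- **Pearson** — r with Fisher-z 95% CI.

The marginal-SE TOST for proportions ignores the pairing (a paired
TOST would use the discordant-cell variance); it is kept because it is
the form whose intervals match the published validation analysis this
suite is designed to reproduce.

## Synthetic data: what it emulates and what it does not

The generator produces, deterministically per seed: an ellipsoidal
brain exactly mirror-symmetric across x = 0 (even x-dimension, so the
midplane falls between voxel columns); a Voronoi parcellation from
seeds sampled in one hemisphere and mirrored, giving exactly paired
parcels (n = 2 recovers the hemispheres themselves); tube-shaped
mirrored tract pairs; and a resection probability map that is either
constant (making RI an exact oracle) or radially increasing toward the
surface, reflecting that superficial tissue is more often resected
than deep central tissue.

Tumors are unions of spheres specified in world mm. Cohort defaults
emulate a surgical glioblastoma population: main-focus radii 14–24 mm
(median normalized volume around 30 mL), 23% of patients with a
satellite focus, and a native grid scaled by ~0.96 per axis so native
volumes run smaller than normalized ones (patient brains are mostly
smaller than the reference brain). Second-rater noise is structured
rather than i.i.d.: a uniform boundary dilation/erosion of up to ±2 mm,
satellite components dropped with probability 0.15, and a small false
component added with probability 0.03 — the modes in which human and
automated segmentations actually disagree (cysts and boundary calls,
missed satellites, vessels mistaken for tumor).

What passing tests on these fixtures shows: the geometry, feature
definitions, statistics, and their interactions are implemented
correctly, and planted effect sizes (volume scale, focality
disagreement rate, intra-pair correlation) are recovered. What it does
not show: performance on real MRI — no intensity model, no
gadolinium-enhancement appearance, no registration error, no
inter-subject anatomical variability, and spherical tumors are far
more regular than real infiltrative margins.

## Problem sizes in the shipped checks

The brute-force oracle comparisons (flood-fill components, O(n²)
minimum distances, per-voxel overlap tallies, probability-map tallies)
run on 100 random masks of 8–14 voxels per axis — small enough for the
exhaustive references to stay exact and fast. Parameter-recovery runs
use 200-patient cohorts on the default 64³ × 2 mm grid; the null-case
FDR check uses 50 identical pairs with 500 permutations; the CLI
determinism check uses a 6-patient cohort on a 32³ × 4 mm grid. The
recovery tolerance for the planted radius scale (±0.01 on the
cube-root volume ratio) reflects sphere-voxelization bias at 2 mm
resolution, which is ~0.005 at these radii.

## Known limitations

- Laterality for exactly balanced midline tumors is a convention, not
  an estimate; other implementations may legitimately differ on those
  patients.
- The foci count's 0.1 mL floor is a design decision; published counts
  that include sub-0.1 mL satellites will differ for speckled masks.
- The permutation-FDR estimator is the plug-in exceedance ratio; it is
  conservative relative to π₀-corrected estimators.
- The exact McNemar CI can differ in the final digit from CIs produced
  by other interval constructions (mid-p, Wilson-transformed).
- DICOM ingestion, registration, intensity processing and segmentation
  itself are out of scope by design.
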