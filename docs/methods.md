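# Methods

This note documents the models and procedures implemented in
`florascreen`, the defaults chosen where the design was genuinely open,
and what the synthetic-data tests do and do not establish about real data.

## Rosette shape descriptors

A plant-day observation is a binary raster (foreground 8-connected,
background 4-connected) with a mm/pixel scale. The largest 8-connected
component is taken as the rosette; smaller components are dropped and
counted in the QC flags. All geometry is computed in a single millimetre
frame with the origin at the top-left pixel corner and pixel centres at
half-integer coordinates.

**Area and perimeter.** Area is the foreground pixel count times the
pixel area. For the perimeter, raw edge-pixel counting systematically
overestimates smooth boundaries, so the default estimator is the
marching-squares sub-pixel contour whose vertices are smoothed with a
circular moving average (window 5) before summing segment lengths. On
reference shapes this estimator is within 1% of the closed form (filled
square −0.96%, disc of radius 100 px +0.30%, radius 30 px −0.11%, 10:1
rectangle −0.87%). A 4-direction Crofton estimator and the raw
edge-pixel count remain available through `method=`; Crofton was rejected
as the default because it underestimates a square's perimeter by 5.5%.
Within `describe()` the perimeter is additionally clamped from below by
the convex-hull perimeter — a true geometric bound for connected regions —
which keeps the invariant roundness2 ≥ roundness exact on coarse rasters.

**Convex hull.** The hull is taken over the outer corners of boundary
pixels, so a filled k×k square has hull area exactly k². Hull area is the
shoelace value reported by Qhull; hull perimeter the vertex-to-vertex sum.

**Skeleton.** `skimage.morphology.skeletonize` thinning, with length
counted as 1 per orthogonal and √2 per diagonal neighbour pair. Thinning
has a directional bias, so the mask is first brought to a canonical
orientation among its eight dihedral transforms; skeleton length is then
exactly invariant under 90° rotations and mirroring, matching the
symmetry guarantees of the other descriptors.

**Descriptors.** roundness = 4πA/P²; roundness2 = 4πA_h/P_h² on the
hull; compactness = A/A_h; SOL = L²/A. Eccentricity is the moment-ellipse
definition √(1 − λ₂/λ₁) from the eigenvalues of the second-central-moment
matrix, giving values in [0, 1) rather than an axis ratio. RMS compares
the hull with the disc of equal area centred at the centroid:
`area(hull Δ disc) / area(hull ∩ disc)`, evaluated by exact polygon
clipping against a 256-segment circle polygon (relative area error
< 10⁻⁴). Ratios pushed above 1 by discretisation are clipped to 1 and
flagged.

**Isotropy and tip detection.** The isotropy polygon is a
reconstruction: the original instrument's definition is unpublished
beyond "a polygon drawn on top of the rosette". Tips are local maxima of
the centroid-distance profile along the boundary, resampled on a 720-bin
angular grid (outermost radius per bin), with peaks required to be ≥ 10°
apart and radially prominent by ≥ 5% of the maximum radius; the polygon
connects the actual boundary points of those peaks in angular order and
isotropy is its 4πA/P². Masks with fewer than three tips fall back to
the hull polygon and are flagged. The centroid used for the profile is
kept in the contour coordinate frame so that the detection commutes with
raster mirror/rotation symmetries.

A note on one closed form: the RMS of a unit square against its
equal-area centred disc is 0.1993 by the circular-segment closed form
(intersection 0.9094), which the implementation reproduces to 0.001 on a
100-px raster square.

## Longitudinal genotype comparison

Daily descriptor values are modelled by ordinary least squares on
polynomials of the day axis, centred and scaled to [−1, 1] to keep
order-6 designs well conditioned. The pooled model fits one curve to both
genotypes; the genotype model adds, per non-reference genotype, an
intercept and all polynomial interactions (order + 1 coefficients — the
genotype is allowed to change the whole curve, not just its level). The
comparison is a Gaussian likelihood-ratio test, 2Δℓ = n·log(RSS₀/RSS₁),
referred to χ² with df equal to the coefficient difference. Default
polynomial orders per descriptor: area 3, perimeter 3, compactness 4,
roundness 5, roundness 2 5, isotropy 6, eccentricity 6, RMS 6, SOL 3.

The OLS likelihood treats repeated measures within a plant as
independent. No random-effects structure is imposed; instead a
plant-level permutation bootstrap (`bootstrap_genotype_p`, 1000
label permutations of whole plants by default) is provided as a
safeguard when within-plant correlation is a concern. Under the
generator's independent-noise conditions the χ² test is well calibrated:
1000 null simulations at n = 20 plants per genotype over days 10–20
give a rejection rate within 0.05 ± 0.02, and a 3-SD area offset is
detected at p < 0.001 in ≥ 99% of 200 runs (sizes chosen to keep the
suite fast while leaving the binomial noise well inside the bands).

Flowering traits (leaves at bolting, days to bolting) are analysed per
trait by one-way ANOVA plus Dunnett many-to-one contrasts against the
control, using the multivariate-t implementation in
`scipy.stats.dunnett` with a pinned integration seed so outputs are
reproducible. With a single contrast the procedure reduces to the
two-sample t test. Flower-defect counts are displayed as percentages
rounded half-up (43/80 → 54%, 6/50 → 12%) with Fisher's exact test and
odds ratio against the control genotype.

## Expression screen

The screen is a plain ratio filter, not a moderated test: per category,
log2(FL) − log2(R) against the developed-rosette reference; genes with a
missing or non-positive value in either column are excluded and counted
in a coverage report. Up-regulation requires log2FC strictly greater
than 1, so an exactly 2-fold gene is excluded. Multiple probes per gene
collapse by the per-condition maximum before the ratio — a gene counts
as enriched if any probe shows enrichment. Up-sets feed exclusive-region
Venn counts (all 2^k − 1 membership patterns; ≤ 6 sets) and an ordered
union.

## qPCR quantification

2^−ΔΔCt with technical replicates averaged first and multiple reference
genes combined by the arithmetic mean of their per-gene mean Cts (the
combining rule across the three standard reference genes is not
standardised; the arithmetic mean on the Ct scale is the geometric mean
on the linear scale). Classification bands: fold < 0.1 knock-out,
0.1 ≤ fold ≤ 0.5 knock-down (both boundaries inside the band), fold > 2
up-regulated, otherwise unchanged. Replicate SDs are reported per
(sample, gene) as QC. Amplification-efficiency correction is out of
scope.

## RING domain screen

Candidate spans come from InterProScan-style TSV annotations restricted
to six member databases (Gene3D, SUPERFAMILY, ProSiteProfiles, SMART,
Pfam, ProSitePatterns); rows from other databases are kept but flagged.
The acceptance rule is any-hit: a protein with at least one in-scope
signature is tested by direct ligand location on the sequence, and
proteins whose signature cannot be validated form a separate
"signature-only" tier rather than being silently discarded.

Ligand location searches the canonical spacing
`M1-x2-M2-x(9..39)-M3-x(1..3)-M4-x(2..3)-M5-x2-M6-x(4..48)-M7-x2-M8`
with positions 1, 2, 3, 6, 7, 8 fixed to cysteine and positions 4 and 5
drawn from {C, H, D, S, T} by default; both the gap bounds and the
allowed residue sets are configuration (`RingSpacing`), not constants.
When several placements exist the leftmost-longest wins: smallest first
ligand position, then largest last position, then the lexicographically
smallest tuple — a deterministic rule that the test suite checks against
an exhaustive enumeration oracle.

Subtypes are read from an editable YAML rule table
(`florascreen/data/ring_classes.yaml`): with canonical cysteines at the
six fixed positions, the (position 4, position 5) pair decides HC, H2,
v or C2; otherwise a substituting D, S/T or G at any metal position
names the class (position 4 checked before 5), and anything else is
non-canonical. G-type is included for completeness although rare in
practice. The classifier is total on arbitrary residue 8-tuples.
Census reconciliation strips isoform suffixes, partitions the old set
into matched and dropped (with evidence codes: merged, no-RING-domain,
absent-from-db, pseudogene, split-new-locus, transposable-element) and
reports unresolved drops explicitly.

## Synthetic data: what it emulates and what it does not

The rosette renderer implements the phyllotactic leaf cycle: leaves
initiate in pairs (first two pairs decussate, then a 137.5° spiral) at a
default interval of 2.5 days from day 6, each expanding along a logistic
schedule (rate 0.9 day⁻¹, midpoint 1.6 days after emergence, mature
length 16 mm). A leaf is a thin petiole quadrilateral (32% of its
length) plus an elliptical blade (width/length 0.68), optionally with
radial serration; a small central disc keeps the silhouette connected;
anti-aliasing is off so masks are hard 0/255. Defaults were set so the
rendered wild type lands in published wild-type descriptor ranges —
roundness2 within ~0.7–1.0 with an early eccentricity peak decaying over
days 10–20, roundness in 0.1–0.5, SOL below 50 — since raw instrument
data are not available to fit against. Genotype effects enter as
multipliers on blade length and initiation interval.

The longitudinal generator does not go through images: it draws values
from per-descriptor wild-type mean curves plus genotype offset/slope
effects and iid Gaussian noise (area SD 30 mm²), which is exactly the
assumption set of the χ² test it calibrates. Passing calibration
therefore shows the statistics are correct under their own model, not
that real rosette measurements are independent within plants — that gap
is why the block bootstrap exists. The expression generator separates
planted folds (> 2) from null folds (< 2) by construction so recovery
is exact rather than probabilistic; the Ct generator shifts the mutant
target by −log2(fold); the proteome generator fills non-ligand positions
from an alphabet free of C/H/D/S/T so the planted ligand placement is
provably the only consensus match. Real data are messier on every one
of these axes; the generators test correctness of the computations, not
robustness to biological noise.

All generators are pure functions of their seed and parameters;
re-running any pipeline stage with an unchanged configuration reproduces
every tabular output byte for byte.

## Known limitations

* Isotropy (and to a lesser degree RMS and roundness 2) reconstructs an
  unpublished instrument definition; absolute values may differ from the
  original analyzer even where dynamics agree.
* The growth test's χ² reference distribution ignores within-plant
  correlation; use the bootstrap p-value when that matters.
* The expression screen is a ratio filter without variance moderation,
  faithful to the screening design it reproduces.
* Dunnett p-values rely on numerical multivariate-t integration; they
  are reproducible (pinned seed) but carry ~10⁻⁴-level integration
  error.
* The RING consensus bounds are one published parameterisation; proteins
  with unusual spacing fall to the signature-only tier rather than being
  reclassified.
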