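# Methods

`paskin` reimplements a photoacoustic (PA) dermal-imaging analysis chain as a
tested library: dual-wavelength unmixing of hemoglobin and melanin, per-voxel
oxygen saturation from an amplitude ratio, slice-wise structure extraction,
skeleton-based 3D morphometry with equal-depth layering, and Spearman
age-trend statistics. Because no imaging cohort ships with the package, a
synthetic phantom/cohort generator with exhaustively known ground truth
serves as the test bed; every analysis stage is validated against quantities
the generator records at construction time.

## Coordinate and unit conventions

Arrays are `(z, y, x)` with `z = 0` at the skin surface, z increasing into
the tissue. Voxel spacing is explicit everywhere, in micrometres; the
synthetic default is isotropic 30 µm (the lateral scan step of the emulated
acquisition; the axial reconstruction pitch is not a fixed device constant,
so it is a parameter rather than an assertion). Depth intervals are half-open
`[lo, hi)`; indices are 0-based. Amplitudes stay in arbitrary units (A.U.);
no SI conversion is attempted, since the features of interest are relative
comparisons across subjects.

## Oximetry

With `S` the oxygen saturation and `T` total hemoglobin, the PA amplitude at
wavelength λ is taken proportional to the absorption coefficient
`µ_a(λ) ∝ T·(ε_Hb(λ) + S·ε_ΔHb(λ))`, where `ε_ΔHb = ε_HbO2 − ε_Hb`. The
amplitude ratio `q = µ_a(λ1)/µ_a(λ2)` is independent of `T` and of any shared
scale (fluence, Grüneisen parameter), and inverts in closed form:

    S = (ε_Hb(λ1) − q·ε_Hb(λ2)) / (q·ε_ΔHb(λ2) − ε_ΔHb(λ1))

λ1/λ2 default to 575/586 nm. Degenerate spectra — `ε_Hb` and `ε_ΔHb`
proportional across the pair — make every ratio uninformative and raise at
call time. Voxels are invalidated when the λ2 amplitude sits below a floor
(default 1e−6 of the volume maximum — a pure numerical guard), when the
closed form is non-finite, or when the raw value falls outside [−0.25, 1.25];
surviving values are clamped to [0, 1]. The accept-then-clamp window reflects
that small overshoot is ordinary measurement noise while gross violations
signal a non-hemoglobin voxel.

The pipeline additionally excludes voxels whose λ2 amplitude is below
`so2_floor_frac` (default 0.15) of the volume maximum before layer
averaging: under amplitude noise, ratios at near-zero denominators are
meaningless, and a segmentation mask may overhang the true vessel boundary
by a voxel. SO2 averaging is masked to segmented vessels by default; the
unmasked variant is available (`so2_mask_to_vessels=False`) since either
reading of the original protocol is defensible.

## Structure extraction

Channels: the vessel channel is `max(PA(575) − PA(650), 0)` (650 nm is
melanin-dominated; amplitudes are non-negative energies, so negative
differences clip to zero); the melanin channel is the 650 nm volume,
restricted by default to the superficial 0–300 µm band where the epidermal
melanin structures live.

Segmentation is deliberately a pluggable per-slice contract — each
horizontal (xy) plane is segmented independently and restacked along z —
because the reference extraction in the emulated study is a learned model
whose training data is unavailable. The deterministic `baseline` backend
does per-slice Gaussian smoothing (σ = 1 voxel), hysteresis thresholding at
`(k_low, k_high) = (3.5, 5.0)` times a robust slice scale, and 1-voxel hole
filling; restacked components smaller than 27 voxels (3³, below device
resolution) are removed in 3D (26-connectivity). The robust scale is
`median + MAD` of the smoothed slice, floored at 0.12 of the slice maximum:
depth attenuation is constant within a slice, so the floor makes the high
threshold track roughly half the local signal amplitude on structure-bearing
slices (preserving caliber), while the median+MAD term keeps noise-only
slices thresholded well above their noise floor. A `truth` passthrough
backend allows downstream morphometry to be validated independently of
segmentation quality.

## Morphometry

* **Volume** — exact voxel count, optionally per layer.
* **Thinning** — topology-preserving 3D skeletonization. Parallel thinning
  can annihilate perfectly even-symmetric structures (an even-diameter
  digital cylinder erodes to a 2×2 bar that then vanishes); components that
  lose their skeleton are re-thinned on a copy dilated by a one-sided corner
  element — breaking the symmetry while moving the centerline at most half a
  voxel — and clipped back to the mask.
* **Direction** — principal axis (SVD) of skeleton voxels within a ±3-voxel
  path window along the skeleton graph, sign-normalised; endpoints get
  one-sided windows, isolated voxels have no direction and are excluded from
  thickness means.
* **Radius** — the mask is sampled nearest-neighbour on a bounded 2D grid
  (0.5-voxel pitch) in the plane orthogonal to the local direction; the area
  is the 8-connected in-plane component containing the centre times the
  sample-cell area, and the radius is `sqrt(A/π)`. The sampling window is
  seeded from the Euclidean distance transform and doubles while the
  component touches the window border, so it never truncates a cross-section.
  Layer thickness is the arithmetic mean of per-skeleton-voxel radii (the
  per-voxel reading of "average of the radii"; a coarser per-cross-section
  average would be an equally valid but different estimator).
* **Branches** — after pruning terminal twigs shorter than 3 voxels
  (thinning artefacts), skeleton voxels of 26-degree ≥ 3 are clustered by
  adjacency; clusters closer than five mean voxel pitches (about one vessel
  diameter) consolidate by single linkage, because a junction zone where a
  branch departs at a shallow angle can fragment into several nearby
  degree-3 voxels that are anatomically one bifurcation. Clusters are
  assigned to layers by centroid depth.
* **Analysis depth** — automated stand-in for a per-subject visual choice:
  D − 1 is the deepest slice whose structure fraction is at least 10% of the
  peak slice's fraction; an explicit override preserves a manual workflow.
* **Layers** — D splits at ⌊D/3⌋ and ⌊2D/3⌋ into three half-open layers
  whose widths differ by at most one slice; layer 3 is computed internally
  but excluded from reported features, since its lower boundary is the least
  reliable part of the depth choice.

## Synthetic phantoms and the cohort simulator

Vessels are random mostly-horizontal branching trees: polyline centerlines
with per-point radii, rasterized as a union of capsules (a voxel belongs to
a vessel when its centre lies within the local radius of the axis). Children
attach at interior points of the parent at a 30–75° departure angle and at
~0.8× the parent radius; bifurcations are only recorded when the child has
at least three segments, so the recorded count equals the degree-≥3 node
count of the polyline adjacency graph, which tests recompute independently.
Growth is collision-checked (2.5-voxel clearance between non-adjacent
branches, no self-folding, bounded per-step turning), so distinct branches
never merge in the mask and every mask junction corresponds to a constructed
bifurcation — the trees are "clean" by design, which is what makes exact
branch-count oracles possible. Radii below 1.5 voxels are refused rather
than silently clipped.

Melanin structures are tori (vertical axis, ring radius ≫ tube radius)
confined to the 0–300 µm band and rejection-placed to be disjoint, emulating
the annular melanin pattern around pores; their voxel count is the melanin
volume truth.

The forward model is single-scatter and absorption-proportional:
`amplitude(λ) = Σ_c ε_c(λ)·C_c · exp(−µ_eff·depth)` plus additive Gaussian
noise of sd `noise_sd` × the maximum noiseless amplitude, clipped at zero.
No acoustic propagation, PSF, or fluence modelling: the analysis operates on
reconstructed amplitude volumes, and the per-voxel identity between
concentration and amplitude is exactly what lets oximetry be tested against
per-voxel truth. Default attenuation 0.4 /mm gives the ~2× surface-to-2 mm
amplitude span one expects of visible light in skin. The noise model is a
stand-in — real reconstruction noise is neither white nor Gaussian — so
noise-robustness results transfer to real data only qualitatively.

The default phantom spectra are stylized, not literature: hemoglobin strong
at 575/586 nm and weak at 650 nm, melanin flat between 575 and 650 nm so the
spectral subtraction cancels it exactly, and the HbO2/Hb difference changing
sign between 575 and 586 nm so the ratio inversion is well-conditioned. A
table of approximate literature molar absorption coefficients ships for
real-data use (`literature_spectra`); no test depends on it. All unit tests
use small hand-checkable toy spectra.

**Cohort simulator.** Each subject draws ground-truth parameters that are
exact monotone functions of age before noise: mean vessel radius increases
(+25% across 20→60 years at effect size 1), fine-vessel count decreases
(−35%), per-vessel SO2 decreases (−0.13 absolute, plus a within-subject
decline of 0.05 /mm of depth), melanin torus size increases (+35%).
Lognormal subject-level jitter (sd 0.25) is calibrated so the programmed
age–feature Spearman correlations land near |ρ| ≈ 0.5 — strong enough to be
detectable at n = 60, weak enough to be a realistic biological effect.
Ages are uniform over 20–60 years.

Trees are placed one at a time into the depth terciles of a designed
analysis depth (60 slices ≈ 1.8 mm on the default grid), each tree going to
the tercile whose cumulative truth volume is furthest below its calibrated
share — weights (1.3, 1.0, 0.55) for layers 1–3, so the ground-truth
layer-1 : layer-2 total-volume ratio is calibrated to 1.3, the dermis vs
dermis–subcutaneous boundary ratio the pipeline is expected to recover. The
first three trees go one to each layer (depth detection must always see all
three layers), a capped cohort-level residual carries over between subjects
to cancel rounding and crowding bias, and trees are hard-confined to their
tercile so the calibration survives the tercile bookkeeping. Layer-3 roots
sit in the lower half of their tercile so structure reaches the designed
depth and automated depth detection recovers it. The excluded third layer's
weight (0.55) is itself a free design choice: its only analytical role is to
give depth detection a floor to find.

What the generator does **not** emulate: acoustic reconstruction artefacts,
anisotropic resolution, motion, vessel tortuosity at sub-segment scale, skin
tone and fluence confounds, or inter-site anatomy. Passing tests therefore
demonstrate correctness of the computation chain under its own stated model,
not clinical validity on real scans.

## Statistics

Spearman rank correlation with mid-ranks for ties; two-sided p-values from
the t approximation `t = ρ·sqrt((n−2)/(1−ρ²))` (ρ = ±1 → p = 0), with exact
permutation enumeration used automatically for n ≤ 8 where the approximation
is weakest. Significance at α = 0.05 per test, no multiple-testing
correction by default (a Benjamini–Hochberg flag exists but is off,
mirroring the reproduced analysis); missing values are removed pairwise per
feature. Type-I error of the full per-feature surface is verified by
simulation (200 null cohorts) to sit within ±0.03 of α.

## Problem sizes

Desk-scale defaults are used throughout: 128×128 lateral × 64 depth voxels
(≈ 3.8×3.8×1.9 mm at 30 µm) rather than the full 9×9 mm field, cohorts of
40 (layer-ratio recovery) and 60 (trend recovery) subjects, 20 seeds for
branch-count recovery, and 200 replicate cohorts for the type-I simulation.
The full field size remains available through `VoxelGrid`.

## Known limitations

* The baseline segmenter is threshold-based; on real, artefact-laden scans a
  trained slice-wise model (the pluggable backend exists for this) would be
  needed to match human extraction quality.
* The radius estimator inherits a ~half-voxel dilation bias from smoothing-
  based segmentation and quantization; it is accurate to ≲15% for radii of
  3–8 voxels, degrading below 2 voxels.
* Oximetry accuracy depends strongly on the conditioning of the wavelength
  pair; with near-isosbestic pairs, amplitude noise is amplified severely,
  and per-layer means compress toward the middle of the accepted range.
* Branch counting reports junction clusters; counts for masks with genuine
  high-order junctions (degree > 3) or loops are defined but not separately
  validated.
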