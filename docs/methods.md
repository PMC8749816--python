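# Methods

## Scope

The package implements the analysis chain for intraoperative spectral online
monitoring (SOM) of interstitial photodynamic therapy: spectral quantity
extraction, diffusion-model inversion of the tissue absorption coefficient
between cylindrical diffuser fiber (CDF) pairs, light-transmission-zone
geometry, MRI overlap metrics, and nonparametric cohort statistics.  MRI
acquisition, mutual-information co-registration and manual segmentation are
out of scope: all volumes are assumed pre-registered to a common world frame
(only affine application and resampling plumbing is provided).

## Spectral assessment

* **Windows.** Treatment light 626–642 nm, fluorescence fit 650–750 nm, PpIX
  peak read-out 702–708 nm, noise estimation 500–550 nm (signal-free).
* **Noise level** is the standard deviation of the 500–550 nm window after
  removing its constant baseline.  The source analysis says only "noise
  level"; the s.d. choice matches the 3σ character of the detection criterion.
  RMS-about-zero and peak-to-peak were rejected (the former conflates baseline
  offset with noise, the latter is sample-size dependent).
* **Detectability**: peak intensity in the window strictly greater than
  3 × noise.  For fluorescence the criterion applies to the fitted PpIX
  component, so a large autofluorescence background cannot fake a detection.
* **Fluorescence unmixing** is non-negative least squares of the two
  normalized bases on 650–750 nm (negative PpIX amplitude is unphysical;
  plain least squares can produce it at low signal).  Weighting is uniform —
  the underlying counting noise is nearly constant across the narrow window.
* **Transmission ratio** `R = I_t,pre / I_t,post`.  When the pre signal is
  undetectable, R is defined as 0.  When only the post signal is undetectable,
  the substituted denominator is the detection-threshold-equivalent integral
  intensity `3 × noise × 16 nm` (a peak at exactly the threshold across the
  full window); R is then a *lower bound* and is flagged as such.  The ratio's
  relative uncertainty under two independent 8 % intensity errors is
  √2 · 8 % ≈ 11.3 %, below the stated 20 % bound.

## Diffusion forward model and inversion

* **Point-source Green's function** `Φ(r) = 3(μ_a+μ_s′)/(4πr) · exp(−μ_eff r)`
  with `μ_eff = √(3 μ_a (μ_a + μ_s′))`.  This is the standard
  infinite-medium diffusion solution; it reproduces the published worked
  examples (detection-threshold distances of 19 mm at μ_a = 0.06 mm⁻¹ and
  10 mm at 0.212 mm⁻¹, normalized to 0.02 mm⁻¹ at 10 mm).
* **Extended source**: 5 points per mm of active section, placed at the
  centers of 0.2 mm sub-intervals.  Center placement avoids double-weighting
  the endpoints; the alternative (endpoints inclusive) changes pair
  intensities by < 0.1 % at clinical distances.
* **Units**: geometry in mm throughout; the emitter length enters the
  calibrated intensity in cm (the single unit boundary), matching P₀'s units
  of cm·counts/ms.
* **Lookup inversion**: per-pair table over μ_a = 0.0001…0.75 mm⁻¹ at 0.0001
  steps, `μ_s′` fixed at 2 mm⁻¹.  Intensities are strictly decreasing, so
  nearest-intensity matching is equivalent to bisection; ties break toward
  smaller μ_a.  Measured intensities outside the table clip to the nearest
  end with a warning.  Round-trip error is at most one grid step.
* **Non-detections**: the smallest μ_a whose tabulated intensity is at or
  below the threshold-equivalent intensity — a lower bound on the true
  absorption.  Δμ_a inherits the bound qualifier; pairs undetectable *before*
  therapy get no Δμ_a at all.
* **Ratio-anchored mode**: for a case without valid absolute calibration
  (e.g. a deviating detection filter), `I(μ_a,post) = I(μ_a,pre)/R` is solved
  on the table from a supplied μ_a,pre; P₀ cancels.
* **Calibration**: P₀ is the least-squares scalar fitted to phantom
  measurements with known optical properties, unweighted (the stated 8 %
  uncertainty is multiplicative, so relative weighting is uniform).
* **Hemoglobin forward scenarios**: tissue μ_a = (bvf/100) · Σ fractionₛ·μ_a,s
  with pure-species coefficients at 635 nm HbO₂ 0.2477, Hb 2.1149, MetHb
  8.1073 mm⁻¹ and a capillary preset of 85 % HbO₂ / 15 % Hb
  (0.0053 mm⁻¹ per % bvf).

## Light transmission zones

* **Definition**: convex hull of two capsules of radius 2.1 mm around the
  active sections.  Because the hull of two equal-radius capsules equals the
  hull of the two axis segments dilated by the radius, voxelization reduces
  to an exact point-to-segment-hull distance test — no mesh library needed.
  The original derivation used tetrahedral meshes; voxel intersection at
  0.1 mm (configurable) gives equivalent volumes, validated against a
  Monte-Carlo point-membership oracle to < 1 %.
* **Radius derivation**: per-voxel contribution of a voxel to a pair's signal
  is the product of the two fluence fields (canonical parallel pair, 10 mm
  separation, μ_a = 0.02 mm⁻¹).  Voxels are accumulated in decreasing order
  until 67 % of the total; the capsule radius is matched by equal volume
  against the analytic hull volume (Steiner formula for the parallel case).
  Result: 2.09 mm ≈ 2.1 mm, stable across 0.1–0.4 mm grids.
* **Singularity clipping**: source-point distances are clipped at half a
  voxel when evaluating fluence fields on a grid.  Voxel centers can coincide
  exactly with discretized source points, and the unclipped 1/r divergence
  would otherwise dominate the contribution sum (a purely numerical artifact;
  the voxel-averaged fluence is finite).
* A grid coarser than 0.5 mm is refused for the radius derivation — it cannot
  resolve the ~2 mm zone boundary.
* **Caveat**: voxelized volumes of grid-aligned geometries carry a half-voxel
  surface offset (≈ 1 % at 0.1–0.2 mm grids); randomly oriented geometries do
  not show this bias.

## MRI metrics

* Dice `2|∩|/(|A|+|B|)`, Jaccard `|∩|/|∪|` (algebraically `DSC/(2−DSC)`), and
  overlap volume `|∩|/min(|A|,|B|)` on voxel masks; volumes are voxel count ×
  voxel volume, no partial-volume weighting.  Masks on different grids are
  resampled nearest-neighbor onto the first argument's grid.
* Normalized T1 intensity `I_T1` = mean over the hyperintensity mask divided
  by the mean over the union of seven 8 mm white-matter reference spheres;
  invariant to global gain, background neglected.
* **Hyperintensity strength** = (overlap volume / *zone* volume) × I_T1.  The
  phrase "fraction of T1 hyperintensity within the zone" is ambiguous
  (fraction of the zone vs. of the lesion); the zone denominator keeps the
  measure ≤ I_T1 and matches the reported magnitude (≈ 0.20); the lesion
  denominator is available via `denominator="hyp"`.
* Maximum lesion diameter = 3-D maximum Feret diameter over surface-voxel
  centers (the source does not define its measure; Feret is the standard
  "largest caliper" reading).

## Statistics

* Eligibility: pairs with minimum interfiber distance ≤ 19 mm — the distance
  at which transmission should be detectable even at the highest normal-tissue
  absorption (0.06 mm⁻¹).
* Mann–Whitney U, two-sided: exact null distribution for combined n ≤ 12
  without ties, tie-corrected normal approximation otherwise.  The "linear
  two-sided Spearman regression" wording conflates two methods; the package
  reports the Spearman rank test (inference) *and* an OLS line with R²
  (description) side by side.
* Quantiles are linear-interpolation (type 7); IQR endpoints depend on this
  convention, so it is fixed and documented.
* Lower-bound transmission ratios enter rank tests at their bound value
  (ranks are insensitive to the unknown excess) and stay flagged in output.
* All p-values are descriptive; no multiple-testing correction.

## Synthetic world

Defaults state the emulated cohort: 2–10 near-parallel fibers at ~11 mm
spacing (cohort medians 10–13.2 mm), 20/30 mm diffusers at 200 mW/cm,
background μ_a = 0.02 mm⁻¹ (3.8 % capillary bvf), μ_s′ = 2 mm⁻¹, spherical
absorber blobs (Δμ_a 0.04–0.15 mm⁻¹, radii 2.5–5 mm) placed between fiber
pairs, hyperintensity label = union of blob supports, complete post-iPDT PpIX
photobleaching, and 8 % multiplicative intensity noise per spectrum plus an
additive baseline noise.  The additive noise floor is tied to the empirical
normalized detection threshold (1.9 × 10⁻⁴ of the canonical reference pair's
peak), so synthetic detectability mirrors the clinical setup.  The absolute
intensity scale (P₀ = 5 × 10⁴ cm·counts/ms) is arbitrary, as no per-case
absolute counts were published.  The per-pair "true" μ_a is the zone-volume-
weighted mean of the μ_a field, consistent with the homogeneous-average
semantics of the inversion.  Randomness uses one master seed with spawned
per-component substreams; identical seed + config reproduces outputs
bit-identically.

A green synthetic test establishes internal consistency (forward → noise →
inverse recovery, bookkeeping, statistics) — it does **not** establish
clinical accuracy: the generator has no scattering heterogeneity, no realistic
lesion shapes, no MRI physics, and its cohort-scale statistics (medians,
p-values, R²) are not those of the patient cohort, which would require the
unreleased clinical data.

## Known limitations

* The inversion assumes homogeneous optical properties between a pair; only a
  volume-averaged μ_a is meaningful, and a fixed μ_s′ = 2 mm⁻¹ can bias μ_a
  where the true reduced scattering differs (brain range ≈ 1–6 mm⁻¹).
* The diffusion approximation degrades within ~1 transport mean free path of
  the fibers and at very high absorption (μ_a approaching μ_s′).
* Exact polyhedral hulls, Monte-Carlo radiative transport and thermal
  modelling are intentionally absent.
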