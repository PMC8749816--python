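# ipdtmon

Analysis pipeline for **spectral online monitoring (SOM) of interstitial
photodynamic therapy (iPDT)** of brain tumors, and its relation to
post-therapeutic MRI.

During iPDT, cylindrical diffuser fibers (CDFs) implanted in the tumor deliver
635 nm treatment light that activates the 5-ALA-induced photosensitizer
protoporphyrin IX (PpIX).  Spectra recorded between every ordered fiber pair
before and after the illumination carry two signals: the transmitted treatment
light (626–642 nm) and the PpIX fluorescence (peak near 705 nm).  This package
turns those spectra, the stereotactic fiber geometry, and post-therapy MRI
labels into per-pair optical tissue properties and spatial-overlap statistics.
It is aimed at researchers in photodynamic-therapy dosimetry and intraoperative
optical monitoring.

## The model

The transmitted intensity between an emitting and a detecting diffuser is
modelled in the diffusion approximation.  Each active section is a linear array
of isotropic point sources/detectors (5 per mm, equal weights).  A point source
produces the fluence

```
Φ(r) = 3 (μ_a + μ_s′) / (4π r) · exp(−μ_eff r),   μ_eff = √(3 μ_a (μ_a + μ_s′))
```

and the pair intensity is the calibrated double sum

```
I_t,theo = P₀ · (L_E / N) · Σ_i Σ_j Φ(r_ij)
```

with emitter length `L_E` (cm), point-combination count `N`, and calibration
factor `P₀` (cm·counts/ms) fitted on tissue phantoms.  Inverting a per-pair
lookup table `I_t,theo(μ_a)` (grid 0.0001–0.75 mm⁻¹, step 0.0001, `μ_s′` fixed
at 2 mm⁻¹) against the measured intensity yields a volume-averaged absorption
coefficient per pair; the change `Δμ_a = μ_a,post − μ_a,pre` summarizes the
therapy-induced absorption increase.  At 635 nm blood dominates absorption, so
forward scenarios express `μ_a` through the blood volume fraction and the
hemoglobin species mix (HbO₂ / Hb / MetHb — the latter two absorb ≈ 8.5× and
33× more strongly than HbO₂).

The "light transmission zone" of a pair — where most detected light propagates
— is the convex hull of two 2.1 mm capsules around the active sections; the
radius derives from accumulating the strongest per-voxel fluence-product
contributions up to 67 % of the total.  Zones are intersected with the intrinsic
T1-hyperintensity label (a methemoglobin signature) and related to `Δμ_a` with
Mann–Whitney and Spearman statistics; tumor/lesion agreement is quantified with
Dice, Jaccard and overlap-volume coefficients.

No clinical data ship with the package; a synthetic-case generator emulates
all inputs with known ground truth (background `μ_a` 0.02 mm⁻¹, localized
absorber blobs co-located with the hyperintensity label, complete post-iPDT
PpIX photobleaching, 8 % intensity uncertainty).

## Worked example

```python
>>> from ipdtmon import hemoglobin_mua, transmission_curve
>>> round(hemoglobin_mua(3.8), 4)        # tumor tissue: 3.8% capillary bvf
0.0201
>>> transmission_curve([0.06], [10.0, 15.0, 19.0])[0]
array([6.16519526e-02, 2.30798641e-03, 1.74462314e-04])
```

The last number shows that for "brain adjacent tumor" absorption
(0.06 mm⁻¹) the normalized transmission falls to the empirical detection
threshold (1.9 × 10⁻⁴) at about 19 mm interfiber distance — the basis for the
19 mm eligibility cutoff in the statistics.

A full synthetic round trip:

```python
from ipdtmon import CaseConfig, RunConfig, generate_case, run_pipeline
from ipdtmon.io import CaseInputs

case = generate_case(CaseConfig(n_fibers=4, zone_grid_mm=0.5), seed=7)
inputs = CaseInputs(case_id=case.case_id, sections=case.sections,
                    spectra=case.spectra, basis=case.basis, tumor=case.tumor,
                    hyper=case.hyper, wm_spheres=case.wm_spheres, t1=case.t1)
res = run_pipeline(inputs, RunConfig(p0=case.truth.p0, zone_grid_mm=0.5))
print(res.pair_table[["pair_id", "min_distance_mm", "ratio",
                      "mu_a_pre", "mu_a_post", "delta_mu_a", "strength"]].round(4))
```

prints (first rows)

```
pair_id  min_distance_mm  ratio  mu_a_pre  mu_a_post  delta_mu_a  strength
 F1->F2          11.1306 1.0895    0.0203     0.0212      0.0009    0.0000
 F1->F3          15.6233 1.0966    0.0197     0.0203      0.0006    0.0000
 F2->F3          11.0761 1.1940    0.0208     0.0225      0.0017    0.0441
```

Recovered pre-iPDT `μ_a` sits within a few percent of the generated 0.02 mm⁻¹
truth; pairs whose transmission zone intersects an injected absorber blob show
elevated `Δμ_a` and a non-zero hyperintensity strength, and the
strength-vs-`Δμ_a` Spearman correlation on this case is ρ = 0.77 (p = 0.003).

## Command line

```sh
ipdtmon synth --seed 1 --n-fibers 5 --out case1/      # synthetic case with truth
ipdtmon run case1/ --out results/ --p0 50000          # full per-case analysis
ipdtmon fig4 --out curves.tsv                         # bvf/species forward curves
ipdtmon zone-radius --grid-mm 0.2                     # capsule-radius derivation
```

## Acceptance script

`scripts/acceptance.py` recomputes, from scratch through the package, the two
deterministic headline quantities: the interfiber distance at which the
normalized transmission for `μ_a` = 0.06 mm⁻¹ reaches the detection threshold,
and the capsule radius reproducing the 67 % fluence-product light transmission
zone on a 0.1 mm grid.  Run it from the repository root:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the modelling assumptions, numerical choices and
known limitations.
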