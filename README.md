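# paskin — photoacoustic skin analysis

Quantitative analysis of dermal vasculature, blood oxygenation and epidermal
melanin from multi-wavelength photoacoustic (PA) volumes. The package is
aimed at skin-imaging researchers who want a tested, scriptable version of
the standard dual-wavelength PA analysis chain:

* **vessel channel** by spectral subtraction, `max(PA₅₇₅ − PA₆₅₀, 0)` — the
  650 nm volume is melanin-dominated, so subtracting it isolates hemoglobin;
* **oxygen saturation** per voxel from the 575/586 nm amplitude ratio.
  With µₐ(λ) ∝ T·(ε_Hb(λ) + S·ε_ΔHb(λ)), ε_ΔHb = ε_HbO₂ − ε_Hb and
  q = µₐ(λ₁)/µₐ(λ₂):

  S = (ε_Hb(λ₁) − q·ε_Hb(λ₂)) / (q·ε_ΔHb(λ₂) − ε_ΔHb(λ₁))

* **3D structure extraction** slice-by-slice (pluggable backend, a
  deterministic classical segmenter by default) with restacking along depth;
* **skeleton morphometry** — voxel-count volume, thickness as `sqrt(A/π)` of
  cross-sections orthogonal to the local centerline direction, bifurcation
  counting on the thinned structure — reported per depth layer, where the
  analysis depth D is split equally into three layers and the deepest is
  excluded;
* **melanin volume** of torus-like superficial structures in the 650 nm
  channel;
* **cohort statistics** — Spearman rank correlation of every feature with
  age at α = 0.05.

Because the kind of clinical cohort this analysis targets is not publicly
distributable, the package ships a first-class synthetic generator:
branching vessel phantoms with exhaustively known ground truth (centerlines,
radii, bifurcation counts, per-voxel SO₂, melanin masks) and an
age-parameterized cohort simulator whose programmed trends — vessel radius
up, fine-vessel count down, SO₂ down, melanin volume up with age, and a
layer-1 : layer-2 vessel-volume ratio calibrated to 1.3 — are what the test
suite demands the pipeline recover.

## Worked example

```python
from paskin import (CohortSpec, PipelineConfig, analyze_cohort,
                    analyze_subject, cohort_feature_table, generate_cohort)

spec = CohortSpec(n_subjects=12, seed=3)          # rendered aging cohort
subjects = generate_cohort(spec)
reports = [analyze_subject(s.scan, PipelineConfig(), age=s.params.age)
           for s in subjects]
table = cohort_feature_table(reports)
for r in analyze_cohort(table):
    print(r.feature, r.layer, round(r.rho, 2), round(r.p_value, 3))
```

prints (abridged):

```
mean_thickness_um     1  0.2   0.527
mean_so2              1 -0.94  0.0
mean_thickness_um     2 -0.08  0.812
mean_so2              2 -0.88  0.0
melanin_volume_voxels None  0.57  0.051
```

Mean oxygen saturation falls strongly with age in both analysed layers and
melanin volume rises; the vessel-thickness trend (programmed at Spearman
ρ ≈ 0.5) is invisible at n = 12 — exactly the sampling behaviour one should
expect at this size. The acceptance suite runs the same check at n = 60,
where all three programmed trends (thickness up, SO₂ down, melanin up) come
out significant with the right signs.

The `examples/` directory holds one short script per capability (phantom +
forward model, unmixing + SO₂, morphometry, cohort trends).

## Command line

A thin CLI wraps the library for cohort-on-disk workflows:

```bash
paskin simulate --n 10 --seed 7 --out cohort/          # volumes + truth + manifest
paskin analyze  --manifest cohort/manifest.csv --out results/
paskin cohort   --features results/features.csv --out correlations.csv
paskin report   --features results/features.csv --out report/   # + scatter plots
```

Scans are single-channel TIFF stacks per wavelength with a JSON spacing
sidecar; masks are NRRD; manifests and feature tables are CSV.

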