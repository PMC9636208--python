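# psrquant

Automated quantification of liver fibrosis from picrosirius-red (PSR) stained
whole-slide images, for preclinical research groups that need a continuous,
operator-independent fibrosis endpoint alongside hydroxyproline assays and
histological staging.

Conventional fibrosis readouts have complementary blind spots: ordinal staging
systems (Ishak, modified Ishak, NASH CRN) are reader-dependent and coarse,
while the biochemical hydroxyproline (HYP) assay consumes a large piece of
tissue and says nothing about localization. The **collagen proportionate
area** (CPA) — the percentage of the delineated tissue section occupied by
red-stained fibrillar collagen — is a continuous endpoint that can be computed
fully automatically on the entire section.

## Method

For a slide with RGB intensities *I* and per-channel background *I₀*
(a high percentile of the slide, robust to dust):

1. **Optical density**: OD_c = log₁₀(I₀_c / max(I_c, ε)) per channel
   (Beer–Lambert absorbance; linear in stain concentration).
2. **Tissue delineation**: pixels with ‖OD‖₂ ≥ τ_t, cleaned by morphological
   closing, small-hole filling and small-component removal. Cleanup sizes are
   given in µm/µm² and converted per slide, so 20X (0.452 µm/px) and 40X
   (0.226 µm/px) scans behave identically.
3. **Stain axes**: SVD of the uncentered N×3 matrix of tissue-pixel OD
   vectors, computed exactly from its 3×3 Gram matrix.
4. **Collagen**: each pixel's OD is projected on the third singular vector
   v₃ (the least-variance axis of the tissue OD cloud, sign-fixed so pure red
   projects positively); tissue pixels with OD·v₃ ≥ τ_c are collagen, with one
   global τ_c shared by every slide of a study.
5. **CPA** = 100 · |collagen| / |tissue|; per animal, the arithmetic mean over
   its (typically 3) sections.

All whole-slide statistics are accumulated in integer histograms tile by tile,
so results are bit-identical across reruns and tile sizes: the run-to-run
standard error of the collagen pixel count is exactly 0.

The package also ships:

* `psrquant.synthetic` — a PSR slide/cohort simulator with exact ground-truth
  masks (septal and perisinusoidal fibrosis patterns, staged cohorts with
  CPA-linked HYP values), used to validate every stage of the pipeline;
* `psrquant.scoring` — Ishak / modified Ishak / NASH CRN encodings with the
  highest-section-value aggregation rule;
* `psrquant.stats` — Spearman correlation, Fisher z, Steiger's one-sided Z
  for comparing the stage-vs-CPA and stage-vs-HYP correlations (dependent,
  since both are measured on the same animals), and OLS regression for the
  20X/40X equivalence check.

## Worked example

```python
from psrquant import (SegmentationConfig, SlideGenParams, compute_cpa,
                      make_slide, segment_slide)

slide = make_slide(SlideGenParams(width_px=1024, height_px=1024,
                                  target_cpa=10.0, seed=42))
result = segment_slide(slide.as_wsi(), SegmentationConfig())
meas = compute_cpa(result, "example")
print(meas.tissue_px, meas.collagen_px, round(meas.cpa_percent, 3))
```

prints `530364 53189 10.029` — 530 364 tissue pixels of which 53 189 are
collagen, i.e. an estimated CPA of 10.029% against a ground truth of 10.035%
(the generator targeted 10%). The singular values of this slide's tissue OD
cloud are s₁ = 286.3, s₂ = 67.6, s₃ = 25.5, and the collagen mask agrees with
the ground truth at IoU 1.00.

The `examples/` directory walks through each capability: slide simulation,
segmentation, the exact-repeatability check (SE = 0.0 pixels over 5 runs),
20X/40X equivalence (r² = 0.99991 on 8 slides in `04_…py`), and a full cohort
analysis ending in the stage-as-reference correlation report, e.g.

```
           system   r_CPA  r_HYP     r23   n       Z  p_one_sided
0           ishak  0.9498  0.832  0.8881  12  2.0650       0.0195
```

meaning CPA correlates with the Ishak stage significantly better than the HYP
assay does on the same 12 animals (one-sided p ≈ 0.02).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates a fixed 2048×2048 synthetic PSR slide, runs the full segmentation
pipeline five times, and writes the standard error of the five collagen pixel
counts (in pixels) as target `t1`. See `docs/methods.md` for the model,
parameter defaults, calibration procedure and known limitations.
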