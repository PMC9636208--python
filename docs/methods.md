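# Methods

## 1. The measurement

The pipeline quantifies liver fibrosis on picrosirius-red (PSR) stained
whole-slide images as the collagen proportionate area,

CPA = 100 · (collagen pixels) / (tissue pixels),

with the denominator the **entire** delineated section (not tissue minus
collagen). Per animal, the endpoint is the arithmetic mean CPA over its
sections (three in the emulated study design); missing sections are averaged
over with a logged warning, never imputed. Ordinal fibrosis stages are
reader-supplied inputs; per animal the highest section value is used.

## 2. Segmentation model and numerical choices

**Optical density.** OD_c = log₁₀(I₀_c / max(I_c, ε)), ε = 0.5 on the 0–255
scale. Base 10 because absorbance is conventionally decadic. I₀ is the
per-channel 99th-percentile intensity of the whole slide (nearest-rank, from
exact 256-bin histograms), clamped to ≥ 1; a high percentile tracks the glass
level while ignoring specular dust.

**Tissue.** A pixel is raw tissue when ‖OD‖₂ ≥ 0.08. Cleanup: morphological
closing (radius 2 µm), filling of holes ≤ 150 µm², removal of components
< 1000 µm². These are physical units converted per slide via µm/pixel, which
is what makes 20X and 40X runs equivalent. Holes larger than 150 µm² (vessel
lumina) are deliberately kept open; whether "tissue area" should include
lumina is genuinely open, and this choice is the conservative one. An empty
tissue mask (blank slide) is legal and logged, not an error.

**Stain axes.** The basis is the SVD of the *uncentered* N×3 matrix of
tissue-pixel OD vectors. Uncentered, because the physical model is a
nonnegative mixture of stain vectors and the axes should pass through the
origin of absorbance space; tissue-only, so that glass cannot dominate the
first axis. The 3×3 Gram matrix is assembled exactly from per-channel and
pairwise 256×256 joint intensity histograms (OD takes ≤ 256 values per
channel, so Σ OD_i·OD_j factors over histogram bins). Histogram counts are
integers, and integer addition is associative — this is what makes the result
independent of tile size and bit-identical across reruns, turning the
"100% repeatability" contract into arithmetic rather than luck. Eigenvectors
come from `numpy.linalg.eigh`; singular values are √eigenvalues, descending.
Singular vectors are sign-ambiguous: v₁/v₂ are fixed by making their
largest-magnitude component positive, v₃ by requiring the OD of pure red
(255, 0, 0) to project nonnegatively.

**Collagen.** Collagen = tissue ∧ (OD·v₃ ≥ τ_c) with a single global
threshold τ_c used for every slide of a study. Per-slide adaptive thresholds
were rejected: the whole point of the automated readout is that detection
criteria are strictly identical across sections. The default τ_c = 0.04 was
frozen by running `psrquant.segmentation.calibrate_threshold` once over the
standard calibration set (`psrquant.synthetic.calibration_slides`, seed 2026:
CPA 1–25% septal, 1–12% perisinusoidal, both magnifications), maximizing mean
IoU against ground truth; the maximum is flat (mean IoU 0.997 at 0.04). The
Gram accumulation supports deterministic stride subsampling
(`subsample_stride`, default 1 = all pixels) for very large slides.

**Two-pass tiling.** Pass 1 accumulates background histograms, the raw tissue
mask and the Gram histograms per tile; morphology is applied globally to the
assembled mask. Pass 2 projects and thresholds per tile. Only per-pixel
operations and integer accumulators cross tile boundaries, hence tile-size
invariance is exact (asserted bitwise in tests).

## 3. The synthetic world

The generator exists to make every downstream stage testable with exact ground
truth. It emulates, per slide: a white glass background (245, 245, 245), one
large star-convex tissue silhouette (low-order random Fourier boundary,
~50% of the frame) pierced by 1–2 vessel-like lumina, and collagen drawn as

* **septal** bands: random-walk strokes (width 3–10 px, length 150–500 µm at
  the 0.452 µm/px reference scale) from Poisson-scattered vein seeds — the
  bridging-fibrosis morphology of chronic CCl₄ injury; or
* **perisinusoidal** "chicken-wire": 1–2 px curvilinear strands along a
  jittered ~25 µm lattice — early steatohepatitis morphology.

Strokes are added until the ground-truth pixel ratio reaches the requested
CPA; stroke size shrinks near the target, so the achieved CPA lands well
within the contracted 1.5 pp band. Rendering is internally supersampled 2×
and area-averaged down (masks by majority vote, ties count as covered),
emulating partial-volume mixing at fiber edges. Everything derives from one
`numpy` generator seeded by `params.seed`: equal seeds give byte-identical
slides.

**Color geometry.** Colors are synthesized in OD space as three populations:
parenchyma m + t·A·d̂ (mean OD m from RGB (166, 142, 132), tone axis d̂ ⊥ m,
amplitude A = 0.26 scaled by a smooth ±1 field with ~100 µm correlation
length, emulating zonal staining heterogeneity), collagen c (from RGB
(210, 131, 170)), and glass at OD ≈ 0, plus Gaussian RGB jitter (σ = 1.2 on
tissue) and sensor noise (σ = 0.8 everywhere). The collagen OD was chosen
with a zero component along d̂ and a 0.12 component along the plane normal
n̂ = m̂×d̂, so that the tissue OD cloud is genuinely rank-3 with collagen
carrying the only consistent signal on the least-variance axis — the geometry
the third-singular-vector projection exploits on real PSR slides. The
counterstain is rendered darker (‖m‖ ≈ 0.40) and the collagen paler than on a
typical PSR photomicrograph: a strong first axis keeps v₃ from tilting with
collagen load, which is what keeps a *single global* threshold accurate from
1% to 25% CPA. With these defaults the segmenter recovers true CPA to
≤ 0.05 pp at 1024² and the calibration-set IoU is ≥ 0.99.

What the generator does **not** emulate: nuclei, steatosis vacuoles,
inflammation, folds/bubbles, batch-to-batch stain variation, scanner color
profiles, or compression artifacts. A green test therefore establishes the
correctness of the algorithmic chain (OD → SVD → projection → threshold →
aggregation → statistics) under a controlled stain model, not robustness to
real-world staining variability.

**Cohorts.** The default design emulates a CCl₄ time course: groups at weeks
0/1/3/6/12/18 (4 control + 6 treated animals each), 3 sections per animal,
mean CPA rising from a 0.8% baseline with fold-changes ≈ 1, 2.7, 4.0, 5.7 and
8.3 — the published longitudinal profile of that model. Between-animal CPA
spread is 0.5 pp (σ). HYP is linked linearly: HYP = 25·CPA + 150 ± 30 µg/g
liver, giving control values near 170 µg/g and a strong but imperfect CPA–HYP
correlation, as observed in practice. Stage labels are assigned by
thresholding the animal's mean true CPA at ordered cutpoints (Ishak and
modified Ishak: 1, 2, 4, 8, 14, 22%; NASH CRN: 0.8, 1.5, 2.5, 4, 8, 16%) —
a stylized reader whose stages are deterministic in CPA.

**Resolution rendering.** `render_at_resolution` supports integer downscale
factors only (0.226 → 0.452 µm/px is exactly 2×); images are area-averaged,
masks majority-voted, true CPA recomputed. Upsampling is refused.

## 4. Statistics

* **Spearman** via rank-Pearson with mean ranks for ties; two-sided p from the
  t approximation. Pairwise deletion of missing values; constant inputs are an
  error.
* **Fisher z** = atanh(r), defined for |r| < 1.
* **Dependent-correlation comparison** (stage as reference, CPA vs HYP arms
  measured on the same animals): the default is Steiger's Z,
  z = (z₁₂ − z₁₃)·√((n−3)/(2(1−s̄))), s̄ = ψ̄/(1−r̄²)²,
  ψ̄ = r₂₃(1−2r̄²) − ½r̄²(1−2r̄²−r₂₃²), r̄ = (r₁₂+r₁₃)/2.
  Ignoring the dependence is wrong in either direction depending on r₂₃, so
  the naive independent-samples statistic (z₁₂−z₁₃)/√(2/(n−3)) is exposed only
  as the explicit `fisher_independent` variant. One-sided upper-tail p by
  default. Monte-Carlo calibration (20 000 trivariate-normal samples,
  ρ₁₂ = ρ₁₃ = 0.7, ρ₂₃ = 0.5, n = 35) puts the empirical size at ≈ 0.05 with
  Pearson sample correlations; fed Spearman correlations instead, the size
  inflates to ≈ 0.064, the known consequence of var(atanh r_s) ≈ 1.06/(n−3) —
  worth remembering when applying the test to rank correlations, which is
  nonetheless standard practice in this literature.
* **NASH CRN substages** 1A/1B/1C encode to 1 by default (they are substages
  of stage 1; the letter survives in the label). An alternative "thirds"
  coding (1, 4/3, 5/3) is available via `substage_coding="thirds"` since
  published analyses rarely state their coding. Correlations with a perfect
  (|r| = 1) arm report Z = NaN rather than failing the whole report.
* **20X/40X equivalence** by OLS of CPA at 0.452 on CPA at 0.226 µm/px;
  r² is the squared Pearson correlation. A constant response returns r² = 0.

## 5. Degenerate inputs and edge cases

Blank slides give empty masks and no CPA (explicit "no tissue" error
downstream); an all-black slide clamps I₀ to 1; fewer than 1000 tissue pixels
after striding refuse a stain fit; `pattern="none"` with a positive CPA target
and unreachable targets raise errors naming the achievable range; masks with
values other than {0, 255} or extra channels are format errors; µm/pixel is
never guessed — explicit override beats TIFF tags, and PNGs without an
override are an error.

## 6. Known limitations

* The color model is a 3-vector mixture; it cannot express metachromasia or
  saturation nonlinearity of real scanners.
* The global threshold default is calibrated on the synthetic world; a real
  deployment would recalibrate once on reference slides of the actual stain
  batch and scanner (and then hold the value fixed across the study).
* Slide rasters are processed in memory (tiling bounds per-tile cost, not peak
  memory); gigapixel pyramidal formats would need a streaming reader upstream.
* Localization-specific quantification (septal vs perisinusoidal CPA split)
  is out of scope; the patterns exist only in the simulator.
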