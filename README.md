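# spinestitch

Whole-spine MR views are acquired as separate cervical, thoracic and
lumbar (C-T-L) fields of view; radiologists reading the full vertebral
column need those segments composited into one image.  `spinestitch`
implements SIFT-based stitching of such multi-segment, multi-slice
2-D spine images: scale-invariant keypoint detection, 128-element
gradient descriptors, Euclidean-distance matching, inter-segment
transform estimation (automatic or from manually picked point pairs),
sequential compositing with feather blending, and central-slice
transform propagation across stacks — plus the agreement statistics
(NMSE, Pearson r, R², Bland–Altman limits) used to compare a stitched
result against a reference.

It is aimed at medical-imaging researchers prototyping or validating
field-of-view composition; a synthetic spine-phantom generator with
known ground truth makes every stage testable without patient data.

## Method

Keypoints are extrema of the difference-of-Gaussians (DoG) scale space

    L(x, y, σ) = G(x, y, σ) * I(x, y)
    D(x, y, σ) = L(x, y, kσ) − L(x, y, σ),        k = 2^(1/s)

found by comparing each sample with its 26 neighbors (8 in-plane, 9 in
each adjacent scale), refined to sub-pixel position with a second-order
Taylor expansion of D, and filtered by an interpolated-contrast gate
(|D(X̂)| ≥ 0.03 on [0,1]-normalized images) and the principal-curvature
edge test Tr(H)²/Det(H) ≤ (γ+1)²/γ with γ = 10.  Each keypoint gets the
dominant orientation(s) of its Gaussian-weighted gradient histogram and
a 4×4×8 = 128-element descriptor of locally binned gradient magnitudes.
Descriptors are matched by Euclidean distance with ratio, mutual and
geometric-consistency filters; the inter-segment translation is the
component-wise median of the matched displacement vectors (a similarity
model is also available).  Segments are composited sequentially —
stitch(C, T), then stitch(C-T, L) — and for multi-slice stacks the
transform estimated on the most central slice is applied to all slices.

## Worked example

```sh
spinestitch simulate --out work/sim --seed 1 --noise 0.01
spinestitch stitch --mode aptp -o work/stitched \
    work/sim/segment_0 work/sim/segment_1 work/sim/segment_2
```

writes a stitched whole-spine PNG plus `transforms.json`.  The same run
through the library:

```python
import spinestitch as ss

phantom = ss.make_phantom()                       # 700x256 spine phantom
segs = ss.split_overlapping(phantom, overlap_px=56, noise_sd=0.01, seed=1)
res = ss.stitch_sequence(segs.segments, mode="aptp")[0]
for t, truth in zip(res.transforms[1:], segs.true_offsets):
    print(f"recovered ({t.dx:.3f}, {t.dy:.3f})  true {truth}")
crop = res.canvas.pixels[:phantom.height, :phantom.width]
print(f"NMSE vs phantom: {ss.nmse(phantom, crop):.2e}")
```

prints

```
recovered (0.021, 215.005)  true (0, 215)
recovered (0.015, 430.015)  true (0, 215)
NMSE vs phantom: 6.58e-04
```

i.e. the automatic point-to-point (aPTP) chain recovers both 215-px
inter-segment translations to a few hundredths of a pixel (the second
transform is cumulative), and the reassembled canvas differs from the
original phantom only by the injected acquisition noise — a normalized
mean square error of about 7 × 10⁻⁴.  `evaluate` produces the agreement
report (NMSE, Pearson r with p-value, R², Bland–Altman mean difference
and ±1.96·SD limits) and the corresponding scatter/Bland–Altman plots
for any reference/test pair.

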