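# Methods

## Model

Pixels of a single-channel 8-bit image are clustered by gray value into
`c` fuzzy classes. Both variants minimize the usual FCM cost
`J_m = Σ_i Σ_k u_ik^m d_ik²` by alternating membership and center
updates; MMTDFCM inserts one spatial step between them.

**Membership.** `u_ik = [Σ_j (d_ik/d_jk)^(2/(m−1))]^(−1)` with
`d_ik = |x_k − v_i|`. If a pixel coincides with a center (`d_ik = 0`) its
column is crisp: grade 1 for the first zero-distance cluster, 0 for the
rest. Columns whose distance powers overflow are handled by the same
crisp rule, so the update never emits NaNs.

**Similarity field.** The medium similarity `hh(f,x)` of two grays is the
mean of the two one-sided distance ratios to the anchors −1 and 256 (see
README). `h̄(k)` is the mean of `hh` between pixel `k` and its eight 3×3
neighbours, computed **once** from the input image and held fixed for the
whole run. It is implemented through a precomputed 256×256 table, so the
map costs eight array lookups per pixel.

**Spatial blend.** With `ū_ik` the neighbourhood *mean* membership, the
medium membership is

```
u′_ik = [ |NB| · h̄(k) · ū_ik + (1 − h̄(k)) · u_ik ] / [ 1 + (|NB|−1) h̄(k) ]
```

i.e. the neighbourhood membership *sum* enters with weight `h̄` against
`(1−h̄)` for the pixel's own membership, and the column is renormalized.
This is a per-pixel convex combination of `u` and `ū` with effective
neighbourhood weight `|NB|·h̄ / (1 + (|NB|−1)h̄)`, so every invariant of a
membership matrix is preserved (entries in [0,1], columns sum to 1,
`u′ = ū` at `h̄ = 1`, `u′ → u` as `h̄ → 0`).

The weighting of the neighbourhood term was the one genuinely open design
choice. The plain convex blend `h̄·ū + (1−h̄)·u` ("mean" option) can never
reassign an extreme impulse: a 0/255 pixel inside a uniform region has
`h̄ ≈ 0.19–0.32 < 1/2` while its own membership is crisp, so its own vote
always wins and impulse noise survives segmentation. With the full
neighbourhood sum the flip threshold drops to `h̄ > 1/(1+|NB|) = 1/9`, and
isolated impulses are outvoted whenever their neighbourhood is coherent —
the behaviour the method exists for. The sum is therefore the default
(`neighborhood_blend="sum"`); `"mean"` remains available for comparison.

**Centers, convergence, labels.** Centers are the `u′^m`-weighted gray
means. Convergence is the Chebyshev norm of the center step dropping
below `eps` (scale-free in `c`, the strictest common matrix-norm choice).
Labels come from the maximum-membership rule on the final (blended)
matrix; ties go to the lowest cluster index. Non-convergence within
`max_iter` is reported as `converged=False`, not an error.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `c` | 3 | clusters; 3 for the three-level phantom, 4 for background/WM/GM/CSF-style images |
| `m` | 2.0 | fuzzifier (>1); the customary mid-point of the useful 1.5–2.5 range |
| `eps` | 1e-5 | center-step threshold (gray levels) |
| `max_iter` | 100 | iteration cap |
| `init_method` | quantile | centers at the (i+½)/c gray quantiles — deterministic, lands on well-separated histogram masses; `random` draws distinct pixel values with `seed` |
| `border_mode` | replicate | edge replication gives every pixel 8 neighbours and a uniform /8; `valid` averages in-bounds neighbours only |
| `include_center` | False | whether a pixel joins its own neighbourhood (the 8-neighbour construction is the default) |
| `neighborhood_blend` | sum | see above |

The 3×3 neighbourhood, the −1/256 anchors, and the raw gray scale
(no rescaling) are fixed properties of the similarity measure.

## Synthetic data

`make_phantom` produces piecewise-constant phantoms with known labels;
the default emulates a 128×128 image of three flat gray levels 0/160/255
as equal-width vertical bands (the band layout is this package's own
choice — only the size and levels are canonical; a disk-and-square
geometry is available to break the straight-edge special case).
Noise (applied to the image only, so ground truth stays exact):

* salt-and-pepper at density 0.05 — each pixel independently replaced,
  half to 0 and half to 255 (`skimage.util.random_noise`, `s&p`);
* Gaussian with variance 0.01 on the unit gray scale (σ ≈ 25.5 gray
  levels), clipped and re-quantized.

What these phantoms do **not** emulate: textured tissue, smooth intensity
gradients, bias fields, Rician noise, partial-volume boundaries. Passing
the suite therefore demonstrates the mechanism (spatial outvoting of
incoherent pixels) under clean separable conditions, not clinical-grade
accuracy on real MR data. A visible consequence of the mechanism's limit:
impulses whose value coincides with an adjacent class's level *and* whose
neighbourhood similarity falls below 1/9 (e.g. a 255 impulse inside the
0 band, `h̄ = 1/256`) are indistinguishable from signal and stay
misclassified; on the three-level phantom roughly the extreme-band third
of the impulses survives, which is why the salt-and-pepper error halves
rather than vanishes.

## Metrics

PSNR is computed between a reference image and the piecewise-constant
reconstruction (each pixel replaced by its rounded cluster center) — for
noisy conditions the reference is the *clean* image, so PSNR measures
denoising of the segmentation, and it is infinite when the reconstruction
is exact. The PSNR peak defaults to the reference maximum (a `--psnr-peak
255` option forces the fixed peak). `vpc = (1/n)ΣΣu²` and
`vpe = −(1/n)ΣΣ u ln u` (natural log, the standard for partition entropy;
the base is an option) score crispness of the final membership matrix —
note a noise-blind segmentation can be *crisply wrong*, so on noisy input
FCM may show better vpc/vpe while misclassifying more pixels; both are
reported without forcing a direction. The misclassification rate against
phantom truth is exact: minimized over all `c!` relabelings (c ≤ 8).

## Numerical notes

* All membership stages are column-stochastic to ≤1e-9 by construction;
  the blend renormalizes explicitly.
* Degenerate clusters (zero total weight, possible when `c` exceeds the
  number of distinct grays) keep their previous center for that iteration
  and log a warning.
* Coincident centers: the crisp column goes to the lowest cluster index;
  defuzzification ties break the same way.
* Rasterization is row-major with 0-based indices throughout.
* Problem sizes in the test suite: the full 128×128 phantom for recovery
  and the ten-seed noise sweeps; 16×16 random images (50 of them) for the
  objective-descent property; a 5×5 image for the loop-level
  transliteration oracle. The whole suite runs in a few seconds.

## Known limitations

* Gray-value clustering only — no color, multi-feature, or kernelized
  distances, and no cluster-number selection.
* 2-D slices only; no DICOM/NIfTI readers (PNG/TIFF in and out).
* The similarity field is input-derived and fixed; heavy noise (impulse
  density ≫ 0.1) erodes neighbourhood coherence and with it the
  correction mechanism.
* `vpc`/`vpe` reward crispness, not correctness; use the misclassification
  rate (phantoms) or PSNR for accuracy claims.
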