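# mmtdfcm

Noise-robust fuzzy c-means (FCM) segmentation of single-channel 8-bit
grayscale images — MR slices, regions of interest, or synthetic phantoms —
for anyone who needs tissue-style clustering that does not fall apart under
impulse or Gaussian noise.

Classical FCM clusters pixels by gray value alone: memberships

```
u_ik = [ Σ_j (d_ik / d_jk)^(2/(m−1)) ]^(−1),      d_ik = |x_k − v_i|,
v_i  = Σ_k u_ik^m x_k / Σ_k u_ik^m,
```

alternate until the centers stop moving. Because no spatial context enters,
a salt-and-pepper pixel is always assigned to the gray-nearest cluster, and
the label map inherits every noise speck.

**MMTDFCM** adds spatial context through a *medium-truth-degree* similarity
measure. Two gray values `f`, `x` are compared by their distance ratios to
anchor points just outside the gray range (−1 and 256):

```
h(f,x) = (f+1)/(x+1)  if f<x,   1  if f=x,   (256−f)/(256−x)  if f>x
hh(f,x) = [h(f,x) + h(x,f)] / 2            ∈ (0, 1],  =1 iff f=x
```

Averaging `hh` between each pixel and its eight 3×3 neighbours gives a
fixed similarity field `h̄(k)`: ≈1 inside homogeneous regions, low at noise
pixels. Each iteration the fuzzy membership `u_ik` is blended with the
neighbourhood membership (the sum over the 8 neighbours, column-normalized):

```
u′_ik ∝ h̄(k) · Σ_{j∈NB(k)} u_ij + (1 − h̄(k)) · u_ik
```

a per-pixel convex combination of a pixel's own membership and its
neighbourhood mean. A noise pixel whose neighbourhood outvotes it
(`h̄ > 1/9`) is pulled into the surrounding region, which is what makes the
variant anti-noise. The package also ships the standard evaluation metrics
(PSNR, partition coefficient `vpc`, partition entropy `vpe`,
misclassification rate vs. ground truth) and a seeded phantom + noise
generator, so everything is testable without external data.

## Worked example

Generate the default phantom (128×128, three gray levels 0/160/255) and run
the paired comparison over clean, 5% salt-and-pepper, and variance-0.01
Gaussian conditions:

```sh
$ mmtdfcm compare --noise-seed 0
condition         algorithm  psnr     vpc     vpe     misclassification_rate  n_iter
clean             fcm        inf      1.0000  0.0000  0.0000                  1
clean             mmtdfcm    inf      0.9856  0.0205  0.0000                  2
salt_pepper_0.05  fcm        16.7279  1.0000  0.0000  0.0338                  1
salt_pepper_0.05  mmtdfcm    17.9024  0.9230  0.1275  0.0167                  3
gaussian_0.01     fcm        24.1131  0.9143  0.1690  0.0227                  14
gaussian_0.01     mmtdfcm    28.5883  0.8745  0.2516  0.0003                  7
```

Both algorithms recover the clean phantom exactly (misclassification 0, so
the PSNR of the reconstruction is infinite). Under noise, MMTDFCM halves
the salt-and-pepper error (3.4% → 1.7%: the impulses landing in the
mid-gray band are outvoted by their neighbourhoods; impulses that coincide
with the extreme bands are indistinguishable from signal) and nearly
removes the Gaussian error (2.3% → 0.03%), with correspondingly higher
PSNR against the clean reference. FCM's crisper `vpc`/`vpe` on the noisy
image merely reflects confident *mis*classification of the noise pixels.

Segment a single image (PNG or TIFF), writing a label map, a
center-reconstruction, and a YAML metrics report:

```sh
$ mmtdfcm phantom --out ph
$ mmtdfcm segment ph.png --noise sp --variant mmtdfcm --out seg
mmtdfcm: 3 iteration(s), converged=True, centers=[2.39, 159.57, 252.98]
psnr=17.9024 dB  vpc=0.9230  vpe=0.1275
outputs in seg
```

The same operations are available as a library:

```python
from mmtdfcm import FcmConfig, PhantomSpec, make_phantom, add_salt_pepper, run_mmtdfcm

image, truth = make_phantom(PhantomSpec())
noisy = add_salt_pepper(image, 0.05, seed=0)
result = run_mmtdfcm(noisy, FcmConfig(c=3, m=2.0, eps=1e-5))
```

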