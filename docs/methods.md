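# Methods

This note records the models, estimators and numerical choices behind
`msicoreg`, and what the synthetic test bed does and does not establish.

## Data model and geometry conventions

An `MSIDataset` is a dense `float32` matrix of non-negative intensities
over (mass feature, pixel) with a single strictly increasing m/z axis;
processed-mode imzML files, which carry per-pixel peak lists, are binned
onto a common axis at the median native bin spacing on read. Coordinates
are 0-based `(x=column, y=row)`, pixel-centered; imzML's 1-based
convention is shifted on read and restored on write. Optical images are
ingested to `[0, 1]` by dividing by the source bit-depth range, with alpha
dropped. Datasets in scope are desk-scale after peak processing, so the
dense cube is deliberate; out-of-core storage is a non-goal.

A spatial transform always maps **fixed** (H&E) coordinates to **moving**
(MSI) coordinates — the resampling convention — so warping evaluates the
moving image at `T(x)` on the fixed grid, and annotation transfer uses
`T⁻¹` (exact for rigid/affine, fixed-point iteration for B-spline).

## Image preparation

Tissue outlining defaults to Otsu on a tissue-bright channel (for RGB
input, `1 − mean(RGB)`, since stains are dark on a light slide), followed
by 3×3 morphological closing, hole filling, and retention of connected
components at least half the size of the largest — the 50% rule keeps
multi-core TMA layouts intact while removing specks. Resolution matching
upscales the MSI-derived image bilinearly by the integer `spatial_scaling`
(default 4, sufficient for typical raster step sizes in the 50–200 µm
range against ×20 microscopy) and downscales the H&E image with
antialiasing; aspect mismatches are resolved by symmetric zero-padding,
never anisotropic stretch, and padding precedes the optional center crop.
Centering the tissue also improves the basin of attraction of the MI
optimization.

## Spatial shrunken centroids

Given pixel spectra `x_ij` and segment labels, centroids are shrunk toward
the overall mean by soft-thresholding the standardized difference

    d_kj = (c_kj − c̄_j) / (m_k (s_j + s_0)),   m_k = sqrt(1/n_k − 1/n),

where `s_j` is the pooled within-segment standard deviation and
`s_0 = median(s_j)` guards small denominators. The iteration alternates
these statistics with assignment by standardized distance to the shrunken
centroids, where each pixel's per-segment score is averaged over a
Gaussian-weighted neighborhood (σ = r/2, truncated at radius `r`,
normalized over pixels actually present) — this is what makes the
segmentation respect tissue contiguity. Convergence is declared when fewer
than 0.1% of labels change (or `max_iter`). Initial labels come from
k-means on standardized spectra with a fixed seed; empty segments are
dropped. Feature informativeness is `max_k |d'_kj|` after thresholding;
selection keeps nonzero scores, descending. With `s = 0` the centroids are
exact segment means, and with `r = 0, s = 0` one iteration reduces to plain
nearest-centroid assignment — both covered by tests against independent
implementations. Defaults `k = 5, r = 2`; when no shrinkage is given the
pipeline picks the smallest `s` retaining at most half the features,
keeping the workflow unsupervised. Selection happens after convergence;
ties in assignment go to the lowest segment index.

## Representative images

The MSI cube collapses to one channel by 1-component t-SNE (Barnes-Hut,
perplexity 30 capped at `(n−1)/3`, PCA initialization, 500 iterations,
fixed seed) over the tissue pixels' selected-feature vectors, standardized
per feature; background pixels are excluded so they cannot dominate the
embedding, and are exactly zero in the output. A 1-D t-SNE axis has
arbitrary sign, so polarity is fixed by positive rank-correlation with
total ion current; MI does not care, but overlays and correlation metrics
do. The H&E representative is `1 − mean(RGB)` masked and min-max rescaled;
a constant tissue maps to 1 (degenerate rescale, documented).

## Registration

The loss is Mattes mutual information from a Parzen joint histogram
(32 bins by default) over pixels sampled from the union of the two tissue
supports **dilated by 4 px**: the tissue margin is only localizable when
both of its sides contribute samples, and the margin ring measurably halves
boundary error on phantoms. The *reported* metric (`mattes_mi`) uses
first-order (linear) windows on both axes — exactly symmetric in its
arguments, and collapsing to a plain histogram on bin-centered data, so
MI(img, img) equals the marginal entropy to machine precision. The
*optimizer* uses the classic asymmetric construction — linear window on
the fixed axis, cubic B-spline window on the moving axis — because the
cubic window makes the metric analytically differentiable in the moving
intensities. Histogram objectives are piecewise linear under pure linear
windows; finite differences on them measure kink noise rather than slope,
which stalls quasi-Newton line searches.

The metric gradient chains ∂MI/∂(moving value) through the moving image's
spatial gradient and the transform Jacobian. The moving image is modeled
per pyramid level as an interpolating bicubic spline, so sampled values
and derivatives are mutually consistent. Transforms: rigid (angle about
the image center + translation), affine (center-relative matrix +
translation, matrix entries scaled by the half-diagonal so one parameter
unit ≈ one pixel of motion), and cubic B-spline free-form deformation
(control spacing 32 px by default, coefficients bounded to ±2 spacings,
which prevents folding in the common case). The default run initializes
the B-spline stage from a preceding affine stage — a cold-started
free-form deformation cannot recover large translations. Composition is
`T(x) = A(x + u(x))`.

Optimization is L-BFGS-B (or a plain gradient-descent alternative) over a
Gaussian multi-resolution schedule (smoothing σ = factor/2 for pyramid
factors 4, 2, 1), warm-starting parameters across levels; under random
sampling (default fraction 0.25, seeded) a deterministic full-sampling
polish pass at the finest level removes subsample bias. A thin-plate
bending penalty on the B-spline coefficients (mean squared second
difference, weight 1e-3, annealed ×factor² over the pyramid) regularizes
the parts of the deformation the image content does not constrain — MI is
blind to tangential slides inside flat tissue regions, and without the
penalty the optimizer attains higher MI than the true warp while drifting
from it. Registration is deterministic given the seed.

For tissue-microarray frames with independent per-core motion, the control
spacing must resolve single cores; the bundled TMA analyses use 16 px
spacing for 10 px-radius cores against the 32 px default.

## Metrics

Dice is computed on binary masks (two empty masks define 1.0, logged);
NCC is the Pearson correlation of representative intensities over the
union of tissue supports — excluding background prevents inflation by
zero-zero matches. The local metric is `det(I + ∇u)` per pixel by central
differences (one-sided at borders; the border-pixel count is reported),
summarized over the fixed tissue mask.

## The phantom generator

Phantoms emulate: a contiguous multi-segment tissue (elliptical support,
Voronoi segments) or a TMA grid of cores with inner/outer zones; 50 mass
features of which 5 carry a 2-SD mean shift in their segment (round-robin
across segments) over Gaussian noise; an H&E-like rendering at a chosen
resolution factor with per-segment gray levels, eosin-like tint and
texture noise; and a known warp applied to the H&E side. A shared smooth
"cellularity" field (Gaussian-filtered noise, 4 px correlation length)
modulates each segment's effect by ±40% and the stain density coherently —
this is the cross-modality tissue heterogeneity that landmark-free MI
registration fundamentally relies on; without it, sub-pixel recovery
inside homogeneous segments is information-theoretically impossible (the
aperture problem), which a purely independent-noise phantom would
misrepresent as a method failure. Elastic warps are Gaussian-smoothed
random fields with amplitude clamped to 0.4× the smoothness scale and are
verified diffeomorphic at generation; per-core TMA warps compose rigid
per-core motions feathered over one third of the background gap, with
shift magnitudes in the upper half of the stated bound (staining-induced
core movement is large on the scale of a core) and positive Jacobian
asserted on tissue (the background ring between independently moving cores
may legitimately compress; no tissue lives there).

What the phantoms do **not** emulate: realistic isotope envelopes or peak
shapes, stain-specific chromatics, section-to-section content differences
(the same underlying tissue generates both modalities), and acquisition
artifacts (striping, matrix crystals, TIC drift). Passing tests therefore
demonstrate the correctness and accuracy of the algorithms under the
stated deformation families and noise model, not end-to-end performance on
any particular instrument's data.

## Problem sizes and determinism

The bundled tests and the acceptance script run phantoms at 100×100 MSI
pixels (contiguous) and 150×180 (29-core TMA) with H&E rendered at the
same grid, five replicate seeds per warp family — sizes chosen so the full
evaluation completes in minutes on one CPU while leaving the studied
effects (6 px elastic warps, 10 px per-core shifts, 2-SD feature effects)
well resolved. Every stochastic step (k-means and t-SNE initialization, MI
sampling, phantom generation) is driven by an explicit seed, and identical
configurations reproduce byte-identical outputs.

## Known limitations

2-D single-pair registration only (no 3-D stacks, no groupwise
optimization); no stain normalization or deconvolution; the B-spline
bounds prevent but do not forbid folding (the Jacobian metric reports it);
SSC assumes roughly Gaussian per-feature noise after preprocessing;
processed-mode binning at the median native spacing can merge peaks closer
than the local spacing in dense regions.
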