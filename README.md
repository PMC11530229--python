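# msicoreg

Landmark-free coregistration of mass spectrometry imaging (MSI) and H&E
microscopy.

## The problem

An MSI experiment records a full mass spectrum at every pixel of a tissue
section — thousands of ion images at coarse spatial resolution — while the
H&E-stained microscopy image of the same (or an adjacent) section carries
fine morphology in three color channels. Joint interpretation requires the
two images to be in register, but they differ in resolution, aspect ratio,
framing and intensity meaning, and the tissue itself deforms between
acquisitions: globally (the section moved or rotated on the slide, each
core of a tissue microarray shifted independently during staining) and
locally (elastic stretch and compression of soft tissue). Manual
landmarking does not scale and is hard to reproduce.

`msicoreg` implements an automated workflow:

1. **Geometry harmonization** — tissue outlining (Otsu / fixed threshold /
   polygon), background removal, and an upscale/downscale strategy that
   puts both modalities on one pixel grid (`spatial_scaling`, default 4)
   with symmetric zero-padding instead of anisotropic stretch.
2. **Feature filtering** — *spatial shrunken centroids* (SSC): pixels are
   segmented by nearest shrunken centroid with spatially smoothed
   assignment; per-feature soft-thresholded t-statistics
   `d_kj = (c_kj − c̄_j) / (m_k (s_j + s_0))` score how strongly each mass
   feature distinguishes the segments. Features whose statistics survive
   the shrinkage threshold `s` are kept.
3. **Dimensionality reduction** — 1-component t-SNE collapses the selected
   ion images into a single representative MSI image, comparable to the
   inverted-grayscale H&E representative.
4. **Registration** — the representative pair is aligned by maximizing
   Mattes mutual information over a rigid, affine, or cubic B-spline
   free-form deformation (default: B-spline initialized from an affine
   stage, L-BFGS-B, linear resampling), with a multi-resolution schedule
   and analytic metric gradients.
5. **Evaluation** — dice overlap of tissue masks and Pearson correlation
   of representative intensities (global), and the displacement-field
   Jacobian determinant `det(I + ∇u)` (local: expansion > 1, contraction
   < 1, folding ≤ 0).

A synthetic phantom generator produces MSI/H&E pairs with known segment
labels, informative features, and ground-truth warps (translation, affine,
diffeomorphic elastic, independent per-core rigid motion for TMA layouts),
so every stage is testable against ground truth.

## Worked example

```python
import numpy as np
from msicoreg import (PhantomSpec, RegistrationConfig, SSCParams,
                      apply_transform, dice, make_phantom, register_images,
                      select_features, ssc_segment, to_displacement_field)
from msicoreg.embed import he_representative, tsne_embed_1d

# a 100x100 three-segment tissue, H&E side warped by a smooth elastic field
ph = make_phantom(PhantomSpec(warp=("elastic", 6, 20), seed=3))

fixed = he_representative(ph.he, ph.he_mask)
res = ssc_segment(ph.msi, SSCParams(k=3, r=2.0, s=2.0, seed=3))
print("features kept:", len(select_features(res)), "of", ph.msi.n_features)
moving = tsne_embed_1d(ph.msi, select_features(res), perplexity=30, seed=3,
                       grid_shape=ph.spec.grid)

model = register_images(fixed, moving, RegistrationConfig(seed=3))
u = to_displacement_field(model)
err = np.hypot(*(u.u - ph.true_field.u).transpose(2, 0, 1))
print("mean residual on tissue: %.3f px" % err[ph.he_mask.pixels].mean())
warped = apply_transform(ph.msi_mask, model, "nearest")
print("dice after registration: %.4f" % dice(ph.he_mask, warped))
```

Output:

```
features kept: 5 of 50
mean residual on tissue: 0.583 px
dice after registration: 0.9932
```

Five of the fifty mass features carry segment-specific signal and exactly
those survive the shrinkage threshold; the recovered B-spline deformation
reproduces the hidden 6 px elastic warp to about half a pixel on tissue,
and the warped MSI tissue mask overlaps the H&E mask almost perfectly.

## Command line

```bash
msicoreg simulate --spec phantom.yaml --out data/        # phantom bundle
msicoreg register --msi a.imzML --he b.tiff --out run/ \
    --spatial-scaling 4 --transform bspline --optimizer lbfgsb \
    --metric mattesMI --interpolator linear --seed 42
msicoreg run --config pipeline.yaml                      # full config file
msicoreg evaluate --fixed-mask ... --moving-mask ... \
    --fixed-rep ... --moving-rep ... --transform run/transform.json --out m.json
```

Every run writes representative TIFFs, the transform (JSON + coefficients),
warped images, before/after overlay PNGs, a metrics JSON and a provenance
JSON with all parameters and seeds.

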