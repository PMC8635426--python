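# histoquant

Quantitative image analysis for wound-healing and graft-remodeling
histology: trichrome color deconvolution, immunofluorescence (IF)
quantification, multicolor-reporter clonal analysis, collagen fiber
architecture statistics, and box-counting fractal dimension — each stage
validated end to end against seeded synthetic phantoms with exactly known
ground truth.

The package is aimed at researchers quantifying tissue remodeling in
histologic and confocal micrographs: how much collagen a graft deposits,
how many cells express a marker, how clonally myeloid cells proliferate,
and whether deposited collagen is fibrotically aligned or retains the
isotropic basket-weave of physiologic dermis.

## Methods at a glance

**Stain deconvolution.** Bright-field staining obeys the Beer–Lambert
law: per-channel optical density `OD_c = −log10(I_c / I0_c)` is a linear
mixture of dye densities, `OD = Cᵀ d`, where the rows of the stain matrix
`C` are unit absorbance vectors (trichrome red, trichrome blue,
counterstain):

```
C = [0.7995  0.5914  0.1053]
    [0.1000  0.7374  0.6680]
    [0.5923  0.3264  0.7366]
```

Unmixing is an exact 3×3 solve per pixel, with negative densities clipped
and the clipped fraction reported. The trichrome-blue density plane
proxies collagen; collagen content is its thresholded area fraction over
a tissue mask.

**IF quantification.** The DAPI channel is binarized with an automated
256-bin Otsu threshold; marker channels use a fixed threshold (0.30,
strict `>`). Nuclei are 8-connected components of area ≥ 15 px; marker
coverage is reported as area per cell, and relative counts (e.g. GFP⁺ /
DAPI⁺ objects) use the same size filter on both channels.

**Clonal analysis.** Each reporter color channel is thresholded and
labeled independently; components with area ≥ 2000 px are clones, smaller
ones single cells. Group comparisons use one-way ANOVA with Tukey HSD (or
Benjamini–Hochberg) post hoc tests.

**Fiber architecture.** A structure-tensor orientation field supplies
per-pixel axial angles θ ∈ [0, π), gated by tensor coherence. Angles are
doubled (axial data) before circular statistics: the alignment
coefficient `R̄ = |Σ e^{2iθ}|/n` (1 = parallel/fibrotic, ~0 = isotropic),
the Rayleigh uniformity test `z = nR̄²`, and correlation-matrix PCA over
per-image fiber features. Tissue complexity is the box-counting fractal
dimension, the slope of log N(s) vs log(1/s).

**Phantoms.** Every stage's input can be synthesized with known truth:
Beer–Lambert trichrome fields from known density planes, IF fields with
exact nucleus counts and marker areas, clone fields with exact component
areas straddling the 2000-px rule, fiber textures with von
Mises-distributed axial angles of chosen concentration κ, and binary
patterns of analytic fractal dimension.

## Worked example

```python
import numpy as np
from histoquant import (PhantomSpec, make_phantom, rgb_to_od, deconvolve,
                        tissue_mask_from_od, collagen_content, fiber_metrics)

# Trichrome phantom: uniform red+counterstain tissue, 30% blue (collagen) blobs
spec = PhantomSpec(kind="trichrome", width=256, height=256, seed=11,
                   params={"uniform": (0.3, 0.0, 0.2),
                           "coverage": {"trichrome_blue": {"fraction": 0.30,
                                                           "density": 1.0}}})
image, truth = make_phantom(spec)
od = rgb_to_od(image, i0=255.0)
dmap = deconvolve(od)
res = collagen_content(dmap, tissue_mask_from_od(od), density_threshold=0.15)
print(f"collagen area fraction: {res.area_fraction:.4f} "
      f"(truth {truth.data['collagen_area_fraction']:.4f})")

# Fiber texture with strongly concentrated orientations (kappa = 4)
fspec = PhantomSpec(kind="fiber_texture", width=512, height=512, seed=11,
                    params={"n_fibers": 300, "length": 70, "kappa": 4.0, "mu": 0.9})
fimg, _ = make_phantom(fspec)
m = fiber_metrics(fimg)
print(f"alignment R={m.alignment:.3f}, "
      f"mean axial angle {np.rad2deg(m.mean_axial_angle):.1f} deg")
```

prints

```
collagen area fraction: 0.3000 (truth 0.3000)
alignment R=0.877, mean axial angle 52.5 deg
```

The deconvolved collagen fraction matches the generated layout exactly,
and the measured alignment is close to the von Mises population value
I₁(4)/I₀(4) ≈ 0.864 at the requested mean axis of 0.9 rad ≈ 51.6°.

## Command line

```sh
histoquant demo --seed 7 --out demo/        # 12-phantom end-to-end batch
histoquant phantoms --kind trichrome --out p/ --seed 1 --params params.yaml
histoquant run --manifest manifest.csv --config config.yaml --out results/
histoquant trichrome|ifquant|clones|fibers --manifest manifest.csv ...
```

The manifest CSV maps images to stages with columns
`image_id, path, assay (trichrome|if|clone|fiber), group, timepoint`.
Per-image results are written as one CSV per stage, group summaries
(mean ± SEM, ANOVA + post hoc where group sizes permit) as JSON, and a
run record captures the config so identical configs reproduce identical
outputs byte for byte.

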