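# deepuv

Label-free analysis of deep-ultraviolet (255 nm) T cell microscopy:
static image features for **viability / activation-state** classification,
and pixelwise temporal-frequency analysis of image stacks for
**CD4-like vs CD8-like subtyping** — together with a seeded synthetic-data
generator that supplies ground truth for every stage, so the whole pipeline
runs and is tested without a microscope.

## Who this is for

Deep-UV transmission microscopy exploits intrinsic biomolecular absorption
(nucleic acids peak near 255 nm) to image live, unlabeled cells.  Static
frames carry morphology and texture; time series (~8 Hz × 500 frames)
carry intracellular dynamics.  This package implements the analysis side
of that workflow for immunology-style questions: is a T cell alive,
activated, and which subtype is it — without stains or flow cytometry.

## The core quantities

For each pixel trace `x(t)` the magnitude spectrum
`I(f) = |FFT(x - x̄)|` is computed at positive frequencies up to Nyquist,
excluding everything below 0.1 Hz.  Two summaries are derived:

* **Power-law log slope β** — `I(f) ∝ f^−β`, fitted by OLS of
  `log10 I` on `log10 f`; β ≈ 1 indicates diffuse Brownian motion,
  β ≈ 2 advective cellular motion.  Displayed over the range [1, 2].
* **Phasor (g, s)** — the first-harmonic phasor of the normalized
  spectral decay over the retained frequency axis:
  `g = Σ I cos(2πx)/Σ I`, `s = Σ I sin(2πx)/Σ I`, with
  `x = (f − f_min)/(f_Nyq − f_min)`.  A constant pixel maps to the origin;
  distance from the origin grows monotonically with β.

Per cell, these maps are averaged over the whole cell and over its
Otsu-segmented nucleus / cytoplasm compartments; the CD4-like phenotype is
characterized by higher cytoplasmic β and fluctuation amplitude, with
nuclei matched across subtypes.  Static crops yield morphology
(area, circularity, equivalent diameter, eccentricity), intensity
statistics (mean, std, 64-bin Shannon entropy, skewness, kurtosis), and a
box-counting fractal dimension per each of eight equal intensity bins
(`[(k−1)/8, k/8)`).  Features are ranked by chi-square tests and embedded
with UMAP (n_neighbors = 15, min_dist = 0.1); classification uses either a
small residual conv-net (numpy) or a deterministic linear-discriminant
baseline with the same metric interface.

## Worked example

```python
import numpy as np
from deepuv import synth, dynamics, pipeline

cfg = synth.SceneConfig(n_cells=10, class_mix={"cd4": 0.5, "cd8": 0.5},
                        seed=7, n_frames=500, frame_rate=8.0)
frame, truth = synth.make_scene(cfg)
stack = synth.render_stack(cfg, frame, truth)          # (500, 256, 256)
table, labels, _ = pipeline.dynamic_cell_features(stack, frame, truth)
cd4, cd8 = table[labels == "cd4"], table[labels == "cd8"]
t, p = dynamics.compare_groups(cd4["cyto_mean_beta"], cd8["cyto_mean_beta"])
```

printing (via the obvious format strings):

```
cells detected: 10 (6 CD4-like, 4 CD8-like)
cytoplasm mean beta: CD4-like 1.690, CD8-like 1.298
nucleus   mean beta: CD4-like 1.190, CD8-like 1.161
cytoplasm beta t-test: t = 163.3, p = 2.21e-15
```

The scene was generated with CD4-like cytoplasm β = 1.7 and CD8-like
β = 1.3 (nuclei matched at 1.15): the pipeline segments the cells,
recovers the cytoplasmic exponents to ~0.01, finds the nuclear dynamics
statistically matched, and separates the subtypes — the same structure the
method reports on real T cells.

A full demo run (scenes → segmentation → features → dynamics → baseline
classifiers → metrics JSON) is one call or one command:

```bash
deepuv report --seed 0 --out runs/demo
deepuv sweep-frames --counts 100,300,500 --out sweep.csv
```

## Layout

| module | contents |
| --- | --- |
| `deepuv.synth` | scene/trace/stack generator with ground truth |
| `deepuv.segment` | background correction, cell + nucleus segmentation, crops |
| `deepuv.features` | static/fractal features, chi-square ranking, UMAP |
| `deepuv.dynamics` | spectra, power-law fits, phasors, maps, group tests |
| `deepuv.classify` | residual net, linear baseline, CV, composition |
| `deepuv.pipeline` | dataset builders, end-to-end runs, frame sweep |
| `deepuv.cli` | `deepuv` command-line interface |

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
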