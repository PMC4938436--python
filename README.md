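# specmix

Binary-constrained linear unmixing of excitation-concatenated spectral
images, for identifying objects labeled with *pairs* of fluorophores.

## The problem

Fluorescence imaging can only distinguish as many labels as its spectral
channels and signal-to-noise allow: plain linear unmixing solves
`y = F x` for the abundances `x` of `n` fluorophores given an observed
`m`-channel spectrum `y` and an `m x n` reference matrix `F`, and needs
`m >= n` with decent SNR in every channel. Combinatorial labeling breaks
this ceiling: if every object (say, a FISH-labeled microbial cell) carries
exactly **two** fluorophores, then `n` dyes encode `C(n, 2)` distinguishable
*label types* — 120 from 16 — far more than the channel count would allow as
independent unknowns.

`specmix` implements the three ingredients that make this work:

1. **Excitation concatenation.** Emission spectra recorded at `p` different
   laser lines are joined end-to-end into one `m`-channel vector, so both
   excitation and emission information constrain the fit. Reference spectra
   are peak-normalized after concatenation (the brightest
   excitation/emission channel is unit intensity).
2. **Per-object averaging.** The raw spectral image is segmented
   (Otsu threshold on a channel-sum image, 8-connected components) and pixel
   spectra are averaged over each particle *before* unmixing — ~10,000×
   fewer least-squares problems for ~100 cells in a 1024×1024 field, and
   √N-fold noise reduction for an N-pixel cell.
3. **The binary label constraint.** For each particle the model
   `y = f_i x_i + f_j x_j + b` (with `b` a fixed stray-light background
   estimated from a cell-free ROI) is fitted by non-negative least squares
   for *every* pair `{i, j}`, and the pair with the smallest sum of squared
   residuals wins. Assignment confidence is the Pearson correlation between
   the observed and reconstructed spectrum.

A general solver policy is used throughout: ordinary least squares first,
and only when an abundance comes back negative is the non-negativity-
constrained problem solved (a fluorophore cannot have negative abundance).

A simulation module generates everything needed to validate the pipeline
without a microscope: parametric Gaussian excitation/emission fluorophores,
binary-labeled elliptical cells in an image, constant background, and
Poisson shot noise at a controlled SNR (peak expected photon count
`snr²`).

## Worked example

```python
import numpy as np
from specmix import simulation as sim
from specmix.spectra import concatenate_stacks
from specmix.segmentation import compute_threshold, segment_particles
from specmix.unmixing import classify_image

layout = sim.default_layout()                    # 6 lasers, 120 channels
spec = sim.SimulationSpec(sim.DEFAULT_FLUOROPHORES, layout, snr=20.0, seed=0)
pairs = [(0, 1), (4, 5), (10, 15)]               # three label types
stacks, truth = sim.generate_synthetic_image(
    spec, pairs, shape=(256, 256), n_cells=60)

image = concatenate_stacks(stacks, layout)       # (120, 256, 256)
mask = segment_particles(image, compute_threshold(image))
ref = sim.reference_matrix_from_models(sim.DEFAULT_FLUOROPHORES, layout)
table = classify_image(image, mask, ref, np.full(layout.m, 2.0))
score = sim.score_assignments(table, truth)
print(mask.n_particles, score["percent_correct"], score["proportion_correlation"])
```

prints

```
60 100.0 1.0
```

— all 60 segmented cells were assigned their true fluorophore pair, and the
detected label-type proportions match the input proportions exactly.

The same pipeline is available from the shell:

```
specmix simulate --out sim/ --n-cells 200 --snr 20 --seed 0
specmix classify --stacks sim/ --layout sim/layout.yaml \
    --references sim/references.csv --roi 0,0,16,16 --out results/
specmix experiment snr --out snr.csv --plot snr.png
```

`classify` writes a per-particle assignment CSV, a 16-bit label mask and a
pseudo-colored label-type map; `experiment snr` writes the percent-correct
vs SNR comparison of constrained vs standard unmixing.

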