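# ajquant

Per-cell quantification of adherens-junction remodeling in confocal
fluorescence microscopy: where a marker sits inside each cell (membrane
ring vs nucleus vs cytoplasm), how much of each cell's boundary touches
its neighbors, and how strongly two markers co-localize — plus a
synthetic-scene generator with planted ground truth so the whole
pipeline is testable without microscope data.

## Who this is for

Cell biologists quantifying junction markers (E-cadherin, β-catenin and
their regulators) in sparse adherent cultures imaged by confocal
microscopy, and anyone who needs reproducible, scriptable versions of
the classic per-cell measurements usually done by hand in ImageJ/Matlab:
compartment intensity ratios, percent cell–cell contact, and
mask-restricted Manders/PDM co-localization.

## The measurements

Every metric is computed per individual cell (typically 10–40 cells per
condition), on background-subtracted channels (a scalar per channel,
median by default), inside three masks per cell:

* **cell** — the supplied outline (label mask or polygons, center-sampling
  rasterization);
* **membrane** — a ring of width *w* (default 3 px) along the cell
  boundary: the cell mask minus its morphological erosion;
* **nucleus** — pixels with DAPI strictly above a threshold (default
  60 counts), membrane pixels removed, largest connected component kept.

With `I_R = Σ_{i∈R} I_i` the summed intensity over mask `R`:

* distribution ratios `I_membrane / I_cell` and `I_nucleus / I_cell` —
  ratios of sums from the same acquisition, hence invariant to detector
  gain and zoom ("internal calibration") — plus the size-normalized
  total `I_cell / area`;
* percent cellular contact
  `%contact = 100 × shared perimeter / total perimeter`, with the
  boundary length measured by an 8-connected chain estimator
  (straight 1, diagonal √2; Crofton available) and the shared portion
  defined as boundary pixels within Chebyshev distance 2 of another cell;
* longitudinal/horizontal extents and their ratio (moment-ellipse axes);
* split Manders coefficients restricted to a compartment
  (`M1 = Σ A_i [B_i > 0] / Σ A_i`, symmetric for `M2`), PDM maps
  `(A_i − Ā)(B_i − B̄)` and 64×64 frequency scatter histograms;
* condition comparisons: two-tailed Student's t-test on per-cell values
  (Welch optional), mean ± SEM, with `*` for P < 0.05 and `**` for
  P < 0.01.

The synthetic generator plants all of these: compartment fractions are
budgeted exactly, cell adjacency is built from coincident polygon edges
(isolated / closed-chain / clustered layouts), co-localization is a
per-pixel texture mixture with level ρ, and noise is Poisson shot plus
Gaussian read noise. See `docs/methods.md` for the model.

## Worked example

```python
from ajquant import (SceneSpec, ChannelParams, NoiseParams,
                     generate_scene, analyze_scene)

channels = {
    "DAPI": ChannelParams(background_level=5, cell_amplitude=50,
                          membrane_fraction=0, nucleus_fraction=1, smooth=True),
    "A488": ChannelParams(membrane_fraction=0.6, nucleus_fraction=0.1),
    "A555": ChannelParams(membrane_fraction=0.6, nucleus_fraction=0.1),
}
spec = SceneSpec(n_cells=6, adjacency_mode="chained",
                 target_contact_fraction=0.25, cell_size=100,
                 channels=channels, coloc_rho=0.75,
                 noise=NoiseParams(poisson=True, gaussian_sd=5.0), seed=11)
image, truth = generate_scene(spec)
res = analyze_scene(image, truth.cells)
print(res["profiles"].query("channel == 'A488'")
      [["cell_id", "ratio_membrane", "ratio_nucleus"]].round(3))
```

This prints (planted: 60% membrane, 10% nucleus, 25% contact, ρ = 0.75):

```
 cell_id  ratio_membrane  ratio_nucleus
       1           0.604          0.099
       2           0.603          0.097
       ...
```

and `res["morphology"]` / `res["coloc"]` give, for the same cells,
`percent_contact` ≈ 26.2–26.9 (planted 25, measured on the digital
boundary) and nuclear `M1` ≈ 0.92–0.95: the measured values recover the
planted scene parameters to within the pipeline's documented pixel-level
tolerances.

The same stages are available from the shell:

```bash
ajquant simulate --out scene/ --seed 11
ajquant metrics  --image scene/image.tif --outlines scene/cells.tif --out out/
ajquant coloc    --image scene/image.tif --outlines scene/cells.tif \
                 --channels A488,A555 --region nucleus --out coloc.csv
```

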