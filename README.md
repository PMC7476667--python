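# ubmseg

Segmentation and morphometry of Schlemm's canal (SC) and the trabecular
meshwork (TM) in ultrasound biomicroscopy (UBM) images.

The TM–SC pathway drains most of the aqueous humor, so the geometry of this
region — how the canal lumen and the meshwork band deform as intraocular
pressure (IOP) changes — is a readout of outflow physiology and a target of
glaucoma research. UBM shows the region as a bright tissue band with a dark,
horizontally elongated lumen, but the images carry a strong multiplicative
intensity inhomogeneity (bias field) plus speckle and Gaussian noise, which
defeats plain intensity clustering. `ubmseg` provides, behind one API:

* **Segmentation** — K-means and fuzzy C-means baselines on pixel
  intensities, and a two-phase **level-set method with joint bias-field
  estimation** by local intensity clustering;
* **Morphometry** — SC area, SC perimeter, SC length, and TM width in pixel
  units, measured by edge-detection-based pixel counting;
* **Agreement statistics** — relative error, two-way random-effects
  ICC(2,1), paired t-tests, and Pearson correlation with linear regression
  of each measure against IOP;
* **Synthetic phantoms** — a generator that emulates the UBM imaging model
  with full ground truth (label masks, bias field, geometry), including
  rising-IOP series in which the SC and TM shrink monotonically, so the
  whole chain is testable without clinical data.

## The model

The observed image is modelled as

```
I(x) = B(x) · J(x) + n(x)
```

with `J` piecewise constant (one intensity `c_i` per tissue region `Ω_i`),
`B` a slowly varying positive bias field, and `n` zero-mean Gaussian noise.
Within the truncated-Gaussian neighbourhood `k` of any point, `B` is nearly
constant, so local intensities cluster around `B(y)·c_i`. Integrating this
local clustering criterion over the image domain gives the data energy

```
ε(φ, c, b) = Σ_x Σ_i e_i(x) u_i(x),
e_i(x)     = Σ_y k(y − x) (I(x) − b(y) c_i)²,
```

with two-phase memberships `u₁ = H(φ)`, `u₂ = 1 − H(φ)` built from a
smoothed Heaviside of a level-set function `φ`. The total energy
`F = ε + ν·L(φ) + μ·R_p(φ)` adds a contour-length penalty and a distance
regulariser. Minimisation alternates exact closed-form updates of the
region constants `c` and the bias `b` with gradient-descent steps on `φ`;
the estimated bias is divided out of the image for bias correction. Only
the products `b·c_i` are identifiable, so bias comparisons are made after
mean normalisation.

## Worked example

```python
from ubmseg import PhantomSpec, generate_phantom, segment_levelset, select_regions, dice

truth = generate_phantom(PhantomSpec(seed=3))   # 150×100 ROI, bias 0.3, noise 0.02
out = segment_levelset(truth.observed_image)
sel = select_regions(out.label_mask)
print(dice(sel.sc_mask, truth.sc_mask))
```

Running `python examples/02_compare_segmenters.py` prints:

```
SC Dice vs truth, kmeans  : 0.000
SC Dice vs truth, fcm     : 0.000
SC Dice vs truth, levelset: 1.000
bias-field correlation with truth: 0.903
level-set outer iterations: 49
```

Under a 0.3-amplitude bias field the intensity histograms of the dark lumen
and the locally darkened background overlap, so the clustering baselines
select the wrong dark component (Dice 0), while the bias-aware level set
recovers the lumen exactly and its bias estimate tracks the true field.
The other examples generate phantoms (`01`), quantify agreement with ICC
and paired t-tests (`03`), and run the full pipeline on a rising-IOP series
(`04`), which prints strongly negative Pearson correlations of all four
geometric measures with IOP — e.g. `sc_area vs IOP: r = -0.997`.

A thin CLI wraps the same pipeline: `ubmseg simulate|segment|measure|stats|run`
(see `ubmseg --help`).

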