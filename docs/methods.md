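# Methods

## Imaging model and segmentation energies

All segmenters operate on 2-D grayscale images in `[0, 1]` (8-bit inputs are
scaled by 255), row-major with row 0 at the top. The observed image is
modelled as `I = B·J + n`: `J` piecewise constant over disjoint tissue
regions with distinct constants `c_i`, `B` a strictly positive,
slowly varying multiplicative bias field, `n` zero-mean Gaussian noise.

**K-means / FCM.** Both cluster pixel intensity alone (the 1-D feature the
classical formulations use). K-means minimises the within-cluster sum of
squares by Lloyd alternation; centroids start at evenly spaced intensity
quantiles (deterministic), with optional seeded random initialisation and an
`exhaustive` mode that polishes every contiguous split of the sorted
intensities — for 1-D data the optimal clusters are contiguous in sorted
order, so this attains the global minimum on small inputs. Empty clusters
re-seed to the intensity farthest from its centroid. FCM alternates the
closed-form membership update with weighted-mean centroids; a pixel exactly
on a centroid gets crisp membership on the first coincident centroid.
Defaults: K = 3 (dark lumen / mid tissue / bright band), fuzzifier m = 2,
relative objective tolerance 1e-6, 100 iterations. Clusters are relabelled
so centroids ascend; label 0 is always the darkest class.

**Level set.** The data energy is the local intensity-clustering criterion
(see README for the formulas), with a truncated Gaussian kernel on a
`(2ρ+1)²` stencil, two-phase memberships from a smoothed Heaviside, a
length penalty `ν·Σ δ(φ)|∇φ|` and the distance regulariser
`μ·Σ ½(|∇φ|−1)²`. One outer iteration performs: exact c-update, exact
b-update, then 10 explicit gradient steps on φ. Termination when the
relative change of the total energy F falls below `energy_tol` or at
`max_iter`; non-convergence is recorded in the returned state, not raised.

### Numerical choices

* **Border handling.** All kernel sums truncate at the image border (no
  padding). This makes the closed-form `c` and `b` updates *exact*
  minimisers of the discrete energy — each update provably never increases
  ε — and because both are ratios of kernel sums, the bias estimate is not
  attenuated near edges.
* **Smoothed Heaviside.** Compact-support sine ramp:
  `H(x) = ½(1 + x/ε + sin(πx/ε)/π)` on `[−ε, ε]`, 0/1 outside; `δ = H'`.
  The lumen occupies ~1% of an ROI, so any heavy-tailed smoothing (e.g. an
  arctan profile) lets the vast background dominate the lumen phase's
  intensity statistics and collapses the constants; compact support keeps
  memberships exactly crisp away from the contour and confines the
  evolution force to the contour band, which also prevents spurious phase
  flips far from the contour.
* **Monotone descent.** The φ step uses backtracking: if the explicit step
  would raise F, the timestep is halved (up to 6 times, else the step is
  skipped). Combined with the exact c/b minimisers this makes the energy
  trace non-increasing by construction, which the tests assert at relative
  tolerance 1e-6.
* **Stability.** The explicit scheme enforces `timestep·μ < 0.25`;
  violations raise at configuration time. Divergence (non-finite φ) raises
  an error naming the step size.
* **Initialisation.** Default is a dark-lumen threshold at
  `q₀.₀₀₁ + 0.4·(q₅₀ − q₀.₀₀₁)` of the intensity distribution: the 0.1st
  percentile sits inside the lumen whenever the lumen covers ≥ 0.1% of the
  ROI, and variance-based splits (Otsu) are unusable here because they
  ignore a ~1% minority class in favour of halving the background. A
  centered rectangle and a user mask are also available. φ starts as a
  binary step ±2.

### Parameter defaults and why

| parameter | default | meaning / rationale |
|---|---|---|
| σ (kernel) | 40 px | neighbourhood over which the bias is treated as constant. Must exceed the anatomical feature scale (the ~11 px TM band) or tissue structure is absorbed into the bias estimate; must stay below the inhomogeneity's dominant scale. 40 px suits ROI-sized (~150×100) inputs. |
| ρ (radius) | 2σ | standard truncation of the Gaussian stencil |
| ν (length) | 0.003 | on [0,1] intensities; suppresses noise specks without rounding the lumen tips |
| μ (distance reg.) | 0.2 | keeps φ well-conditioned; larger values smooth the zero contour off the pixel grid that the data term pins it to, costing ~1 px of boundary accuracy |
| timestep | 0.1 | explicit scheme, `dt·μ` well under the 0.25 bound |
| ε (Heaviside) | 0.5 px | half-width of the membership transition |
| max_iter / energy_tol | 200 / 1e-6 | typical convergence in ~50 outer iterations on ROI phantoms |

Two phases only: the formulation segments {lumen} vs {rest}. For TM
morphometry the pipeline expands the level-set result to three classes by
clustering the bias-corrected intensities of the non-lumen phase
(`expand_levelset_labels`), so TM width is measurable from the same run.

## Morphometry

* SC area = pixel count of the selected SC mask.
* SC perimeter = count of inner 4-neighbour boundary pixels (a mask pixel
  with ≥ 1 four-neighbour outside; the image border counts as outside).
  A Canny-based boundary is provided as a cross-check, but Canny on a
  binary mask rides the outer 8-connected contour and its count runs
  roughly 30% above the inner-4 contract at lumen scale, and depends on its
  pre-smoothing and hysteresis settings — hence inner-4 is canonical.
* SC length = mean of the three largest per-row SC pixel counts (the lumen
  is horizontally elongated, so rows measure its extent).
* TM width = mean of the three largest per-column TM pixel counts (vertical
  band thickness). A Sobel variant binarises the band's boundary curves and
  counts band pixels between the outermost edge rows per column; the two
  agree within a pixel on clean bands, and band thickness is the default
  because the inter-edge reading is ambiguous at columns where the band
  touches the lumen.
* Region selection from a label mask: SC is the largest 8-connected
  component of the darkest class; TM is the brightest class's component
  adjacent to SC (largest bright component as fallback). With fewer than
  three nonempty rows/columns the mean is over what exists and a warning is
  logged; empty regions yield zero measures plus explicit flags.

All measures are in pixel units. Physical calibration is out of scope.

## Agreement statistics

* Relative error `|measured − reference| / reference`.
* ICC(2,1): single-measure, absolute-agreement intraclass correlation from
  the two-way random-effects ANOVA mean squares,
  `(MS_R − MS_E) / (MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E))`. Chosen because
  systematic offsets between raters/methods are part of measurement error
  in method comparison; the form tag is recorded in the result. Negative
  estimates are reported as computed and flagged, never clipped; an
  all-identical table is undefined (flagged NaN). Note the ICC needs
  between-subject spread to be meaningful: a suite of phantoms with
  identical true geometry has no subject variance, so agreement tables are
  built over series whose geometry varies (e.g. the IOP series).
* Paired t-test on `d = x − y` with `n − 1` df, two-sided p; zero-variance
  differences are flagged (t = 0, p = 1 if the mean difference is zero,
  else infinite t with p = 0).
* Pearson r with least-squares regression; two-sided p via
  `t = r√((n−2)/(1−r²))`. Zero variance raises.
* p-values are two-sided throughout; no multiple-testing correction.

## Synthetic phantoms

The generator emulates a cropped UBM ROI of the iridocorneal angle:
background tissue at intensity 0.55, a gently curved bright TM band (0.80,
11 px thick, parabolic sag 6 px), and a dark SC lumen (0.10) as an ellipse
with semi-axes (12, 4) px carved out of the band, in a 150×100 ROI. These
defaults put the ground-truth geometry on the scale clinical reports give
for this region (SC area ≈ 150 px, length ≈ 22 px, TM width ≈ 11 px). The
constants place the background closer to the band than to the lumen, as in
UBM where the lumen is anechoic and all tissue is comparatively echogenic.

The bias field is `1 + a·f` with `f` a fixed-weight blend (0.40 / 0.10 /
0.25) of a random linear ramp, a small random quadratic, and white noise
smoothed at the scale parameter (default 30 px), each demeaned and
max-normalised. The weights sum to < 1, so `a` bounds `|B − 1|`, the mean
is exactly 1, and the worst-case local gradient keeps the field's relative
range over any 5-px-radius disc below 5% at amplitude 0.3 — the
slowly-varying assumption holds by construction rather than per-seed luck.
Gaussian noise (default σ = 0.02) is additive; optional unit-mean gamma
speckle (off by default, since the additive model is the baseline) is
multiplicative and folded into the stored noise term so that
`I = B·J + n_realised` holds bit-exactly. Geometry truth is computed from
the label mask by direct pixel enumeration, independently of the
measurement module.

Rising-IOP series scale the SC semi-axes and TM thickness by a linear
monotone shrink model (defaults: SC scale `1 − 0.018·(IOP − IOP_min)`, TM
scale `1 − 0.008·(IOP − IOP_min)`), emulating compression of the outflow
tissues under acute pressure elevation; each level redraws bias and noise
from child seeds.

**What the phantoms do not emulate:** ultrasound physics (point-spread,
attenuation, scan conversion), partial-volume boundaries (each pixel is
purely one tissue), anatomical variability of the angle, or the operator-
dependent image-quality spectrum of clinical UBM. Passing tests therefore
demonstrate correctness of the algorithms under the stated imaging model
and favourable lumen contrast — not clinical-grade performance; on real
images the boundary jitter, speckle, and quality triage will dominate.

## Validation problem sizes

The test suite and the acceptance script validate on 20-phantom suites
(150×100, bias amplitude 0.3, noise σ 0.02) and 20-level IOP series —
sizes at which the brute-force oracles (assignment enumeration, dense
centroid grids, double-sum energies on 1×8 images, sliding-disc bias
checks) remain exact and fast while every pipeline stage is exercised
end-to-end.

## Known limitations

* Two-phase formulation: more than two tissue classes are handled only via
  the post-hoc expansion of the non-lumen phase; a true multiphase level
  set is out of scope.
* The bias estimate absorbs a small amount of band structure when the
  kernel scale approaches the band thickness; with the default σ = 40 the
  residual contamination limits bias-field recovery correlation to ~0.95 on
  three-tissue phantoms.
* Canny/Sobel boundary counts are convention-sensitive; the inner-4 and
  band-thickness contracts are canonical and the alternatives are surfaced
  for comparison only.
* No physical-unit calibration, no DICOM ingestion, no automatic ROI
  localisation or image-quality scoring: inclusion/exclusion of images is
  an explicit user decision, and every exclusion is listed in the run
  report.
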