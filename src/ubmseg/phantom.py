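"""Synthetic UBM-like phantoms of the trabecular meshwork / Schlemm's canal region.

The generative model mirrors the physics-of-imaging decomposition used by
bias-field-aware segmentation methods: the observed image is

    I(x) = B(x) * J(x) + n(x)

where ``J`` is a piecewise-constant "true" image (one intensity per tissue
region), ``B`` is a strictly positive, slowly varying multiplicative bias
field, and ``n`` is zero-mean Gaussian noise.  An optional multiplicative
speckle term can be enabled to emulate the granular texture of ultrasound.

A phantom region-of-interest contains three tissue classes laid out like the
iridocorneal angle seen in a cropped ultrasound biomicroscopy frame:

* background sclera/ciliary tissue (mid gray),
* a roughly horizontal, gently curved bright band for the trabecular
  meshwork (TM), and
* a dark elliptical lumen for Schlemm's canal (SC), carved out of the band.

Every phantom carries full ground truth (label mask, bias field, noise
realisation, and geometry measured directly from the label mask), so each
downstream stage can be validated without clinical images.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "BiasParams",
    "PhantomSpec",
    "PhantomTruth",
    "generate_bias_field",
    "generate_phantom",
    "generate_iop_series",
    "linear_shrink_model",
    "write_phantom",
    "write_series",
]

# Region labels used in every ground-truth mask.
BACKGROUND, TM, SC = 0, 1, 2


@dataclass(frozen=True)
class BiasParams:
    """Shape of the multiplicative bias field.

    Parameters
    ----------
    amplitude : float
        Upper bound on ``|B - 1|``; must lie in ``[0, 1)`` so the field
        stays strictly positive.
    scale : float
        Smoothness scale in pixels of the random (non-polynomial) component;
        larger values give a flatter field.  Must be at least 5 px.
    """

    amplitude: float = 0.3
    scale: float = 30.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.amplitude < 1.0):
            raise ValueError(f"bias amplitude must be in [0, 1), got {self.amplitude}")
        if self.scale < 5.0:
            raise ValueError(f"bias smoothness scale must be >= 5 px, got {self.scale}")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic ROI.

    The intensity constants are the per-region values of the piecewise
    constant true image ``J`` and must be pairwise distinct.  All geometry
    is in pixel units with row 0 at the top of the image.
    """

    height: int = 100
    width: int = 150
    # TM band: vertical center row at the middle column, thickness, and a
    # parabolic sag (pixels of downward bow at the lateral edges).
    tm_center_row: float = 40.0
    tm_thickness: float = 11.0
    tm_curvature: float = 6.0
    # SC lumen: ellipse center (row, col), semi-axes (horizontal, vertical),
    # rotation in radians.
    sc_center: tuple[float, float] = (40.0, 75.0)
    sc_semi_axes: tuple[float, float] = (12.0, 4.0)
    sc_rotation: float = 0.0
    # True region constants (background, TM, SC) of J, in [0, 1].
    true_constants: tuple[float, float, float] = (0.55, 0.80, 0.10)
    bias_params: BiasParams = field(default_factory=BiasParams)
    noise_sigma: float = 0.02
    speckle_on: bool = False
    speckle_shape: float = 30.0
    seed: int = 0
    iop: float | None = None

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("phantom dimensions must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        c = self.true_constants
        if len(set(c)) != len(c):
            raise ValueError("true region constants must be pairwise distinct")
        if self.tm_thickness <= 0:
            raise ValueError("TM thickness must be positive")
        a, b = self.sc_semi_axes
        if a <= 0 or b <= 0:
            raise ValueError("SC semi-axes must be positive")


@dataclass(frozen=True)
class PhantomTruth:
    """A generated phantom together with its complete ground truth."""

    spec: PhantomSpec
    label_mask: np.ndarray      # (H, W) int: 0 background, 1 TM, 2 SC
    true_image: np.ndarray      # J, piecewise constant
    true_bias: np.ndarray       # B, strictly positive, mean 1
    noise: np.ndarray           # realised noise, I - B*J exactly
    observed_image: np.ndarray  # I = B*J + noise
    geometry: "TruthGeometry"
    iop: float | None = None

    @property
    def sc_mask(self) -> np.ndarray:
        return self.label_mask == SC

    @property
    def tm_mask(self) -> np.ndarray:
        return self.label_mask == TM


@dataclass(frozen=True)
class TruthGeometry:
    """SC/TM geometry of a phantom, in pixels, by direct enumeration."""

    sc_area: int
    sc_perimeter: int
    sc_length: float
    tm_width: float


def generate_bias_field(
    shape: tuple[int, int], bias_params: BiasParams, seed: int
) -> np.ndarray:
    """Generate a strictly positive, mean-one, slowly varying bias field.

    The field is ``1 + amplitude * f`` where ``f`` is a fixed-weight blend of
    a random first-order polynomial ramp, a small random quadratic, and a
    broad-Gaussian-smoothed white-noise surface, each demeaned and scaled to
    unit maximum absolute value before blending.  The blend weights are
    chosen so that the worst-case local gradient keeps the relative range of
    the field over any small disc well below the amplitude itself, honouring
    the slowly-varying assumption of the imaging model.

    Parameters
    ----------
    shape : (int, int)
        Image shape ``(rows, cols)``.
    bias_params : BiasParams
        Amplitude (bound on ``|B - 1|``) and smoothness scale in pixels.
    seed : int
        Seed for the random coefficients and the noise surface.
    """
    h, w = shape
    if h <= 0 or w <= 0:
        raise ValueError(f"bias-field shape must be positive, got {shape}")
    amp = bias_params.amplitude
    if amp == 0.0:
        return np.ones(shape, dtype=float)

    rng = np.random.default_rng(seed)
    yy, xx = np.meshgrid(
        np.linspace(-1.0, 1.0, h), np.linspace(-1.0, 1.0, w), indexing="ij"
    )
    a = rng.normal(size=5)
    lin = a[0] * xx + a[1] * yy
    quad = a[2] * (xx**2 - 1 / 3) + a[3] * (yy**2 - 1 / 3) + a[4] * xx * yy
    noise = gaussian_filter(
        rng.normal(size=shape), sigma=bias_params.scale, mode="reflect"
    )

    def _unit(f: np.ndarray) -> np.ndarray:
        f = f - f.mean()
        m = np.abs(f).max()
        return f / m if m > 0 else f

    # Fixed weights (sum < 1): bounds the worst-case slope of the blend so
    # that a 0.3-amplitude field varies by < 5% over any 5-px-radius disc.
    f = 0.40 * _unit(lin) + 0.10 * _unit(quad) + 0.25 * _unit(noise)
    f = f - f.mean()
    return 1.0 + amp * f


def _render_labels(spec: PhantomSpec) -> np.ndarray:
    """Rasterise the region partition by pixel-center membership."""
    h, w = spec.height, spec.width
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")

    # TM band: per-column center row with parabolic sag; constant per-column
    # pixel thickness so the band's vertical extent is exact.
    half_span = max(w - 1, 1) / 2.0
    center = spec.tm_center_row + spec.tm_curvature * (
        (np.arange(w) - half_span) / half_span
    ) ** 2
    t = int(round(spec.tm_thickness))
    top = np.round(center).astype(int) - t // 2
    band = (rows >= top[None, :]) & (rows < top[None, :] + t)

    # SC lumen: rotated-ellipse membership of pixel centers.
    cy, cx = spec.sc_center
    ax, ay = spec.sc_semi_axes  # horizontal, vertical semi-axes
    dx = cols - cx
    dy = rows - cy
    ct, st = np.cos(spec.sc_rotation), np.sin(spec.sc_rotation)
    u = ct * dx + st * dy
    v = -st * dx + ct * dy
    sc = (u / ax) ** 2 + (v / ay) ** 2 <= 1.0

    if not sc.any():
        raise ValueError("SC ellipse rasterises to an empty region")
    sc_rows, sc_cols = np.nonzero(sc)
    if (
        sc_rows.min() == 0
        or sc_cols.min() == 0
        or sc_rows.max() == h - 1
        or sc_cols.max() == w - 1
    ):
        raise ValueError("SC ellipse must lie strictly inside the image")

    labels = np.zeros((h, w), dtype=np.int64)
    labels[band] = TM
    labels[sc] = SC  # SC carved out of (or adjacent to) the band
    return labels


def _truth_geometry(labels: np.ndarray) -> TruthGeometry:
    """Measure SC/TM geometry from the label mask by direct enumeration.

    Intentionally self-contained (no reliance on the measurement module) so
    the ground truth is an independent reference for it.
    """
    sc = labels == SC
    tm = labels == TM

    area = int(sc.sum())
    # Inner 4-neighbour boundary: an SC pixel with at least one 4-neighbour
    # outside SC (image border counts as outside).
    padded = np.pad(sc, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    perimeter = int((sc & ~interior).sum())

    def _top3_mean(counts: np.ndarray) -> float:
        counts = counts[counts > 0]
        if counts.size == 0:
            return 0.0
        top = np.sort(counts)[::-1][:3]
        return float(top.mean())

    length = _top3_mean(sc.sum(axis=1))
    width = _top3_mean(tm.sum(axis=0))
    return TruthGeometry(area, perimeter, length, width)


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Generate one phantom ROI under ``I = B * J + n``.

    The label mask and true image depend only on the geometry; the bias
    field, Gaussian noise, and optional speckle are drawn from child streams
    of ``spec.seed`` so identical specs reproduce byte-identical phantoms.
    The stored noise array is defined as ``I - B*J`` (it therefore includes
    the speckle deviation when speckle is enabled), making the model
    identity exact by construction.
    """
    labels = _render_labels(spec)
    constants = np.asarray(spec.true_constants, dtype=float)
    true_image = constants[labels]

    ss = np.random.SeedSequence(spec.seed)
    bias_seed, noise_seed, speckle_seed = (
        int(s.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF) for s in ss.spawn(3)
    )
    bias = generate_bias_field((spec.height, spec.width), spec.bias_params, bias_seed)

    clean = bias * true_image
    observed = clean.copy()
    if spec.speckle_on:
        rng_s = np.random.default_rng(speckle_seed)
        k = spec.speckle_shape
        observed = observed * rng_s.gamma(shape=k, scale=1.0 / k, size=clean.shape)
    rng_n = np.random.default_rng(noise_seed)
    if spec.noise_sigma > 0:
        observed = observed + rng_n.normal(0.0, spec.noise_sigma, size=clean.shape)
    noise = observed - clean
    # Re-derive the observed image from the stored terms so the model
    # identity I = B*J + n holds bit-exactly, not just to rounding.
    observed = clean + noise

    return PhantomTruth(
        spec=spec,
        label_mask=labels,
        true_image=true_image,
        true_bias=bias,
        noise=noise,
        observed_image=observed,
        geometry=_truth_geometry(labels),
        iop=spec.iop,
    )


def linear_shrink_model(
    sc_rate: float = 0.018, tm_rate: float = 0.008, iop_ref: float = 10.0
) -> Callable[[float], tuple[float, float]]:
    """Linear monotone map from IOP (mm Hg) to (SC scale, TM scale).

    Both scales are 1 at ``iop_ref`` and decrease linearly with IOP,
    emulating compression of the outflow tissues as pressure rises.  Scales
    must stay in (0, 1]; an IOP outside the valid range raises.
    """

    def model(iop: float) -> tuple[float, float]:
        sc = 1.0 - sc_rate * (iop - iop_ref)
        tm = 1.0 - tm_rate * (iop - iop_ref)
        for name, s in (("SC", sc), ("TM", tm)):
            if not (0.0 < s <= 1.0):
                raise ValueError(
                    f"{name} shrink scale {s:.3f} outside (0, 1] at IOP {iop}"
                )
        return sc, tm

    return model


def generate_iop_series(
    base_spec: PhantomSpec,
    iops: Sequence[float],
    shrink_model: Callable[[float], tuple[float, float]] | None = None,
    seed: int | None = None,
) -> list[PhantomTruth]:
    """Generate one phantom per IOP with SC/TM geometry shrinking as IOP rises.

    Each phantom scales the base spec's SC semi-axes and TM thickness by the
    shrink model evaluated at its IOP; noise and bias are redrawn per
    phantom from child seeds so the series behaves like independent
    acquisitions of the same eye at different pressures.
    """
    if len(iops) == 0:
        raise ValueError("iops must be nonempty")
    if shrink_model is None:
        shrink_model = linear_shrink_model(iop_ref=min(iops))
    if seed is None:
        seed = base_spec.seed

    children = np.random.SeedSequence(seed).spawn(len(iops))
    out: list[PhantomTruth] = []
    for iop, child in zip(iops, children):
        sc_scale, tm_scale = shrink_model(iop)
        a, b = base_spec.sc_semi_axes
        spec = dataclasses.replace(
            base_spec,
            sc_semi_axes=(a * sc_scale, b * sc_scale),
            tm_thickness=base_spec.tm_thickness * tm_scale,
            seed=int(child.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF),
            iop=float(iop),
        )
        out.append(generate_phantom(spec))
    return out


# ---------------------------------------------------------------------------
# On-disk representation


def _to_uint8(image: np.ndarray) -> np.ndarray:
    return (np.clip(image, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def write_phantom(truth: PhantomTruth, directory: str | Path, stem: str) -> dict:
    """Write observed image, label mask, and truth metadata for one phantom.

    Returns the manifest entry (filenames plus IOP) for series bookkeeping.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    img_name = f"{stem}.png"
    mask_name = f"{stem}_labels.png"
    iio.imwrite(directory / img_name, _to_uint8(truth.observed_image))
    iio.imwrite(directory / mask_name, truth.label_mask.astype(np.uint8))
    meta = {
        "spec": {
            **{
                k: v
                for k, v in dataclasses.asdict(truth.spec).items()
                if k != "bias_params"
            },
            "bias_params": dataclasses.asdict(truth.spec.bias_params),
        },
        "geometry": dataclasses.asdict(truth.geometry),
        "iop": truth.iop,
    }
    with open(directory / f"{stem}.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return {"filename": img_name, "label_mask": mask_name, "iop": truth.iop}


def write_series(series: Sequence[PhantomTruth], directory: str | Path) -> Path:
    """Write a phantom series plus a CSV manifest (filename, iop)."""
    import pandas as pd

    directory = Path(directory)
    rows = []
    for i, truth in enumerate(series):
        rows.append(write_phantom(truth, directory, f"phantom_{i:03d}"))
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
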