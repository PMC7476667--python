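"""End-to-end orchestration: simulate/load -> segment -> measure -> statistics.

A run takes either a directory of grayscale ROI images with an optional
covariate table (image_id, iop_mmHg) or a synthetic phantom suite / IOP
series, applies the requested segmentation methods, extracts SC/TM geometry,
and assembles the agreement statistics: relative errors and Dice against the
reference, ICC across methods, paired t-tests versus the reference, and
Pearson/linear regression of each measure against IOP when pressures are
available.  Images that fail a segmentation method are excluded from that
method's statistics and listed in the report — never dropped silently.

Everything is reproducible from (config, seed): outputs are written with
fixed formatting so identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import geometry as geo
from . import phantom as ph
from . import stats as st
from .clustering import ClusteringConfig, fcm_segment, harden_memberships, kmeans_segment
from .levelset import LevelSetConfig, segment_levelset

__all__ = ["RunConfig", "expand_levelset_labels", "load_roi", "run_pipeline"]

logger = logging.getLogger(__name__)

MEASURES = ("sc_area", "sc_perimeter", "sc_length", "tm_width")
KNOWN_METHODS = ("kmeans", "fcm", "levelset")


class ConfigError(ValueError):
    """Invalid run configuration."""


class DataError(ValueError):
    """Unreadable or inconsistent input data."""


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one pipeline run."""

    # Input: either a directory of images (+ optional covariates CSV) ...
    images_dir: str | None = None
    covariates_csv: str | None = None
    # ... or a phantom suite (n_phantoms independent seeds) / IOP series.
    n_phantoms: int = 0
    iops: tuple[float, ...] | None = None
    phantom: dict[str, Any] = field(default_factory=dict)

    roi: tuple[int, int, int, int] | None = None  # (row, col, height, width)
    methods: tuple[str, ...] = ("kmeans", "fcm", "levelset")
    reference: str = "truth"
    kmeans: dict[str, Any] = field(default_factory=dict)
    fcm: dict[str, Any] = field(default_factory=dict)
    levelset: dict[str, Any] = field(default_factory=dict)
    output_dir: str = "ubmseg_out"
    seed: int = 0
    save_masks: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.methods:
            raise ConfigError("methods must be nonempty")
        for m in self.methods:
            if m not in KNOWN_METHODS:
                raise ConfigError(f"unknown method {m!r}")
        if self.reference != "truth" and self.reference not in self.methods:
            raise ConfigError("reference must be 'truth' or one of the methods")
        if self.images_dir is None and self.n_phantoms <= 0 and not self.iops:
            raise ConfigError("no input: set images_dir, n_phantoms, or iops")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("methods", "iops", "roi"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def load_roi(
    path: str | Path, roi: tuple[int, int, int, int] | None = None
) -> tuple[np.ndarray, dict]:
    """Load a grayscale image, optionally crop, and scale to [0, 1] float.

    ``roi`` is (row, col, height, width).  Multichannel inputs are converted
    by luminance with a warning; 8- and 16-bit integer images are scaled by
    their type maximum.
    """
    try:
        raw = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise DataError(f"cannot read image {path}: {exc}") from exc
    if raw.ndim == 3:
        logger.warning("multichannel image %s converted by luminance", path)
        rgb = raw[..., :3].astype(float)
        raw = rgb @ np.array([0.2126, 0.7152, 0.0722])
    image = np.asarray(raw, dtype=float)
    if np.issubdtype(np.asarray(raw).dtype, np.integer):
        image = image / np.iinfo(np.asarray(raw).dtype).max
    elif raw.dtype.kind == "f" and image.max() > 1.0:
        image = image / 255.0
    meta = {"path": str(path), "original_shape": tuple(image.shape), "roi": roi}
    if roi is not None:
        r, c, h, w = roi
        if r < 0 or c < 0 or r + h > image.shape[0] or c + w > image.shape[1]:
            raise DataError(f"ROI {roi} outside image bounds {image.shape}")
        image = image[r : r + h, c : c + w]
    return image, meta


def expand_levelset_labels(out) -> "LabelMask":
    """Three-class mask from a two-phase level-set result.

    The level set delineates the dark lumen; the remaining tissue is split
    into mid-gray background and the bright TM band by clustering the
    bias-corrected intensities, so TM width is measurable from the same run.
    """
    from .clustering import LabelMask

    two = out.label_mask
    rest = two.labels != 0
    vals = out.corrected[rest]
    if np.unique(vals).size < 2:
        return two
    split = kmeans_segment(vals.reshape(1, -1), ClusteringConfig(n_clusters=2))
    labels = np.zeros(two.labels.shape, dtype=np.int64)
    labels[rest] = split.labels.ravel() + 1
    sc_vals = out.corrected[~rest]
    centroids = np.array(
        [sc_vals.mean() if sc_vals.size else 0.0, *split.centroids]
    )
    return LabelMask(
        labels=labels, centroids=centroids, objective=two.objective, trace=two.trace
    )


def _method_mask(method: str, image: np.ndarray, config: RunConfig):
    if method == "kmeans":
        return kmeans_segment(image, ClusteringConfig(**config.kmeans)), None
    if method == "fcm":
        return harden_memberships(fcm_segment(image, ClusteringConfig(**config.fcm))), None
    if method == "levelset":
        out = segment_levelset(image, LevelSetConfig(**config.levelset))
        return expand_levelset_labels(out), out
    raise ConfigError(f"unknown method {method!r}")


def _gather_inputs(config: RunConfig) -> list[dict]:
    """Build the worklist: image id, pixel data, optional truth and IOP."""
    items: list[dict] = []
    if config.images_dir is not None:
        directory = Path(config.images_dir)
        paths = sorted(
            p for p in directory.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not paths:
            raise DataError(f"no PNG/TIFF images in {directory}")
        iop_by_id: dict[str, float] = {}
        if config.covariates_csv:
            cov = pd.read_csv(config.covariates_csv)
            if "image_id" not in cov or "iop_mmHg" not in cov:
                raise DataError("covariates CSV needs image_id and iop_mmHg columns")
            iop_by_id = dict(zip(cov["image_id"].astype(str), cov["iop_mmHg"]))
        for p in paths:
            image, _ = load_roi(p, config.roi)
            items.append(
                {
                    "image_id": p.stem,
                    "image": image,
                    "truth": None,
                    "iop": iop_by_id.get(p.stem),
                }
            )
        return items

    base = ph.PhantomSpec(**{**config.phantom, "seed": config.seed})
    if config.iops:
        series = ph.generate_iop_series(base, list(config.iops), seed=config.seed)
        for i, truth in enumerate(series):
            items.append(
                {
                    "image_id": f"phantom_{i:03d}",
                    "image": truth.observed_image,
                    "truth": truth,
                    "iop": truth.iop,
                }
            )
    else:
        children = np.random.SeedSequence(config.seed).spawn(config.n_phantoms)
        for i, child in enumerate(children):
            spec = dataclasses.replace(
                base, seed=int(child.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
            )
            truth = ph.generate_phantom(spec)
            items.append(
                {
                    "image_id": f"phantom_{i:03d}",
                    "image": truth.observed_image,
                    "truth": truth,
                    "iop": None,
                }
            )
    return items


def _measure_one(method: str, item: dict, config: RunConfig) -> dict:
    image_id = item["image_id"]
    mask, ls_out = _method_mask(method, item["image"], config)
    selection = geo.select_regions(mask)
    measures = geo.measure_selection(selection)
    row = {
        "image_id": image_id,
        "method": method,
        "iop": item["iop"],
        **{m: getattr(measures, m) for m in MEASURES},
        "sc_empty": measures.sc_empty,
        "tm_empty": measures.tm_empty,
    }
    if item["truth"] is not None:
        row["dice_sc"] = geo.dice(selection.sc_mask, item["truth"].sc_mask)
    if config.save_masks:
        outdir = Path(config.output_dir) / "masks"
        outdir.mkdir(parents=True, exist_ok=True)
        iio.imwrite(outdir / f"{image_id}_{method}.png", mask.labels.astype(np.uint8))
        if ls_out is not None:
            iio.imwrite(
                outdir / f"{image_id}_levelset_corrected.png",
                (np.clip(ls_out.corrected, 0, 1) * 255).round().astype(np.uint8),
            )
    return row


def _truth_row(item: dict) -> dict:
    g = item["truth"].geometry
    return {
        "image_id": item["image_id"],
        "method": "truth",
        "iop": item["iop"],
        "sc_area": g.sc_area,
        "sc_perimeter": g.sc_perimeter,
        "sc_length": g.sc_length,
        "tm_width": g.tm_width,
        "sc_empty": False,
        "tm_empty": False,
        "dice_sc": 1.0,
    }


def _stats_block(df: pd.DataFrame, config: RunConfig) -> dict:
    """Agreement and correlation statistics from the tidy measures table."""
    methods = [m for m in config.methods]
    raters = methods + (["truth"] if (df["method"] == "truth").any() else [])
    reference = config.reference if config.reference in raters else None
    stats: dict[str, Any] = {"per_measure": {}}

    for measure in MEASURES:
        wide = df.pivot_table(index="image_id", columns="method", values=measure)
        wide = wide.reindex(columns=raters).dropna()
        block: dict[str, Any] = {"n_complete": int(len(wide))}
        if len(wide) >= 2 and len(raters) >= 2:
            icc = st.icc_two_way_random(wide.to_numpy())
            block["icc"] = {
                "value": icc.value,
                "form": icc.form,
                "n_subjects": icc.n_subjects,
                "n_raters": icc.n_raters,
                "negative": icc.negative,
                "undefined": icc.undefined,
            }
        if reference is not None and reference in wide.columns:
            ref_vals = wide[reference].to_numpy()
            block["vs_reference"] = {}
            for m in methods:
                if m == reference or m not in wide.columns or len(wide) < 2:
                    continue
                vals = wide[m].to_numpy()
                rel = [
                    st.relative_error(v, r)
                    for v, r in zip(vals, ref_vals)
                    if r > 0
                ]
                tt = st.paired_ttest(vals, ref_vals)
                block["vs_reference"][m] = {
                    "relative_error_mean": float(np.mean(rel)) if rel else None,
                    "relative_error_median": float(np.median(rel)) if rel else None,
                    "t": tt.t,
                    "p_value": tt.p_value,
                    "mean_difference": tt.mean_difference,
                    "degenerate": tt.degenerate,
                }
        stats["per_measure"][measure] = block

    has_iop = df["iop"].notna()
    if has_iop.any():
        corr: dict[str, Any] = {}
        for m in methods:
            sub = df[(df["method"] == m) & has_iop]
            for measure in MEASURES:
                x = sub["iop"].to_numpy(dtype=float)
                y = sub[measure].to_numpy(dtype=float)
                if len(x) >= 3 and np.std(x) > 0 and np.std(y) > 0:
                    res = st.pearson_linreg(x, y)
                    corr.setdefault(m, {})[measure] = {
                        "r": res.r,
                        "slope": res.slope,
                        "intercept": res.intercept,
                        "p_value": res.p_value,
                        "n": res.n,
                    }
        stats["iop_correlation"] = corr

    if (df["method"] == "truth").any():
        dice_block = {}
        for m in methods:
            d = df.loc[df["method"] == m, "dice_sc"].dropna()
            if len(d):
                dice_block[m] = {
                    "median": float(d.median()),
                    "mean": float(d.mean()),
                    "n": int(len(d)),
                }
        stats["dice_sc"] = dice_block
    return stats


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full run and write measures CSV, stats JSON, and a log.

    Returns the report dict (also written to ``stats.json``): counts of
    processed/excluded image-method pairs, the tidy measures, agreement
    statistics, and the echoed configuration for provenance.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    items = _gather_inputs(config)

    rows: list[dict] = []
    excluded: list[dict] = []
    for item in items:
        for method in config.methods:
            try:
                rows.append(_measure_one(method, item, config))
            except Exception as exc:  # noqa: BLE001 - report, never drop silently
                logger.warning("excluding %s / %s: %s", item["image_id"], method, exc)
                excluded.append(
                    {"image_id": item["image_id"], "method": method, "reason": str(exc)}
                )
        if item["truth"] is not None:
            rows.append(_truth_row(item))

    df = pd.DataFrame(rows)
    if df.empty:
        raise DataError("every image failed every method")
    df = df.sort_values(["image_id", "method"], kind="stable").reset_index(drop=True)
    df.to_csv(outdir / "measures.csv", index=False, float_format="%.6f")

    report = {
        "n_images": len(items),
        "n_pairs_attempted": len(items) * len(config.methods),
        "n_pairs_processed": int((df["method"] != "truth").sum()),
        "n_pairs_excluded": len(excluded),
        "excluded": excluded,
        "stats": _stats_block(df, config),
        "config": _config_dict(config),
    }
    with open(outdir / "stats.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    with open(outdir / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(_config_dict(config), fh, sort_keys=True)
    return report


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def _json_default(obj: Any):
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
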