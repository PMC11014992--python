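"""Formats, run configuration, provenance, and assay dispatch.

TIFF reading/writing goes through tifffile; label maps are written as
16-bit TIFF; tabular outputs are UTF-8 CSV with units stated in the
header row; structured results are JSON. Coordinates are 0-based
(row, column) throughout. A run is reproducible by construction: every
parameter is echoed into a provenance record together with input
checksums, and result files are byte-identical across reruns of the same
configuration (only the provenance timestamp differs).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .stack import ImageStack, InstanceLabelMap

logger = logging.getLogger("sarcoquant")

ASSAYS = (
    "simulate",
    "segment",
    "morphometry",
    "tmre",
    "droplets",
    "tccf",
    "integrity",
)


def read_stack(
    path, pixel_size_um: float | None = None, channel_name: str = ""
) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF as an ImageStack.

    Calibration comes from ``pixel_size_um``; when absent, the TIFF
    XResolution tag is used as a fallback (with a logged note). RGB input
    is rejected; 8- and 16-bit intensities are preserved as-is.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        if pixel_size_um is None:
            pixel_size_um = _pixel_size_from_tags(tf)
            if pixel_size_um is not None:
                logger.info(
                    "calibration for %s taken from TIFF resolution tags: %g um/px",
                    path.name,
                    pixel_size_um,
                )
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected grayscale pages, got shape {data.shape}")
    if data.shape[-1] in (3, 4) and data.ndim == 3 and data.shape[0] > 8:
        raise ValueError(f"{path}: looks like an RGB image; grayscale required")
    if pixel_size_um is None:
        raise ValueError(
            f"{path}: no pixel calibration supplied and none found in TIFF tags"
        )
    return ImageStack(data, float(pixel_size_um), channel_name=channel_name)


def _pixel_size_from_tags(tf: "tifffile.TiffFile") -> float | None:
    page = tf.pages[0]
    tag = page.tags.get("XResolution")
    if tag is None:
        return None
    num, den = tag.value
    if num == 0:
        return None
    unit_tag = page.tags.get("ResolutionUnit")
    # pixels per unit -> unit per pixel; we only honour centimetre units
    if unit_tag is not None and getattr(unit_tag.value, "name", "") == "CENTIMETER":
        return 1e4 * den / num  # cm/px -> um/px
    return None


def write_stack(stack: ImageStack, path) -> None:
    """Write an ImageStack as a multi-page TIFF (dtype preserved)."""
    tifffile.imwrite(Path(path), stack.planes, photometric="minisblack")


def write_label_map(label_map: InstanceLabelMap, path) -> None:
    """Write an instance label map as 16-bit TIFF."""
    if label_map.n_instances > np.iinfo(np.uint16).max:
        raise ValueError("too many instances for a 16-bit label TIFF")
    tifffile.imwrite(Path(path), label_map.labels.astype(np.uint16))


def read_label_map(path, pixel_size_um: float) -> InstanceLabelMap:
    data = tifffile.imread(Path(path))
    if data.ndim != 2:
        raise ValueError(f"{path}: label map must be a single 2D page")
    return InstanceLabelMap(data.astype(np.int32), pixel_size_um)


def write_json(obj, path) -> None:
    """Deterministic JSON: sorted keys, round-trip float repr."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    ``params`` holds the assay-specific parameters (defaults applied by
    the assay runner); every field is echoed verbatim into the provenance
    record.
    """

    assay: str
    inputs: dict = field(default_factory=dict)  # name -> path
    pixel_size_um: float | None = None
    params: dict = field(default_factory=dict)
    rng_seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "assay": self.assay,
            "inputs": {k: str(v) for k, v in self.inputs.items()},
            "pixel_size_um": self.pixel_size_um,
            "params": self.params,
            "rng_seed": self.rng_seed,
            "out_dir": str(self.out_dir),
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_provenance(config: RunConfig, out: Path) -> None:
    record = {
        "config": config.to_dict(),
        "software": {"name": "sarcoquant", "version": __version__},
        "timestamp_unix": time.time(),
        "input_checksums": {
            name: _sha256(Path(p))
            for name, p in config.inputs.items()
            if Path(p).is_file()
        },
    }
    write_json(record, out / "provenance.json")


def run_assay(config: RunConfig) -> Path:
    """Dispatch a configured run; returns the output directory.

    Result files (CSV/JSON/TIFF) are deterministic for a fixed config and
    inputs; timestamps live only in provenance.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    runner = _RUNNERS[config.assay]
    try:
        runner(config, out)
    except Exception as exc:
        raise RuntimeError(f"assay {config.assay!r} failed: {exc}") from exc
    _write_provenance(config, out)
    return out


# --------------------------------------------------------------------------
# assay runners


def _records_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "instance_id": [r.instance_id for r in records],
            "pixel_count": [r.pixel_count for r in records],
            "area_um2": [r.area_um2 for r in records],
            "log10_area": [r.log10_area for r in records],
            "size_class": [r.size_class for r in records],
        }
    )


def _run_simulate(config: RunConfig, out: Path) -> None:
    from . import synth

    p = dict(config.params)
    kind = p.pop("kind", "mito")
    seed = config.rng_seed
    if kind == "mito":
        spec = synth.MitoImageSpec(rng_seed=seed, **p)
        stack, gt = synth.generate_mito_image(spec)
        _save_ground_truth(out, stack, gt, spec.__dict__)
    elif kind == "two_channel":
        frac = p.pop("active_fraction", 0.5)
        spec = synth.MitoImageSpec(rng_seed=seed, **p)
        total, active, gt = synth.generate_two_channel(spec, frac)
        write_stack(total, out / "total.tif")
        write_stack(active, out / "active.tif")
        _save_ground_truth(
            out, total, gt, {**spec.__dict__, "active_fraction": frac}
        )
    elif kind == "droplets":
        stack, gt = synth.generate_droplet_image(rng_seed=seed, **p)
        _save_ground_truth(out, stack, gt, {"kind": "droplets", "rng_seed": seed, **p})
    elif kind == "fillet":
        stack, realized = synth.generate_fillet_image(rng_seed=seed, **p)
        write_stack(stack, out / "image.tif")
        write_json(
            {"parameters": {"rng_seed": seed, **p}, "realized_fraction": realized},
            out / "ground_truth.json",
        )
    else:
        raise ValueError(f"unknown simulation kind {kind!r}")


def _save_ground_truth(out: Path, stack: ImageStack, gt, params: dict) -> None:
    write_stack(stack, out / "image.tif")
    write_label_map(gt.instance_map, out / "labels.tif")
    pd.DataFrame(
        {
            "instance_id": np.arange(1, gt.n_instances + 1),
            "area_um2": gt.areas_um2,
        }
    ).to_csv(out / "instances.csv", index=False)
    write_json({"parameters": params}, out / "parameters.json")


def _run_segment(config: RunConfig, out: Path) -> None:
    from . import morphometry as mm
    from . import segmentation as seg

    p = config.params
    stack = read_stack(config.inputs["image"], config.pixel_size_um)
    plane_policy = p.get("plane_policy", "max_projection")
    intensity_weight = p.get("intensity_weight", seg.DEFAULT_INTENSITY_WEIGHT)

    if "annotation" in config.inputs:
        annotation = tifffile.imread(config.inputs["annotation"]) > 0
        plane = seg._select_planes(stack, plane_policy)[0]
        bg = seg.classify_background(plane, rng_seed=config.rng_seed)
        tuning = seg.tune_parameters(
            plane,
            bg,
            annotation,
            seg.TuningConfig(
                min_cluster_size_range=tuple(
                    p.get("min_cluster_size_range", (3, 50))
                ),
                search_radius_range=tuple(p.get("search_radius_range", (0.5, 5.0))),
                n_iterations=p.get("n_iterations", 200),
                target_iou=p.get("target_iou", 0.95),
                rng_seed=config.rng_seed,
                intensity_weight=intensity_weight,
            ),
        )
        write_json(tuning.to_dict(), out / "tuning.json")
        params = tuning.best_params
    else:
        params = seg.DbscanParams(
            p.get("min_cluster_size", 10), p.get("search_radius", 2.0)
        )

    label_map = seg.segment_stack(
        stack, params, plane_policy, intensity_weight, config.rng_seed
    )
    maps = label_map if isinstance(label_map, list) else [label_map]
    for i, lm in enumerate(maps):
        suffix = f"_plane{i}" if len(maps) > 1 else ""
        write_label_map(lm, out / f"labels{suffix}.tif")
        records = mm.classify_sizes(mm.measure_areas(lm))
        _records_frame(records).to_csv(out / f"instances{suffix}.csv", index=False)


def _run_morphometry(config: RunConfig, out: Path) -> None:
    from . import morphometry as mm

    groups = {}
    for name, paths in config.params.get("groups", {}).items():
        reps = []
        for path in paths:
            lm = read_label_map(path, config.pixel_size_um)
            reps.append(mm.classify_sizes(mm.measure_areas(lm)))
        groups[name] = mm.summarize_distribution(reps, group_label=name)

    rows = []
    for name, dist in groups.items():
        for k, (s, m, l) in enumerate(dist.per_replicate_percentages):
            rows.append((name, k, s, m, l))
    pd.DataFrame(
        rows,
        columns=[
            "group", "replicate", "small_pct", "medium_pct", "large_pct",
        ],
    ).to_csv(out / "distributions.csv", index=False)

    names = list(groups)
    if len(names) == 2:
        mode = config.params.get("table_mode", "percent_as_count")
        chi2, dof, pval = mm.compare_distributions(
            groups[names[0]], groups[names[1]], table_mode=mode
        )
        write_json(
            {
                "groups": names,
                "table_mode": mode,
                "chi2": chi2,
                "df": dof,
                "p_value": pval,
            },
            out / "chi_square.json",
        )


def _run_tmre(config: RunConfig, out: Path) -> None:
    from . import fluorescence as fl

    total = read_stack(config.inputs["total"], config.pixel_size_um, "total")
    active = read_stack(config.inputs["active"], config.pixel_size_um, "active")
    p = config.params
    cfg = fl.TmreConfig(
        blur_sigma_px=p.get("blur_sigma_px", 2.0),
        outlier_radius_px=p.get("outlier_radius_px", 2),
        outlier_threshold=p.get("outlier_threshold", 50.0),
        roi=_roi_from_params(p.get("roi")),
    )
    res = fl.percent_active_mitochondria(total, active, cfg)
    write_json(
        {
            "area_total_um2": res.area_total_um2,
            "area_active_um2": res.area_active_um2,
            "percent_active": res.percent_active,
            "flagged_over_100": res.flagged_over_100,
        },
        out / "tmre.json",
    )


def _run_droplets(config: RunConfig, out: Path) -> None:
    from . import fluorescence as fl

    stack = read_stack(config.inputs["image"], config.pixel_size_um)
    p = config.params
    img = fl.to_8bit(stack.max_projection())
    _, mask = fl.isodata_threshold(img)
    h, w = mask.shape
    field_area_mm2 = h * w * (stack.pixel_size_um * 1e-3) ** 2
    pfilter = fl.ParticleFilter(
        p.get("min_area_um2", 0.0), p.get("max_area_um2", float("inf"))
    )
    count, areas, density = fl.count_particles(
        mask, pfilter, stack.pixel_size_um, field_area_mm2
    )
    pd.DataFrame({"area_um2": areas}).to_csv(out / "particles.csv", index=False)
    write_json(
        {
            "count": count,
            "density_per_mm2": density,
            "field_area_mm2": field_area_mm2,
            "filter": {"min_area_um2": pfilter.min_area,
                       "max_area_um2": pfilter.max_area},
            "threshold_method": "IsoData",
        },
        out / "droplets.json",
    )


def _run_tccf(config: RunConfig, out: Path) -> None:
    from . import fluorescence as fl

    stack = read_stack(config.inputs["image"], config.pixel_size_um)
    p = config.params
    cell = _roi_from_params(p["cell_roi"])
    bgs = [_roi_from_params(r) for r in p["background_rois"]]
    res = fl.tccf(stack.max_projection(), cell, bgs)
    write_json(
        {
            "integrated_density": res.integrated_density,
            "roi_area_px": res.roi_area_px,
            "background_mean": res.background_mean,
            "tccf": res.tccf,
        },
        out / "tccf.json",
    )


def _run_integrity(config: RunConfig, out: Path) -> None:
    from . import fluorescence as fl

    stack = read_stack(config.inputs["image"], config.pixel_size_um)
    p = config.params
    roi = _roi_from_params(p.get("cuticle_roi")) if p.get("cuticle_roi") else None
    if roi is None:
        h, w = stack.shape
        roi = fl.Roi("rectangle", [(0, 0), (h - 1, w - 1)], "full_frame")
    raw, norm = fl.muscle_integrity(
        stack.max_projection(), roi, p.get("control_mean")
    )
    write_json(
        {
            "raw_fraction": raw,
            "normalized_fraction": norm,
            "threshold_method": "IsoData",
        },
        out / "integrity.json",
    )


def _roi_from_params(spec) -> "object | None":
    from .fluorescence import Roi

    if spec is None:
        return None
    return Roi(
        shape=spec["shape"],
        vertices=[tuple(v) for v in spec["vertices"]],
        label=spec.get("label", ""),
    )


_RUNNERS = {
    "simulate": _run_simulate,
    "segment": _run_segment,
    "morphometry": _run_morphometry,
    "tmre": _run_tmre,
    "droplets": _run_droplets,
    "tccf": _run_tccf,
    "integrity": _run_integrity,
}
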