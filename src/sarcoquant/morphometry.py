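"""Mitochondrial morphometry: calibrated areas, size classes, chi-square.

Instance areas are the pixel count of each cluster multiplied by the pixel
area (µm²). Areas are log10-transformed and binned into three sizes:

* small  : log10(area) <= -0.5        (area <= ~0.316 µm²)
* medium : -0.5 < log10(area) <= 0    (up to 1 µm²)
* large  : log10(area) > 0

Per-replicate size-class percentages are averaged across replicates, and
two groups are compared with a Pearson chi-square on the resulting 2x3
table (df = 2). Two table constructions are offered: ``percent_as_count``
(rows are the mean percentages, mirroring tests run directly on averaged
percentage distributions) and ``pooled_counts`` (rows are raw instance
counts summed over replicates, the statistically orthodox variant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .stack import InstanceLabelMap

__all__ = [
    "SIZE_CLASSES",
    "MitochondrionRecord",
    "SizeClassDistribution",
    "size_class_of",
    "measure_areas",
    "classify_sizes",
    "summarize_distribution",
    "compare_distributions",
]

SIZE_CLASSES = ("small", "medium", "large")

# log10-area bin edges: X <= -0.5 small, -0.5 < X <= 0 medium, X > 0 large
_LOG10_SMALL_MAX = -0.5
_LOG10_MEDIUM_MAX = 0.0


@dataclass
class MitochondrionRecord:
    """One segmented instance with its calibrated morphometry."""

    instance_id: int
    pixel_count: int
    area_um2: float
    log10_area: float
    size_class: str | None = None


@dataclass
class SizeClassDistribution:
    """Size-class percentages of one experimental group.

    Each replicate's (small%, medium%, large%) triple sums to 100;
    ``mean_percentages`` is their arithmetic mean. Raw per-replicate
    counts are kept alongside so the pooled-counts chi-square variant
    stays computable.
    """

    group_label: str
    per_replicate_percentages: list[tuple[float, float, float]]
    mean_percentages: tuple[float, float, float]
    n_replicates: int
    per_replicate_counts: list[tuple[int, int, int]] = field(default_factory=list)


def size_class_of(log10_area: float) -> str:
    """Size class from a log10-transformed area; boundaries per the bins above."""
    if not np.isfinite(log10_area):
        raise ValueError(f"log10_area must be finite, got {log10_area}")
    if log10_area <= _LOG10_SMALL_MAX:
        return "small"
    if log10_area <= _LOG10_MEDIUM_MAX:
        return "medium"
    return "large"


def measure_areas(label_map: InstanceLabelMap) -> list[MitochondrionRecord]:
    """One record per instance: pixel count x pixel area, plus log10 area.

    Records are sorted by instance id. The label map must carry its pixel
    calibration (µm per pixel).
    """
    px = label_map.pixel_size_um
    if not np.isfinite(px) or px <= 0:
        raise ValueError("label map carries no pixel calibration")
    counts = label_map.pixel_counts()
    px_area = px * px
    records = []
    for i, n in enumerate(counts, start=1):
        n = int(n)
        if n == 0:
            continue
        area = n * px_area
        records.append(
            MitochondrionRecord(
                instance_id=i,
                pixel_count=n,
                area_um2=area,
                log10_area=float(np.log10(area)),
            )
        )
    return records


def classify_sizes(records: list[MitochondrionRecord]) -> list[MitochondrionRecord]:
    """Fill ``size_class`` on each record in place; returns the same list."""
    for rec in records:
        rec.size_class = size_class_of(rec.log10_area)
    return records


def _class_counts(records: list[MitochondrionRecord]) -> tuple[int, int, int]:
    counts = {c: 0 for c in SIZE_CLASSES}
    for rec in records:
        cls = rec.size_class or size_class_of(rec.log10_area)
        counts[cls] += 1
    return tuple(counts[c] for c in SIZE_CLASSES)


def summarize_distribution(
    per_replicate_records: list[list[MitochondrionRecord]],
    group_label: str = "",
) -> SizeClassDistribution:
    """Per-replicate percentages from each replicate's own total, then averaged."""
    if not per_replicate_records:
        raise ValueError("at least one replicate required")
    percentages = []
    counts_all = []
    for k, records in enumerate(per_replicate_records):
        if not records:
            raise ValueError(f"replicate {k} has no records")
        counts = _class_counts(records)
        total = sum(counts)
        percentages.append(tuple(100.0 * c / total for c in counts))
        counts_all.append(counts)
    mean = tuple(np.mean([p[j] for p in percentages]) for j in range(3))
    return SizeClassDistribution(
        group_label=group_label,
        per_replicate_percentages=percentages,
        mean_percentages=mean,
        n_replicates=len(percentages),
        per_replicate_counts=counts_all,
    )


def compare_distributions(
    a: SizeClassDistribution,
    b: SizeClassDistribution,
    table_mode: str = "percent_as_count",
) -> tuple[float, int, float]:
    """Pearson chi-square between two groups' size-class distributions.

    ``table_mode='percent_as_count'`` builds the 2x3 table from the mean
    percentages of each group; ``'pooled_counts'`` sums raw counts across
    replicates. Returns (chi2, df, p) with df = 2.
    """
    if table_mode == "percent_as_count":
        table = np.array([a.mean_percentages, b.mean_percentages], dtype=float)
        table = np.round(table / 1e-6) * 1e-6
    elif table_mode == "pooled_counts":
        if not a.per_replicate_counts or not b.per_replicate_counts:
            raise ValueError("pooled_counts mode requires raw per-replicate counts")
        table = np.array(
            [
                np.sum(a.per_replicate_counts, axis=0),
                np.sum(b.per_replicate_counts, axis=0),
            ],
            dtype=float,
        )
    else:
        raise ValueError(f"unknown table_mode: {table_mode!r}")

    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / table.sum()
    if np.any(expected == 0):
        raise ValueError("degenerate table: an expected cell is zero")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)
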