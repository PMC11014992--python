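"""Shared fixtures and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from sarcoquant import MitoImageSpec, generate_mito_image


def brute_force_dbscan(X: np.ndarray, min_pts: int, eps: float) -> np.ndarray:
    """Independent O(n²) DBSCAN oracle.

    Same semantics as the pipeline contract — a point is core if at least
    ``min_pts`` points (itself included) lie within ``eps``; clusters are
    connected components of core points, numbered by their first core
    point in row order; a border point joins the cluster of its
    lowest-index core neighbour — but computed from a dense distance
    matrix with union-find, sharing no code with the implementation.
    """
    n = X.shape[0]
    diff = X[:, None, :] - X[None, :, :]
    within = (diff**2).sum(-1) <= eps**2
    core = within.sum(axis=1) >= min_pts

    labels = np.zeros(n, dtype=int)
    visited = np.zeros(n, dtype=bool)
    next_label = 0
    for seed in np.nonzero(core)[0]:
        if visited[seed]:
            continue
        next_label += 1
        frontier = np.zeros(n, dtype=bool)
        frontier[seed] = True
        while frontier.any():
            visited |= frontier
            labels[frontier] = next_label
            frontier = within[frontier].any(axis=0) & core & ~visited
    for i in np.nonzero(~core)[0]:
        nb = np.nonzero(within[i] & core)[0]
        if nb.size:
            labels[i] = labels[nb[0]]
    return labels


def exhaustive_intermeans_splits(values: np.ndarray) -> list[tuple[float, float]]:
    """All intermeans fixed points of a sample, by exhaustive enumeration.

    For every split of the sorted unique values into a non-empty low and
    high part, computes m = (mean(low) + mean(high)) / 2 and keeps the
    split iff max(low) <= m < min(high), i.e. thresholding at m
    reproduces the split. Returns the (gap_lo, gap_hi) interval of
    admissible thresholds for each fixed point.
    """
    v = np.sort(np.unique(np.asarray(values, dtype=float)))
    out = []
    for k in range(1, v.size):
        low, high = v[:k], v[k:]
        lo_mask = values <= v[k - 1]
        m = 0.5 * (values[lo_mask].mean() + values[~lo_mask].mean())
        if v[k - 1] <= m < v[k]:
            out.append((v[k - 1], v[k]))
    return out


@pytest.fixture(scope="session")
def small_mito():
    """A modest synthetic mitochondria field with ground truth."""
    spec = MitoImageSpec(
        width_px=256, height_px=256, n_instances=20, rng_seed=11
    )
    stack, gt = generate_mito_image(spec)
    return spec, stack, gt


@pytest.fixture(scope="session")
def representative_mito():
    """A representative-image field matching the tuning study conditions."""
    spec = MitoImageSpec(rng_seed=5)  # 512x512, ~30 instances, SNR (180-20)/5
    stack, gt = generate_mito_image(spec)
    return spec, stack, gt
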