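"""ROI construction: R^2 thresholds, group overlap, eccentricity binning.

Eccentricity is expressed in degrees of visual angle; the outermost
represented eccentricity is 88 deg.  The default eccentricity bin edges
(0.5, 2, 2.5, 6, 20, 88) separate the stimulus representation (the 4 x 6
deg face ellipse reaches ~2 deg radius), its suppressive penumbra
(2.5-6 deg) and three far-peripheral bands; they are a configurable
convention, not a measured quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

MAX_ECCENTRICITY = 88.0
DEFAULT_ECC_EDGES = (0.5, 2.0, 2.5, 6.0, 20.0, MAX_ECCENTRICITY)
DEFAULT_STIMULUS_EXTENT = 2.0
DEFAULT_GUARD_BAND = 0.5


@dataclass
class EccentricityMap:
    """Per-voxel visual eccentricity (deg) with a validity mask."""

    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values/valid shape mismatch")
        if np.any(self.values[self.valid] < 0):
            raise ValueError("eccentricities must be >= 0")


def threshold_by_r2(r2: np.ndarray, threshold: float = 0.1) -> np.ndarray:
    """Voxels whose coefficient of determination strictly exceeds ``threshold``."""
    return np.asarray(r2) > threshold


def group_overlap_mask(masks: list[np.ndarray], min_fraction: float = 1.0 / 3.0) -> np.ndarray:
    """Voxels present in at least ``ceil(min_fraction * n_subjects)`` masks."""
    if not masks:
        raise ValueError("need at least one subject mask")
    masks = [np.asarray(m, dtype=bool) for m in masks]
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("subject masks are not on a common grid")
    need = math.ceil(min_fraction * len(masks))
    counts = np.sum(masks, axis=0)
    return counts >= max(need, 1)


def bin_by_eccentricity(
    emap: EccentricityMap,
    edges: tuple[float, ...] = DEFAULT_ECC_EDGES,
) -> tuple[np.ndarray, list[str]]:
    """Label voxels by iso-eccentricity band.

    Bins are half-open ``[e_i, e_{i+1})`` with the last bin closed at the
    outer edge.  Returns an integer label volume (-1 for voxels outside all
    bins or invalid) and the bin labels.
    """
    edges = tuple(float(e) for e in edges)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing with >= 2 values")
    labels = [f"{lo:g}-{hi:g}deg" for lo, hi in zip(edges[:-1], edges[1:])]
    out = np.full(emap.values.shape, -1, dtype=int)
    v = emap.values
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        sel = emap.valid & (v >= lo) & ((v < hi) | ((i == len(edges) - 2) & (v == hi)))
        out[sel] = i
    return out, labels


def bin_masks(labelled: np.ndarray, n_bins: int) -> list[np.ndarray]:
    return [labelled == i for i in range(n_bins)]


def define_stimulus_and_peripheral_v1(
    emap: EccentricityMap,
    v1_mask: np.ndarray,
    stimulus_extent: float = DEFAULT_STIMULUS_EXTENT,
    guard_band: float = DEFAULT_GUARD_BAND,
    outer_edge: float = MAX_ECCENTRICITY,
) -> tuple[np.ndarray, np.ndarray]:
    """Central (stimulus-representation) and peripheral V1 ROIs.

    The central ROI covers V1 voxels within ``stimulus_extent`` deg of the
    fovea (default 2 deg, the radius reached by the 4 x 6 deg face
    ellipse); the peripheral ROI extends from beyond the stimulus
    representation plus a guard band out to ``outer_edge`` (default 88 deg).
    """
    v1 = np.asarray(v1_mask, dtype=bool) & emap.valid
    if stimulus_extent <= 0 or stimulus_extent > float(np.nanmax(emap.values[v1], initial=0.0)):
        raise ValueError("stimulus extent outside the eccentricity range of V1")
    central = v1 & (emap.values <= stimulus_extent)
    peripheral = v1 & (emap.values > stimulus_extent + guard_band) & (emap.values <= outer_edge)
    if not central.any():
        raise ValueError("central V1 ROI is empty")
    if not peripheral.any():
        raise ValueError("peripheral V1 ROI is empty")
    return central, peripheral
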