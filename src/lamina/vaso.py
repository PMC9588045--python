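"""VASO processing: interleave handling, BOLD correction, T1-EPI anatomy.

A VASO acquisition alternates blood-nulled and blood-not-nulled (BOLD)
frames (nulled readout 2.088 s, not-nulled 2.737 s; effective volume TR
4.825 s).  The processing chain splits the interleaved series, cubic-
interpolates both groups onto a common uniform timebase (trimming two
frames at each end), and removes BOLD contamination by frame-wise
division of nulled by not-nulled, multiplied by -1 so that a cerebral
blood volume increase appears as a positive response.  Percent change is
taken against the fixation-epoch baseline.

The "VASO anatomy" (T1-EPI) contrast is computed per voxel from the
inverse signal variability across both frame groups divided by the mean
signal; an alternative tSNR-style mean/SD contrast is available since the
convention is ambiguous, but ``(1/sd)/mean`` is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .design import FIXATION, TR_NOTNULLED, TR_NULLED
from .synth import RunSeries


@dataclass
class VasoPair:
    """Matched blood-nulled / not-nulled series.

    ``effective_tr`` is the duration of one interleaved nulled+not-nulled
    cycle; after :func:`align_and_trim` both members share timestamps.
    """

    nulled: RunSeries
    notnulled: RunSeries
    effective_tr: float

    @property
    def aligned(self) -> bool:
        return (
            self.nulled.data.shape == self.notnulled.data.shape
            and abs(self.nulled.t0 - self.notnulled.t0) < 1e-9
            and abs(self.nulled.tr - self.notnulled.tr) < 1e-9
        )


def split_interleaved(
    series: RunSeries,
    nulled_first: bool = True,
    tr_nulled: float = TR_NULLED,
    tr_notnulled: float = TR_NOTNULLED,
) -> VasoPair:
    """Split an interleaved acquisition into its nulled/not-nulled groups.

    Frames alternate strictly; each group keeps its own acquisition
    timestamps (readout centers).  An odd or empty frame count is
    rejected.
    """
    data = series.data
    n = data.shape[0]
    if n == 0 or n % 2 != 0:
        raise ValueError(f"interleaved series needs an even, nonzero frame count (got {n})")
    eff = tr_nulled + tr_notnulled
    first, second = data[0::2], data[1::2]
    if nulled_first:
        nulled_data, notnulled_data = first, second
        t0_nulled, t0_notnulled = tr_nulled / 2.0, tr_nulled + tr_notnulled / 2.0
    else:
        notnulled_data, nulled_data = first, second
        t0_notnulled, t0_nulled = tr_notnulled / 2.0, tr_notnulled + tr_nulled / 2.0
    nulled = RunSeries(nulled_data, tr=eff, modality="nulled", design=series.design, t0=t0_nulled)
    notnulled = RunSeries(
        notnulled_data, tr=eff, modality="not-nulled", design=series.design, t0=t0_notnulled
    )
    return VasoPair(nulled=nulled, notnulled=notnulled, effective_tr=eff)


def interleave(pair: VasoPair, nulled_first: bool = True) -> RunSeries:
    """Re-interleave a split pair (inverse of :func:`split_interleaved`)."""
    a, b = (pair.nulled, pair.notnulled) if nulled_first else (pair.notnulled, pair.nulled)
    if a.data.shape != b.data.shape:
        raise ValueError("groups differ in shape; cannot interleave")
    out = np.empty((a.data.shape[0] * 2,) + a.data.shape[1:])
    out[0::2] = a.data
    out[1::2] = b.data
    return RunSeries(out, tr=pair.effective_tr / 2.0, modality="interleaved", design=a.design)


def align_and_trim(pair: VasoPair, n_trim: int = 2) -> VasoPair:
    """Cubic-interpolate both groups onto a common uniform timebase.

    The target grid has a step of half the effective TR (a temporal
    upsampling of each group by two); the first and last ``n_trim`` frames
    are dropped, which also discards any extrapolated edge samples.
    """
    for s in (pair.nulled, pair.notnulled):
        if s.n_timepoints < 8:
            raise ValueError("need at least 8 frames per group to align")
    dt = pair.effective_tr / 2.0
    t_start = max(pair.nulled.times[0], pair.notnulled.times[0])
    t_end = min(pair.nulled.times[-1], pair.notnulled.times[-1])
    k0 = int(np.ceil(t_start / dt - 1e-9))
    k1 = int(np.floor(t_end / dt + 1e-9))
    grid = np.arange(k0, k1 + 1) * dt
    grid = grid[n_trim : grid.size - n_trim]
    if grid.size < 4:
        raise ValueError("too few frames after trimming")

    def resample(s: RunSeries, modality: str) -> RunSeries:
        spline = CubicSpline(s.times, s.data, axis=0)
        return RunSeries(spline(grid), tr=dt, modality=modality, design=s.design, t0=grid[0])

    return VasoPair(
        nulled=resample(pair.nulled, "nulled"),
        notnulled=resample(pair.notnulled, "not-nulled"),
        effective_tr=pair.effective_tr,
    )


def _fixation_frames(series: RunSeries) -> np.ndarray:
    design = series.design
    if design is None:
        raise ValueError("series has no design reference for baseline epochs")
    times = series.times
    keep = np.zeros(times.size, dtype=bool)
    for cond, onset, dur in design.events:
        if cond == FIXATION:
            keep |= (times >= onset - 1e-9) & (times < onset + dur - 1e-9)
    if not keep.any():
        raise ValueError("no frames fall inside fixation epochs")
    return keep


def bold_correct(pair: VasoPair) -> RunSeries:
    """Frame-wise nulled / not-nulled division, sign flip, percent change.

    Removes multiplicative BOLD contamination (any strictly positive
    common factor cancels exactly); the result is percent change relative
    to the fixation-epoch baseline, in which a planted CBV increase is
    positive.  Non-positive not-nulled values are rejected rather than
    clipped, since silent clipping corrupts laminar profiles.
    """
    if not pair.aligned:
        raise ValueError("pair must be aligned (run align_and_trim first)")
    if np.any(pair.notnulled.data <= 0):
        raise ValueError("non-positive not-nulled values: division hazard")
    ratio = -pair.nulled.data / pair.notnulled.data
    out = RunSeries(
        ratio, tr=pair.nulled.tr, modality="vaso", design=pair.nulled.design, t0=pair.nulled.t0
    )
    baseline_frames = _fixation_frames(out)
    baseline = ratio[baseline_frames].mean(axis=0)
    denom = np.abs(baseline)
    if np.any(denom == 0):
        raise ValueError("zero fixation baseline; cannot form percent change")
    pct = 100.0 * (ratio - baseline) / denom
    return RunSeries(
        pct, tr=pair.nulled.tr, modality="vaso", design=pair.nulled.design, t0=pair.nulled.t0
    )


def vaso_anatomy(pair: VasoPair, contrast: str = "inverse-cv") -> tuple[np.ndarray, np.ndarray]:
    """T1-EPI anatomical contrast from the VASO time series itself.

    Pools all nulled and not-nulled frames per voxel.  The default
    contrast is ``(1/sd)/mean``; ``contrast="tsnr"`` gives ``mean/sd``.
    Zero-variance voxels get a NaN sentinel and are flagged in the
    returned mask instead of raising.
    """
    for s in (pair.nulled, pair.notnulled):
        if s.n_timepoints < 2:
            raise ValueError("need at least 2 frames per group")
    frames = np.concatenate([pair.nulled.data, pair.notnulled.data], axis=0)
    mu = frames.mean(axis=0)
    sd = frames.std(axis=0)
    flagged = (sd == 0) | (mu == 0)
    if flagged.any():
        warnings.warn(f"{int(np.sum(flagged))} voxels with zero variance or mean flagged")
    with np.errstate(divide="ignore", invalid="ignore"):
        if contrast == "inverse-cv":
            out = (1.0 / sd) / mu
        elif contrast == "tsnr":
            out = mu / sd
        else:
            raise ValueError(f"unknown contrast {contrast!r}")
    out = np.where(flagged, np.nan, out)
    return out, flagged
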