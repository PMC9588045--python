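"""Cortical-depth analysis: upsampling, depth growing, profiles, smoothing.

Depths are expressed as a fraction between the white-matter boundary
(depth 0) and the CSF boundary (depth 1) and partitioned into ``K = 21``
half-open bins ``[i/K, (i+1)/K)`` (last bin closed).  The 21 bins are a
visualization grid, not independent samples, which is why cross-depth
statistics go through the penalized-spline stage rather than treating bins
as independent measurements.

The depth metric is equidistant: the fraction of the Euclidean distance to
the nearest white-matter boundary voxel over the summed distances to both
boundaries.  No curvature (equivolume) correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.interpolate import BSpline

DEFAULT_N_DEPTHS = 21


@dataclass
class CorticalRibbon:
    """Gray-matter ribbon with per-voxel depth fraction and bin index.

    Boundary voxels belong to neither the gray-matter mask nor any bin;
    ``depth_bin`` is -1 outside gray matter.
    """

    wm_boundary: np.ndarray
    csf_boundary: np.ndarray
    gray_mask: np.ndarray
    depth_fraction: np.ndarray
    depth_bin: np.ndarray
    n_bins: int = DEFAULT_N_DEPTHS
    upsample_factor: int = 1

    @property
    def shape(self) -> tuple[int, ...]:
        return self.gray_mask.shape


def grow_depths(
    wm_boundary: np.ndarray,
    csf_boundary: np.ndarray,
    gray_mask: np.ndarray,
    n_bins: int = DEFAULT_N_DEPTHS,
    upsample_factor: int = 1,
) -> CorticalRibbon:
    """Assign equidistant cortical depths between the WM and CSF boundaries.

    ``depth_fraction = d_wm / (d_wm + d_csf)`` with Euclidean distances to
    the nearest boundary voxel; ``depth_bin = min(K-1, floor(K * fraction))``.
    Voxels unreachable from a boundary are excluded from the gray mask (and
    flagged with NaN depth).
    """
    wm_boundary = np.asarray(wm_boundary, dtype=bool)
    csf_boundary = np.asarray(csf_boundary, dtype=bool)
    gray_mask = np.asarray(gray_mask, dtype=bool)
    if wm_boundary.shape != csf_boundary.shape or wm_boundary.shape != gray_mask.shape:
        raise ValueError("boundary and gray masks must share a grid")
    if np.any(wm_boundary & csf_boundary):
        raise ValueError("WM and CSF boundaries intersect")
    if not wm_boundary.any() or not csf_boundary.any():
        raise ValueError("empty boundary mask: gray voxels unreachable")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")

    d_wm = ndimage.distance_transform_edt(~wm_boundary)
    d_csf = ndimage.distance_transform_edt(~csf_boundary)
    total = d_wm + d_csf
    frac = np.full(gray_mask.shape, np.nan)
    ok = gray_mask & (total > 0) & np.isfinite(total)
    frac[ok] = d_wm[ok] / total[ok]
    dropped = gray_mask & ~ok
    if dropped.any():
        warnings.warn(f"excluded {int(dropped.sum())} gray voxels unreachable from a boundary")
    bins = np.full(gray_mask.shape, -1, dtype=int)
    bins[ok] = np.minimum(n_bins - 1, np.floor(n_bins * frac[ok]).astype(int))
    return CorticalRibbon(
        wm_boundary=wm_boundary,
        csf_boundary=csf_boundary,
        gray_mask=ok,
        depth_fraction=frac,
        depth_bin=bins,
        n_bins=n_bins,
        upsample_factor=upsample_factor,
    )


def upsample_inplane(volume: np.ndarray, factor: int, kind: str = "replicate") -> np.ndarray:
    """Upsample the first two (in-plane) axes by an integer factor.

    ``kind="replicate"`` (default for data and masks) repeats each voxel
    ``factor**2`` times, so averaging over any region of the fine grid
    equals a volume-weighted average on the original grid exactly.
    ``kind="cubic"`` gives a smooth interpolation for display; masks should
    always use replication.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be an integer >= 1")
    factor = int(factor)
    volume = np.asarray(volume)
    if factor == 1:
        return volume.copy()
    if kind == "replicate":
        return np.repeat(np.repeat(volume, factor, axis=0), factor, axis=1)
    if kind == "cubic":
        zoom = [factor, factor] + [1] * (volume.ndim - 2)
        return ndimage.zoom(volume.astype(float), zoom, order=3, grid_mode=True, mode="nearest")
    raise ValueError(f"unknown interpolation kind {kind!r}")


def upsample_ribbon(ribbon: CorticalRibbon, factor: int) -> CorticalRibbon:
    """Replicate boundary/gray masks onto the fine grid and regrow depths."""
    return grow_depths(
        upsample_inplane(ribbon.wm_boundary, factor),
        upsample_inplane(ribbon.csf_boundary, factor),
        upsample_inplane(ribbon.gray_mask, factor),
        n_bins=ribbon.n_bins,
        upsample_factor=ribbon.upsample_factor * factor,
    )


@dataclass
class DepthProfile:
    """Per-depth-bin mean response (% CBV or % signal) with standard errors."""

    mean: np.ndarray
    se: np.ndarray
    n_voxels: np.ndarray
    n_bins: int
    slices_used: list[int] = field(default_factory=list)
    fit: np.ndarray | None = None
    band: np.ndarray | None = None

    @property
    def depth_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) / self.n_bins

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.mean)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "bin": np.arange(self.n_bins),
                "depth_fraction": self.depth_centers,
                "mean": self.mean,
                "se": self.se,
                "n_voxels": self.n_voxels,
            }
        )
        if self.fit is not None:
            df["fit"] = self.fit
            df["band"] = self.band
        return df


def extract_depth_profile(
    response: np.ndarray,
    r2: np.ndarray,
    ribbon: CorticalRibbon,
    roi_mask: np.ndarray,
    slice_axis: int = 2,
) -> DepthProfile:
    """Depth profile around the peak-R^2 axial slice.

    The axial slice with the highest mean R^2 inside the ROI is located,
    then per-bin responses are averaged across that slice and its two
    neighbours; the standard error is the across-voxel SE per bin.
    """
    response = np.asarray(response, dtype=float)
    roi = np.asarray(roi_mask, dtype=bool) & ribbon.gray_mask
    if response.shape != ribbon.shape or np.asarray(r2).shape != ribbon.shape:
        raise ValueError("volume/ribbon grid mismatch")
    n_slices = response.shape[slice_axis]
    if n_slices < 3:
        raise ValueError("need at least 3 slices along the slice axis")

    slice_means = np.full(n_slices, -np.inf)
    for k in range(n_slices):
        sel = np.take(roi, k, axis=slice_axis)
        if sel.any():
            slice_means[k] = np.take(np.asarray(r2, float), k, axis=slice_axis)[sel].mean()
    if not np.isfinite(slice_means).any():
        raise ValueError("ROI does not intersect any slice")
    k_peak = int(np.argmax(slice_means))
    slices = [k for k in (k_peak - 1, k_peak, k_peak + 1) if 0 <= k < n_slices]

    K = ribbon.n_bins
    mean = np.full(K, np.nan)
    se = np.full(K, np.nan)
    n_vox = np.zeros(K, dtype=int)
    sel_slices = np.zeros(ribbon.shape, dtype=bool)
    for k in slices:
        idx = [slice(None)] * ribbon.depth_bin.ndim
        idx[slice_axis] = k
        sel_slices[tuple(idx)] = True
    for b in range(K):
        vox = roi & sel_slices & (ribbon.depth_bin == b)
        vals = response[vox]
        n_vox[b] = vals.size
        if vals.size:
            mean[b] = vals.mean()
            se[b] = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
    if np.isnan(mean).any():
        warnings.warn(f"{int(np.isnan(mean).sum())} depth bins empty on the selected slices")
    return DepthProfile(mean=mean, se=se, n_voxels=n_vox, n_bins=K, slices_used=slices)


def _bspline_basis(x: np.ndarray, n_basis: int, degree: int = 3) -> np.ndarray:
    # uniform extended (unclamped) knots: polynomial trends up to the penalty
    # order have index-linear coefficients, so they are never penalized
    h = 1.0 / (n_basis - degree)
    t = (np.arange(n_basis + degree + 1) - degree) * h
    x = np.clip(x, 0.0, 1.0 - 1e-12)
    return BSpline.design_matrix(x, t, degree).toarray()


def smooth_profile(
    profile: DepthProfile,
    n_basis: int = 10,
    degree: int = 3,
    penalty_order: int = 2,
) -> DepthProfile:
    """Uncertainty-weighted penalized-spline fit of a cross-depth profile.

    A cubic B-spline basis with a second-order difference penalty is fit by
    weighted penalized least squares (weights ``1/SE^2``); the smoothing
    parameter is selected by restricted maximum likelihood.  The returned
    profile carries the fitted curve and a +-1 standard-error band of the
    fit.  Profiles that are linear in depth are reproduced exactly (the
    penalty null space contains linear trends).
    """
    good = ~profile.missing
    if good.sum() < 5:
        raise ValueError("need at least 5 non-missing bins to smooth")
    x = profile.depth_centers[good]
    y = profile.mean[good]
    se = profile.se[good].copy()
    if np.all(se == 0):
        warnings.warn("all standard errors are zero; falling back to unweighted fit")
        w = np.ones_like(y)
    else:
        se[se == 0] = se[se > 0].min()
        w = 1.0 / se**2
    n_basis = min(n_basis, good.sum() - 1)
    B = _bspline_basis(x, n_basis, degree)
    D = np.diff(np.eye(n_basis), n=penalty_order, axis=0)
    P = D.T @ D
    BtWB = B.T @ (w[:, None] * B)
    BtWy = B.T @ (w * y)
    yWy = float(y @ (w * y))
    n = y.size
    null_dim = penalty_order
    rank_p = n_basis - null_dim
    eig_p = np.linalg.eigvalsh(P)
    log_det_p_plus = float(np.sum(np.log(eig_p[eig_p > 1e-10])))

    def reml(log_rho: float) -> float:
        rho = np.exp(log_rho)
        A = BtWB + rho * P
        try:
            cho = np.linalg.cholesky(A)
        except np.linalg.LinAlgError:
            return np.inf
        beta = np.linalg.solve(A, BtWy)
        pss = yWy - 2 * beta @ BtWy + beta @ (BtWB + rho * P) @ beta
        pss = max(pss, 1e-12)
        phi = pss / max(n - null_dim, 1)
        log_det_a = 2 * float(np.sum(np.log(np.diag(cho))))
        return (n - null_dim) * np.log(phi) + log_det_a - rank_p * np.log(rho) - log_det_p_plus

    res = optimize.minimize_scalar(reml, bounds=(-12.0, 12.0), method="bounded")
    rho = float(np.exp(res.x))
    A = BtWB + rho * P
    beta = np.linalg.solve(A, BtWy)
    pss = yWy - 2 * beta @ BtWy + beta @ A @ beta
    phi = max(pss, 1e-12) / max(n - null_dim, 1)

    B_all = _bspline_basis(profile.depth_centers, n_basis, degree)
    fit = B_all @ beta
    A_inv = np.linalg.inv(A)
    cov_beta = phi * (A_inv @ BtWB @ A_inv)
    band = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", B_all, cov_beta, B_all), 0.0, None))
    out = DepthProfile(
        mean=profile.mean.copy(),
        se=profile.se.copy(),
        n_voxels=profile.n_voxels.copy(),
        n_bins=profile.n_bins,
        slices_used=list(profile.slices_used),
        fit=fit,
        band=band,
    )
    return out
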