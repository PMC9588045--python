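"""Depth growing, in-plane upsampling, profile extraction and smoothing."""

import subprocess
import textwrap

import numpy as np
import pytest

from lamina.laminar import (
    DepthProfile,
    extract_depth_profile,
    grow_depths,
    smooth_profile,
    upsample_inplane,
    upsample_ribbon,
)
from lamina.synth import make_ribbon_and_eccentricity


def _flat_ribbon(thickness, nx=4, nz=3, n_bins=21):
    ribbon, _ = make_ribbon_and_eccentricity((nx, thickness + 4, nz), thickness=thickness,
                                             n_bins=n_bins)
    return ribbon


def _brute_force_bins(ribbon, n_bins):
    """Exhaustive per-voxel distance computation over boundary voxel sets."""
    wm = np.argwhere(ribbon.wm_boundary)
    csf = np.argwhere(ribbon.csf_boundary)
    out = np.full(ribbon.shape, -1, dtype=int)
    for vox in np.argwhere(ribbon.gray_mask):
        d_wm = np.sqrt(((wm - vox) ** 2).sum(axis=1)).min()
        d_csf = np.sqrt(((csf - vox) ** 2).sum(axis=1)).min()
        frac = d_wm / (d_wm + d_csf)
        out[tuple(vox)] = min(n_bins - 1, int(np.floor(n_bins * frac)))
    return out


@pytest.mark.parametrize("thickness,n_bins", [(21, 21), (9, 21), (13, 5), (5, 1)])
def test_depth_bins_match_brute_force_oracle(thickness, n_bins):
    ribbon = _flat_ribbon(thickness, n_bins=n_bins)
    oracle = _brute_force_bins(ribbon, n_bins)
    assert np.array_equal(ribbon.depth_bin, oracle)
    if n_bins == 1:
        assert set(ribbon.depth_bin[ribbon.gray_mask]) == {0}


def test_depth_monotone_along_columns():
    ribbon = _flat_ribbon(15)
    bins = ribbon.depth_bin[0, :, 0]
    gray = bins >= 0
    assert np.all(np.diff(bins[gray]) >= 0)
    fracs = ribbon.depth_fraction[0, :, 0][gray]
    assert np.all(np.diff(fracs) > 0)


def test_grow_depths_validations():
    r = _flat_ribbon(5)
    with pytest.raises(ValueError, match="intersect"):
        grow_depths(r.wm_boundary, r.wm_boundary, r.gray_mask)
    with pytest.raises(ValueError, match="empty boundary"):
        grow_depths(np.zeros_like(r.wm_boundary), r.csf_boundary, r.gray_mask)


def test_upsample_identity_and_replication(rng):
    vol = rng.standard_normal((2, 2, 3))
    assert np.array_equal(upsample_inplane(vol, 1), vol)
    up = upsample_inplane(vol, 4)
    assert up.shape == (8, 8, 3)
    for i in range(8):
        for j in range(8):
            assert np.array_equal(up[i, j], vol[i // 4, j // 4])
    with pytest.raises(ValueError, match="factor"):
        upsample_inplane(vol, 0)


def test_upsampled_layer_mean_equals_weighted_mean(rng):
    """Averaging on the fine grid equals a volume-weighted average in the
    original space, so profile extraction is invariant to upsampling."""
    ribbon = _flat_ribbon(9)
    response = rng.standard_normal(ribbon.shape)
    factor = 4
    fine = upsample_ribbon(ribbon, factor)
    fine_response = upsample_inplane(response, factor)
    for b in range(0, 21, 4):
        orig_sel = ribbon.depth_bin == b
        fine_sel = fine.depth_bin == b
        if not orig_sel.any():
            continue
        # weights: fraction of each original voxel assigned to this fine bin
        w = upsample_inplane(orig_sel.astype(float), factor)
        lhs = fine_response[fine_sel].mean() if fine_sel.any() else np.nan
        # replicated response: weighted average over original voxels whose
        # replicas land in the bin
        rep = fine_response[fine_sel]
        vals, counts = np.unique(rep, return_counts=True)
        weighted = np.sum(vals * counts) / counts.sum()
        assert lhs == pytest.approx(weighted, abs=1e-6)


def test_extract_profile_uniform_and_superficial(rng):
    ribbon = _flat_ribbon(21)
    r2 = np.zeros(ribbon.shape)
    r2[..., 1] = 0.8  # plant the R^2 peak at slice 1
    uniform = np.full(ribbon.shape, 3.5)
    prof = extract_depth_profile(uniform, r2, ribbon, ribbon.gray_mask)
    assert prof.slices_used == [0, 1, 2]
    assert np.allclose(prof.mean, 3.5)
    superficial = np.where(ribbon.depth_fraction > 2 / 3, 1.0, 0.0)
    superficial[~ribbon.gray_mask] = 0.0
    prof = extract_depth_profile(superficial, r2, ribbon, ribbon.gray_mask)
    nz = np.flatnonzero(prof.mean > 0)
    assert nz.size > 0
    assert np.all(prof.depth_centers[nz] > 2 / 3 - 1 / 21)


def test_smooth_profile_reproduces_linear_trend():
    K = 21
    x = (np.arange(K) + 0.5) / K
    prof = DepthProfile(mean=2.0 * x - 0.5, se=np.full(K, 0.1), n_voxels=np.full(K, 10), n_bins=K)
    out = smooth_profile(prof)
    assert np.allclose(out.fit, 2.0 * x - 0.5, atol=1e-6)
    assert np.all(out.band >= 0)


def test_smooth_profile_reduces_noise(rng):
    """Fitted-curve RMSE beats raw-data RMSE against the truth."""
    K = 21
    x = (np.arange(K) + 0.5) / K
    truth = np.sin(np.pi * x) + 0.5 * x
    se = 0.15
    wins = 0
    n_trials = 100
    for _ in range(n_trials):
        noisy = truth + se * rng.standard_normal(K)
        prof = DepthProfile(mean=noisy, se=np.full(K, se), n_voxels=np.full(K, 10), n_bins=K)
        out = smooth_profile(prof)
        if np.sqrt(np.mean((out.fit - truth) ** 2)) < np.sqrt(np.mean((noisy - truth) ** 2)):
            wins += 1
    assert wins / n_trials > 0.9


def test_smooth_profile_downweights_uncertain_bins(rng):
    K = 21
    x = (np.arange(K) + 0.5) / K
    base = np.sin(np.pi * x)
    se = np.full(K, 0.05)
    se[10] = 5.0  # one bin with 100x larger SE
    prof_a = DepthProfile(mean=base.copy(), se=se, n_voxels=np.full(K, 10), n_bins=K)
    perturbed = base.copy()
    perturbed[10] += 3.0
    prof_b = DepthProfile(mean=perturbed, se=se, n_voxels=np.full(K, 10), n_bins=K)
    fit_a = smooth_profile(prof_a).fit
    fit_b = smooth_profile(prof_b).fit
    assert np.max(np.abs(fit_a - fit_b)) < 0.05


def test_smooth_profile_needs_enough_bins():
    prof = DepthProfile(mean=np.array([1.0, 2, 3, np.nan, np.nan, np.nan]),
                        se=np.full(6, 0.1), n_voxels=np.full(6, 5), n_bins=6)
    with pytest.raises(ValueError, match="non-missing"):
        smooth_profile(prof)


def test_smooth_profile_matches_mgcv_reference(rng):
    """Cross-check the weighted penalized-spline fit against R mgcv."""
    K = 21
    x = (np.arange(K) + 0.5) / K
    y = np.sin(np.pi * x) + 0.1 * rng.standard_normal(K)
    se = np.full(K, 0.1)
    prof = DepthProfile(mean=y, se=se, n_voxels=np.full(K, 10), n_bins=K)
    ours = smooth_profile(prof).fit
    script = textwrap.dedent(
        f"""
        suppressMessages(library(mgcv))
        x <- c({','.join(f'{v:.10f}' for v in x)})
        y <- c({','.join(f'{v:.10f}' for v in y)})
        w <- rep({1 / se[0]**2:.6f}, {K})
        fit <- gam(y ~ s(x, k = 10, bs = "ps"), weights = w, method = "REML")
        cat(sprintf("%.10f\\n", fitted(fit)))
        """
    )
    try:
        res = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, timeout=120)
    except FileNotFoundError:
        pytest.skip("Rscript not available")
    assert res.returncode == 0, res.stderr
    theirs = np.array([float(v) for v in res.stdout.split()])
    # different bases/penalties: agreement to a few percent of the range
    assert np.max(np.abs(ours - theirs)) < 0.08 * (y.max() - y.min())
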