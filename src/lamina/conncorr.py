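"""Residual inter-area correlation analysis.

After the mean stimulus-evoked response is removed by deconvolution, the
residual time series of each ROI is cut into condition epochs (each face
block plus its following fixation block), concatenated across blocks and
runs, and correlated between every pair of ROIs.  Valence contrasts are
differences of per-condition correlation matrices (fearful - neutral,
happy - neutral); baseline correlations are tested against zero with a
one-sided Wilcoxon signed-rank test and contrasts with a two-tailed
one-sample t test, both Bonferroni-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import FIXATION, BlockDesign


def epoch_frames(
    design: BlockDesign,
    condition: str,
    n_timepoints: int,
    tr: float | None = None,
    t0: float = 0.0,
) -> np.ndarray:
    """Frame indices belonging to the epochs of one condition.

    An epoch spans a face block from its onset through the end of the
    following fixation block; frames are assigned by their acquisition time
    ``t0 + i * tr``.
    """
    tr = design.tr if tr is None else tr
    if condition == FIXATION or condition not in {c for c, _, _ in design.events}:
        raise ValueError(f"condition {condition!r} not present in design")
    times = t0 + np.arange(n_timepoints) * tr
    keep = np.zeros(n_timepoints, dtype=bool)
    for onset, dur in design.onsets(condition):
        fix_onset, fix_dur = design.following_fixation(onset)
        keep |= (times >= onset - 1e-9) & (times < fix_onset + fix_dur - 1e-9)
    return np.flatnonzero(keep)


def extract_condition_epochs(
    residuals: dict[str, np.ndarray],
    design: BlockDesign,
    condition: str,
    tr: float | None = None,
    t0: float = 0.0,
) -> dict[str, np.ndarray]:
    """Concatenated residual epoch samples of one condition, per ROI."""
    lengths = {len(v) for v in residuals.values()}
    if len(lengths) != 1:
        raise ValueError("residual series lengths differ across ROIs")
    (n,) = lengths
    idx = epoch_frames(design, condition, n, tr=tr, t0=t0)
    return {roi: np.asarray(series, dtype=float)[idx] for roi, series in residuals.items()}


def concatenate_runs(
    runs: list[tuple[dict[str, np.ndarray], BlockDesign]],
    condition: str,
    tr: float | None = None,
) -> dict[str, np.ndarray]:
    """Concatenate condition epochs across the runs of a session."""
    rois = list(runs[0][0])
    parts = {roi: [] for roi in rois}
    for residuals, design in runs:
        ep = extract_condition_epochs(residuals, design, condition, tr=tr)
        for roi in rois:
            parts[roi].append(ep[roi])
    return {roi: np.concatenate(parts[roi]) for roi in rois}


@dataclass
class CorrMatrixSet:
    """Per-condition ROI x ROI correlation matrices and their contrasts."""

    rois: list[str]
    r: dict[str, pd.DataFrame] = field(default_factory=dict)

    def contrast(self, c1: str, c2: str) -> pd.DataFrame:
        return self.r[c1] - self.r[c2]


def correlation_matrices(
    epochs_by_condition: dict[str, dict[str, np.ndarray]],
    rois: list[str],
    method: str = "pearson",
) -> CorrMatrixSet:
    """Pairwise ROI correlations of concatenated residual epochs.

    ``method`` is ``"pearson"`` (default) or ``"spearman"``.  Zero-variance
    series produce NaN cells (flagged undefined) rather than an error.
    """
    out = CorrMatrixSet(rois=list(rois))
    for cond, epochs in epochs_by_condition.items():
        n_samples = {len(epochs[r]) for r in rois}
        if min(n_samples) < 3:
            raise ValueError("need at least 3 samples per condition")
        data = np.column_stack([epochs[r] for r in rois])
        if method == "spearman":
            data = np.apply_along_axis(stats.rankdata, 0, data)
        elif method != "pearson":
            raise ValueError(f"unknown correlation method {method!r}")
        sd = data.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mat = np.corrcoef(data, rowvar=False)
        mat[sd == 0, :] = np.nan
        mat[:, sd == 0] = np.nan
        np.fill_diagonal(mat, 1.0)
        out.r[cond] = pd.DataFrame(mat, index=rois, columns=rois)
    return out


def average_sessions(matrices: list[pd.DataFrame], fisher_z: bool = False) -> pd.DataFrame:
    """Average correlation matrices across sessions of one participant.

    The default is a plain average of r; Fisher-z averaging is available
    by flag.
    """
    if fisher_z:
        stacked = np.stack([np.arctanh(np.clip(m.to_numpy(), -1 + 1e-12, 1 - 1e-12)) for m in matrices])
        avg = np.tanh(stacked.mean(axis=0))
    else:
        avg = np.stack([m.to_numpy() for m in matrices]).mean(axis=0)
    return pd.DataFrame(avg, index=matrices[0].index, columns=matrices[0].columns)


def test_baseline_correlations(values: np.ndarray, m: int = 1) -> tuple[float, float, float]:
    """One-sided Wilcoxon signed-rank test of per-subject r against zero.

    Returns (statistic, p, Bonferroni-adjusted p with ``p_adj = min(1, m p)``).
    Zeros are discarded by the standard convention; an all-zero vector is
    undefined and returns NaN.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ValueError("need at least 5 subjects")
    if np.all(values == 0):
        return np.nan, np.nan, np.nan
    res = stats.wilcoxon(values, alternative="greater", zero_method="wilcox")
    return float(res.statistic), float(res.pvalue), min(1.0, m * float(res.pvalue))


def test_contrast(diffs: np.ndarray, m: int = 1) -> tuple[float, float, float]:
    """Two-tailed one-sample t test of per-subject correlation differences.

    Zero variance with a nonzero mean yields an infinite statistic (flagged
    by ``inf``); zero variance and zero mean is undefined (NaN).
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size < 3:
        raise ValueError("need at least 3 subjects")
    sd = diffs.std(ddof=1)
    if sd == 0:
        if diffs.mean() == 0:
            return np.nan, np.nan, np.nan
        return float(np.sign(diffs.mean()) * np.inf), 0.0, 0.0
    res = stats.ttest_1samp(diffs, 0.0)
    return float(res.statistic), float(res.pvalue), min(1.0, m * float(res.pvalue))


def matrix_tests(
    per_subject: list[pd.DataFrame],
    kind: str = "contrast",
    correction_cells: int | None = None,
) -> pd.DataFrame:
    """Cell-wise group tests over a stack of per-subject matrices.

    ``kind="baseline"`` applies the one-sided Wilcoxon test, ``"contrast"``
    the two-tailed t test.  The Bonferroni denominator defaults to the
    number of tested cells (the lower-triangle count); pass
    ``correction_cells`` to use another convention (e.g. the ROI count).
    """
    rois = list(per_subject[0].index)
    pairs = [(i, j) for i in range(len(rois)) for j in range(i + 1, len(rois))]
    m = correction_cells if correction_cells is not None else len(pairs)
    stack = np.stack([df.to_numpy() for df in per_subject])
    rows = []
    for i, j in pairs:
        vals = stack[:, i, j]
        vals = vals[np.isfinite(vals)]
        if kind == "baseline":
            stat, p, p_adj = test_baseline_correlations(vals, m=m)
        elif kind == "contrast":
            stat, p, p_adj = test_contrast(vals, m=m)
        else:
            raise ValueError(f"unknown test kind {kind!r}")
        rows.append((rois[i], rois[j], stat, p, p_adj, p_adj < 0.05))
    return pd.DataFrame(rows, columns=["roi_i", "roi_j", "stat", "p", "p_adj", "significant"])
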