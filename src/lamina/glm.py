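"""Design matrices, ordinary-least-squares GLM, and FIR deconvolution.

The canonical hemodynamic response is a double-gamma function (peak near
5 s, undershoot near 15 s).  Condition regressors are boxcars convolved
with that response on an oversampled grid and resampled at frame times;
FIR (deconvolution) designs carry one delta column per (condition, lag).
All designs are augmented with a constant and a linear drift column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.stats import gamma as gamma_dist

from .design import FIXATION, BlockDesign


def double_gamma_hrf(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled at times ``t`` (s), peak-normalized to 1."""
    t = np.asarray(t, dtype=float)
    h = gamma_dist.pdf(t, peak_delay / peak_disp, scale=peak_disp) - (
        undershoot_ratio * gamma_dist.pdf(t, undershoot_delay / undershoot_disp, scale=undershoot_disp)
    )
    h = np.where(t < 0, 0.0, h)
    peak = h.max()
    return h / peak if peak > 0 else h


@dataclass
class DesignMatrix:
    """Time x regressor matrix with named columns.

    ``basis`` is ``"canonical-hrf"`` (one convolved column per face
    condition) or ``"fir"`` (one column per condition x lag).  Constant and
    linear-drift columns are always appended last.
    """

    matrix: np.ndarray
    labels: list[str]
    basis: str
    tr: float
    fir_window: float | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.labels):
            raise ValueError("matrix shape inconsistent with labels")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]

    def columns(self, prefix: str) -> np.ndarray:
        idx = [i for i, lab in enumerate(self.labels) if lab == prefix or lab.startswith(prefix + ":")]
        return self.matrix[:, idx]


def _condition_labels(design: BlockDesign) -> list[str]:
    seen: list[str] = []
    for cond, _, _ in design.events:
        if cond != FIXATION and cond not in seen:
            seen.append(cond)
    return seen


def convolved_regressor(
    design: BlockDesign,
    condition: str,
    frame_times: np.ndarray,
    oversample: int = 16,
    hrf_kwargs: dict | None = None,
) -> np.ndarray:
    """Boxcar of one condition convolved with the canonical HRF.

    The convolution runs on a grid of ``tr / oversample`` resolution and is
    linearly interpolated at ``frame_times``, so block onsets need not fall
    on frame boundaries.
    """
    onsets = design.onsets(condition)
    if not onsets:
        return np.zeros(np.shape(frame_times))
    dt = design.tr / oversample
    t_end = max(design.run_duration, float(np.max(frame_times)) + design.tr) + 33.0
    fine_t = np.arange(0.0, t_end, dt)
    boxcar = np.zeros_like(fine_t)
    for onset, dur in design.onsets(condition):
        boxcar[(fine_t >= onset) & (fine_t < onset + dur)] = 1.0
    hrf = double_gamma_hrf(np.arange(0.0, 33.0, dt), **(hrf_kwargs or {}))
    conv = signal.fftconvolve(boxcar, hrf * dt, mode="full")[: fine_t.size]
    # normalize so an isolated block response peaks at 1 (amplitudes in % signal)
    block_dur = design.onsets(condition)[0][1]
    single = signal.fftconvolve(_unit_block(fine_t, block_dur), hrf * dt, mode="full")[: fine_t.size]
    scale = single.max()
    if scale > 0:
        conv = conv / scale
    return np.interp(frame_times, fine_t, conv)


def _unit_block(fine_t: np.ndarray, duration: float) -> np.ndarray:
    return ((fine_t >= 0) & (fine_t < duration)).astype(float)


def _drift_columns(n: int) -> tuple[np.ndarray, list[str]]:
    const = np.ones(n)
    drift = np.linspace(-0.5, 0.5, n)
    return np.column_stack([const, drift]), ["constant", "drift"]


def build_design_matrix(
    design: BlockDesign,
    n_timepoints: int,
    tr: float,
    basis: str = "canonical-hrf",
    fir_window: float = 30.0,
    t0: float = 0.0,
    oversample: int = 16,
) -> DesignMatrix:
    """Design matrix for one run.

    ``t0`` shifts the frame times (``t_i = t0 + i * tr``), which is needed
    for interleaved acquisitions realigned to an offset timebase.
    """
    if basis not in ("canonical-hrf", "fir"):
        raise ValueError(f"unknown basis {basis!r}")
    frame_times = t0 + np.arange(n_timepoints) * tr
    conditions = _condition_labels(design)
    cols: list[np.ndarray] = []
    labels: list[str] = []
    if basis == "canonical-hrf":
        for cond in conditions:
            cols.append(convolved_regressor(design, cond, frame_times, oversample=oversample))
            labels.append(cond)
    else:
        if fir_window < tr:
            raise ValueError("fir_window must cover at least one TR")
        n_lags = int(round(fir_window / tr))
        for cond in conditions:
            onset_frames = [int(round((onset - t0) / tr)) for onset, _ in design.onsets(cond)]
            for lag in range(n_lags):
                col = np.zeros(n_timepoints)
                for f in onset_frames:
                    if 0 <= f + lag < n_timepoints:
                        col[f + lag] = 1.0
                cols.append(col)
                labels.append(f"{cond}:lag{lag}")
    drift, drift_labels = _drift_columns(n_timepoints)
    matrix = np.column_stack(cols + [drift]) if cols else drift
    return DesignMatrix(
        matrix=matrix,
        labels=labels + drift_labels,
        basis=basis,
        tr=tr,
        fir_window=fir_window if basis == "fir" else None,
    )


@dataclass
class GlmFit:
    """Least-squares fit: betas, predicted series, residual, and R^2.

    ``betas`` has shape (n_regressors,) or (n_regressors, n_units); the
    residual and prediction reconstruct the input exactly
    (``yhat + residual == y``).
    """

    betas: np.ndarray
    labels: list[str]
    yhat: np.ndarray
    residual: np.ndarray
    r2: np.ndarray | float

    def beta(self, label: str) -> np.ndarray | float:
        return self.betas[self.labels.index(label)]


def fit_glm(y: np.ndarray, X: DesignMatrix) -> GlmFit:
    """Ordinary least squares of ``y`` (time, or time x units) on ``X``."""
    y = np.asarray(y, dtype=float)
    if y.shape[0] != X.n_timepoints:
        raise ValueError(f"series length {y.shape[0]} != design rows {X.n_timepoints}")
    M = X.matrix
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise ValueError("design matrix is rank deficient")
    betas, *_ = np.linalg.lstsq(M, y, rcond=None)
    yhat = M @ betas
    residual = y - yhat
    ss_res = np.sum(residual**2, axis=0)
    ss_tot = np.sum((y - y.mean(axis=0)) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    if y.ndim == 1:
        r2 = float(r2)
    return GlmFit(betas=betas, labels=list(X.labels), yhat=yhat, residual=residual, r2=r2)


def default_fir_window(design: BlockDesign) -> float:
    """One design period: a face block plus its following fixation block.

    Longer windows can make the FIR system rank deficient for some block
    orders (columns of overlapping conditions become collinear once the
    window exceeds the block spacing), so the period is the widest window
    that is identifiable for every pseudo-randomized order.
    """
    cond, onset, dur = design.face_blocks()[0]
    _, fix_dur = design.following_fixation(onset)
    return dur + fix_dur


def deconvolve_evoked(
    y: np.ndarray,
    design: BlockDesign,
    tr: float | None = None,
    fir_window: float | None = None,
    t0: float = 0.0,
) -> tuple[dict[str, np.ndarray], GlmFit]:
    """FIR deconvolution of the mean evoked response per condition.

    Returns the lag-indexed mean response for each face condition (shape
    (n_lags,) or (n_lags, n_units)) together with the underlying ``GlmFit``
    whose residual is the stimulus-removed series.  Overlapping responses
    from short fixation blocks are handled by the joint least-squares fit.
    ``fir_window`` defaults to one design period (block + fixation).
    """
    y = np.asarray(y, dtype=float)
    tr = design.tr if tr is None else tr
    fir_window = default_fir_window(design) if fir_window is None else fir_window
    X = build_design_matrix(design, y.shape[0], tr, basis="fir", fir_window=fir_window, t0=t0)
    try:
        fit = fit_glm(y, X)
    except ValueError as err:
        raise ValueError(f"FIR system not identifiable: {err}") from err
    responses: dict[str, np.ndarray] = {}
    for cond in _condition_labels(design):
        idx = [i for i, lab in enumerate(X.labels) if lab.startswith(cond + ":lag")]
        responses[cond] = fit.betas[idx]
    return responses, fit
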