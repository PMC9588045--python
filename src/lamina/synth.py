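"""Seeded synthetic fMRI data with the structure the pipeline assumes.

The generator emulates the block-design study conditions end to end:

* three-condition block designs with the protocol timings (:mod:`.design`);
* BOLD ROI time series obeying response linearity — evoked responses are
  HRF-convolved condition boxcars scaled by per-(ROI, condition)
  amplitudes — plus condition-gated shared latent fluctuations between ROI
  pairs and AR(1) noise;
* interleaved blood-nulled / not-nulled VASO run pairs in which a planted
  depth-dependent CBV response enters the nulled series multiplicatively
  (opposite-signed to BOLD) under a common multiplicative BOLD
  contamination, so that division recovers the CBV response;
* a flat cortical ribbon with labeled WM/CSF boundary voxels and an
  eccentricity map increasing monotonically out to 88 deg, with an
  additive, eccentricity-flat valence effect on the simulated voxel data.

All randomness flows from ``SyntheticConfig.seed``: a fixed seed gives
byte-identical outputs.  Deliberately not modeled: vasculature and
draining-vein biophysics, physiological noise, eye movements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .conncorr import epoch_frames
from .design import (
    FACE_CONDITIONS,
    PROTOCOLS,
    TR_NOTNULLED,
    TR_NULLED,
    BlockDesign,
    make_block_design,
)
from .glm import convolved_regressor
from .laminar import CorticalRibbon, grow_depths
from .roibin import MAX_ECCENTRICITY, EccentricityMap

DEFAULT_ROIS = (
    "amygdala",
    "FFA",
    "V1",
    "V2",
    "V3",
    "hV4",
    "VO",
    "PHC",
    "LO",
    "TO",
    "V3AB",
    "IPS0",
    "IPS1",
    "SPL1",
    "FEF",
)


@dataclass
class RunSeries:
    """A run's time series in percent-signal units.

    ``data`` is (time,) for an ROI average or (time, *spatial) for a
    volume; frames are acquired at ``t0 + i * tr`` seconds.  ``modality``
    tags the acquisition (``bold``, ``nulled``, ``not-nulled``, ``vaso``).
    """

    data: np.ndarray
    tr: float
    modality: str
    design: BlockDesign | None = None
    t0: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in run series")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_timepoints) * self.tr


def _default_amplitudes(rois: Sequence[str]) -> dict[str, dict[str, float]]:
    # valence ordering fearful > happy > neutral; amygdala amplitudes are
    # much smaller than visual cortex, as in the emulated measurements
    amps = {}
    for roi in rois:
        if roi == "amygdala":
            amps[roi] = {"fearful": 0.35, "neutral": 0.25, "happy": 0.30}
        else:
            amps[roi] = {"fearful": 2.0, "neutral": 1.7, "happy": 1.85}
    return amps


def default_couplings(rois: Sequence[str]) -> list[tuple[str, str, str, float]]:
    """Baseline cortico-cortical coupling in every condition plus a
    fearful-gated amygdala->cortex increment."""
    cortical = [r for r in rois if r != "amygdala"]
    entries: list[tuple[str, str, str, float]] = []
    for i, a in enumerate(cortical):
        for b in cortical[i + 1 :]:
            entries.append((a, b, "all", 0.4))
    if "amygdala" in rois:
        for b in cortical:
            entries.append(("amygdala", b, "all", 0.2))
            entries.append(("amygdala", b, "fearful", 0.6))
    return entries


#: depth-band CBV responses (% CBV): a mid-depth stimulus peak for every
#: condition and a superficial-only increment for expressive faces
DEFAULT_LAYER_EFFECT: tuple[tuple[float, float, str, float], ...] = (
    (0.25, 0.65, "all", 2.0),
    (0.70, 1.00, "all", 0.6),
    (0.70, 1.00, "fearful", 0.6),
    (0.70, 1.00, "happy", 0.3),
)


@dataclass
class SyntheticConfig:
    """Generative parameters of one synthetic dataset.

    Amplitudes and noise are in percent signal change; couplings are
    unitless loadings of unit-variance latents; ``layer_effect`` entries
    are ``(depth_lo, depth_hi, condition, %CBV)`` bands with condition
    ``"all"`` applying to every face condition.
    """

    seed: int = 0
    protocol: str = "7T-BOLD"
    roi_names: tuple[str, ...] = DEFAULT_ROIS
    evoked_amplitude: dict = field(default_factory=dict)
    shared_latent_coupling: list = field(default_factory=list)
    noise_sd: float = 1.0
    ar1_coef: float = 0.3
    layer_effect: tuple = DEFAULT_LAYER_EFFECT
    bold_contamination_amplitude: float = 0.01
    vaso_noise_sd: float = 0.3
    ecc_stimulus_amp: float = 2.0
    ecc_penumbra_amp: float = -0.5
    ecc_valence_add: dict = field(
        default_factory=lambda: {"fearful": 0.3, "neutral": 0.0, "happy": 0.15}
    )

    def __post_init__(self):
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if not (abs(self.ar1_coef) < 1):
            raise ValueError("ar1_coef magnitude must be < 1")
        if not self.evoked_amplitude:
            self.evoked_amplitude = _default_amplitudes(self.roi_names)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["roi_names"] = list(self.roi_names)
        d["layer_effect"] = [list(e) for e in self.layer_effect]
        d["shared_latent_coupling"] = [list(e) for e in self.shared_latent_coupling]
        return d


def _ar1(rng: np.random.Generator, n: int, phi: float, innovation_sd: float) -> np.ndarray:
    """AR(1) series with innovation SD ``innovation_sd`` (stationary start);
    marginal variance is ``innovation_sd**2 / (1 - phi**2)``."""
    x = np.empty(n)
    if n == 0:
        return x
    marg = innovation_sd / np.sqrt(1.0 - phi**2) if innovation_sd > 0 else 0.0
    x[0] = marg * rng.standard_normal()
    eps = innovation_sd * rng.standard_normal(n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def _unit_ar1(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Unit-variance AR(1) latent."""
    return _ar1(rng, n, phi, np.sqrt(1.0 - phi**2))


def _gate(design: BlockDesign, condition: str, n: int, tr: float) -> np.ndarray:
    mask = np.zeros(n)
    if condition == "all":
        mask[:] = 1.0
        return mask
    mask[epoch_frames(design, condition, n, tr=tr)] = 1.0
    return mask


def simulate_bold_runs(design: BlockDesign, cfg: SyntheticConfig) -> dict[str, RunSeries]:
    """One run of ROI-averaged BOLD series for every configured ROI.

    Each series is the superposition of HRF-convolved condition boxcars
    scaled by ``evoked_amplitude``, condition-gated shared latents loaded
    through ``shared_latent_coupling``, and AR(1) noise.
    """
    if design.protocol and design.protocol != cfg.protocol:
        raise ValueError(f"design protocol {design.protocol!r} != config {cfg.protocol!r}")
    n = design.n_timepoints
    tr = design.tr
    frame_times = np.arange(n) * tr
    rng = np.random.default_rng(cfg.seed)

    regressors = {
        cond: convolved_regressor(design, cond, frame_times) for cond in FACE_CONDITIONS
    }
    series = {roi: np.zeros(n) for roi in cfg.roi_names}
    for roi in cfg.roi_names:
        amps = cfg.evoked_amplitude.get(roi, {})
        for cond in FACE_CONDITIONS:
            series[roi] += float(amps.get(cond, 0.0)) * regressors[cond]

    # one independent unit-variance latent per configured (pair, condition)
    for roi_a, roi_b, condition, coupling in cfg.shared_latent_coupling:
        latent = _unit_ar1(rng, n, cfg.ar1_coef)
        gated = latent * _gate(design, condition, n, tr)
        for roi in (roi_a, roi_b):
            if roi in series:
                series[roi] += float(coupling) * gated

    for roi in cfg.roi_names:
        series[roi] += _ar1(rng, n, cfg.ar1_coef, cfg.noise_sd)

    return {
        roi: RunSeries(data=series[roi], tr=tr, modality="bold", design=design)
        for roi in cfg.roi_names
    }


def make_ribbon_and_eccentricity(
    shape: tuple[int, int, int],
    thickness: int = 21,
    max_ecc: float = MAX_ECCENTRICITY,
    n_bins: int = 21,
) -> tuple[CorticalRibbon, EccentricityMap]:
    """Flat synthetic cortical ribbon plus a monotone eccentricity map.

    The ribbon runs along the y axis of each axial (x, y) plane: one
    labeled WM boundary row, ``thickness`` gray-matter rows, one CSF
    boundary row.  Eccentricity grows geometrically along x from 0.5 deg
    to ``max_ecc`` and is constant across y and z.
    """
    nx, ny, nz = shape
    if thickness < 3:
        raise ValueError("ribbon thickness must be >= 3 voxels")
    if ny < thickness + 2:
        raise ValueError("grid too small for ribbon thickness")
    y0 = (ny - thickness - 2) // 2
    wm = np.zeros(shape, dtype=bool)
    csf = np.zeros(shape, dtype=bool)
    gray = np.zeros(shape, dtype=bool)
    wm[:, y0, :] = True
    gray[:, y0 + 1 : y0 + 1 + thickness, :] = True
    csf[:, y0 + 1 + thickness, :] = True
    ribbon = grow_depths(wm, csf, gray, n_bins=n_bins)

    return ribbon, make_eccentricity_map(shape, max_ecc=max_ecc)


def make_eccentricity_map(shape: tuple[int, ...], max_ecc: float = MAX_ECCENTRICITY) -> EccentricityMap:
    """Eccentricity growing geometrically along x from 0.5 deg to ``max_ecc``."""
    nx = shape[0]
    ecc_x = 0.5 * (max_ecc / 0.5) ** (np.arange(nx) / max(nx - 1, 1))
    values = np.broadcast_to(ecc_x.reshape((-1,) + (1,) * (len(shape) - 1)), shape).copy()
    return EccentricityMap(values=values, valid=np.ones(shape, dtype=bool))


def _layer_amplitude(cfg: SyntheticConfig, depth: np.ndarray, condition: str) -> np.ndarray:
    """Planted % CBV response at each gray voxel's depth for one condition."""
    amp = np.zeros_like(depth, dtype=float)
    for lo, hi, cond, value in cfg.layer_effect:
        if cond == condition or cond == "all":
            amp += np.where((depth >= lo) & (depth <= hi), float(value), 0.0)
    return amp


def simulate_vaso_run(
    design: BlockDesign,
    cfg: SyntheticConfig,
    ribbon: CorticalRibbon,
) -> tuple[RunSeries, RunSeries]:
    """Interleaved blood-nulled / not-nulled pair on the ribbon grid.

    The not-nulled series carries a positive multiplicative BOLD-like
    response ``b(t)``; the nulled series is ``b(t) * (1 - v(t))`` with the
    planted CBV response ``v`` following ``cfg.layer_effect`` across depth,
    so the frame-wise ratio recovers ``v`` with opposite sign.
    """
    if cfg.protocol != "7T-VASO":
        raise ValueError("VASO simulation requires the 7T-VASO protocol")
    if design.protocol and design.protocol != "7T-VASO":
        raise ValueError("design/config protocol mismatch")
    depth = ribbon.depth_fraction
    if depth.ndim != 3:
        raise ValueError("ribbon must be defined on a 3-D grid")
    n = design.n_timepoints
    eff_tr = design.tr
    t_nulled = np.arange(n) * eff_tr + TR_NULLED / 2.0
    t_notnulled = np.arange(n) * eff_tr + TR_NULLED + TR_NOTNULLED / 2.0
    rng = np.random.default_rng(cfg.seed + 1)

    gray = ribbon.gray_mask
    flat_depth = np.where(gray, depth, 0.0)

    def cbv_response(times: np.ndarray) -> np.ndarray:
        v = np.zeros((times.size,) + depth.shape)
        for cond in FACE_CONDITIONS:
            reg = convolved_regressor(design, cond, times)
            amp = _layer_amplitude(cfg, flat_depth, cond) * gray
            v += reg[:, None, None, None] * (amp / 100.0)[None]
        return v

    def bold_factor(times: np.ndarray) -> np.ndarray:
        reg = np.zeros(times.size)
        for cond in FACE_CONDITIONS:
            reg += convolved_regressor(design, cond, times)
        return 1.0 + cfg.bold_contamination_amplitude * reg

    noise_sd = cfg.vaso_noise_sd / 100.0
    b_null = bold_factor(t_nulled)[:, None, None, None]
    nulled = b_null * (1.0 - cbv_response(t_nulled))
    nulled *= 1.0 + noise_sd * rng.standard_normal(nulled.shape)
    b_not = bold_factor(t_notnulled)[:, None, None, None]
    notnulled = np.broadcast_to(b_not, (n,) + depth.shape).copy()
    notnulled *= 1.0 + noise_sd * rng.standard_normal(notnulled.shape)

    return (
        RunSeries(data=nulled, tr=eff_tr, modality="nulled", design=design, t0=TR_NULLED / 2.0),
        RunSeries(
            data=notnulled,
            tr=eff_tr,
            modality="not-nulled",
            design=design,
            t0=TR_NULLED + TR_NOTNULLED / 2.0,
        ),
    )


def simulate_retinotopic_run(
    design: BlockDesign,
    cfg: SyntheticConfig,
    emap: EccentricityMap,
    v1_mask: np.ndarray | None = None,
) -> RunSeries:
    """Voxel-wise BOLD run over an eccentricity map.

    The stimulus-evoked amplitude follows a "half-Mexican-hat" profile
    (positive at the stimulus representation out to 2 deg, a negative
    penumbra at 2.5-6 deg, baseline beyond), identical across conditions;
    the valence effect is purely additive and flat across eccentricity
    (``cfg.ecc_valence_add``).
    """
    mask = np.ones(emap.values.shape, dtype=bool) if v1_mask is None else np.asarray(v1_mask, bool)
    ecc = emap.values
    stim_profile = np.zeros_like(ecc)
    stim_profile[(ecc >= 0.0) & (ecc <= 2.0)] = cfg.ecc_stimulus_amp
    stim_profile[(ecc >= 2.5) & (ecc <= 6.0)] = cfg.ecc_penumbra_amp
    n = design.n_timepoints
    tr = design.tr
    frame_times = np.arange(n) * tr
    rng = np.random.default_rng(cfg.seed + 2)

    data = np.zeros((n,) + ecc.shape)
    for cond in FACE_CONDITIONS:
        reg = convolved_regressor(design, cond, frame_times)
        amp = (stim_profile + float(cfg.ecc_valence_add.get(cond, 0.0))) * mask
        data += reg.reshape((-1,) + (1,) * ecc.ndim) * amp[None]

    flat = data.reshape(n, -1)
    phi = cfg.ar1_coef
    innov = cfg.noise_sd
    marg = innov / np.sqrt(1 - phi**2)
    noise = np.empty_like(flat)
    noise[0] = marg * rng.standard_normal(flat.shape[1])
    eps = innov * rng.standard_normal((n - 1, flat.shape[1]))
    for i in range(1, n):
        noise[i] = phi * noise[i - 1] + eps[i - 1]
    data = (flat + noise).reshape(data.shape)
    return RunSeries(data=data, tr=tr, modality="bold", design=design)
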