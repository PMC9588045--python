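"""VASO interleave handling, BOLD correction algebra, and T1-EPI anatomy."""

import numpy as np
import pytest

from lamina.design import BlockDesign, make_block_design
from lamina.synth import RunSeries, SyntheticConfig, make_ribbon_and_eccentricity, simulate_vaso_run
from lamina.vaso import (
    VasoPair,
    align_and_trim,
    bold_correct,
    interleave,
    split_interleaved,
    vaso_anatomy,
)


def _series(data, tr=4.825, design=None, t0=0.0, modality="interleaved"):
    return RunSeries(np.asarray(data, float), tr=tr, modality=modality, design=design, t0=t0)


def test_split_indices_and_roundtrip():
    s = _series(np.arange(10.0), tr=4.825 / 2)
    pair = split_interleaved(s, nulled_first=True)
    assert np.array_equal(pair.nulled.data, [0, 2, 4, 6, 8])
    assert np.array_equal(pair.notnulled.data, [1, 3, 5, 7, 9])
    assert pair.nulled.t0 < pair.notnulled.t0
    back = interleave(pair, nulled_first=True)
    assert np.array_equal(back.data, s.data)


@pytest.mark.parametrize("n", [0, 7])
def test_split_rejects_bad_frame_counts(n):
    with pytest.raises(ValueError, match="even"):
        split_interleaved(_series(np.arange(float(n))))


def test_align_preserves_constants_and_ramps():
    n = 20
    t_n = np.arange(n) * 4.825 + 1.0
    t_b = np.arange(n) * 4.825 + 3.5
    pair = VasoPair(
        nulled=_series(np.full(n, 7.0), t0=1.0, modality="nulled"),
        notnulled=_series(np.full(n, 7.0), t0=3.5, modality="not-nulled"),
        effective_tr=4.825,
    )
    out = align_and_trim(pair)
    assert np.allclose(out.nulled.data, 7.0, atol=1e-12)
    ramp = VasoPair(
        nulled=_series(2.0 * t_n + 1.0, t0=1.0, modality="nulled"),
        notnulled=_series(2.0 * t_b + 1.0, t0=3.5, modality="not-nulled"),
        effective_tr=4.825,
    )
    out = align_and_trim(ramp)
    assert np.allclose(out.nulled.data, 2.0 * out.nulled.times + 1.0, atol=1e-10)
    assert np.allclose(out.notnulled.data, 2.0 * out.notnulled.times + 1.0, atol=1e-10)
    assert out.aligned


def test_align_recovers_staggered_sinusoid():
    period = 60.0  # >= 10 samples per cycle at the 4.825 s group TR
    n = 40
    t_n = np.arange(n) * 4.825 + 1.044
    t_b = np.arange(n) * 4.825 + 3.4565
    f = lambda t: np.sin(2 * np.pi * t / period)
    pair = VasoPair(
        nulled=_series(f(t_n), t0=1.044, modality="nulled"),
        notnulled=_series(f(t_b), t0=3.4565, modality="not-nulled"),
        effective_tr=4.825,
    )
    out = align_and_trim(pair)
    for s in (out.nulled, out.notnulled):
        assert np.max(np.abs(s.data - f(s.times))) < 0.01  # within 1% amplitude


def test_align_rejects_short_series():
    pair = VasoPair(
        nulled=_series(np.ones(5), modality="nulled"),
        notnulled=_series(np.ones(5), t0=2.0, modality="not-nulled"),
        effective_tr=4.825,
    )
    with pytest.raises(ValueError, match="8 frames"):
        align_and_trim(pair)


def _toy_design(n_frames=24, tr=2.0):
    # alternating 8 s face / 8 s fixation blocks on a common timebase
    events = [("fixation", 0.0, 8.0)]
    t = 8.0
    while t + 16.0 <= n_frames * tr:
        events.append(("fearful", t, 8.0))
        events.append(("fixation", t + 8.0, 8.0))
        t += 16.0
    return BlockDesign(events=events, run_duration=n_frames * tr, tr=tr,
                       conditions=frozenset({"fearful", "fixation"}))


def test_bold_correct_identity_and_planted_response():
    design = _toy_design()
    n = design.n_timepoints
    times = np.arange(n) * design.tr
    # identity: nulled == notnulled -> percent change 0
    base = np.full(n, 2.0)
    pair = VasoPair(
        nulled=RunSeries(base, tr=design.tr, modality="nulled", design=design),
        notnulled=RunSeries(base.copy(), tr=design.tr, modality="not-nulled", design=design),
        effective_tr=design.tr,
    )
    out = bold_correct(pair)
    assert np.allclose(out.data, 0.0, atol=1e-12)
    # planted multiplicative CBV response v(t), zero during fixation epochs
    v = 0.02 * np.clip(np.sin(2 * np.pi * (times - 8.0) / 16.0), 0, None)
    v[times < 8.0] = 0.0
    b = 2.0 * (1.0 + 0.01 * np.cos(2 * np.pi * times / 30.0))  # contamination
    pair = VasoPair(
        nulled=RunSeries(b * (1 - v), tr=design.tr, modality="nulled", design=design),
        notnulled=RunSeries(b, tr=design.tr, modality="not-nulled", design=design),
        effective_tr=design.tr,
    )
    out = bold_correct(pair)
    # fixation baseline is -1 exactly, so percent change recovers 100 v
    assert np.allclose(out.data, 100.0 * v, atol=1e-6)


def test_bold_correct_contamination_invariance(rng):
    """For v = 0 the output is flat for any strictly positive b(t)."""
    design = _toy_design()
    n = design.n_timepoints
    b = np.exp(0.05 * rng.standard_normal(n)) * 3.0
    pair = VasoPair(
        nulled=RunSeries(1.7 * b, tr=design.tr, modality="nulled", design=design),
        notnulled=RunSeries(b, tr=design.tr, modality="not-nulled", design=design),
        effective_tr=design.tr,
    )
    out = bold_correct(pair)
    assert np.max(np.abs(out.data)) < 1e-6


def test_bold_correct_rejects_nonpositive_denominator():
    design = _toy_design()
    n = design.n_timepoints
    bad = np.ones(n)
    bad[5] = 0.0
    pair = VasoPair(
        nulled=RunSeries(np.ones(n), tr=design.tr, modality="nulled", design=design),
        notnulled=RunSeries(bad, tr=design.tr, modality="not-nulled", design=design),
        effective_tr=design.tr,
    )
    with pytest.raises(ValueError, match="division hazard"):
        bold_correct(pair)


def test_planted_bold_and_vaso_are_antiphase(design_vaso):
    """Fitted sinusoid phases of the not-nulled (BOLD) response and the
    corrected VASO response differ by ~180 degrees."""
    ribbon, _ = make_ribbon_and_eccentricity((4, 25, 3), thickness=21)
    cfg = SyntheticConfig(seed=0, protocol="7T-VASO", vaso_noise_sd=0.0,
                          bold_contamination_amplitude=0.02)
    nulled, notnulled = simulate_vaso_run(design_vaso, cfg, ribbon)
    pair = VasoPair(nulled=nulled, notnulled=notnulled, effective_tr=design_vaso.tr)
    vox = tuple(np.argwhere(ribbon.depth_bin == 10)[0])  # mid-depth voxel
    aligned = align_and_trim(pair)
    # the raw nulled/notnulled ratio decreases when CBV rises (the -1 flip
    # in bold_correct is what turns it positive again)
    ratio_ts = (aligned.nulled.data / aligned.notnulled.data)[(slice(None),) + vox]
    bold_ts = notnulled.data[(slice(None),) + vox]

    def phase(ts, times, period):
        w = 2 * np.pi / period
        X = np.column_stack([np.sin(w * times), np.cos(w * times), np.ones_like(times)])
        beta, *_ = np.linalg.lstsq(X, ts, rcond=None)
        return np.arctan2(beta[1], beta[0])

    period = 28.95  # one face+fixation cycle
    dphi = phase(ratio_ts, aligned.nulled.times, period) - phase(bold_ts, notnulled.times, period)
    dphi = np.angle(np.exp(1j * dphi))
    assert abs(abs(dphi) - np.pi) < 0.35  # ~180 deg


def test_vaso_anatomy_formula_and_sentinel():
    pair = VasoPair(
        nulled=RunSeries(np.array([[1.0, 5.0], [1.0, 5.0]]), tr=2.0, modality="nulled"),
        notnulled=RunSeries(np.array([[3.0, 5.0], [3.0, 5.0]]), tr=2.0, modality="not-nulled"),
        effective_tr=4.0,
    )
    with pytest.warns(UserWarning, match="zero variance"):
        anat, flagged = vaso_anatomy(pair)
    # voxel frames {1,3}: population sd 1, mean 2 -> (1/sd)/mean = 0.5
    assert anat[0] == pytest.approx(0.5)
    assert np.isnan(anat[1]) and flagged[1]
    tsnr, _ = vaso_anatomy(pair, contrast="tsnr")
    assert tsnr[0] == pytest.approx(2.0)


def test_vaso_anatomy_tissue_ordering(rng):
    """On a 3-tissue phantom, tissue with large nulled/not-nulled difference
    (gray-matter-like) ranks below low-variability high-mean tissue
    (CSF-like), matching a brute-force per-voxel computation."""
    n = 50
    design = _toy_design(n_frames=n)
    # columns: gray-like (big modality difference), wm-like, csf-like
    nulled = np.column_stack([
        1.0 + 0.02 * rng.standard_normal(n),   # gray nulled low
        2.0 + 0.02 * rng.standard_normal(n),
        3.0 + 0.02 * rng.standard_normal(n),
    ])
    notnulled = np.column_stack([
        2.0 + 0.02 * rng.standard_normal(n),   # gray not-nulled high -> big sd pooled
        2.1 + 0.02 * rng.standard_normal(n),
        3.02 + 0.02 * rng.standard_normal(n),
    ])
    pair = VasoPair(
        nulled=RunSeries(nulled, tr=design.tr, modality="nulled", design=design),
        notnulled=RunSeries(notnulled, tr=design.tr, modality="not-nulled", design=design),
        effective_tr=2 * design.tr,
    )
    anat, _ = vaso_anatomy(pair)
    frames = np.concatenate([nulled, notnulled], axis=0)
    brute = np.array([(1.0 / frames[:, j].std()) / frames[:, j].mean() for j in range(3)])
    assert np.allclose(anat, brute, rtol=1e-12)
    assert anat[0] < anat[2]  # gray-like below csf-like


def test_vaso_split_align_correct_recovers_planted_dip():
    """A planted 2% mid-depth CBV response survives the full
    split -> align -> correct chain within interpolation tolerance.

    A single face block with long surrounding fixation lets the response
    return to baseline, so the peak percent change equals the planted
    amplitude."""
    tr = 4.825
    events = [("fixation", 0.0, 48.25), ("fearful", 48.25, 19.3),
              ("fixation", 67.55, 144.75)]
    design = BlockDesign(events=events, run_duration=44 * tr, tr=tr,
                         conditions=frozenset({"fearful", "fixation"}))
    ribbon, _ = make_ribbon_and_eccentricity((4, 25, 3), thickness=21)
    cfg = SyntheticConfig(
        seed=0, protocol="7T-VASO", vaso_noise_sd=0.0,
        bold_contamination_amplitude=0.01,
        layer_effect=((0.25, 0.65, "all", 2.0),),
    )
    nulled, notnulled = simulate_vaso_run(design, cfg, ribbon)
    pair = split_interleaved(interleave(
        VasoPair(nulled=nulled, notnulled=notnulled, effective_tr=tr)
    ))
    pair.nulled.design = pair.notnulled.design = design
    corrected = bold_correct(align_and_trim(pair))
    vox = tuple(np.argwhere(ribbon.depth_bin == 10)[0])
    peak = corrected.data[(slice(None),) + vox].max()
    assert peak == pytest.approx(2.0, abs=0.1)
    deep_vox = tuple(np.argwhere(ribbon.depth_bin == 1)[0])
    assert np.max(np.abs(corrected.data[(slice(None),) + deep_vox])) < 0.1
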