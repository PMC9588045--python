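"""Block-design stimulus timing for the gender-judgment protocols.

Three protocols are supported, mirroring the block structure of the study
conditions the generator emulates:

``3T-BOLD``
    3 repeats each of fearful/neutral/happy (20 s face blocks) and 10
    fixation blocks of 10 s; TR 2.0 s; 280 s per run.
``7T-BOLD``
    Same counts with 18 s face and 9 s fixation blocks; TR 1.5 s; 252 s.
``7T-VASO``
    6 repeats per expression (18 face blocks of 19.3 s) and 19 fixation
    blocks of 9.65 s; interleaved acquisition with an effective TR of
    4.825 s (2.088 s blood-nulled + 2.737 s not-nulled readouts).

Every face block is followed by a fixation block; runs start with fixation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FACE_CONDITIONS = ("fearful", "neutral", "happy")
FIXATION = "fixation"

#: protocol -> (face s, fixation s, repeats per condition, TR s)
PROTOCOLS: dict[str, tuple[float, float, int, float]] = {
    "3T-BOLD": (20.0, 10.0, 3, 2.0),
    "7T-BOLD": (18.0, 9.0, 3, 1.5),
    "7T-VASO": (19.3, 9.65, 6, 4.825),
}

#: readout durations (s) of the interleaved blood-nulled / not-nulled frames
TR_NULLED = 2.088
TR_NOTNULLED = 2.737


@dataclass(frozen=True)
class BlockDesign:
    """Ordered stimulus timing of one run.

    ``events`` is a list of ``(condition, onset_s, duration_s)`` blocks,
    non-overlapping and sorted by onset; every face block is followed by a
    fixation block.  ``tr`` is the sampling interval of the associated
    acquisition (the effective volume TR for interleaved protocols).
    """

    events: list[tuple[str, float, float]]
    run_duration: float
    tr: float
    protocol: str = ""
    conditions: frozenset = field(default_factory=lambda: frozenset(FACE_CONDITIONS) | {FIXATION})

    def __post_init__(self):
        last_end = 0.0
        for cond, onset, dur in self.events:
            if onset < last_end - 1e-9:
                raise ValueError(f"overlapping events at onset {onset}")
            if cond not in self.conditions:
                raise ValueError(f"unknown condition {cond!r}")
            last_end = onset + dur
        if last_end > self.run_duration + 1e-9:
            raise ValueError("events extend past run_duration")

    @property
    def n_timepoints(self) -> int:
        return int(round(self.run_duration / self.tr))

    def onsets(self, condition: str) -> list[tuple[float, float]]:
        """(onset, duration) pairs of one condition, in temporal order."""
        return [(o, d) for c, o, d in self.events if c == condition]

    def face_blocks(self) -> list[tuple[str, float, float]]:
        return [(c, o, d) for c, o, d in self.events if c != FIXATION]

    def following_fixation(self, onset: float) -> tuple[float, float]:
        """The fixation block immediately following the block at ``onset``."""
        for i, (c, o, d) in enumerate(self.events):
            if abs(o - onset) < 1e-9:
                if i + 1 >= len(self.events) or self.events[i + 1][0] != FIXATION:
                    raise ValueError(f"block at {onset} s is not followed by fixation")
                return self.events[i + 1][1], self.events[i + 1][2]
        raise ValueError(f"no block at onset {onset}")


def make_block_design(protocol: str, seed: int) -> BlockDesign:
    """Pseudo-randomized block order for one run of ``protocol``.

    The per-condition block counts and block/fixation durations are fixed by
    the protocol; only the order of the face conditions is permuted by
    ``seed``.  Runs begin with a fixation block and alternate face/fixation,
    so every face block is followed by a fixation block.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; expected one of {sorted(PROTOCOLS)}")
    face_dur, fix_dur, n_rep, tr = PROTOCOLS[protocol]
    rng = np.random.default_rng(seed)
    order = rng.permutation(np.repeat(FACE_CONDITIONS, n_rep))

    events: list[tuple[str, float, float]] = []
    t = 0.0
    events.append((FIXATION, t, fix_dur))
    t += fix_dur
    for cond in order:
        events.append((str(cond), t, face_dur))
        t += face_dur
        events.append((FIXATION, t, fix_dur))
        t += fix_dur
    # round total up to a whole number of TRs
    n_tr = int(np.ceil(t / tr - 1e-9))
    return BlockDesign(events=events, run_duration=n_tr * tr, tr=tr, protocol=protocol)
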