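"""Keystroke segmentation: recover note and chord structures from traces.

A keystroke is one excursion of a key-position trace above the rest noise
floor that reaches at least ``min_peak`` steps.  Landmarks:

* ``onset`` — the key leaves rest: time of the last at-rest sample before the
  excursion (the quantized rest floor 0 when the trace reaches it, else the
  last sample at or below ``rest_threshold``); keeping the near-zero head
  matters for convex (pressed) attacks whose early rise sits below the
  position resolution;
* ``amax_time`` — first sample attaining the excursion maximum ``Amax``;
* ``release_start`` — last sample at which the position is within
  ``release_tolerance`` steps of ``Amax``, before the final descent;
* ``offset`` — first sample back at rest (<= ``rest_threshold``).

All landmark times are quantized to the sample grid and reported in ms.
Segmentation is deterministic and idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .synth import ScoreSpec

__all__ = [
    "NoteEvent",
    "ChordEvent",
    "ChordGrouping",
    "detect_keystrokes",
    "associate_hammers",
    "group_chords",
    "segment_recording",
    "REST_THRESHOLD",
    "MIN_PEAK",
    "RELEASE_TOLERANCE",
    "HAMMER_SLACK_MS",
]

logger = logging.getLogger(__name__)

REST_THRESHOLD = 5  # steps; noise floor for onset/offset detection
MIN_PEAK = 20  # steps; excursions below this are not keystrokes
RELEASE_TOLERANCE = 5  # steps; plateau jitter when locating release_start
HAMMER_SLACK_MS = 20.0  # hammer launch precedes key bottoming by <= this


@dataclass
class NoteEvent:
    """One segmented keystroke with its landmarks (times in ms)."""

    pitch: int
    onset: float
    amax_time: float
    amax: int
    release_start: float
    offset: float
    mhv: int | None = None
    mhv_time: float | None = None
    hand: str | None = None
    truncated: bool = False
    # sample indices into the source trace, for feature computation
    onset_i: int = 0
    amax_i: int = 0
    release_i: int = 0
    offset_i: int = 0

    def __post_init__(self):
        if not (self.onset < self.amax_time <= self.release_start < self.offset):
            raise ValueError(
                f"landmarks out of order for pitch {self.pitch}: "
                f"{self.onset}, {self.amax_time}, {self.release_start}, {self.offset}"
            )
        if not (0 < self.amax <= 250):
            raise ValueError(f"Amax {self.amax} outside (0, 250]")


@dataclass
class ChordEvent:
    """Notes grouped into one chord; hand is 'left', 'right' or 'mixed'."""

    index: int
    notes: list
    hand: str = "mixed"
    score_index: int | None = None
    extra: bool = False

    def __post_init__(self):
        if not self.notes:
            raise ValueError("chord must contain at least one note")

    @property
    def onset(self) -> float:
        return min(n.onset for n in self.notes)

    @property
    def offset(self) -> float:
        return max(n.offset for n in self.notes)

    @property
    def hands(self) -> frozenset:
        return frozenset(("left", "right")) if self.hand == "mixed" else frozenset((self.hand,))


@dataclass
class ChordGrouping:
    chords: list
    missing_score_indices: list = field(default_factory=list)


def detect_keystrokes(
    trace,
    rate: float = 500.0,
    rest_threshold: int = REST_THRESHOLD,
    min_peak: int = MIN_PEAK,
    release_tolerance: int = RELEASE_TOLERANCE,
    pitch: int = 0,
):
    """Segment one key-position trace into :class:`NoteEvent` objects."""
    if not (0 < rest_threshold < min_peak <= 250):
        raise ValueError("need 0 < rest_threshold < min_peak <= 250")
    trace = np.asarray(trace)
    dt = 1000.0 / rate
    above = trace > rest_threshold
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = ([0] if above[0] else []) + [int(e) + 1 for e in edges if not above[e]]
    ends = [int(e) for e in edges if above[e]]  # last above-threshold index of a run
    events = []
    prev_end = 0
    for k, i0 in enumerate(starts):
        truncated = k >= len(ends)
        i1 = ends[k] if not truncated else len(trace) - 1
        run = trace[i0 : i1 + 1]
        amax = int(run.max())
        if amax < min_peak:
            prev_end = i1 + 1
            continue
        # the key leaves rest at the last at-rest sample before the excursion;
        # prefer the quantized rest floor (0) so that slow, convex attacks keep
        # their near-zero head, else fall back to the threshold crossing
        onset_i = max(i0 - 1, 0)
        j = onset_i
        while j > prev_end and trace[j] > 0:
            j -= 1
        if trace[j] == 0:
            onset_i = j
        amax_i = i0 + int(np.argmax(run))
        rel_candidates = np.flatnonzero(run >= amax - release_tolerance)
        release_i = i0 + int(rel_candidates[-1])
        offset_i = i1 + 1 if not truncated else len(trace) - 1
        if release_i >= offset_i:  # degenerate short excursion
            release_i = offset_i - 1
        if amax_i > release_i:
            amax_i = release_i
        events.append(
            NoteEvent(
                pitch=pitch,
                onset=onset_i * dt,
                amax_time=amax_i * dt,
                amax=amax,
                release_start=release_i * dt,
                offset=offset_i * dt,
                truncated=truncated,
                onset_i=onset_i,
                amax_i=amax_i,
                release_i=release_i,
                offset_i=offset_i,
            )
        )
        prev_end = i1 + 1
    return events


def associate_hammers(notes, hammer_events, slack_ms: float = HAMMER_SLACK_MS):
    """Assign each hammer event to the keystroke it belongs to (in place).

    A hammer event joins the unique note of the same pitch whose
    ``[onset, amax_time + slack]`` window contains it; with two events in one
    window the larger MHV wins (with a warning).  Notes left without an event
    keep ``mhv = None``.
    """
    by_pitch: dict[int, list] = {}
    for note in notes:
        by_pitch.setdefault(note.pitch, []).append(note)
    for group in by_pitch.values():
        group.sort(key=lambda n: n.onset)
    for ev in hammer_events:
        target = None
        for note in by_pitch.get(ev.pitch, ()):
            if note.onset <= ev.time_ms <= note.amax_time + slack_ms:
                target = note
                break
        if target is None:
            logger.warning(
                "hammer event at %.1f ms (pitch %d) matches no keystroke", ev.time_ms, ev.pitch
            )
            continue
        if target.mhv is not None:
            logger.warning(
                "two hammer events for pitch %d near %.1f ms; keeping larger MHV",
                ev.pitch, ev.time_ms,
            )
            if ev.mhv <= target.mhv:
                continue
        target.mhv = ev.mhv
        target.mhv_time = ev.time_ms
    return notes


def group_chords(notes, score: ScoreSpec | None, window_fraction: float = 0.25):
    """Score-guided chord grouping with hand assignment.

    The performed time base is aligned to the score by a least-squares global
    scale, then notes are matched greedily, in chord order, by pitch within a
    window of ``window_fraction`` of the local nominal inter-onset interval.
    Unmatched notes become singleton chords flagged ``extra`` (hand from a
    register heuristic); score chords with no matched note are reported in
    ``missing_score_indices``.  Chord hand is the unanimous note hand, else
    ``'mixed'``.
    """
    notes = sorted(notes, key=lambda n: (n.onset, n.pitch))
    if score is None or score.n_chords == 0:
        chords = [
            ChordEvent(i, [n], hand=_register_hand(n), extra=True)
            for i, n in enumerate(notes)
        ]
        return ChordGrouping(chords)

    nominal = np.array([c.nominal_onset_ms for c in score.chords])
    # global time scale from first/last onsets (robust enough for one piece)
    scale = 1.0
    if len(notes) > 1 and nominal[-1] > nominal[0]:
        span = notes[-1].onset - notes[0].onset
        if span > 0:
            scale = span / (nominal[-1] - nominal[0])
    shift = notes[0].onset - nominal[0] * scale if notes else 0.0
    predicted = nominal * scale + shift
    iois = np.diff(predicted)
    local = np.empty(len(predicted))
    if len(iois):
        local[:-1] = iois
        local[-1] = iois[-1]
    else:
        local[:] = 1000.0

    unmatched = list(notes)
    chords = []
    missing = []
    for ci, chord in enumerate(score.chords):
        window = window_fraction * local[ci]
        members = []
        for pitch, hand in chord.notes:
            best = None
            for n in unmatched:
                if n.pitch == pitch and abs(n.onset - predicted[ci]) <= window:
                    if best is None or abs(n.onset - predicted[ci]) < abs(best.onset - predicted[ci]):
                        best = n
            if best is not None:
                best.hand = hand
                members.append(best)
                unmatched.remove(best)
        if members:
            hands = {n.hand for n in members}
            chords.append(
                ChordEvent(
                    len(chords), members,
                    hand=hands.pop() if len(hands) == 1 else "mixed",
                    score_index=ci,
                )
            )
        else:
            missing.append(ci)
    for n in unmatched:
        chords.append(ChordEvent(len(chords), [n], hand=_register_hand(n), extra=True))
    chords.sort(key=lambda c: c.onset)
    for i, c in enumerate(chords):
        c.index = i
    if missing:
        logger.warning("score chords with no matched notes: %s", missing)
    return ChordGrouping(chords, missing)


def _register_hand(note) -> str:
    return note.hand if note.hand else ("left" if note.pitch < 60 else "right")


def segment_recording(
    recording,
    score: ScoreSpec | None = None,
    rest_threshold: int = REST_THRESHOLD,
    min_peak: int = MIN_PEAK,
    release_tolerance: int = RELEASE_TOLERANCE,
):
    """Full segmentation of a recording: keystrokes, hammers, chords."""
    notes = []
    for pitch, trace in sorted(recording.key_traces.items()):
        notes.extend(
            detect_keystrokes(
                trace, recording.rate, rest_threshold, min_peak, release_tolerance, pitch=pitch
            )
        )
    associate_hammers(notes, recording.hammer_events)
    return group_chords(notes, score)
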