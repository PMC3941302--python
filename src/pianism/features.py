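"""Feature extraction: note, chord and performance feature vectors.

The hierarchy and its exact counts (46 note / 168 chord / 202 + 3 x 138 = 616
performance features) are frozen in :mod:`pianism.schema`; this module fills
the vectors in.

Definitions that matter:

* **percussiveness** — normalized area under the normalized attack trajectory,
  ``(1 / (T * Amax)) * integral of depression(t) dt`` over the attack window.
  0.5 for a linear attack, above 0.5 for a concave (struck) attack, below for
  a convex (pressed) one.  For the power-law attack family with exponent
  ``gamma`` the continuous value is exactly ``1 / (gamma + 1)``.
* **melody lead** — mean onset of a chord's non-first notes minus the onset of
  its first (earliest) note; positive when the melody note leads.
* **articulation** — onset of the next same-hand chord minus this chord's
  offset: negative is legato (overlap), positive staccato.
* **part-pedaling** — a pedal counts as "in use" above 10 % of its range
  (25 steps) and "fully depressed" above 90 % (225 steps); part-pedaling is
  in-use-but-not-full, and the mid-depression amount is the mean depression
  over those samples.
* performance-level "variations in ..." (hammer velocity, attack duration,
  key depression depth) are coefficients of variation — the SD over chords as
  a ratio of the mean; other dispersion columns are plain SDs.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .io import METADATA_COLUMNS, PerformanceRecording
from .schema import CV_DISPERSION, GROUPINGS, FeatureSchema, default_schema
from .segment import ChordEvent, segment_recording

__all__ = [
    "note_features",
    "chord_features",
    "performance_features",
    "extract_performance",
    "build_feature_table",
    "PEDAL_USE_THRESHOLD",
    "PEDAL_FULL_THRESHOLD",
]

PEDAL_USE_THRESHOLD = 25  # steps: 10 % of range
PEDAL_FULL_THRESHOLD = 225  # steps: 90 % of range
_PEDAL_KEYS = (("soft", "soft"), ("sust", "sust"))


def _safe_div(a, b):
    return a / b if (b is not None and not math.isclose(b, 0.0)) else float("nan")


# ---------------------------------------------------------------------------
# note level
# ---------------------------------------------------------------------------


def note_features(note, trace, pedal_traces, dt_ms: float) -> dict:
    """The 46-entry note feature vector for one segmented keystroke.

    MHV-dependent entries are missing (NaN) when the note carries no hammer
    event; everything else is still computed.
    """
    f: dict[str, float] = {}
    amax = float(note.amax)
    attack = np.asarray(trace[note.onset_i : note.amax_i + 1], dtype=float)
    t_attack = (note.amax_i - note.onset_i) * dt_ms

    f["amax"] = amax
    f["attack_duration"] = t_attack
    f["attack_speed"] = _safe_div(amax, t_attack)
    if len(attack) >= 2:
        f["percussiveness"] = np.trapezoid(attack, dx=dt_ms) / (t_attack * amax)
        f["attack_depth_mean"] = float(attack.mean())
        mid = len(attack) // 2
        t_mid = mid * dt_ms
        f["attack_early_speed"] = _safe_div(attack[mid] - attack[0], t_mid)
        f["attack_late_speed"] = _safe_div(amax - attack[mid], t_attack - t_mid)
        f["attack_speed_ratio"] = _safe_div(f["attack_early_speed"], f["attack_late_speed"])
        half = np.flatnonzero(attack >= amax / 2.0)
        f["half_depth_time"] = float(half[0]) * dt_ms if len(half) else float("nan")
    else:
        for k in ("percussiveness", "attack_depth_mean", "attack_early_speed",
                  "attack_late_speed", "attack_speed_ratio", "half_depth_time"):
            f[k] = float("nan")

    window = np.asarray(trace[note.onset_i : note.offset_i + 1], dtype=float)
    f["depression_mean"] = float(window.mean())
    f["depression_area"] = float(np.trapezoid(window, dx=dt_ms))
    f["pitch"] = float(note.pitch)

    # hammer-dependent
    if note.mhv is not None:
        mhv = float(note.mhv)
        f["mhv"] = mhv
        f["mhv_amax_ratio"] = _safe_div(mhv, amax)
        f["mhv_amax_lag"] = note.mhv_time - note.amax_time
        f["attack_duration_mhv"] = note.mhv_time - note.onset
        f["attack_speed_mhv"] = _safe_div(mhv, note.mhv_time - note.onset)
        f["mhv_time_point"] = note.mhv_time
    else:
        for k in ("mhv", "mhv_amax_ratio", "mhv_amax_lag", "attack_duration_mhv",
                  "attack_speed_mhv", "mhv_time_point"):
            f[k] = float("nan")

    # articulation / durations
    f["sustain_duration"] = note.release_start - note.amax_time
    f["release_duration"] = note.offset - note.release_start
    f["release_speed"] = _safe_div(amax, f["release_duration"])
    f["note_duration"] = note.offset - note.onset
    f["key_down_duration"] = note.release_start - note.onset
    f["attack_fraction"] = _safe_div(t_attack, f["note_duration"])
    f["sustain_fraction"] = _safe_div(f["sustain_duration"], f["note_duration"])
    f["release_fraction"] = _safe_div(f["release_duration"], f["note_duration"])
    f["onset_time"] = note.onset
    f["offset_time"] = note.offset
    f["amax_time_point"] = note.amax_time
    f["release_start_time"] = note.release_start

    # per-note pedal states
    mhv_i = int(round(note.mhv_time / dt_ms)) if note.mhv_time is not None else None
    for prefix, key in _PEDAL_KEYS:
        pedal = np.asarray(pedal_traces[key], dtype=float)
        seg = pedal[note.onset_i : note.offset_i + 1]
        f[f"{prefix}_at_onset"] = float(pedal[note.onset_i])
        f[f"{prefix}_at_amax"] = float(pedal[note.amax_i])
        f[f"{prefix}_at_mhv"] = (
            float(pedal[min(mhv_i, len(pedal) - 1)]) if mhv_i is not None else float("nan")
        )
        f[f"{prefix}_at_offset"] = float(pedal[min(note.offset_i, len(pedal) - 1)])
        f[f"{prefix}_mean"] = float(seg.mean()) if len(seg) else 0.0
        f[f"{prefix}_max"] = float(seg.max()) if len(seg) else 0.0
        f[f"{prefix}_active_fraction"] = float((seg > PEDAL_USE_THRESHOLD).mean()) if len(seg) else 0.0
        f[f"{prefix}_full_fraction"] = float((seg > PEDAL_FULL_THRESHOLD).mean()) if len(seg) else 0.0
    return f


# ---------------------------------------------------------------------------
# chord level
# ---------------------------------------------------------------------------


def _chord_depression(chord, key_traces, n_samples):
    """Max depression over member keys, sampled on the chord's span."""
    i0 = min(n.onset_i for n in chord.notes)
    i1 = max(n.offset_i for n in chord.notes) + 1
    depth = np.zeros(i1 - i0)
    for n in chord.notes:
        depth = np.maximum(depth, np.asarray(key_traces[n.pitch][i0:i1], dtype=float))
    return i0, depth


def _neighbor(chords, i, relation, direction):
    """Next/previous chord in a hand relation: 'all', 'same', 'other'."""
    me = chords[i].hands
    rng = range(i + 1, len(chords)) if direction > 0 else range(i - 1, -1, -1)
    for j in rng:
        hands = chords[j].hands
        if relation == "all":
            return chords[j]
        if relation == "same" and (hands & me):
            return chords[j]
        if relation == "other" and not (hands & me):
            return chords[j]
    return None


def chord_features(
    chord: ChordEvent,
    chords,
    note_vectors,
    key_traces,
    pedal_traces,
    dt_ms: float,
    schema: FeatureSchema | None = None,
) -> dict:
    """The 168-entry chord feature vector.

    ``note_vectors`` maps ``id(note) ->`` its note feature vector.  Aggregated
    entries are the nan-aware mean and population SD of each note feature over
    the chord's notes; forward-looking chord-specific entries are missing for
    the last chord.
    """
    schema = schema or default_schema()
    f: dict[str, float] = {}
    vecs = [note_vectors[id(n)] for n in chord.notes]
    for name in schema.note_feature_names:
        vals = np.array([v[name] for v in vecs], dtype=float)
        ok = vals[~np.isnan(vals)]
        f[f"{name}_cmean"] = float(ok.mean()) if len(ok) else float("nan")
        f[f"{name}_csd"] = float(ok.std()) if len(ok) else float("nan")

    notes = sorted(chord.notes, key=lambda n: (n.onset, n.pitch))
    onsets = np.array([n.onset for n in notes])
    offsets = np.array([n.offset for n in notes])
    pitches = np.array([float(n.pitch) for n in notes])
    n = len(notes)
    onset, offset = chord.onset, chord.offset
    duration = offset - onset

    f["n_notes"] = float(n)
    f["chord_duration"] = duration
    f["onset_time"] = onset
    f["offset_time"] = offset
    f["onset_asynchrony_span"] = float(onsets.max() - onsets.min())
    f["onset_asynchrony_rate"] = f["onset_asynchrony_span"] / max(1, n - 1)
    f["onset_asynchrony_amount"] = float(np.abs(onsets - onsets.mean()).mean())
    f["offset_asynchrony_span"] = float(offsets.max() - offsets.min())
    f["offset_asynchrony_rate"] = f["offset_asynchrony_span"] / max(1, n - 1)
    f["offset_asynchrony_amount"] = float(np.abs(offsets - offsets.mean()).mean())
    if n > 1:
        f["melody_lead"] = float(onsets[1:].mean() - onsets[0])
        mhvs = np.array([v["mhv"] for v in vecs], dtype=float)
        first = note_vectors[id(notes[0])]["mhv"]
        others = np.array(
            [note_vectors[id(m)]["mhv"] for m in notes[1:]], dtype=float
        )
        others = others[~np.isnan(others)]
        f["melody_mhv_excess"] = (
            float(first - others.mean()) if len(others) and not np.isnan(first) else float("nan")
        )
    else:
        f["melody_lead"] = float("nan")
        f["melody_mhv_excess"] = float("nan")

    i = chord.index
    for relation, stem in (("all", "all"), ("same", "same_hand"), ("other", "other_hand")):
        nxt = _neighbor(chords, i, relation, +1)
        f[f"articulation_{stem}"] = (nxt.onset - offset) if nxt else float("nan")
        if relation != "other":
            key = "ioi_next" if relation == "all" else "ioi_same_hand_next"
            f[key] = (nxt.onset - onset) if nxt else float("nan")
        else:
            f["ioi_other_hand_next"] = (nxt.onset - onset) if nxt else float("nan")
    prev_same = _neighbor(chords, i, "same", -1)
    f["articulation_prev_same_hand"] = (onset - prev_same.offset) if prev_same else float("nan")

    # overlaps with other chords, by hand relation
    i0, depth = _chord_depression(chord, key_traces, None)
    for relation, stem in (("all", "all"), ("same", "same_hand"), ("other", "other_hand")):
        me = chord.hands
        count = 0
        total = 0.0
        mask = np.zeros(len(depth), dtype=bool)
        for other in chords:
            if other.index == i:
                continue
            hands = other.hands
            if relation == "same" and not (hands & me):
                continue
            if relation == "other" and (hands & me):
                continue
            lo = max(onset, other.onset)
            hi = min(offset, other.offset)
            if hi > lo:
                count += 1
                total += hi - lo
                a = max(0, int(round(lo / dt_ms)) - i0)
                b = min(len(depth), int(round(hi / dt_ms)) - i0 + 1)
                mask[a:b] = True
        f[f"overlap_count_{stem}"] = float(count)
        f[f"overlap_duration_{stem}"] = total
        f[f"overlap_amount_{stem}"] = float(depth[mask].mean()) if mask.any() else 0.0

    nxt_all = _neighbor(chords, i, "all", +1)
    f["duty_cycle"] = _safe_div(duration, f["ioi_next"]) if nxt_all else float("nan")
    f["overlap_next_duration"] = (
        max(0.0, offset - nxt_all.onset) if nxt_all else float("nan")
    )

    mhvs = np.array([v["mhv"] for v in vecs], dtype=float)
    mhvs = mhvs[~np.isnan(mhvs)]
    f["chord_mhv_max"] = float(mhvs.max()) if len(mhvs) else float("nan")
    f["chord_mhv_min"] = float(mhvs.min()) if len(mhvs) else float("nan")
    f["chord_mhv_range"] = (
        f["chord_mhv_max"] - f["chord_mhv_min"] if len(mhvs) else float("nan")
    )
    amaxes = np.array([float(m.amax) for m in notes])
    f["chord_amax_max"] = float(amaxes.max())
    f["chord_amax_min"] = float(amaxes.min())
    f["chord_amax_range"] = float(amaxes.max() - amaxes.min())
    f["chord_pitch_low"] = float(pitches.min())
    f["chord_pitch_high"] = float(pitches.max())
    f["chord_pitch_span"] = float(pitches.max() - pitches.min())
    for key, times in (("onset_pitch_slope", onsets), ("offset_pitch_slope", offsets)):
        if n > 1 and pitches.std() > 0:
            f[key] = float(np.polyfit(pitches, times, 1)[0])
        else:
            f[key] = float("nan")
    hands = [m.hand for m in notes]
    f["n_notes_left"] = float(hands.count("left"))
    f["n_notes_right"] = float(hands.count("right"))
    f["hand_balance"] = f["n_notes_right"] - f["n_notes_left"]

    # pedaling during the chord (32 features); all exactly 0 for an unused pedal
    ci0 = min(m.onset_i for m in notes)
    ci1 = max(m.offset_i for m in notes) + 1
    best = max(
        (m for m in notes if m.mhv is not None), key=lambda m: m.mhv, default=None
    )
    for prefix, key in _PEDAL_KEYS:
        pedal = np.asarray(pedal_traces[key], dtype=float)
        seg = pedal[ci0:ci1]
        in_use = seg > PEDAL_USE_THRESHOLD
        full = seg > PEDAL_FULL_THRESHOLD
        part = in_use & ~full
        f[f"{prefix}_use_duration"] = float(in_use.sum()) * dt_ms
        f[f"{prefix}_full_duration"] = float(full.sum()) * dt_ms
        f[f"{prefix}_part_duration"] = float(part.sum()) * dt_ms
        f[f"{prefix}_use_fraction"] = float(in_use.mean()) if len(seg) else 0.0
        f[f"{prefix}_full_fraction"] = float(full.mean()) if len(seg) else 0.0
        f[f"{prefix}_part_fraction"] = float(part.mean()) if len(seg) else 0.0
        f[f"{prefix}_mid_depression"] = float(seg[part].mean()) if part.any() else 0.0
        f[f"{prefix}_depression_mean"] = float(seg.mean()) if len(seg) else 0.0
        f[f"{prefix}_depression_max"] = float(seg.max()) if len(seg) else 0.0
        f[f"{prefix}_depression_min"] = float(seg.min()) if len(seg) else 0.0
        f[f"{prefix}_depression_range"] = f[f"{prefix}_depression_max"] - f[f"{prefix}_depression_min"]
        f[f"{prefix}_depression_at_onset"] = float(seg[0]) if len(seg) else 0.0
        f[f"{prefix}_depression_at_offset"] = float(seg[-1]) if len(seg) else 0.0
        if best is not None:
            bi = int(round(best.mhv_time / dt_ms))
            f[f"{prefix}_depression_at_mhv"] = float(pedal[min(bi, len(pedal) - 1)])
        else:
            f[f"{prefix}_depression_at_mhv"] = 0.0 if not in_use.any() else float("nan")
        if in_use.any():
            idx = np.flatnonzero(in_use)
            f[f"{prefix}_use_start_re_onset"] = float(idx[0]) * dt_ms
            f[f"{prefix}_use_end_re_offset"] = float(idx[-1] - (len(seg) - 1)) * dt_ms
        else:
            f[f"{prefix}_use_start_re_onset"] = 0.0
            f[f"{prefix}_use_end_re_offset"] = 0.0
    return f


# ---------------------------------------------------------------------------
# performance level
# ---------------------------------------------------------------------------


def performance_features(
    chord_vectors,
    chords,
    grouping: str,
    schema: FeatureSchema | None = None,
) -> dict:
    """Mean and dispersion over a chord grouping of the conserved features.

    ``grouping`` is one of ``all``, ``left``, ``right``, ``hand_diff``; the
    hand groupings exclude pedaling features, and ``hand_diff`` is the
    feature-wise left-minus-right difference of the per-hand vectors.
    An empty grouping gives missing entries (counts 0).
    """
    schema = schema or default_schema()
    if grouping == "hand_diff":
        left = performance_features(chord_vectors, chords, "left", schema)
        right = performance_features(chord_vectors, chords, "right", schema)
        return {
            k.replace("left.", "hand_diff.", 1): left[k] - right[k.replace("left.", "right.", 1)]
            for k in left
        }

    if grouping == "all":
        subset = list(range(len(chords)))
        names = schema.conserved
    else:
        subset = [i for i, c in enumerate(chords) if c.hand == grouping]
        # derive the grouping's conserved set from the frozen column list
        prefix = f"{grouping}."
        names = tuple(
            n for n in schema.conserved
            if f"{prefix}{n}_pmean" in schema.performance_columns
        )

    out: dict[str, float] = {}
    for name in names:
        vals = np.array([chord_vectors[i][name] for i in subset], dtype=float)
        ok = vals[~np.isnan(vals)]
        mean = float(ok.mean()) if len(ok) else float("nan")
        sd = float(ok.std()) if len(ok) else float("nan")
        if name in CV_DISPERSION:
            disp_name, disp = f"{grouping}.{name}_pcv", _safe_div(sd, abs(mean))
        else:
            disp_name, disp = f"{grouping}.{name}_psd", sd
        out[f"{grouping}.{name}_pmean"] = mean
        out[disp_name] = disp
    out[f"{grouping}.n_chords"] = float(len(subset))
    out[f"{grouping}.n_notes_total"] = float(
        sum(len(chords[i].notes) for i in subset)
    )
    return out


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def extract_performance(
    recording: PerformanceRecording,
    score=None,
    schema: FeatureSchema | None = None,
) -> dict:
    """Segment one recording and compute its 616-entry performance vector."""
    schema = schema or default_schema()
    grouping = segment_recording(recording, score)
    chords = grouping.chords
    dt = recording.dt_ms
    note_vecs = {}
    for chord in chords:
        for note in chord.notes:
            note_vecs[id(note)] = note_features(
                note, recording.key_traces[note.pitch], recording.pedal_traces, dt
            )
    chord_vecs = [
        chord_features(
            c, chords, note_vecs, recording.key_traces, recording.pedal_traces, dt, schema
        )
        for c in chords
    ]
    row: dict[str, float] = {}
    for g in GROUPINGS:
        row.update(performance_features(chord_vecs, chords, g, schema))
    return row


def build_feature_table(
    recordings,
    schema: FeatureSchema | None = None,
) -> pd.DataFrame:
    """One row per recording, metadata plus the 616 feature columns.

    ``recordings`` is an iterable of ``(PerformanceRecording, ScoreSpec)``
    pairs as produced by :func:`pianism.synth.generate_study`.
    """
    schema = schema or default_schema()
    rows = []
    for rec, score in recordings:
        row = {
            "pianist": rec.pianist,
            "piece": rec.piece,
            "timbre": rec.timbre,
            "repetition": rec.repetition,
        }
        row.update(extract_performance(rec, score, schema))
        rows.append(row)
    columns = list(METADATA_COLUMNS) + list(schema.column_names)
    return pd.DataFrame(rows, columns=columns)
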