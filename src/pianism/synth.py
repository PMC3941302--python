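"""Synthetic performance generator.

Generates continuous key/pedal position traces and hammer events with the
statistical structure the downstream analysis assumes: stable per-pianist
touch profiles, per-timbre modulations of those profiles, pianist-by-timbre
interactions, and small repetition-to-repetition noise.  Every parameter of a
:class:`PianistProfile` is recoverable from the generated traces by the
segmentation and feature-extraction stages (noise-free profiles round-trip to
within quantization error).

Keystroke model
---------------
A keystroke is a power-law attack ramp followed by a hold and a linear
release::

    position(t) = D * (t / T_attack) ** gamma     0 <= t < T_attack
                = D                               during the hold
                = D * (1 - s / T_release)         during the release

sampled on the recording grid (500 Hz by default) and quantized to integer
8-bit steps in [0, 250].  The single shape exponent ``gamma`` maps
analytically onto the attack-percussiveness statistic: the normalized area
under the normalized attack trajectory is ``1 / (gamma + 1)``, so ``gamma = 1``
is a linear (area 0.5) attack and ``gamma < 1`` a concave, percussive one.

Maximum hammer velocity is deterministically coupled to the realized mean
attack speed, ``MHV = round(min(250, K_MHV * D / T_attack))`` with
``K_MHV = 25`` steps per (step/ms): hammer velocity and mean attack speed are
highly correlated but distinct quantities, and the generator controls the
attack duration from the target hammer velocity through this map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .io import HammerEvent, PerformanceRecording

__all__ = [
    "ScoreChord",
    "ScoreSpec",
    "PedalPolicy",
    "PianistProfile",
    "TimbreModulation",
    "StudyDesign",
    "synthesize_keystroke",
    "synthesize_performance",
    "generate_study",
    "random_score",
    "default_profiles",
    "default_modulation",
    "load_config",
    "K_MHV",
    "TIMBRES",
]

K_MHV = 25.0  # hammer-velocity steps per (step/ms) of mean attack speed
TIMBRES = ("bright", "dark", "dry", "round", "velvety")
MIN_GAP_SAMPLES = 2  # rest gap enforced between re-strikes of one key


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoreChord:
    nominal_onset_ms: float
    notes: tuple  # of (pitch, hand)


@dataclass(frozen=True)
class ScoreSpec:
    """Machine-readable score: chord onsets, pitches and hand assignment."""

    chords: tuple
    meter: str = "4/4"
    nominal_duration_ms: float = 13000.0

    def __post_init__(self):
        onsets = [c.nominal_onset_ms for c in self.chords]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("nominal onsets must be strictly increasing")
        for c in self.chords:
            if not c.notes:
                raise ValueError("every chord needs at least one note")
            pitches = [p for p, _ in c.notes]
            if len(set(pitches)) != len(pitches):
                raise ValueError("pitches must be unique within a chord")
            for p, hand in c.notes:
                if not (21 <= p <= 108):
                    raise ValueError(f"pitch {p} outside 21..108")
                if hand not in ("left", "right"):
                    raise ValueError(f"unknown hand {hand!r}")

    @property
    def n_chords(self):
        return len(self.chords)


def random_score(rng, n_chords: int | None = None, max_notes: int = 4) -> ScoreSpec:
    """Programmatic two-hand chord sequence (4-16 chords, 1-4 notes each).

    Nominal duration at score tempo is drawn in 12-15 s.  Adjacent chords of
    the same hand avoid repeating pitches so that synthetic keystrokes do not
    re-strike a still-depressed key under legato articulation.
    """
    rng = np.random.default_rng(rng)
    if n_chords is None:
        n_chords = int(rng.integers(4, 17))
    total = float(rng.uniform(12000.0, 15000.0))
    ioi = total / n_chords
    chords = []
    prev_pitches: set = set()
    for i in range(n_chords):
        hand = ("left", "right", "both")[int(rng.integers(0, 3))]
        hands = ("left", "right") if hand == "both" else (hand,)
        notes = []
        used = set(prev_pitches)
        for h in hands:
            lo, hi = (40, 60) if h == "left" else (62, 84)
            k = int(rng.integers(1, max_notes // len(hands) + 1))
            pool = [p for p in range(lo, hi) if p not in used]
            picks = rng.choice(pool, size=min(k, len(pool)), replace=False)
            for p in sorted((int(x) for x in picks), reverse=True):
                notes.append((p, h))
                used.add(p)
        # melody (lead) note first: highest right-hand pitch if present
        notes.sort(key=lambda n: (n[1] != "right", -n[0]))
        chords.append(ScoreChord(i * ioi, tuple(notes)))
        prev_pitches = {p for p, _ in notes}
    return ScoreSpec(tuple(chords), nominal_duration_ms=total)


# ---------------------------------------------------------------------------
# profiles and modulations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PedalPolicy:
    use_prob: float = 0.0
    depth: float = 0.0


# (lower bound, upper bound) for truncating repetition noise / modulations
_PARAM_BOUNDS = {
    "mhv_mean": (1.0, 250.0),
    "mhv_cv": (0.0, 1.0),
    "depth_cv": (0.0, 1.0),
    "attack_convexity": (0.1, 5.0),
    "depth_mean": (1.0, 250.0),
    "articulation_offset": (-2000.0, 2000.0),
    "tempo_scale": (0.1, 5.0),
    "melody_lead_ms": (-200.0, 200.0),
    "right_hand_mhv_bonus": (-100.0, 100.0),
    "release_ms": (8.0, 500.0),
    "timing_jitter_sd": (0.0, 100.0),
    "soft_pedal.use_prob": (0.0, 1.0),
    "soft_pedal.depth": (0.0, 250.0),
    "sustain_pedal.use_prob": (0.0, 1.0),
    "sustain_pedal.depth": (0.0, 250.0),
}


@dataclass(frozen=True)
class PianistProfile:
    """Parameterization of one pianist's touch idiosyncrasies.

    Units: hammer velocity and depression depths in 8-bit steps, intervals in
    ms, ``attack_convexity`` is the dimensionless attack shape exponent
    (gamma < 1 gives a concave, percussive attack), ``tempo_scale`` multiplies
    the score's nominal inter-onset intervals, and positive
    ``articulation_offset`` detaches successive same-hand chords (negative
    values overlap them, i.e. legato).
    """

    name: str = ""
    mhv_mean: float = 120.0
    mhv_cv: float = 0.08
    attack_convexity: float = 1.0
    depth_mean: float = 200.0
    depth_cv: float = 0.0
    articulation_offset: float = 20.0
    tempo_scale: float = 1.0
    melody_lead_ms: float = 15.0
    right_hand_mhv_bonus: float = 10.0
    soft_pedal_policy: PedalPolicy = field(default_factory=PedalPolicy)
    sustain_pedal_policy: PedalPolicy = field(default_factory=PedalPolicy)
    release_ms: float = 60.0
    timing_jitter_sd: float = 0.0
    repetition_noise_sd: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 < self.mhv_mean <= 250):
            raise ValueError(f"mhv_mean {self.mhv_mean} outside (0, 250]")
        if not (0 < self.depth_mean <= 250):
            raise ValueError(f"depth_mean {self.depth_mean} outside (0, 250]")
        if self.tempo_scale <= 0:
            raise ValueError("tempo_scale must be positive")
        if self.attack_convexity <= 0:
            raise ValueError("attack_convexity must be positive")
        for pol in (self.soft_pedal_policy, self.sustain_pedal_policy):
            if not (0.0 <= pol.use_prob <= 1.0):
                raise ValueError(f"pedal use_prob {pol.use_prob} outside [0, 1]")

    # -- parameter access by dotted name --------------------------------

    def get(self, param: str) -> float:
        if "." in param:
            head, tail = param.split(".", 1)
            return getattr(getattr(self, head + "_policy"), tail)
        return getattr(self, param)

    def with_param(self, param: str, value: float) -> "PianistProfile":
        lo, hi = _PARAM_BOUNDS[param]
        value = float(np.clip(value, lo, hi))
        if "." in param:
            head, tail = param.split(".", 1)
            pol = getattr(self, head + "_policy")
            return replace(self, **{head + "_policy": replace(pol, **{tail: value})})
        return replace(self, **{param: value})

    def perturbed(self, rng) -> "PianistProfile":
        """Repetition noise: additive Gaussian per parameter, truncated."""
        prof = self
        for param, sd in self.repetition_noise_sd.items():
            if sd:
                prof = prof.with_param(param, prof.get(param) + rng.normal(0.0, sd))
        return prof


@dataclass(frozen=True)
class TimbreModulation:
    """Per-timbre profile modulation plus a pianist-by-timbre interaction table.

    ``offsets[timbre][param]`` is added, ``scales[timbre][param]`` multiplies,
    and ``interaction[(pianist, timbre)][param]`` adds on top; the modulated
    profile is truncated back to the parameter's valid range.
    """

    offsets: dict = field(default_factory=dict)
    scales: dict = field(default_factory=dict)
    interaction: dict = field(default_factory=dict)

    @property
    def timbres(self):
        return tuple(sorted(set(self.offsets) | set(self.scales)))

    def apply(self, profile: PianistProfile, timbre: str) -> PianistProfile:
        prof = profile
        for param, factor in self.scales.get(timbre, {}).items():
            prof = prof.with_param(param, prof.get(param) * factor)
        for param, delta in self.offsets.get(timbre, {}).items():
            prof = prof.with_param(param, prof.get(param) + delta)
        for param, delta in self.interaction.get((profile.name, timbre), {}).items():
            prof = prof.with_param(param, prof.get(param) + delta)
        return prof


@dataclass(frozen=True)
class StudyDesign:
    """Fully crossed pianists x pieces x timbres x repetitions design."""

    pianists: int = 4
    pieces: int = 4
    timbres: tuple = TIMBRES
    repetitions: int = 3
    seed: int = 0

    def __post_init__(self):
        if min(self.pianists, self.pieces, len(self.timbres), self.repetitions) < 1:
            raise ValueError("all design counts must be positive")

    @property
    def total(self) -> int:
        return self.pianists * self.pieces * len(self.timbres) * self.repetitions


# ---------------------------------------------------------------------------
# keystroke synthesis
# ---------------------------------------------------------------------------


def synthesize_keystroke(
    onset_ms: float,
    depth: float,
    t_attack_ms: float,
    gamma: float,
    sustain_ms: float,
    t_release_ms: float,
    rate: float = 500.0,
):
    """Sample one keystroke on the recording grid.

    Returns ``(start_index, segment)`` where ``segment`` is the quantized
    integer position series beginning at sample ``start_index``.
    """
    if not (0 < depth <= 250):
        raise ValueError(f"depth {depth} outside (0, 250]")
    if t_attack_ms <= 0 or t_release_ms <= 0 or sustain_ms < 0 or gamma <= 0:
        raise ValueError("durations and gamma must be positive")
    dt = 1000.0 / rate
    start = int(np.ceil(onset_ms / dt))
    total = t_attack_ms + sustain_ms + t_release_ms
    n = int(np.floor((onset_ms + total) / dt)) - start + 1
    t = np.arange(start, start + n) * dt - onset_ms
    pos = np.empty(n)
    attack = t < t_attack_ms
    hold = (t >= t_attack_ms) & (t < t_attack_ms + sustain_ms)
    rel = ~attack & ~hold
    pos[attack] = depth * (t[attack] / t_attack_ms) ** gamma
    pos[hold] = depth
    s = t[rel] - t_attack_ms - sustain_ms
    pos[rel] = depth * np.clip(1.0 - s / t_release_ms, 0.0, 1.0)
    seg = np.clip(np.rint(pos), 0, 250).astype(np.int16)
    return start, seg


# ---------------------------------------------------------------------------
# performance synthesis
# ---------------------------------------------------------------------------


def _plan_notes(score, prof, rng):
    """Realize per-note onset/offset/depth/MHV targets from a profile."""
    onsets = np.array([c.nominal_onset_ms for c in score.chords]) * prof.tempo_scale
    if prof.timing_jitter_sd:
        onsets = onsets + rng.normal(0.0, prof.timing_jitter_sd, size=len(onsets))
        onsets = np.maximum.accumulate(onsets)  # keep chronological order
    iois = np.diff(onsets)
    default_hold = 0.7 * (np.median(iois) if len(iois) else 600.0 * prof.tempo_scale)

    # chord offsets from the articulation interval to the next same-hand chord
    hands = [set(h for _, h in c.notes) for c in score.chords]
    offsets_ms = np.empty(len(score.chords))
    for i in range(len(score.chords)):
        nxt = next(
            (j for j in range(i + 1, len(score.chords)) if hands[j] & hands[i]), None
        )
        if nxt is None:
            offsets_ms[i] = onsets[i] + default_hold
        else:
            offsets_ms[i] = onsets[nxt] - prof.articulation_offset
        offsets_ms[i] = max(offsets_ms[i], onsets[i] + 40.0)

    notes = []
    for i, chord in enumerate(score.chords):
        chord_mult = max(0.2, 1.0 + prof.mhv_cv * rng.normal()) if prof.mhv_cv else 1.0
        depth_mult = max(0.2, 1.0 + prof.depth_cv * rng.normal()) if prof.depth_cv else 1.0
        for j, (pitch, hand) in enumerate(chord.notes):
            onset = onsets[i] if j == 0 else onsets[i] + prof.melody_lead_ms
            if prof.timing_jitter_sd and j > 0:
                onset += rng.normal(0.0, prof.timing_jitter_sd / 2)
            onset = max(onset, 0.0)
            mhv = prof.mhv_mean * chord_mult
            if hand == "right":
                mhv += prof.right_hand_mhv_bonus
            mhv = float(np.clip(mhv, 10.0, 250.0))
            depth = prof.depth_mean * depth_mult
            if prof.depth_cv:  # per-note spread within the chord
                depth += rng.normal(0.0, 2.0)
            depth = float(np.clip(depth, 1.0, 250.0))
            t_attack = float(np.clip(K_MHV * depth / mhv, 4.0, 400.0))
            notes.append(
                dict(
                    chord=i,
                    pitch=pitch,
                    hand=hand,
                    onset=onset,
                    offset=max(offsets_ms[i], onset + t_attack + 8.0),
                    depth=depth,
                    t_attack=t_attack,
                    gamma=prof.attack_convexity,
                )
            )
    return notes


def synthesize_performance(
    score: ScoreSpec,
    profile: PianistProfile,
    modulation: TimbreModulation | None = None,
    timbre: str = "",
    seed=None,
    rate: float = 500.0,
    piece: str = "",
    repetition: int = 0,
) -> PerformanceRecording:
    """Render one performance of ``score`` by ``profile`` as a recording.

    Timing: chord onsets land at ``nominal_onset * tempo_scale`` (+ jitter),
    non-lead notes within a chord are staggered by ``melody_lead_ms``, and
    chord offsets realize the profile's articulation interval against the next
    same-hand chord.  Hammer events are emitted once per keystroke, shortly
    before the key bottoms, with MHV coupled to the realized attack speed.
    Re-strikes of a key before its release completes are resolved by
    truncating the earlier keystroke to leave a 2-sample rest gap.
    """
    rng = np.random.default_rng(seed)
    prof = modulation.apply(profile, timbre) if modulation is not None else profile
    if modulation is not None and timbre not in modulation.timbres:
        raise ValueError(f"timbre {timbre!r} not in modulation domain {modulation.timbres}")
    dt = 1000.0 / rate
    notes = _plan_notes(score, prof, rng)

    # resolve same-key re-strikes: earlier offset ends >= 2 samples before next onset
    by_pitch: dict[int, list] = {}
    for note in notes:
        by_pitch.setdefault(note["pitch"], []).append(note)
    for group in by_pitch.values():
        group.sort(key=lambda n: n["onset"])
        for prev, nxt in zip(group, group[1:]):
            limit = nxt["onset"] - MIN_GAP_SAMPLES * dt
            if prev["offset"] > limit:
                prev["offset"] = max(limit, prev["onset"] + prev["t_attack"] + 2 * dt)

    # pedal engagement decided per recording from the policies
    last_off = max(n["offset"] for n in notes)
    first_on = min(n["onset"] for n in notes)
    n_samples = int(np.ceil((last_off + 500.0) / dt)) + 1

    key_traces = {}
    events = []
    for pitch, group in sorted(by_pitch.items()):
        trace = np.zeros(n_samples, dtype=np.int16)
        for note in group:
            t_rel = min(prof.release_ms, max(2 * dt, note["offset"] - note["onset"] - note["t_attack"]))
            sustain = max(0.0, note["offset"] - note["onset"] - note["t_attack"] - t_rel)
            start, seg = synthesize_keystroke(
                note["onset"], note["depth"], note["t_attack"], note["gamma"],
                sustain, t_rel, rate,
            )
            stop = min(start + len(seg), n_samples)
            trace[start:stop] = np.maximum(trace[start:stop], seg[: stop - start])
            mhv = int(round(min(250.0, K_MHV * note["depth"] / note["t_attack"])))
            events.append(HammerEvent(pitch, note["onset"] + 0.9 * note["t_attack"], mhv))
        key_traces[pitch] = trace

    pedal_traces = {}
    for name, policy in (("soft", prof.soft_pedal_policy), ("sust", prof.sustain_pedal_policy)):
        trace = np.zeros(n_samples, dtype=np.int16)
        if policy.use_prob > 0 and rng.random() < policy.use_prob and policy.depth > 0:
            depth = float(np.clip(policy.depth, 0, 250))
            t0 = max(0.0, first_on - 150.0)
            t1 = min((n_samples - 1) * dt, last_off + 150.0)
            i0, i1 = int(round(t0 / dt)), int(round(t1 / dt))
            ramp = max(1, int(round(100.0 / dt)))
            prof_depth = np.full(i1 - i0, depth)
            prof_depth[:ramp] = np.linspace(0, depth, ramp, endpoint=False)
            prof_depth[-ramp:] = np.linspace(depth, 0, ramp)
            trace[i0:i1] = np.clip(np.rint(prof_depth), 0, 250).astype(np.int16)
        pedal_traces[name] = trace

    events.sort(key=lambda e: e.time_ms)
    return PerformanceRecording(
        pianist=profile.name,
        piece=piece,
        timbre=timbre,
        repetition=repetition,
        rate=rate,
        key_traces=key_traces,
        pedal_traces=pedal_traces,
        hammer_events=events,
    )


# ---------------------------------------------------------------------------
# study generation
# ---------------------------------------------------------------------------


def generate_study(
    design: StudyDesign,
    profiles: dict | None = None,
    modulation: TimbreModulation | None = None,
    scores: dict | None = None,
):
    """Generate the full crossed study; yields ``(recording, score)`` pairs.

    Exactly ``pianists * pieces * timbres * repetitions`` recordings are
    produced, reproducibly from ``design.seed`` (one independent random stream
    per recording).
    """
    if profiles is None:
        profiles = default_profiles()
    if modulation is None:
        modulation = default_modulation(design.timbres)
    profiles = dict(profiles)
    if len(profiles) != design.pianists:
        raise ValueError(
            f"got {len(profiles)} profiles for {design.pianists} pianists"
        )
    piece_ids = [f"piece{i + 1}" for i in range(design.pieces)]
    if scores is None:
        scores = {
            pid: random_score(np.random.default_rng([design.seed, 10_000 + gi]))
            for gi, pid in enumerate(piece_ids)
        }
    out = []
    for pi, (pname, prof) in enumerate(sorted(profiles.items())):
        for gi, pid in enumerate(piece_ids):
            for ti, timbre in enumerate(design.timbres):
                for ri in range(design.repetitions):
                    rng = np.random.default_rng([design.seed, pi, gi, ti, ri])
                    rec = synthesize_performance(
                        scores[pid],
                        prof.perturbed(rng),
                        modulation,
                        timbre,
                        seed=rng,
                        piece=pid,
                        repetition=ri + 1,
                    )
                    out.append((rec, scores[pid]))
    return out


def default_profiles() -> dict:
    """Four pianist profiles with contrasting touch, articulation and pedaling.

    The contrasts (a quiet legato player with long melody leads; a percussive
    staccato player at slow tempo; a loud, deep, steady player who never uses
    the soft pedal; a shallow-touch player with heavy pedaling and strong
    right-hand emphasis) emulate the kinds of idiosyncrasies the analysis is
    meant to detect, at effect sizes large relative to the repetition noise.
    """
    noise = {
        "mhv_mean": 4.0,
        "depth_mean": 4.0,
        "articulation_offset": 8.0,
        "tempo_scale": 0.02,
        "melody_lead_ms": 3.0,
        "attack_convexity": 0.05,
    }
    return {
        "A": PianistProfile(
            name="A", depth_cv=0.06, mhv_mean=95, mhv_cv=0.14, attack_convexity=1.4,
            depth_mean=190, articulation_offset=-40, tempo_scale=0.95,
            melody_lead_ms=28, right_hand_mhv_bonus=12,
            soft_pedal_policy=PedalPolicy(0.3, 150),
            sustain_pedal_policy=PedalPolicy(0.8, 200),
            timing_jitter_sd=4.0, repetition_noise_sd=noise,
        ),
        "B": PianistProfile(
            name="B", depth_cv=0.04, mhv_mean=115, mhv_cv=0.08, attack_convexity=0.6,
            depth_mean=215, articulation_offset=90, tempo_scale=1.15,
            melody_lead_ms=10, right_hand_mhv_bonus=12,
            soft_pedal_policy=PedalPolicy(0.2, 140),
            sustain_pedal_policy=PedalPolicy(0.4, 180),
            timing_jitter_sd=4.0, repetition_noise_sd=noise,
        ),
        "C": PianistProfile(
            name="C", depth_cv=0.03, mhv_mean=160, mhv_cv=0.05, attack_convexity=1.0,
            depth_mean=230, articulation_offset=30, tempo_scale=0.95,
            melody_lead_ms=12, right_hand_mhv_bonus=5,
            soft_pedal_policy=PedalPolicy(0.0, 0),
            sustain_pedal_policy=PedalPolicy(0.4, 190),
            timing_jitter_sd=4.0, repetition_noise_sd=noise,
        ),
        "D": PianistProfile(
            name="D", depth_cv=0.08, mhv_mean=135, mhv_cv=0.10, attack_convexity=0.9,
            depth_mean=175, articulation_offset=25, tempo_scale=1.10,
            melody_lead_ms=12, right_hand_mhv_bonus=25,
            soft_pedal_policy=PedalPolicy(0.8, 200),
            sustain_pedal_policy=PedalPolicy(0.9, 210),
            timing_jitter_sd=4.0, repetition_noise_sd=noise,
        ),
    }


def default_modulation(timbres=TIMBRES) -> TimbreModulation:
    """Per-timbre modulations plus a few pianist-specific interaction cells."""
    offsets = {
        "bright": {"mhv_mean": 20, "articulation_offset": 20},
        "dark": {"mhv_mean": -20, "sustain_pedal.depth": 20, "articulation_offset": -10},
        "dry": {"articulation_offset": 60, "sustain_pedal.use_prob": -0.5},
        "round": {"articulation_offset": -30},
        "velvety": {"mhv_mean": -15, "soft_pedal.use_prob": 0.3, "articulation_offset": -20},
    }
    scales = {
        "bright": {"attack_convexity": 0.8},
        "dark": {"attack_convexity": 1.2},
        "round": {"attack_convexity": 1.1},
        "velvety": {"attack_convexity": 1.1},
    }
    interaction = {
        # D keeps high dynamics in dark-timbre performances
        ("D", "dark"): {"mhv_mean": 40},
        # B plays velvety with the soft pedal throughout
        ("B", "velvety"): {"soft_pedal.use_prob": 1.0},
        # C shortens attacks drastically only when asked for a bright timbre
        ("C", "bright"): {"mhv_mean": 25},
    }
    offsets = {t: offsets.get(t, {}) for t in timbres}
    scales = {t: scales.get(t, {}) for t in timbres}
    return TimbreModulation(offsets=offsets, scales=scales, interaction=interaction)


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------


def load_config(path):
    """Load a YAML study configuration.

    Recognised top-level keys: ``design`` (StudyDesign fields), ``profiles``
    (mapping name -> PianistProfile fields; pedal policies as
    ``{use_prob, depth}`` mappings), ``modulation`` (``offsets``, ``scales``,
    ``interaction`` with ``pianist|timbre`` keys).  Missing sections fall back
    to the package defaults.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    design_kw = dict(cfg.get("design", {}))
    if "timbres" in design_kw:
        design_kw["timbres"] = tuple(design_kw["timbres"])
    design = StudyDesign(**design_kw)
    profiles = None
    if "profiles" in cfg:
        profiles = {}
        for name, kw in cfg["profiles"].items():
            kw = dict(kw)
            for key in ("soft_pedal_policy", "sustain_pedal_policy"):
                if key in kw:
                    kw[key] = PedalPolicy(**kw[key])
            profiles[name] = PianistProfile(name=name, **kw)
    modulation = None
    if "modulation" in cfg:
        m = cfg["modulation"]
        interaction = {
            tuple(k.split("|")): v for k, v in m.get("interaction", {}).items()
        }
        modulation = TimbreModulation(
            offsets=m.get("offsets", {}), scales=m.get("scales", {}),
            interaction=interaction,
        )
    if modulation is None:
        modulation = default_modulation(design.timbres)
    return design, profiles, modulation
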