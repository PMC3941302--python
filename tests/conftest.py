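import numpy as np
import pandas as pd
import pytest

import pianism as pm

TIMBRE_PAIR = ("bright", "dark")


@pytest.fixture(scope="session")
def schema():
    return pm.default_schema()


@pytest.fixture(scope="session")
def fixed_score():
    """Deterministic 6-chord two-hand score."""
    chords = (
        pm.ScoreChord(0.0, ((72, "right"), (67, "right"), (48, "left"))),
        pm.ScoreChord(700.0, ((74, "right"), (50, "left"))),
        pm.ScoreChord(1400.0, ((76, "right"),)),
        pm.ScoreChord(2100.0, ((71, "right"), (52, "left"), (45, "left"))),
        pm.ScoreChord(2800.0, ((72, "right"), (48, "left"))),
        pm.ScoreChord(3500.0, ((69, "right"), (50, "left"))),
    )
    return pm.ScoreSpec(chords, nominal_duration_ms=4200.0)


@pytest.fixture()
def clean_profile():
    """Noise-free, jitter-free profile for exact round trips."""
    return pm.PianistProfile(
        name="X", mhv_mean=125.0, mhv_cv=0.0, depth_cv=0.0, attack_convexity=1.0,
        depth_mean=200.0, articulation_offset=-50.0, tempo_scale=1.0,
        melody_lead_ms=20.0, right_hand_mhv_bonus=0.0, timing_jitter_sd=0.0,
    )


def small_profiles():
    base = dict(mhv_cv=0.05, depth_cv=0.04, timing_jitter_sd=3.0,
                repetition_noise_sd={"mhv_mean": 3.0, "articulation_offset": 6.0})
    return {
        "A": pm.PianistProfile(name="A", mhv_mean=95, depth_mean=185,
                               articulation_offset=-40, melody_lead_ms=25,
                               attack_convexity=1.3, **base),
        "B": pm.PianistProfile(name="B", mhv_mean=120, depth_mean=215,
                               articulation_offset=80, melody_lead_ms=10,
                               attack_convexity=0.7, **base),
        "C": pm.PianistProfile(name="C", mhv_mean=160, depth_mean=230,
                               articulation_offset=25, melody_lead_ms=12,
                               attack_convexity=1.0, **base),
        "D": pm.PianistProfile(name="D", mhv_mean=135, depth_mean=170,
                               articulation_offset=20, melody_lead_ms=14,
                               attack_convexity=0.9,
                               soft_pedal_policy=pm.PedalPolicy(0.8, 200),
                               sustain_pedal_policy=pm.PedalPolicy(0.9, 210), **base),
    }


@pytest.fixture(scope="session")
def small_study():
    """48-recording study (4 pianists x 2 pieces x 2 timbres x 3 reps)."""
    design = pm.StudyDesign(pianists=4, pieces=2, timbres=TIMBRE_PAIR,
                            repetitions=3, seed=11)
    modulation = pm.TimbreModulation(
        offsets={"bright": {"mhv_mean": 15}, "dark": {"mhv_mean": -15}},
        interaction={("D", "dark"): {"mhv_mean": 45}},
    )
    return pm.generate_study(design, small_profiles(), modulation)


@pytest.fixture(scope="session")
def small_table(small_study):
    return pm.build_feature_table(small_study)


def design_frame(pianists=4, timbres=("bright", "dark", "dry", "round", "velvety"),
                 pieces=4, repetitions=3):
    """Balanced design metadata frame without feature columns."""
    rows = [
        dict(pianist=f"P{p}", timbre=t, piece=f"g{g}", repetition=r + 1)
        for p in range(pianists)
        for t in timbres
        for g in range(pieces)
        for r in range(repetitions)
    ]
    return pd.DataFrame(rows)


def null_feature_table(rng, n_features=200, **design_kw):
    """Design-structured i.i.d. Gaussian features: all pianists identical."""
    meta = design_frame(**design_kw)
    X = rng.normal(size=(len(meta), n_features))
    feats = pd.DataFrame(X, columns=[f"F{j:03d}" for j in range(n_features)])
    return pd.concat([meta, feats], axis=1)
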