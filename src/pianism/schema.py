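"""Frozen feature schema for the performance-feature hierarchy.

The feature set is organised in three levels:

* **note features** (46): computed per keystroke from its landmarks, the hammer
  event and the pedal traces sampled at note landmarks;
* **chord features** (168): the per-chord mean and standard deviation of every
  note feature (92) plus 76 chord-specific features, 32 of which describe the
  soft and sustain pedals during the chord;
* **performance features** (616): per-performance mean and dispersion of the
  100 chord features whose averaging is meaningful ("conserved" features),
  plus chord and note counts, over four chord groupings — all chords (202),
  left-hand chords, right-hand chords and the left-minus-right difference
  (138 each; pedaling features are dropped for the per-hand groupings).

The published description of this hierarchy names a subset of the features and
prints the exact counts; the enumeration below freezes one concrete realisation
containing every named feature, padded within the stated categories to the
printed counts.  Membership of the 100 conserved chord features is likewise a
documented reconstruction (see ``docs/feature_schema.md``).

Every feature carries a category used by the portrait stage:
``dynamics_attack``, ``articulation``, ``soft_pedal`` or ``sustain_pedal``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

__all__ = [
    "FeatureDef",
    "FeatureSchema",
    "CATEGORIES",
    "GROUPINGS",
    "default_schema",
]

CATEGORIES = ("dynamics_attack", "articulation", "soft_pedal", "sustain_pedal")
GROUPINGS = ("all", "left", "right", "hand_diff")


@dataclass(frozen=True)
class FeatureDef:
    """One feature definition.

    Parameters
    ----------
    name:
        Unique feature name at its level.
    category:
        One of :data:`CATEGORIES`.
    unit:
        Physical unit ("ms", "steps", "steps/ms", "" for dimensionless).
    interpretability:
        Rank used as final tie-break when selecting portrait representatives;
        lower is preferred (direct measures before ratios, means before
        dispersions).
    """

    name: str
    category: str
    unit: str = ""
    interpretability: int = 1


def _d(name, cat, unit="", rank=1):
    return FeatureDef(name, cat, unit, rank)


# ---------------------------------------------------------------------------
# Note features (46)
# ---------------------------------------------------------------------------

_NOTE_FEATURES = (
    # dynamics & attack (17)
    _d("mhv", "dynamics_attack", "steps", 0),
    _d("amax", "dynamics_attack", "steps", 0),
    _d("mhv_amax_ratio", "dynamics_attack", "", 2),
    _d("mhv_amax_lag", "dynamics_attack", "ms", 2),
    _d("attack_duration", "dynamics_attack", "ms", 0),
    _d("attack_duration_mhv", "dynamics_attack", "ms", 1),
    _d("attack_speed", "dynamics_attack", "steps/ms", 0),
    _d("attack_speed_mhv", "dynamics_attack", "steps/ms", 1),
    _d("percussiveness", "dynamics_attack", "", 0),
    _d("attack_depth_mean", "dynamics_attack", "steps", 2),
    _d("attack_early_speed", "dynamics_attack", "steps/ms", 2),
    _d("attack_late_speed", "dynamics_attack", "steps/ms", 2),
    _d("attack_speed_ratio", "dynamics_attack", "", 3),
    _d("half_depth_time", "dynamics_attack", "ms", 2),
    _d("depression_mean", "dynamics_attack", "steps", 2),
    _d("depression_area", "dynamics_attack", "steps*ms", 3),
    _d("pitch", "dynamics_attack", "midi", 2),
    # articulation & durations (13)
    _d("sustain_duration", "articulation", "ms", 0),
    _d("release_duration", "articulation", "ms", 0),
    _d("release_speed", "articulation", "steps/ms", 1),
    _d("note_duration", "articulation", "ms", 1),
    _d("key_down_duration", "articulation", "ms", 1),
    _d("attack_fraction", "articulation", "", 3),
    _d("sustain_fraction", "articulation", "", 3),
    _d("release_fraction", "articulation", "", 3),
    _d("onset_time", "articulation", "ms", 4),
    _d("offset_time", "articulation", "ms", 4),
    _d("amax_time_point", "articulation", "ms", 4),
    _d("mhv_time_point", "articulation", "ms", 4),
    _d("release_start_time", "articulation", "ms", 4),
    # per-note soft pedal state (8)
    _d("soft_at_onset", "soft_pedal", "steps", 1),
    _d("soft_at_amax", "soft_pedal", "steps", 2),
    _d("soft_at_mhv", "soft_pedal", "steps", 2),
    _d("soft_at_offset", "soft_pedal", "steps", 1),
    _d("soft_mean", "soft_pedal", "steps", 0),
    _d("soft_max", "soft_pedal", "steps", 1),
    _d("soft_active_fraction", "soft_pedal", "", 1),
    _d("soft_full_fraction", "soft_pedal", "", 1),
    # per-note sustain pedal state (8)
    _d("sust_at_onset", "sustain_pedal", "steps", 1),
    _d("sust_at_amax", "sustain_pedal", "steps", 2),
    _d("sust_at_mhv", "sustain_pedal", "steps", 2),
    _d("sust_at_offset", "sustain_pedal", "steps", 1),
    _d("sust_mean", "sustain_pedal", "steps", 0),
    _d("sust_max", "sustain_pedal", "steps", 1),
    _d("sust_active_fraction", "sustain_pedal", "", 1),
    _d("sust_full_fraction", "sustain_pedal", "", 1),
)

# Note features whose value depends on an associated hammer event; when a note
# has no hammer event these are missing while the rest are still computed.
MHV_DEPENDENT = frozenset(
    {
        "mhv",
        "mhv_amax_ratio",
        "mhv_amax_lag",
        "attack_duration_mhv",
        "attack_speed_mhv",
        "mhv_time_point",
        "soft_at_mhv",
        "sust_at_mhv",
    }
)

# Absolute-instant note features: indispensable as building blocks per chord
# but meaningless when averaged over a performance.
_ABSOLUTE_TIME_NOTE = (
    "onset_time",
    "offset_time",
    "amax_time_point",
    "mhv_time_point",
    "release_start_time",
)

# ---------------------------------------------------------------------------
# Chord-specific features (76 = 44 non-pedal + 32 pedal)
# ---------------------------------------------------------------------------

_CHORD_SPECIFIC_NONPEDAL = (
    _d("n_notes", "articulation", "", 2),
    _d("chord_duration", "articulation", "ms", 1),
    _d("onset_time", "articulation", "ms", 4),
    _d("offset_time", "articulation", "ms", 4),
    _d("onset_asynchrony_span", "articulation", "ms", 1),
    _d("onset_asynchrony_rate", "articulation", "ms", 2),
    _d("onset_asynchrony_amount", "articulation", "ms", 2),
    _d("offset_asynchrony_span", "articulation", "ms", 1),
    _d("offset_asynchrony_rate", "articulation", "ms", 2),
    _d("offset_asynchrony_amount", "articulation", "ms", 2),
    _d("melody_lead", "articulation", "ms", 0),
    _d("melody_mhv_excess", "dynamics_attack", "steps", 1),
    _d("ioi_next", "articulation", "ms", 0),
    _d("ioi_same_hand_next", "articulation", "ms", 1),
    _d("ioi_other_hand_next", "articulation", "ms", 2),
    _d("articulation_all", "articulation", "ms", 1),
    _d("articulation_same_hand", "articulation", "ms", 0),
    _d("articulation_other_hand", "articulation", "ms", 2),
    _d("articulation_prev_same_hand", "articulation", "ms", 2),
    _d("overlap_count_all", "articulation", "", 1),
    _d("overlap_count_same_hand", "articulation", "", 1),
    _d("overlap_count_other_hand", "articulation", "", 1),
    _d("overlap_duration_all", "articulation", "ms", 1),
    _d("overlap_duration_same_hand", "articulation", "ms", 1),
    _d("overlap_duration_other_hand", "articulation", "ms", 1),
    _d("overlap_amount_all", "articulation", "steps", 2),
    _d("overlap_amount_same_hand", "articulation", "steps", 2),
    _d("overlap_amount_other_hand", "articulation", "steps", 2),
    _d("duty_cycle", "articulation", "", 3),
    _d("chord_mhv_max", "dynamics_attack", "steps", 1),
    _d("chord_mhv_min", "dynamics_attack", "steps", 2),
    _d("chord_mhv_range", "dynamics_attack", "steps", 1),
    _d("chord_amax_max", "dynamics_attack", "steps", 1),
    _d("chord_amax_min", "dynamics_attack", "steps", 2),
    _d("chord_amax_range", "dynamics_attack", "steps", 1),
    _d("chord_pitch_low", "dynamics_attack", "midi", 2),
    _d("chord_pitch_high", "dynamics_attack", "midi", 2),
    _d("chord_pitch_span", "dynamics_attack", "semitones", 2),
    _d("onset_pitch_slope", "articulation", "ms/semitone", 3),
    _d("offset_pitch_slope", "articulation", "ms/semitone", 3),
    _d("n_notes_left", "articulation", "", 3),
    _d("n_notes_right", "articulation", "", 3),
    _d("hand_balance", "articulation", "", 3),
    _d("overlap_next_duration", "articulation", "ms", 2),
)

_PEDAL_STEMS = (
    ("use_duration", "ms", 0),
    ("full_duration", "ms", 1),
    ("part_duration", "ms", 1),
    ("use_fraction", "", 1),
    ("full_fraction", "", 2),
    ("part_fraction", "", 2),
    ("mid_depression", "steps", 0),
    ("depression_mean", "steps", 0),
    ("depression_max", "steps", 1),
    ("depression_min", "steps", 2),
    ("depression_range", "steps", 2),
    ("depression_at_onset", "steps", 1),
    ("depression_at_offset", "steps", 1),
    ("depression_at_mhv", "steps", 2),
    ("use_start_re_onset", "ms", 2),
    ("use_end_re_offset", "ms", 2),
)

_CHORD_SPECIFIC_PEDAL = tuple(
    _d(f"{prefix}_{stem}", category, unit, rank)
    for prefix, category in (("soft", "soft_pedal"), ("sust", "sustain_pedal"))
    for stem, unit, rank in _PEDAL_STEMS
)

# ---------------------------------------------------------------------------
# Conserved chord features (100)
# ---------------------------------------------------------------------------

# Chord-level standard deviations of note features retained at the
# performance level (within-chord spread of touch).
_CONSERVED_NOTE_SDS = (
    "mhv",
    "amax",
    "attack_duration",
    "attack_speed",
    "percussiveness",
    "release_duration",
)

_CONSERVED_CHORD_SPECIFIC_NONPEDAL = (
    "chord_duration",
    "onset_asynchrony_span",
    "onset_asynchrony_rate",
    "onset_asynchrony_amount",
    "offset_asynchrony_span",
    "offset_asynchrony_amount",
    "melody_lead",
    "melody_mhv_excess",
    "ioi_next",
    "ioi_same_hand_next",
    "articulation_all",
    "articulation_same_hand",
    "articulation_other_hand",
    "overlap_count_all",
    "overlap_count_same_hand",
    "overlap_count_other_hand",
    "overlap_duration_all",
    "overlap_duration_same_hand",
    "overlap_duration_other_hand",
    "overlap_amount_all",
    "overlap_amount_same_hand",
)

# Performance-level dispersion reported as a coefficient of variation
# (SD over chords divided by the mean) rather than a plain SD: the printed
# "variations in ..." features are ratios of deviation from the average.
CV_DISPERSION = frozenset({"mhv_cmean", "attack_duration_cmean", "amax_cmean"})


class SchemaError(ValueError):
    """Raised when the frozen schema fails its count invariants."""


@dataclass(frozen=True)
class FeatureSchema:
    """The frozen three-level feature enumeration.

    Attributes
    ----------
    note_features : tuple of FeatureDef
        46 per-note definitions.
    chord_features : tuple of FeatureDef
        168 per-chord definitions: ``<note>_cmean`` / ``<note>_csd``
        aggregates (92) followed by the 76 chord-specific definitions.
    conserved : tuple of str
        The 100 chord feature names aggregated to the performance level.
    """

    note_features: tuple = ()
    chord_features: tuple = ()
    conserved: tuple = ()
    performance_columns: dict = field(default_factory=dict)

    # -- construction -------------------------------------------------------

    @staticmethod
    def build() -> "FeatureSchema":
        note = _NOTE_FEATURES
        agg = []
        for f in note:
            agg.append(FeatureDef(f"{f.name}_cmean", f.category, f.unit, f.interpretability))
            agg.append(FeatureDef(f"{f.name}_csd", f.category, f.unit, f.interpretability + 2))
        chord = tuple(agg) + _CHORD_SPECIFIC_NONPEDAL + _CHORD_SPECIFIC_PEDAL

        conserved = []
        absolute = set(_ABSOLUTE_TIME_NOTE)
        for f in note:
            if f.name not in absolute:
                conserved.append(f"{f.name}_cmean")
        for name in _CONSERVED_NOTE_SDS:
            conserved.append(f"{name}_csd")
        conserved.extend(_CONSERVED_CHORD_SPECIFIC_NONPEDAL)
        conserved.extend(f.name for f in _CHORD_SPECIFIC_PEDAL)

        schema = FeatureSchema(
            note_features=note,
            chord_features=chord,
            conserved=tuple(conserved),
            performance_columns=FeatureSchema._performance_columns(chord, tuple(conserved)),
        )
        schema.validate()
        return schema

    @staticmethod
    def _performance_columns(chord_features, conserved):
        """Ordered mapping column name -> FeatureDef for all 616 columns."""
        defs = {f.name: f for f in chord_features}
        # per-hand groupings drop exactly the 32 chord-level pedaling features
        pedal = {f.name for f in _CHORD_SPECIFIC_PEDAL}
        columns: dict[str, FeatureDef] = {}
        for grouping in GROUPINGS:
            names = conserved if grouping == "all" else tuple(n for n in conserved if n not in pedal)
            for name in names:
                base = defs[name]
                disp = "pcv" if name in CV_DISPERSION else "psd"
                for suffix, extra in (("pmean", 0), (disp, 2)):
                    col = f"{grouping}.{name}_{suffix}"
                    columns[col] = FeatureDef(
                        col, base.category, base.unit if suffix == "pmean" else "",
                        base.interpretability + extra,
                    )
            columns[f"{grouping}.n_chords"] = FeatureDef(f"{grouping}.n_chords", "articulation", "", 3)
            columns[f"{grouping}.n_notes_total"] = FeatureDef(f"{grouping}.n_notes_total", "articulation", "", 3)
        return columns

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        """Assert the printed counts: 46/76/168/100/32/202/138/616."""
        n_note = len(self.note_features)
        chord_specific = [f for f in self.chord_features if not f.name.endswith(("_cmean", "_csd"))]
        n_pedal = sum(f.category in ("soft_pedal", "sustain_pedal") for f in chord_specific)
        checks = {
            "note features": (n_note, 46),
            "chord-specific features": (len(chord_specific), 76),
            "pedaling chord features": (n_pedal, 32),
            "chord features": (len(self.chord_features), 168),
            "conserved chord features": (len(self.conserved), 100),
            "performance columns": (len(self.performance_columns), 616),
            "all-chords columns": (sum(c.startswith("all.") for c in self.performance_columns), 202),
            "left-hand columns": (sum(c.startswith("left.") for c in self.performance_columns), 138),
        }
        for label, (got, want) in checks.items():
            if got != want:
                raise SchemaError(f"schema invariant broken: {got} {label}, expected {want}")
        names = [f.name for f in self.chord_features]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate chord feature names")
        for f in list(self.note_features) + list(self.chord_features):
            if f.category not in CATEGORIES:
                raise SchemaError(f"uncategorized feature {f.name!r}")

    # -- lookups ------------------------------------------------------------

    @property
    def note_feature_names(self):
        return tuple(f.name for f in self.note_features)

    @property
    def chord_feature_names(self):
        return tuple(f.name for f in self.chord_features)

    @property
    def column_names(self):
        """The 616 performance feature columns in canonical order."""
        return tuple(self.performance_columns)

    def category_of(self, column: str) -> str:
        """Category of a performance feature column."""
        return self.performance_columns[column].category

    def interpretability_of(self, column: str) -> int:
        return self.performance_columns[column].interpretability


@lru_cache(maxsize=1)
def default_schema() -> FeatureSchema:
    """The package-wide frozen schema (validated on first use)."""
    return FeatureSchema.build()
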