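# Feature schema

Frozen enumeration of the feature hierarchy: 46 note features, 168 chord
features (92 aggregated + 76 chord-specific, of which 32 are pedaling), and
616 performance features (202 over all chords + 138 for each of left-hand
chords, right-hand chords and the left-minus-right difference).

The published description of this hierarchy names a subset of features and
prints the counts; this enumeration is a documented reconstruction that
contains every named feature and pads within the stated categories to the
printed counts.  Membership of the 100 "conserved" chord features (those
meaningfully averaged per performance) is likewise a reconstruction: absolute
instants are excluded, within-chord spreads of six core touch features are
retained, and all 32 pedaling features are conserved (they are dropped again
for the per-hand groupings).

Units: ms (milliseconds), steps (8-bit position/velocity units, 0-250),
steps/ms.  Categories: dynamics_attack, articulation, soft_pedal,
sustain_pedal.


## Note features (46)

| feature | category | unit | description |
|---|---|---|---|
| mhv | dynamics_attack | steps | maximum hammer velocity, from the hammer sensor event |
| amax | dynamics_attack | steps | maximum key depression depth reached in the keystroke |
| mhv_amax_ratio | dynamics_attack | - | MHV divided by Amax |
| mhv_amax_lag | dynamics_attack | ms | time of MHV minus time of Amax |
| attack_duration | dynamics_attack | ms | onset to Amax |
| attack_duration_mhv | dynamics_attack | ms | onset to the MHV instant |
| attack_speed | dynamics_attack | steps/ms | Amax over the attack duration (mean key speed) |
| attack_speed_mhv | dynamics_attack | steps/ms | MHV over the duration to the MHV instant |
| percussiveness | dynamics_attack | - | normalized area under the normalized attack trajectory; 0.5 = linear, >0.5 = struck |
| attack_depth_mean | dynamics_attack | steps | mean depression during the attack |
| attack_early_speed | dynamics_attack | steps/ms | mean speed over the first half of the attack |
| attack_late_speed | dynamics_attack | steps/ms | mean speed over the second half of the attack |
| attack_speed_ratio | dynamics_attack | - | early over late attack speed |
| half_depth_time | dynamics_attack | ms | time from onset to half of Amax |
| depression_mean | dynamics_attack | steps | mean depression over the whole note |
| depression_area | dynamics_attack | steps*ms | time integral of depression over the note |
| pitch | dynamics_attack | midi | MIDI note number |
| sustain_duration | articulation | ms | Amax instant to release start (held depressed) |
| release_duration | articulation | ms | release start to return to rest |
| release_speed | articulation | steps/ms | Amax over the release duration |
| note_duration | articulation | ms | onset to offset |
| key_down_duration | articulation | ms | onset to release start |
| attack_fraction | articulation | - | attack duration as a share of the note duration |
| sustain_fraction | articulation | - | sustain duration as a share of the note duration |
| release_fraction | articulation | - | release duration as a share of the note duration |
| onset_time | articulation | ms | absolute onset instant (building block; not conserved) |
| offset_time | articulation | ms | absolute offset instant (building block; not conserved) |
| amax_time_point | articulation | ms | absolute Amax instant (building block; not conserved) |
| mhv_time_point | articulation | ms | absolute MHV instant (building block; not conserved) |
| release_start_time | articulation | ms | absolute release-start instant (building block; not conserved) |
| soft_at_onset | soft_pedal | steps | soft pedal depression at note onset |
| soft_at_amax | soft_pedal | steps | soft pedal depression at the Amax instant |
| soft_at_mhv | soft_pedal | steps | soft pedal depression at the MHV instant |
| soft_at_offset | soft_pedal | steps | soft pedal depression at note offset |
| soft_mean | soft_pedal | steps | mean soft pedal depression during the note |
| soft_max | soft_pedal | steps | maximum soft pedal depression during the note |
| soft_active_fraction | soft_pedal | - | share of note samples with the soft pedal in use (>10% of range) |
| soft_full_fraction | soft_pedal | - | share of note samples with the soft pedal fully depressed (>90%) |
| sust_at_onset | sustain_pedal | steps | sustain pedal depression at note onset |
| sust_at_amax | sustain_pedal | steps | sustain pedal depression at the Amax instant |
| sust_at_mhv | sustain_pedal | steps | sustain pedal depression at the MHV instant |
| sust_at_offset | sustain_pedal | steps | sustain pedal depression at note offset |
| sust_mean | sustain_pedal | steps | mean sustain pedal depression during the note |
| sust_max | sustain_pedal | steps | maximum sustain pedal depression during the note |
| sust_active_fraction | sustain_pedal | - | share of note samples with the sustain pedal in use (>10% of range) |
| sust_full_fraction | sustain_pedal | - | share of note samples with the sustain pedal fully depressed (>90%) |

## Chord features (168)

For every note feature `X`, `X_cmean` and `X_csd` are the mean and SD over the chord's notes (92 features). The 76 chord-specific features:

| feature | category | unit | conserved | description |
|---|---|---|---|---|
| n_notes | articulation | - | no | number of notes in the chord |
| chord_duration | articulation | ms | yes | chord onset to chord offset |
| onset_time | articulation | ms | no | absolute chord onset (building block; not conserved) |
| offset_time | articulation | ms | no | absolute chord offset (building block; not conserved) |
| onset_asynchrony_span | articulation | ms | yes | latest minus earliest note onset |
| onset_asynchrony_rate | articulation | ms | yes | onset span per note interval (span / (n-1)) |
| onset_asynchrony_amount | articulation | ms | yes | mean absolute deviation of note onsets |
| offset_asynchrony_span | articulation | ms | yes | latest minus earliest note offset |
| offset_asynchrony_rate | articulation | ms | no | offset span per note interval |
| offset_asynchrony_amount | articulation | ms | yes | mean absolute deviation of note offsets |
| melody_lead | articulation | ms | yes | mean onset of the other notes minus the first (melody) note's onset |
| melody_mhv_excess | dynamics_attack | steps | yes | first note's MHV minus the mean MHV of the others |
| ioi_next | articulation | ms | yes | inter-onset interval to the next chord |
| ioi_same_hand_next | articulation | ms | yes | inter-onset interval to the next same-hand chord |
| ioi_other_hand_next | articulation | ms | no | inter-onset interval to the next other-hand chord |
| articulation_all | articulation | ms | yes | next chord onset minus this offset (negative = legato) |
| articulation_same_hand | articulation | ms | yes | next same-hand chord onset minus this offset |
| articulation_other_hand | articulation | ms | yes | next other-hand chord onset minus this offset |
| articulation_prev_same_hand | articulation | ms | no | this onset minus the previous same-hand chord's offset |
| overlap_count_all | articulation | - | yes | number of other chords overlapping this chord in time |
| overlap_count_same_hand | articulation | - | yes | overlapping same-hand chords |
| overlap_count_other_hand | articulation | - | yes | overlapping other-hand chords |
| overlap_duration_all | articulation | ms | yes | summed pairwise overlap durations, all chords |
| overlap_duration_same_hand | articulation | ms | yes | summed overlap durations, same-hand chords |
| overlap_duration_other_hand | articulation | ms | yes | summed overlap durations, other-hand chords |
| overlap_amount_all | articulation | steps | yes | mean chord depression over the overlapping span, all chords |
| overlap_amount_same_hand | articulation | steps | yes | mean depression over same-hand overlaps |
| overlap_amount_other_hand | articulation | steps | no | mean depression over other-hand overlaps |
| duty_cycle | articulation | - | no | chord duration over the IOI to the next chord |
| chord_mhv_max | dynamics_attack | steps | no | loudest note's MHV |
| chord_mhv_min | dynamics_attack | steps | no | softest note's MHV |
| chord_mhv_range | dynamics_attack | steps | no | MHV spread within the chord |
| chord_amax_max | dynamics_attack | steps | no | deepest note depression |
| chord_amax_min | dynamics_attack | steps | no | shallowest note depression |
| chord_amax_range | dynamics_attack | steps | no | depression spread within the chord |
| chord_pitch_low | dynamics_attack | midi | no | lowest pitch |
| chord_pitch_high | dynamics_attack | midi | no | highest pitch |
| chord_pitch_span | dynamics_attack | semitones | no | pitch range in semitones |
| onset_pitch_slope | articulation | ms/semitone | no | least-squares slope of onset time on pitch |
| offset_pitch_slope | articulation | ms/semitone | no | least-squares slope of offset time on pitch |
| n_notes_left | articulation | - | no | left-hand notes in the chord |
| n_notes_right | articulation | - | no | right-hand notes in the chord |
| hand_balance | articulation | - | no | right minus left note count |
| overlap_next_duration | articulation | ms | no | overlap duration with the immediately next chord |
| soft_use_duration | soft_pedal | ms | yes | time the soft pedal is in use during the chord |
| soft_full_duration | soft_pedal | ms | yes | time the soft pedal is fully depressed |
| soft_part_duration | soft_pedal | ms | yes | time of part-pedaling (in use but not full) |
| soft_use_fraction | soft_pedal | - | yes | in-use time as a share of the chord duration |
| soft_full_fraction | soft_pedal | - | yes | fully-depressed share of the chord duration |
| soft_part_fraction | soft_pedal | - | yes | part-pedaling share of the chord duration |
| soft_mid_depression | soft_pedal | steps | yes | mean soft pedal depression over part-pedaling samples |
| soft_depression_mean | soft_pedal | steps | yes | mean soft pedal depression during the chord |
| soft_depression_max | soft_pedal | steps | yes | maximum soft pedal depression during the chord |
| soft_depression_min | soft_pedal | steps | yes | minimum soft pedal depression during the chord |
| soft_depression_range | soft_pedal | steps | yes | soft pedal depression range during the chord |
| soft_depression_at_onset | soft_pedal | steps | yes | soft pedal depression at chord onset |
| soft_depression_at_offset | soft_pedal | steps | yes | soft pedal depression at chord offset |
| soft_depression_at_mhv | soft_pedal | steps | yes | soft pedal depression at the chord's MHV instant |
| soft_use_start_re_onset | soft_pedal | ms | yes | first in-use instant relative to chord onset |
| soft_use_end_re_offset | soft_pedal | ms | yes | last in-use instant relative to chord offset |
| sust_use_duration | sustain_pedal | ms | yes | time the sustain pedal is in use during the chord |
| sust_full_duration | sustain_pedal | ms | yes | time the sustain pedal is fully depressed |
| sust_part_duration | sustain_pedal | ms | yes | time of part-pedaling (in use but not full) |
| sust_use_fraction | sustain_pedal | - | yes | in-use time as a share of the chord duration |
| sust_full_fraction | sustain_pedal | - | yes | fully-depressed share of the chord duration |
| sust_part_fraction | sustain_pedal | - | yes | part-pedaling share of the chord duration |
| sust_mid_depression | sustain_pedal | steps | yes | mean sustain pedal depression over part-pedaling samples |
| sust_depression_mean | sustain_pedal | steps | yes | mean sustain pedal depression during the chord |
| sust_depression_max | sustain_pedal | steps | yes | maximum sustain pedal depression during the chord |
| sust_depression_min | sustain_pedal | steps | yes | minimum sustain pedal depression during the chord |
| sust_depression_range | sustain_pedal | steps | yes | sustain pedal depression range during the chord |
| sust_depression_at_onset | sustain_pedal | steps | yes | sustain pedal depression at chord onset |
| sust_depression_at_offset | sustain_pedal | steps | yes | sustain pedal depression at chord offset |
| sust_depression_at_mhv | sustain_pedal | steps | yes | sustain pedal depression at the chord's MHV instant |
| sust_use_start_re_onset | sustain_pedal | ms | yes | first in-use instant relative to chord onset |
| sust_use_end_re_offset | sustain_pedal | ms | yes | last in-use instant relative to chord offset |

## Conserved chord features (100)

Aggregated note features conserved at the performance level (47): all `X_cmean` except the five absolute instants, plus `X_csd` for mhv, amax, attack_duration, attack_speed, percussiveness and release_duration; the conserved chord-specific features are marked above.


## Performance features (616)

For each grouping (`all`, `left`, `right`, `hand_diff`) and each conserved
chord feature `Y`, the columns `<grouping>.Y_pmean` and `<grouping>.Y_psd`
are the mean and SD over the grouping's chords, plus `<grouping>.n_chords`
and `<grouping>.n_notes_total`.  Three dispersion columns are coefficients
of variation (`_pcv`, the SD as a ratio of the mean): the "variations in"
hammer velocity, attack duration and key depression depth.  The per-hand
groupings exclude the 32 chord-level pedaling features (138 columns each);
`hand_diff` is the feature-wise left minus right difference.

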