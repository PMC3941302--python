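# Methods

## The problem

Expert pianists produce timbral nuances (bright, dark, dry, round, velvety)
through fine-grained control of touch, articulation, dynamics and pedaling.
Given continuous high-resolution performance data — per-key position traces
(8-bit steps 0–250 at 500 Hz), per-note maximum hammer velocities (MHV) and
pedal position traces — the question is which quantitative performance
features are *idiosyncratic*: consistent within a pianist across repeated
performances, and different between pianists, both overall and within each
timbral nuance.

The pipeline has five stages: (1) synthetic study generation, (2) keystroke
segmentation, (3) a frozen 616-feature hierarchy, (4) a repeated-measures
ANOVA selection gate, (5) reduced PCA performance spaces and clustered
Kiviat portraits.

## Synthetic study generation

No public corpus of continuous reproducing-piano recordings of this design
exists, so the generator produces recordings with the statistical structure
the analysis assumes.  The study design is fully crossed: 4 pianists x 4
pieces x 5 timbres x 3 repetitions = 240 recordings by default.  Scores are
programmatic two-hand chord sequences (4–16 chords, 1–4 notes each, nominal
duration 12–15 s), not transcriptions of any existing piece.

A keystroke is a power-law attack `D * (t/T_attack)^gamma`, a hold at depth
`D`, and a linear release, sampled at 500 Hz and quantized to integer steps.
The attack family was fixed to power laws because the single exponent maps
analytically onto the percussiveness statistic: the normalized area under
the normalized attack is exactly `1/(gamma+1)`, giving closed-form oracles
(0.5 for a linear attack; `gamma < 1` is concave/struck, `gamma > 1`
convex/pressed).

MHV is deterministically coupled to the realized mean attack speed:
`MHV = round(min(250, K * D / T_attack))` with `K = 25` steps per (step/ms).
The generator works backwards from a per-note MHV target to the attack
duration, so hammer velocity and mean attack speed are strongly correlated
but remain distinct observables, as they are on a real action.  Hammer
events are emitted at 90 % of the attack duration, inside the 20 ms
association slack the segmenter allows after key bottoming.

A `PianistProfile` parameterizes the idiosyncrasies: mean MHV and its
between-chord coefficient of variation, mean key depression depth and its
CV, attack convexity, articulation offset (the signed gap to the next
same-hand chord; negative = legato overlap), tempo scale, melody lead,
right-hand MHV bonus, pedal policies (use probability and depth per pedal),
release duration and timing jitter.  Default profiles give four pianists
contrasting, plausible combinations (a quiet legato player with long melody
leads; a percussive staccato player at slow tempo; a loud deep steady player
who never touches the soft pedal; a shallow-touch heavy-pedaling player with
strong right-hand emphasis).  Timbre modulations shift profile parameters
per timbre (e.g. brighter = louder and more detached, with more percussive
attacks), and an interaction table adds pianist-specific shifts in
particular timbres — the structure the pianist-by-timbre interaction gate is
meant to detect.  Repetition noise is additive Gaussian on profile
parameters, truncated to their valid ranges, with one seeded stream per
recording; the defaults (e.g. 4 steps on MHV, 8 ms on articulation) are free
parameters of the generator, chosen to be small relative to the
between-pianist contrasts, not estimates of any real pianist's consistency.

What the generator does *not* emulate: realistic action mechanics (escapement,
key-bed bounce), structure-driven expressive timing (phrase arcs, accents),
voicing within chords beyond a constant melody lead, pedal timing
synchronized to harmony, or measurement noise on the position sensors (the
rest floor is exactly 0).  Passing tests therefore demonstrate that the
analysis machinery recovers planted structure of the assumed form — not that
it would behave identically on recordings of human pianists.

## Segmentation

A keystroke is an excursion of a key trace above a rest threshold (default 5
steps) reaching at least 20 steps.  Landmarks: onset is the last at-rest
sample before the excursion — preferring the quantized rest floor 0, which
preserves the near-zero head of convex (pressed) attacks that sits below the
position resolution; Amax time is the first sample attaining the maximum;
release start is the last sample within 5 steps of Amax; offset is the first
sample back at rest.  All landmarks are quantized to the 2 ms grid, so
durations carry a bias of up to one sample per landmark.  Hammer events join
the note of the same pitch whose attack window (plus 20 ms slack) contains
them.  Chord grouping is score-guided: a global time scale aligns performed
onsets to nominal ones, and notes match score chords by pitch within a
window of one quarter of the local nominal inter-onset interval; unmatched
notes become singleton "extra" chords and unmatched score chords are
reported missing.  The thresholds are declared defaults, configurable and
logged — continuous-recording systems do not publish theirs.

## Feature hierarchy

Frozen in `pianism.schema` and documented feature-by-feature in
`docs/feature_schema.md`: 46 note features, 168 chord features (the
chord-wise mean and SD of each note feature, plus 76 chord-specific of which
32 describe the pedals), and 616 performance features (mean and dispersion
over chords of the 100 conserved chord features plus counts, over four chord
groupings: all / left hand / right hand / left-minus-right).  Notable
definitional choices:

* **percussiveness** = normalized area under the normalized attack
  trajectory: 0.5 for a linear attack.  The quantized-trace estimate is
  within 0.02 of `1/(gamma+1)` for attacks of at least 20 ms up to
  `gamma ≈ 2`; for still more convex attacks the sub-resolution head makes
  any trace-based estimate biased upward.
* **melody lead** = mean onset of a chord's non-first notes minus the first
  note's onset (the aggregation over "the others" is a choice; span and rate
  of asynchrony are recorded separately).
* **articulation** = next same-hand chord onset minus this chord's offset;
  negative = legato.
* **part-pedaling** thresholds: in use above 10 % of range (25 steps), full
  above 90 % (225); mid-depression is the mean over in-use-but-not-full
  samples.  Unused pedals yield exactly 0 for every pedal feature.
* **"variations in"** hammer velocity, attack duration and key depression
  depth are coefficients of variation (SD over chords as a ratio of the
  mean); all other dispersion columns are plain SDs.
* Missing values arise only where a structure is absent (no next chord, no
  hammer event, an empty hand grouping) and propagate as missing, never as 0.

## Statistical gate

For each feature, a balanced repeated-measures ANOVA with the performer as
random factor and timbre, piece and repetition as fixed factors (three-way
overall; two-way per timbre).  Sums of squares come from the orthogonal
decomposition of the balanced cell array; error terms follow classical
expected-mean-squares rules for one random factor: fixed effects (and
fixed-fixed interactions) are tested against their interaction with the
performer, while the performer effect and performer-involving interactions
are tested against the pooled residual (the highest-order interaction, the
design having one observation per cell).  The published analysis named this
design but not its denominator algebra; its fractional denominator degrees
of freedom suggest quasi-F pooling that cannot be reconstructed without the
data, so this explicit construction is documented as the package's choice.

The Huynh–Feldt epsilon is estimated from the covariance of the repetition
levels (using performer x piece x timbre cells as replicates) via the
Greenhouse–Geisser estimate and the standard HF correction, clipped to
`[1/(k-1), 1]`, and applied to the degrees of freedom of every
repetition-involving effect.  Partial eta-squared is
`SS_effect / (SS_effect + SS_error)`; observed power is computed from the
noncentral F at alpha = 0.05 with noncentrality `F * df1`.

A feature passes the gate when the performer effect is significant at 5 %
*and* the repetition effect is not (consistency).  Assumptions are checked
per feature: Lilliefors-corrected Kolmogorov–Smirnov normality per performer
group (one flag per feature, Bonferroni across the groups so the family-wise
false-flag rate stays at alpha) and Levene homoscedasticity across
performers; when a significant performer effect fails either check, a
Kruskal–Wallis rank test across performers confirms or vetoes it.  No
multiple-comparison correction is applied across the 616 features — the
false positives this admits are handled downstream, by the PCA's indifference
to uniformly distributed noise and by the portrait stage's per-cluster
thresholds.  Per-timbre analyses are restricted to features protected by a
significant pianist-by-timbre interaction in the overall ANOVA.  Constant
features and features with missing values are excluded with a log entry.

## Reduced spaces and portraits

Selected features are standardized to Z-scores per feature over the included
performances (population SD; constant columns dropped), then decomposed by
PCA (SVD of the centered matrix, sign fixed so each component's
largest-magnitude loading is positive).  Varimax rotation — iterative
pairwise plane rotations of the Kaiser row-normalized loadings, an ascent on
the variance-of-squared-loadings criterion — is the default for the
three-component overall space and off for two-component per-timbre spaces,
where it tends not to improve interpretability.  Plots average the three
repetitions of each condition and draw per-pianist means with +/-1 SE
ellipses.

For portraits, significant features are partitioned into four categories
(dynamics/attack, articulation, soft pedal, sustain pedal) and clustered
within category by average linkage on `1 - |Pearson r|`, cut at 0.3 (so
features correlated at `|r| >= 0.7` merge; the cut is configurable —
nothing in the published procedure pins it).  `|r|` rather than signed `r`
is used because a sign-flipped duplicate is exactly as redundant as a copy.
One representative per cluster: smallest p, then largest eta-squared, then
largest power, then an interpretability rank frozen in the schema (direct
measures before ratios, means before dispersions), then the name — making
selection invariant to feature order and to duplicated non-selected
features.  A cluster contributes nothing when even its best feature has both
eta-squared < 0.2 and power < 0.2; a feature failing only one threshold
remains eligible (a small but highly powered effect is still informative).
Kiviat charts draw per-pianist Z-score polylines with +/-1.96 SE shading and
annotate raw per-pianist means; portraits with fewer than three features
fall back to a bar chart.

## Numerical and test-scale choices

* Time unit: ms everywhere; sample period 2 ms at 500 Hz.
* Quantization tolerances in tests: one sample per landmark (durations two),
  1 step on depths, 0.02 on percussiveness.
* Degenerate inputs: single-note chords have missing melody lead and
  asynchrony slopes; a grouping with one chord has SD 0; an empty hand
  grouping yields missing entries with zero counts; zero-SD features are
  dropped from Z-scoring with a warning.
* The segmentation one-event-per-keystroke property is exercised on 1,000
  randomized keystrokes; the null calibration of the selection gate uses 20
  replicate design-structured tables of 200 i.i.d. Gaussian features (the
  identical-profiles condition expressed at the feature level), checked
  against the exact binomial 99 % interval around the nominal 5 % rate.
  These problem sizes keep the full suite around two minutes on one CPU
  while leaving the binomial check well-powered.

## Known limitations

* The 46/76/168/100/32/202/138/616 enumeration reproduces printed counts and
  every named feature, but the unnamed remainder and the membership of the
  100 conserved features are reconstructions.
* The mixed-model F construction is one defensible choice among several; it
  does not reproduce quasi-F fractional denominator degrees of freedom.
* Percussiveness (and attack-duration) estimates are biased for strongly
  convex attacks whose onset is hidden below the 8-bit resolution.
* The generator's independence assumptions (i.i.d. repetition noise, no
  piece-by-pianist interaction in the defaults) make the null calibration
  cleaner than human data would be.
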