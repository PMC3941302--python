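# pianism

Quantifying pianists' individuality from continuous key, hammer and pedal
recordings.

Expert pianists color their playing with timbral nuances — *bright*, *dark*,
*dry*, *round*, *velvety* — through fine control of touch, articulation,
dynamics and pedaling.  High-accuracy reproducing-piano systems record the
raw material of that control: per-key position traces in 8-bit steps (0 =
rest, 250 = keybed) sampled at 500 Hz, maximum hammer velocity (MHV) per
keystroke, and continuous pedal positions.  `pianism` is a pipeline for
asking, from such data, **which performance features are idiosyncratic**:
consistent when a pianist repeats a performance, yet different between
pianists — overall, and separately within each timbral nuance.

The pipeline, written for researchers in music performance science and
motor behavior:

1. **Synthetic study generation** (`pianism.synth`) — a generator of
   realistic recordings for a fully crossed design (default: 4 pianists x 4
   pieces x 5 timbres x 3 repetitions = 240 recordings), with per-pianist
   profiles, per-timbre modulations, pianist-by-timbre interactions and
   seeded repetition noise.  Keystrokes are power-law attacks
   `D (t/T)^γ` whose percussiveness is analytically `1/(γ+1)`.
2. **Segmentation** (`pianism.segment`) — keystroke landmarks (onset, Amax,
   release start, offset), hammer-event association, score-guided chord
   grouping with hand assignment.
3. **Feature extraction** (`pianism.features`) — a frozen hierarchy of 46
   note features, 168 chord features and 616 performance features per
   recording (see `docs/feature_schema.md`).
4. **Statistical gate** (`pianism.stats`) — per feature, a repeated-measures
   ANOVA with the performer as *random* factor and timbre, piece and
   repetition fixed; Huynh–Feldt correction for the repetition factor;
   KS/Levene assumption checks with a Kruskal–Wallis fallback; selection
   rule: performer effect significant at 5 % **and** repetition effect not.
   Exposed as a scikit-learn style selector, `IndividualityGate`.
5. **Spaces and portraits** (`pianism.spaces`, `pianism.portraits`) —
   Z-scores, PCA with optional varimax rotation (`VarimaxPCA`), per-pianist
   mean/SE plots; correlation-clustered representative selection under
   effect-size/power thresholds (η² / π ≥ 0.2) and Kiviat radar portraits.

## Worked example

```python
import pianism as pm
from pianism.stats import select_features
from pianism.spaces import ZScaler, VarimaxPCA
from pianism.portraits import build_portrait

pairs = pm.generate_study(pm.StudyDesign(seed=1))
table = pm.build_feature_table(pairs)
print(f"recordings: {len(pairs)}; feature table: {table.shape[0]} x {table.shape[1] - 4}")

selection = select_features(table)
print(f"individuality features: {len(selection.selected)}")

Z = ZScaler().fit_transform(table[selection.selected])
space = VarimaxPCA(n_components=3, rotation="varimax").fit(Z.to_numpy())
vf = space.variance_fraction_
print(f"3 varimax components explain {vf.sum():.1%} ({vf[0]:.1%}, {vf[1]:.1%}, {vf[2]:.1%})")

portrait = build_portrait(table, selection)
print(f"portrait: {len(portrait.features)} representative features")
print(portrait.raw_means["all.mhv_cmean_pmean"].round(1).to_dict())
```

prints

```
recordings: 240; feature table: 240 x 616
individuality features: 344
3 varimax components explain 51.6% (18.0%, 18.2%, 15.4%)
portrait: 57 representative features
{'A': 98.7, 'B': 117.2, 'C': 163.5, 'D': 150.3}
```

Reading the numbers: each of the 240 synthetic performances is summarized by
616 features; 344 of them pass the significance + consistency gate (the
synthetic pianists are deliberately well separated); the first three
varimax-rotated principal components of the Z-scored selected features carry
about half the variance, and the portrait stage compresses the significant
features into one representative per cluster of redundant features.  The
last line is one portrait feature in native units — mean maximum hammer
velocity per pianist (8-bit steps): pianist A plays softest, C loudest,
matching the generating profiles.

The same pipeline runs from a shell:

```sh
pianism simulate --out recs/ --seed 1
pianism extract --in recs/ --out features.csv
pianism select --features features.csv --out selection.json
pianism reduce --features features.csv --selection selection.json --components 3 --plots figs/
pianism portrait --features features.csv --selection selection.json --out portrait.json --fig portrait.svg
```

## Documentation

* `docs/methods.md` — models, statistical machinery, design choices and
  limitations.
* `docs/feature_schema.md` — every feature in the frozen 616-column schema,
  one line each.
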