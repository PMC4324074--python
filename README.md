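# dynemg

Categorized, probabilistic analysis of surface EMG (sEMG) recorded
during dynamic contractions.

Interpreting sEMG amplitude in free, dynamic movements is confounded by
the movement itself: joint angle, contraction type (concentric vs
eccentric), load, speed and posture all modulate the signal, and
subjects differ strongly from one another. `dynemg` is for movement
scientists and biomedical engineers who need to compare muscular
activation across movement conditions — for example brachioradialis
activation during elbow flexion/extension — and want, beyond a
significance verdict, a per-subject measure of *how likely* two
activation distributions are to be indistinguishable.

## Method

Every sample of the MVC-normalized sEMG envelope (band-pass 10–500 Hz,
rectification, 100 ms moving average, normalization to the maximum
voluntary contraction) is categorized by a decision tree into a
combination of variable movement factors: contraction type (from the
sign of the joint angular velocity) × joint-angle interval (12 × 10°
bins over 0–120°, merged to 4 × 30° for comparisons). The categorized
data feed two parallel arms:

* **Deterministic arm** — subject-level category means analyzed with a
  paired t-test (contraction type only), one-way repeated-measures
  ANOVA with Greenhouse–Geisser correction and Bonferroni post-hocs
  (angle only), and a two-way repeated-measures interaction with simple
  main effects (type × angle).
* **Probabilistic arm** — per subject and angle interval, empirical
  frequency distributions of concentric and eccentric amplitudes are
  compared: with d the distance between the two distribution modes, an
  analyzing interval A = midpoint ± 2.5 %MVC is placed between the
  modes, and the overlap probability

      P_con+ecc(A) = P_con(A) · P_ecc(A)

  quantifies the likelihood that the two distributions coincide there
  (1 = indistinguishable, 0 = fully separated). Medians and ranges
  across subjects summarize the group.

A `synthetic` module generates complete studies (triangle-wave
kinematics at 25 °/s, amplitude-modulated Gaussian-carrier sEMG at
2000 Hz, 5 MVC trials/subject) with known ground truth, so the entire
pipeline is testable without any recordings. See `docs/methods.md` for
conventions, parameter choices and limitations.

## Worked example

```sh
cat > config.yaml <<EOF
n_subjects: 3
n_cycles: 10
seed: 42
EOF
dynemg simulate --config config.yaml --out data
dynemg analyze  --config config.yaml --data data --out result.json
dynemg report   --result result.json
```

which prints:

```
Deterministic vs probabilistic comparison (scenario C, merged bins)
   angle bin   F(1,n-1)        p  median overlap              range
    0-30          0.132   0.7511          57.01%    34.69-90.68%
   30-60         81.702   0.0120          63.43%    50.46-71.59%
   60-90         44.485   0.0217          10.90%     8.85-37.26%
   90-120        46.030   0.0210           4.78%     2.45-20.74%
scenario A: paired_t statistic=7.088 p=0.01933
scenario B: one_way_rm_anova statistic=16.353 p=0.002713
```

Reading the table: at 0–30° the eccentric attenuation built into the
synthetic ground truth is absent, so the simple main effect of
contraction type is non-significant (p = 0.75) and the concentric and
eccentric distributions overlap with high probability (median 57 %).
Above 30° the attenuation is active: the simple main effects are
significant and the overlap probability collapses with angle (down to a
median of ~5 % at 90–120°), i.e. the two arms agree, but the
probabilistic arm additionally grades, subject by subject, how likely
the effect is to be absent. `result.json` holds the full record
(config echo, per-subject category means and overlaps, aggregate
medians/ranges, test reports, exclusion log).

The same analysis is available as a library:

```python
from dynemg import GeneratorParams, StudyConfig, analyze_study, generate_study

study = generate_study(GeneratorParams(seed=42))
result = analyze_study(study.trials, StudyConfig())
```

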