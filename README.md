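# retodr

Oxygen-saturation-related **optical density ratios (ODR)** of retinal
vessels from a single color fundus photograph.

Retinal oximetry normally needs a dedicated dual-wavelength camera.  This
package extracts a saturation-related surrogate from ordinary fundus
photography instead: the red plane of an RGB photograph is
oxygen-sensitive and the green plane is oxygen-insensitive, so the ratio
of vessel optical densities in the two planes tracks hemoglobin oxygen
saturation without extra hardware.  For each vessel block (3 centerline
pixels) the optical density in channel *c* is

    OD_c = log10(O_EROI / O_IROI)

with O_IROI the mean intensity inside the vessel and O_EROI the mean over
a one-vessel-diameter background band outside it, and

    ODR = OD_red / OD_green .

ODRs are summarized over vascular subgroups — all vessels, arterioles,
venules, each split into main (mean diameter ≥ 6 px ≈ 76 µm) and micro
vessels — and the global **ODR variability**

    ODR_v = Σ |ODR_n − ODR_{n−1}| / n_pairs

is pooled over adjacent blocks of every vessel.  The resulting 8
per-subject parameters feed a cohort stage (pooled t-tests, per-SD
logistic odds ratios, combined-model ROC C-statistic) for discriminating
groups such as diabetic vs healthy subjects.  Intended users: ophthalmic
imaging researchers who already have vessel masks and artery/vein labels
(e.g. from a neural segmenter) and want functional, not just
morphological, parameters from existing photographs.

Because clinical images cannot ship with the package, it includes a
first-class synthetic module: vessel phantoms with analytically known ODR
(`ODR_true = log t_red / log t_green` for per-channel transmittances) and
feature-level cohort simulation — every pipeline stage is testable against
exact ground truth.

## Worked example

```python
from retodr import pipeline, synthetic

# a noiseless straight vessel, 8 px wide, with per-channel transmittances
# t_red = 0.5 and t_green = 0.25 -> analytic ODR = log(0.5)/log(0.25) = 0.5
spec = synthetic.straight_vessel_spec(width_px=8, t_red=0.5, t_green=0.25)
image, mask, labels, truth = synthetic.render_phantom(spec)

result = pipeline.extract_features(image, mask, labels)
print(truth["analytic_odr"].iloc[0])   # 0.5
print(result.features.as_dict())
print(result.counts)
```

prints

```
0.5
{'odr_all': 0.5, 'odr_a': 0.5, 'odr_v': nan, 'odr_main_a': 0.5,
 'odr_main_v': nan, 'odr_mic_a': nan, 'odr_mic_v': nan, 'odr_var': 0.0}
{'n_segments': 1, 'n_blocks': 29, 'n_valid_blocks': 29, 'n_invalid_blocks': 0}
```

The pipeline found one arterial main-caliber segment, cut it into 29
valid blocks, and recovered the analytic ODR exactly; venous and
micro-vessel subgroups are absent from this phantom, so they are missing
(NaN), never zero.  `odr_var` is 0 because the noiseless phantom has
constant ODR along the vessel.

The same flow is available from the shell:

```
retodr phantom  --outdir case --width 8 --t-red 0.5 --t-green 0.25
retodr extract  --image case/image.png --mask case/mask.png \
                --labels case/labels.png --outdir out
retodr simulate --out cohort.csv --n-per-group 50 --seed 1
retodr cohort   --features cohort.csv --outdir stats
```

`retodr cohort` writes the group-comparison table, the per-parameter
odds-ratio table (per 1 SD), ROC points and a plain-text report.

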