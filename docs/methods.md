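# Methods

## The measurement model

A color fundus photograph carries two usable absorption contrasts for
hemoglobin: the red plane (oxygen-sensitive — oxy- and deoxyhemoglobin
absorb very differently there) and the green plane (oxygen-insensitive —
both species absorb similarly).  For a vessel block, the optical density
in channel *c* is

    OD_c = log10(O_EROI / O_IROI)

where O_IROI is the mean reflected intensity inside the vessel
(intravascular ROI) and O_EROI the mean over the surrounding retinal
background (extravascular ROI).  The per-block optical density ratio

    ODR = OD_red / OD_green

rises with hemoglobin oxygen saturation but is not calibrated SO2: it is a
saturation-*related* ratio.  Because both ODs are log-ratios of local
intensities, the ODR is invariant to the illumination level and to any
common rescaling of a channel — which is what makes it extractable from an
ordinary, uncalibrated photograph.

The global ODR variability pools adjacent-block differences along every
vessel:

    ODR_v = sum |ODR_n − ODR_{n−1}| / n_pairs

Adjacency never crosses a segment boundary, and a pair is skipped if
either member is invalid.  An open question is whether variability should
instead be averaged per segment and then across segments; we pool pairs
with equal weight (pair-count weighting), which keeps the statistic
well-defined for images dominated by few long vessels and makes the
two-segment identity `[0.5,0.7] + [0.9,0.9] -> 0.10` hold exactly.

## Pipeline

1. **Channel separation** — the red and green planes are extracted
   verbatim; no illumination normalization is applied (none is part of the
   measurement model; users with strongly vignetted images should flat-field
   upstream).
2. **Skeletonization** — medial-axis thinning of the binary vessel mask
   (scikit-image), preserving 8-connectivity.  The thinning algorithm is
   isolated behind `graph.skeletonize` so an alternative can be swapped in.
3. **Junction detection** — a 3×3 ones-kernel convolution of the skeleton;
   a skeleton pixel with value ≥ 4 (i.e. ≥ 3 skeleton neighbors) is a
   junction.  Adjacent junction pixels form clusters that are removed
   together.
4. **Segment extraction** — 8-connected components of the junction-free
   skeleton.  Each centerline is ordered by a deterministic walk from the
   lexicographically smallest endpoint (cycles are opened at the smallest
   pixel, with a warning).  Segments shorter than
   `block_length_px × min_blocks_per_segment` (default 3 × 2 = 6 px) are
   discarded and counted: every kept segment then contributes at least one
   adjacent-block pair to ODR_v, which needs n ≥ 2.
5. **Diameter** — per centerline pixel, twice the Euclidean distance
   transform of the mask; the segment mean decides the caliber class:
   **main** if mean diameter ≥ 6 px (≈ 76 µm at the default
   12.69 µm/px), inclusive at the boundary, else **micro**.
6. **Blocks and ROIs** — centerlines are cut into consecutive 3-px blocks
   (trailing remainders discarded, keeping block statistics homogeneous).
   Every vessel pixel is assigned to its nearest block centerline pixel
   (KD-tree; insertion order makes ties deterministic), so block IROIs
   partition the vessel mask.  The EROI is the IROI dilated by a disk of
   radius round(local diameter) — "one vessel diameter outward" — minus
   all vessels dilated by a 1-px guard ring.  The guard ring keeps
   partial-volume edge pixels out of the background estimate; without it
   vessel-edge blur biases O_EROI downward.  EROIs of neighboring blocks
   may overlap; overlap only smooths the background estimate and no
   exclusivity is enforced.
7. **OD/ODR** — arithmetic means over ROI pixels (the standard oximetry
   reduction; the model does not prescribe mean vs median), excluding
   saturated (2^bit_depth − 1) and zero pixels.  Blocks become invalid —
   never zero — with a reason code when an ROI empties, a mean is
   non-positive, or |OD_green| < 1e-3 (vessels without green contrast
   indicate mask leakage).
8. **Subgroups** — segment A/V class is a majority vote of the label map
   over the segment's IROI pixels (ties → unknown, kept in "all vessels"
   but excluded from A/V subgroups).  The seven subgroup ODRs (all, A, V,
   main A, main V, micro A, micro V) are unweighted means over valid
   blocks — a long segment legitimately contributes more blocks — not
   means of per-segment means.

## Cohort statistics

Group comparison uses the two-sided pooled-variance Student's t
(df = n1 + n2 − 2; the groups are size-matched) with a Lilliefors
(Kolmogorov–Smirnov with estimated moments) normality p reported per
group, and a chi-square for the sex contingency when demographics are
present.  Per-parameter logistic regressions model case status on the
z-standardized parameter, so odds ratios are per 1 SD (raw ODR units span
the whole physiological range, making per-unit ORs uninterpretable); Wald
95% CIs, with (quasi-)separation flagged and reported as unbounded.  The
combined model fits all 8 parameters jointly; its C-statistic is the
trapezoidal ROC AUC of the fitted probabilities (identical to the
Mann–Whitney pair count) with a DeLong placement-value 95% CI.  No
multiple-testing correction is applied by default.  Missing features are
deleted listwise per analysis, with counts logged.

## Synthetic data

**Phantoms.** Vessels are constant-width tubes along polylines over a
uniform per-channel background; inside a vessel the channel intensity is
`background_c × transmittance_c`, so the true block OD is −log10 t_c and
the true ODR is `log(t_red)/log(t_green)` exactly — an analytic ground
truth for every pipeline stage.  A uniform tube (no parabolic profile, no
central light reflex by default) is the minimal phantom matching a
bulk-ROI measurement model; an optional central-reflex mode exists for
robustness exploration.  Smooth Gaussian-filtered texture and additive
Gaussian noise (clipped to bit range) are applied after rasterization;
mask and labels come from the rasterization itself and are exact.
Phantoms do not emulate field-dependent illumination, media opacity,
defocus, vessel crossings with continuous trees, or segmentation error —
so passing phantom tests validates the computation, not robustness to
clinical image quality.

**Cohorts.** Feature-level simulation: per-group multivariate Gaussians
over the 8 parameters with the reference marginals (healthy means
0.711/0.713/0.709/0.728/0.717/0.634/0.599 and variability 0.273; diabetic
0.754/0.755/0.754/0.773/0.761/0.672/0.627 and 0.236, with the matching
SDs) and a single exchangeable correlation ρ = 0.5.  Only marginals are
known for the real cohort; exchangeable ρ is a declared approximation, and
0.5 reflects that subgroup ODRs share blocks and so are substantially but
not perfectly correlated.  A consequence worth knowing: with ρ = 0.5 each
parameter still carries independent information, so the combined model's
C-statistic on simulated cohorts (≈ 0.95) is higher than what a real
cohort with strongly redundant subgroup ODRs would give; simulated
C-statistics characterize the statistics code, not clinical
discriminability.

## Numerical choices and degenerate inputs

- Caliber boundary inclusive: exactly 6.0 px is main.
- EROI dilation radius `round(local diameter)`, minimum 1 px.
- Empty masks, zero-vessel phantoms and all-invalid subjects propagate as
  missing values (NaN) with zero counts, never as zeros.
- Zero pooled variance in a t-test is reported as degenerate, not as a
  number; |beta| > 20 or SE > 50 in a logistic fit is flagged as
  separation.
- All tie-breaks (centerline start, walk order, KD-tree assignment,
  segment ordering) are lexicographic or insertion-ordered, making the
  whole extraction bitwise deterministic for fixed inputs.
- Problem sizes in the test and acceptance runs (80–192 px phantoms,
  50 + 50 subject cohorts, 100–500 Monte-Carlo replicates) were chosen as
  the smallest sizes at which the checked identities and Monte-Carlo bands
  are stable.

## Known limitations

- ODR is not calibrated oxygen saturation; no per-diameter correction
  curves or pulsatility analysis are included.
- Vessel segmentation and A/V labeling are *inputs*; the package does not
  reproduce the upstream neural segmenters.  Label errors propagate into
  subgroup assignment (majority voting absorbs only small disagreement).
- No optic-disc or peripapillary exclusion zone is applied; no
  field-of-view check is possible from a raster alone.
- JPEG inputs are accepted with a warning; lossy compression perturbs ODR.
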