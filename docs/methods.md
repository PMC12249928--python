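# Methods

This note records what each pbmquant stage computes, the assumptions and
defaults behind it, what the synthetic generators do and do not emulate,
and the numerical choices a maintainer would otherwise have to
reverse-engineer from the code.

## Trajectory motility statistics

**Estimators.** For one track of N uniformly sampled positions (spacing
δt, minutes), the per-lag statistics average every overlapping
displacement pair: at lag i there are exactly N−i start points, and

    MSD(i) = 1/(N−i) Σ_j ‖r_{j+i} − r_j‖²,   MAD(i) = 1/(N−i) Σ_j ‖r_{j+i} − r_j‖.

Overlapping windows use all the data but make neighbouring lags
correlated; the pair counts (N−i) are carried in `LagStatistics` so a
weighted fit could be added later. Jensen's inequality guarantees
MSD(i) ≥ MAD(i)² at every lag, which the tests assert.

**Regressions.** `fit_motility` runs ordinary least squares of MSD
(resp. MAD) against lag time with a **free intercept**; D = slope/4 (2-D
Einstein relation — the 4 is dimension-specific and deliberately not
generalised) and V = slope. The free intercept absorbs static offsets
(e.g. localisation noise adds a constant to MSD); forcing the fit
through the origin would change D (on the worked 4-point collinear track
it shifts the MSD slope from 4 to 18/7). R² = 1 − SSres/SStot; when the
response is constant (a stationary cell) SStot = 0 and R² is reported as
NaN with a `defined` flag rather than 1 — a flat line is not evidence of
a good linear trend.

**Fit window.** Default lags 1..⌊(N−1)/4⌋ with a minimum of 3 lags
(`FitPolicy`). Long lags average few pairs and have high variance; a
quarter of the available lags is the conventional compromise. The window
is fully configurable, since the lag range behind any published
regression is rarely stated.

**Per-track D is skewed.** For finite tracks the per-track D̂
distribution is right-skewed: its ensemble mean is unbiased (≈0.50
μm²/min for σ=1 μm, δt=1 min Brownian input) while the median sits
~8–12% low. Both are reported; cohort comparisons should use the same
summary on both arms.

**Acquisition emulation.** The generator defaults to δt = 10 min and 37
points per track (a 6 h observation window), the single-cell-tracking
design the pipeline targets; a 12 h window is a parameter change, not a
code change.

## Synthetic trajectory models

* `brownian` — i.i.d. Gaussian steps, std `step_sigma` per axis per
  step; implied D = σ²/(2δt).
* `prw` — per-axis discrete Ornstein–Uhlenbeck velocity,
  v_{k+1} = a v_k + σ_v √(1−a²) η with a = exp(−δt/P), σ_v chosen as
  speed·√(2/π) so the stationary mean speed E|v| equals `speed`
  (Rayleigh). Positions integrate v·δt. This is a generator-side
  modelling choice: the analysis itself assumes no motion model.
* `ballistic` — constant speed, per-track random heading: MAD is exactly
  linear (V recovered to machine precision, R² = 1).
* `stationary` — degenerate control for the R²-undefined path.

Seeding: each generator draws from an independent stream keyed by
(seed, generator-name) via CRC-hashed `SeedSequence` entropy, so adding a
stage to a pipeline never perturbs another stage's data.

## Wound closure

Closure is always `100·(A₀ − A_t)/A₀` against the first timepoint; the
first timepoint is therefore 0 by construction, values may legitimately
exceed neither 100 (area ≥ 0) nor fall below 0 unless the wound enlarged —
negative values are returned as-is and flagged, never clipped.

**Segmentation** (the acquisition papers rarely state theirs): the wound
is the largest connected low-texture region. Local variance (uniform
filter, default 9 px window) maps the cell lawn to high values and the
cell-free gap to low; Otsu's threshold is taken on the *smoothed
log-variance* because the raw lawn-variance distribution is heavy-tailed
and drags the threshold into the lawn mode. Two guards make the result
honest: (1) if the two classes' mean log-variance differs by less than
`min_contrast` (default 1.5, i.e. a variance ratio under ~4.5), the frame
is declared wound-free instead of force-splitting lawn texture; (2) the
variance window smears lawn texture half a window into the gap, eroding
the detected core, so the final mask is dilated by (window−1)/2 px — a
boundary-bias correction matched to the filter, not a tuning knob. On the
generator's default scenes (512², texture amplitude 60, read noise σ=4,
gap fraction ≥ 0.10) recovered areas are within 5% of planted truth;
gaps narrower than the variance window are below the method's resolution
and will be missed — use the mask path there. The mask path (planted or
manually traced masks) bypasses segmentation and reproduces the closure
formula to machine precision; it also serves in vivo photographs where
only traced outlines are trustworthy.

Scratch scenes plant the wound as a centred band whose area is exactly
round(fraction·H·W) pixels (full columns plus one partial edge column),
so planted truth is pixel-exact rather than rounded to a band width.

## Fluorescence morphometrics

**Nuclei.** Otsu threshold on the DNA channel → connected components →
oversized components (> 1.6× the median area) are split by
distance-transform watershed → area gate (20–10 000 px default). A
nucleus is **positive** when its *per-nucleus mean* marker intensity
exceeds a threshold over the population of per-nucleus means — per-pixel
calling would let single hot pixels flip a cell. That threshold is an
exact sample-based Otsu (`_otsu_split`): between-class variance evaluated
at every split of the sorted means, with the threshold placed at the
*midpoint* of the optimal gap. The histogram Otsu puts the cut at the gap's
left edge (empty bins leave its criterion flat across the gap), right
against the negative population, where noise leaks negatives across; the
midpoint rule is robust to that. An absolute threshold override exists
for calibrated data. Blank nuclei channels return a flagged zero result,
not an exception.

**Adhesions.** Puncta are connected components of the white-top-hat-
filtered marker channel (default radius 8 px) above Otsu's threshold
within the cell mask, gated to 0.1–10 μm² when pixel size is known
(3–1000 px otherwise). Per punctum: area, centroid, elongation
(major/minor axis of the second-moment ellipse), mean intensity. Per
cell: mask area and aspect ratio from mask moments, mean/total intensity
per channel. The feature set is declared, planted-truth-testable, and
covers intensity plus morphology generically; it does not claim to match
any particular lab's unpublished feature code.

**Generators.** Nuclei are uniform disks (rejection-sampled to
non-overlap), the marker channel lights a planted subset, puncta are
elongated Gaussian spots of stated axis ratio; ground truth (object
table) is always emitted and acceptance checks read the truth, never
re-derive it from pixels. The scenes emulate counts, fractions and shape
statistics — not point-spread functions, uneven illumination, bleed-
through or clumped colonies; passing tests demonstrate estimator
correctness on resolvable objects, not robustness to every real-world
artefact.

## Expression quantification

2^−ΔΔCt with a single reference gene and fixed efficiency 2. Technical
replicates are averaged at the Ct level before ΔCt (the conventional
order); ΔΔCt is taken against the mean ΔCt of the calibrator condition's
samples, and SEM is computed over biological samples. The calibrator is
a free label: an untreated-control condition for culture experiments or
a day-0 baseline for an in vivo time course. Invariants: calibrator-mean
fold = 1 and reference-gene fold = 1 at zero noise; log₂(fold) ≡ −ΔΔCt.

## Dosimetry

duty = t_on/(t_on+t_off); P_avg = duty·ΣP_λ; E = P_avg·T; Φ = E/A. The
fluence convention is duty-cycle-inclusive (energy actually delivered in
pulsed operation): for the default four-channel device (89.51 mW total,
0.875 duty, 1200 s, 1 cm²) this yields 93.99 J/cm², whereas a
continuous-wave reading would give ≈107.4 J/cm² — back-calculation
against the device's stated session fluence fixes the inclusive
convention. Powers accepted in mW or W; beam area is a free parameter.

## Demo pipeline and problem sizes

`run_demo` simulates both conditions and runs every stage with one seed;
all tables are CSV and the manifest (YAML) echoes the config, so a run
is re-creatable bit-identically (wall-times excluded). Default sizes —
30 tracks × 37 points per cohort, 320² scratch frames at 4 timepoints,
256² fluorescence fields with 60 nuclei and 25 puncta, 3 samples × 3
replicates of qPCR — keep a full demo around a second while leaving every
estimator in its accurate regime (the thinnest demo gap, fraction 0.06
of a 320 px frame, stays wider than the texture window). The acceptance
script uses 512² scenes, 500 Brownian tracks and 100-track oracle
comparisons for the same reason.

## Known limitations

* Trajectories are 2-D only; D = slope/4 is not generalised to 3-D.
* No drift correction, velocity autocorrelation, or Fürth-equation PRW
  fitting; no hypothesis testing anywhere (aggregation is descriptive).
* Segmentation assumes texture contrast between lawn and gap; stained or
  phase-dark gaps need parameter changes or external masks.
* Ct simulation plants condition shifts only; no amplification-efficiency
  or plate effects, and the fold-change math correspondingly fixes
  efficiency at 2.
* Image generators are geometric, not photorealistic (see above).
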