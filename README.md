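# pbmquant

Quantification toolkit for photobiomodulation (low-level red/near-infrared
light) wound-healing experiments. It covers the full measurement chain such
studies rely on, for keratinocyte/fibroblast cultures in vitro and rodent
wounds in vivo:

* **single-cell motility** from time-lapse trajectories — per-lag mean
  squared displacement and mean absolute distance, regression-derived
  diffusion coefficient and velocity;
* **scratch-wound / in vivo closure kinetics** — wound area over time and
  the closed-area percentage;
* **fluorescence morphometrics** — EdU/Ki-67 positive-nucleus fractions
  and focal-adhesion (p-FAK, paxillin) / F-actin intensity and shape
  features;
* **RT-qPCR fold changes** by the 2^−ΔΔCt method with reference-gene
  normalisation;
* **pulsed-LED dosimetry** — duty cycle, average power, session energy
  and fluence for a multi-wavelength source.

Because such studies rarely deposit raw microscopy, every analysis stage
ships with a seeded synthetic-data generator that emits its exact ground
truth, so the whole pipeline is testable for parameter recovery end to end.
It is aimed at cell-biology labs quantifying migration and wound closure,
and at anyone who needs a reproducible, scriptable replacement for
one-off MATLAB/ImageJ measurement code.

## The statistics at the core

For a track of N positions r₁…r_N sampled every δt minutes, the per-lag
curves average over all overlapping pairs i frames apart:

```
MSD(i) = 1/(N−i) · Σ_{j=1}^{N−i} ‖r_{j+i} − r_j‖²        [μm²]
MAD(i) = 1/(N−i) · Σ_{j=1}^{N−i} ‖r_{j+i} − r_j‖          [μm]
```

Ordinary least squares of MSD against lag time Δt = i·δt over a short-lag
window gives the diffusion coefficient via the 2-D Einstein relation,
**D = slope/4** (μm²/min); the same regression on MAD gives the mean
velocity **V = slope** (μm/min). R² close to 1 indicates diffusive-like
spreading (MSD fit) or directionally consistent movement (MAD fit).

Wound closure is the planimetric
`closed % = 100·(A₀ − A_t)/A₀` against the first timepoint; expression
fold changes are `2^−ΔΔCt` with
`ΔCt = Ct(target) − Ct(reference)` and ΔΔCt taken against a calibrator
condition; a pulsed source of channels with powers P_λ delivers fluence
`Φ = duty · ΣP_λ · T / A` with `duty = t_on/(t_on + t_off)`.

## Worked example

Simulate a control cohort and a faster "LED-treated" cohort of persistent
random walkers (30 cells each, one position every 10 min for 6 h), then fit
per-track motility:

```python
import pbmquant as pq

ctrl = pq.simulate_tracks(pq.MotilityModelParams(
    model="prw", speed=0.4, persistence_time=30,
    delta_t=10, n_steps=36, n_tracks=30, seed=0))
led = pq.simulate_tracks(pq.MotilityModelParams(
    model="prw", speed=0.7, persistence_time=30,
    delta_t=10, n_steps=36, n_tracks=30, seed=1))
res = pq.MotilityModel({"control": ctrl, "LED": led}).fit()
print(res.summary())
```

```
Motility regression summary
================================================================
condition       n      D [um^2/min]      V [um/min] R2(MSD) R2(MAD)
control        30       2.085 ± 0.2  0.2409 ± 0.014   0.985   0.982
LED            30      7.175 ± 0.62  0.4402 ± 0.027   0.976   0.967
```

The treated cohort walks ~1.75× faster, which the MAD-slope velocity
reflects directly (0.44 vs 0.24 μm/min; persistent walkers' regression
velocity sits below their instantaneous speed because paths curl between
samples), and the diffusion coefficient — quadratic in speed for a
persistent random walk — rises ~3.4-fold. `res.per_track` holds every
per-cell estimate; `res.by_condition` the aggregates (mean ± SEM).

The device-arithmetic side is one call:

```python
from pbmquant.dosimetry import DEFAULT_DEVICE, DEFAULT_PULSE
print(pq.compute_dose(list(DEFAULT_DEVICE), DEFAULT_PULSE,
                      duration_s=1200, area_cm2=1.0).summary())
```

```
Pulsed LED dose
==============================================
duty cycle        0.8750
average power     78.321 mW
session energy    93.986 J (1200 s)
fluence           93.99 J/cm^2 over 1 cm^2
...
```

i.e. the four-diode device (13.6 + 3.71 + 61.1 + 11.1 mW, 1400 μs on /
200 μs off) delivers 93.99 J/cm² in a 20-minute session over 1 cm².

An end-to-end two-condition demo (simulate → analyse → report, with a
manifest of all outputs) runs from the shell:

```bash
pbmquant demo --seed 1 --out demo_run
pbmquant dose --channel 670:13.6 --channel 780:3.71 \
              --channel 830:61.1 --channel 910:11.1
pbmquant motility --tracks tracks.csv --out results/
```

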