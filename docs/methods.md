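# Methods

## Data model and conventions

A time–activity curve (TAC) is a framed series: decay-corrected
concentration per reconstruction frame, with times in minutes
post-injection. Frame values are treated as frame means reported at the
arithmetic mid-time — the standard convention for framed PET regression.
Two site-realistic schedule templates are provided (a bed-motion protocol
with 0.1-min early frames, and a long-axial-FOV list-mode binning down to
2-s frames); both are harmonized to end at 67 min, a frame extending past
67 min being clipped in time with its value kept.

Concentration units are opaque metadata and are never converted; every
computation requires internally consistent units. The unit string matters
in exactly one place: the AUC-vs-Ca calibration regression has
scale-bound coefficients, so a calibration refuses to apply when its
`units_note` does not match the TAC's unit string.

Window membership is decided on mid-times with closed intervals. The
"terminal single frame" is the window [52, 67] min (the final three 5-min
frames of the harmonized protocol), implemented as a time window so that
arbitrary schedules work.

## Input-function decomposition

`decompose_triexp` implements the method of residuals:

1. OLS of ln Ca on t over the tail window (default [35, 67] min; the
   lower bound is configurable because some protocols use 30 min) gives
   the terminal phase C·e^(−λ3 t).
2. The extrapolate is subtracted from the whole series; positive
   residuals with mid-times in [2, 20] min give B·e^(−λ2 t).
3. A second subtraction isolates A·e^(−λ1 t) between the time of peak
   blood radioactivity and 2 min.

The intermediate and fast windows are not dictated by any protocol; they
were chosen to bracket the visually distinct phases of adult FDG input
functions on the bed-motion schedule and are exposed as parameters.
Numerical choices: residuals below 10⁻⁸ of the curve maximum are treated
as float noise (a purely mono-exponential curve then degrades cleanly to
zero amplitudes with flags rather than fitting debris); a stage with
fewer than three usable residuals likewise degrades with a flag; a fitted
rate ordering violation (λ2 ≤ λ3 or λ1 ≤ λ2 with positive amplitudes) is
an error, since it indicates the windows do not bracket distinct phases.

Validity envelope: terminal-phase recovery to within 2% of truth requires
the intermediate phase to have decayed away by the start of the tail
window — in absolute terms λ2 ≳ λ3 + 0.16 min⁻¹ for B/C up to 1.5 — not
merely a λ2/λ3 ratio above 5. At, say, λ3 = 0.008 and λ2 = 0.12 (ratio
15) the residual intermediate signal at 35–45 min still biases λ3 by
several percent. Physiological adult values (λ2 ≈ 0.15, λ3 ≈ 0.006–0.017)
sit inside the envelope; the property suite samples it explicitly.

First appearance is the mid-time of the first frame exceeding 5% of the
curve maximum; time-to-peak is the mid-time of the maximum frame.

## Plasma integrals

The measured AUC uses the trapezoid over (mid-time, value) samples with a
zero anchor at the appearance time and linear interpolation at window
edges. Because a frame value is the frame mean, the curve is extended
flat from the last mid-time to the last frame end; without this the final
half-frame (2.5 min of the 62–67 min frame, 2–3% of the plasma integral)
would be silently dropped. Model AUCs are closed-form exponential
integrals starting at the appearance time; "recovery" percentages compare
the 1-, 2- and 3-term model AUCs against the measured integral.

θ(52–67) is defined as AUC(0–67) / Ca(52–67), with Ca the unweighted mean
over the late-window frames; the identity θ·Ca = AUC holds exactly by
construction.

## Patlak analysis and the two-point core

The full analysis regresses y = C_T/Ca on x = cumulative AUC / Ca over
frames with mid-time ≥ 12 min (start configurable), unweighted OLS, with
the cumulative integral taken to each frame's mid-time. The two-point
variant — the core shared by all simplified methods — is
Ki = (V_T − V_D) / θ with V_T the late tissue-to-blood ratio.

Two systematic effects deserve explicitness:

* For an irreversible two-tissue model the Patlak ordinate intercept is
  K1·k2/(k2+k3)², **not** K1/k2; with FDG-like rates (k3 ≈ 0.5·k2) the
  fitted intercept is roughly half the free distribution volume. The
  population V_D used to constrain the two-point methods should therefore
  be the cohort's own mean fitted intercept (which is what a site derives
  from its full Patlak fits), and that is what the acceptance pipeline
  does; the shipped calibrations carry the published 0.55 mL g⁻¹.
* θ(52–67) uses the integral to 67 min over the late-window mean
  concentration and therefore overshoots the late frames' own Patlak
  abscissa (mean cumulative AUC to each late mid-time over the late mean)
  by ~6% on the default schedule. The two-point estimators consequently
  run a few percent below the full fit even with perfect inputs. This is
  inherent to the θ convention, matches the scale of published
  simplified-method errors, and is deliberately not "corrected".

White matter reuses the gray-matter population V_D, reproducing the known
low bias of simplified WM estimates.

## Simplified methods and calibration

Methods 1–4 differ only in the θ estimate (see README). Method 1
extrapolates the terminal phase from a configurable default appearance
time of 0.5 min, since single-frame protocols measure none. Site
calibrations are simple one-predictor OLS fits (slope, intercept, r,
two-sided p from the t distribution with n−2 df); the fitted lines pass
through the sample means to machine precision, which is the mechanism
behind the mean-consistency checks in the acceptance suite. The
correlation matrix over {A, λ1, B, λ2, C, λ3, AUC, Ca, θ, age} reports
uncorrected Pearson p-values with significance tiers flagged at 0.05,
0.002, 0.0002 and 10⁻⁵, leaving multiplicity judgements to the reader.

## Synthetic cohorts

The generator draws, per subject: age ~ N(site mean, SD) truncated to
[18, 95]; λ3 from the site age-line plus Gaussian scatter, floored at
0.002 min⁻¹; appearance time ~ N(site mean, SD); amplitudes and fast
rates from lognormal distributions; and region-wise 2TC parameters
(K1, k2, k3) from lognormals with rejection resampling onto Ki ∈
[0.005, 0.06] and K1/k2 ∈ [0.3, 0.8]. Frame values are analytic frame
averages of the model (input: exponential integrals; tissue: closed-form
convolution of each input exponential with the irreversible 2TC kernel
K1/(k2+k3)·[k3 + k2·e^(−(k2+k3)t)]), multiplied by unit-mean lognormal
noise of fixed CV (default 3%). The analysis side still uses mid-times,
deliberately mirroring the frame-average-vs-midpoint mismatch of real
acquisitions.

Population λ3 lines, age distributions and appearance times follow the
published site statistics. Amplitudes and the two fast rates are **not**
published; the defaults (Aarhus A = 75, λ1 = 3.5, B = 5, λ2 = 0.15,
C = 5; Bern with a sharper bolus A = 120, λ1 = 4, B = 7.2) were fixed
once so that cohort-mean terminal-phase AUC recovery lands in the
mid-80s% and θ near 111 min for the Aarhus template — they are
calibration targets of the simulator, not measured facts. For the Bern
template the three published summary values (λ3 0.0094 min⁻¹, recovery
83.6%, θ 100.8 min) are mutually inconsistent with the tri-exponential
model by ~3% (they jointly imply a tail-AUC-to-Ca ratio the model cannot
produce at that λ3); the defaults honour λ3 and the recovery fraction,
letting θ settle at ~103–107 min. 2TC defaults are textbook adult FDG
values giving true Ki = 0.035 (GM) and 0.0143 (WM) mL g⁻¹ min⁻¹.

What the simulator does *not* emulate: arterial dispersion and delay, a
rising bolus limb (the model input appears as a step at t_appear, so
measured trapezoid AUC can slightly exceed the model AUC near the peak),
partial-volume and spill-over effects, NEC-dependent frame noise, blood
volume fraction in tissue (set to 0), and voxel-level heterogeneity.
Passing tests therefore validate the estimator chain and its internal
consistency, not scanner physics.

## Problem sizes and determinism

Acceptance computations use the study-scale cohorts (52 and 24 subjects,
3% frame noise) and run in seconds; every stochastic step is driven by an
explicit integer seed through `numpy.random.default_rng`, and identical
configurations are bit-reproducible.

## Known limitations

* Region-mean TACs stand in for voxelwise-then-averaged analysis
  (differences are second-order for linear estimators).
* No plasma-metabolite or whole-blood/plasma correction (negligible for
  FDG) and no CMRglc conversion (lumped constant and glycemia are out of
  scope).
* The Aarhus AUC-vs-Ca coefficients are bound to the original raw
  concentration scale and cannot be applied to data normalized to a mean
  AUC of 100; the units guard enforces this.
* Simplified WM estimates inherit the GM population V_D and are biased
  low by construction.
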