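# fdgki

Single-time-point quantitation of the cerebral net influx constant of
2-[¹⁸F]fluorodeoxyglucose (FDG), *K*ᵢ, from an image-derived arterial input
function (IDIF), for PET researchers who want absolute quantitation without
arterial blood sampling and — ideally — without a full dynamic recording.

## The problem and the model

Dynamic FDG-PET with a plasma input function yields *K*ᵢ (mL g⁻¹ min⁻¹) by
Patlak–Gjedde linear graphic analysis: for an irreversibly trapped tracer,

```
C_T(t) / Ca(t) = Ki · θ(t) + V_D,        θ(t) = ∫₀ᵗ Ca ds / Ca(t)
```

where `C_T` is the tissue and `Ca` the arterial concentration, θ is the
normalized arterial time (min), and the ordinate intercept `V_D ≈ K1/k2`
(mL g⁻¹) is the distribution volume of free tracer. A descending-aorta
IDIF replaces blood sampling; the IDIF itself is well described by a
tri-exponential after bolus appearance,

```
Ca(t) = A·e^(−λ1 t) + B·e^(−λ2 t) + C·e^(−λ3 t)
```

(bolus mixing, tissue partitioning, renal elimination), decomposed here by
the classical method of residuals (exponential peeling). The package's
point is that the late recording alone nearly determines the plasma
integral: the terminal phase `C·e^(−λ3 t)` carries ~85% of the total
AUC(0–67 min), and AUC and θ(52–67 min) are tightly linked to the terminal
blood concentration Ca(52–67 min), to λ3, and (site-dependently) to age.
Four single-time-point estimators exploit this, each estimating θ and then
computing *K*ᵢ as a two-point Patlak line through a population intercept
(0, V_D) and the late point (θ, V_T):

1. **Method 1** — semi-log fit of the 35–67 min blood curve gives (C, λ3);
   its analytic AUC divided by the population recovery fraction estimates
   the full plasma integral.
2. **Method 2** — site regression AUC(0–67) vs Ca(52–67): a single late
   frame suffices.
3. **Method 3** — site regression θ vs λ3.
4. **Method 4** — site regression θ vs age: no blood kinetics at all.

Shipped calibrations carry the published population coefficients for the
two scanning sites (Aarhus, Bern); `fdgki calibrate` refits all of them
from any cohort. A synthetic-cohort simulator (tri-exponential inputs on
site-realistic frame schedules, irreversible two-tissue-compartment brain
curves with closed-form ground-truth Ki = K1·k3/(k2+k3)) makes the whole
pipeline testable without patient data.

## Worked example

```python
import fdgki as f

sched = f.aarhus_schedule()
p = f.TriExpParams(A=75, B=5, C=5, lambda1=3.5, lambda2=0.15,
                   lambda3=0.0121, t_appear=0.24)
q = f.TwoTCParams(K1=0.10, k2=0.18, k3=0.097, region="GM")
idif = f.simulate_idif(p, sched, noise_cv=0.0, seed=1)
gm = f.simulate_tissue(p, q, sched, noise_cv=0.0, seed=1)

d = f.decompose_triexp(idif)          # method of residuals
m = f.compute_metrics(idif, d)        # AUC, Ca, theta, recoveries
res = f.patlak_full(idif, gm)         # multi-frame reference
```

prints, via the obvious format strings:

```
lambda3 = 0.01226 /min   C = 5.049
AUC(0-67) = 269.1   Ca(52-67) = 2.438   theta = 110.4 min
AUC recovery mono/bi/tri = 85.3 / 96.9 / 100.3 %
full Patlak: Ki = 0.0349 mL/g/min  V_D = 0.270 mL/g  (true Ki 0.0350)
Method 3: theta_est = 111.8 min  Ki = 0.0322  error vs full = -7.7%
```

The terminal phase is recovered within ~1% and carries 85% of the plasma
integral; the full Patlak slope matches the generator's closed-form Ki to
0.3%; and the single-time-point Method 3 lands within 8% of the full
reference using only λ3 and one late frame. (The two-point estimators
carry a small systematic negative offset versus the full fit because
θ(52–67), the ratio of the *whole* integral to the late concentration,
slightly overshoots the late frames' own Patlak abscissa — see
`docs/methods.md`.)

The same pipeline from the shell:

```
fdgki simulate --site aarhus --n 52 --seed 1 --out-dir cohort/
fdgki calibrate --manifest cohort/manifest.csv --out-calibration cal.json
fdgki quantify  --manifest cohort/manifest.csv --calibration cal.json --out results.csv
```

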