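# flunipk

Noncompartmental pharmacokinetics, ELISA calibration statistics, Monte Carlo
residue-data augmentation and regulatory milk-withdrawal-interval estimation
for flunixin and its 5-hydroxy metabolite (5-OH) in dairy goats.

## The problem

Flunixin meglumine is used extra-label in goats, where no approved product —
and hence no label milk-withholding time — exists. Estimating a defensible
milk withdrawal interval from a small depletion study requires a chain of
analyses: plasma pharmacokinetics of the parent drug and metabolite by
noncompartmental analysis (NCA), immunoassay calibration when ELISA is used
alongside UPLC-MS/MS, and the regulatory tolerance-limit calculations on the
milk marker residue (5-OH). This package implements that chain as a tested,
reusable pipeline driven by a synthetic-data generator that emulates a
crossover study design (1.1 mg/kg IV and SC, single dose and q12h × 6), so
every stage can be validated against known ground truth.

It is aimed at veterinary pharmacologists and residue-safety analysts who
want a scriptable, reproducible counterpart to the regulatory point-and-click
tools (EMA's WTM software and FDA-style tolerance-limit calculations).

## The statistics at the core

Milk marker-residue depletion after the last dose is modelled as log-linear:
ln C(t) = a + b·t + ε, ε ~ N(0, σ²), fitted by pooled OLS over animals. The
withdrawal interval is where a one-sided upper tolerance limit on ln C
crosses the operational limit (with a zero tolerance, the assay LOD, 0.4
ng/ml for 5-OH in milk):

    TL(x) = â + b̂·x + s·√d(x)·t′_γ,df(δ),   d(x) = 1/n + (x − t̄)²/Sxx,
    δ = z_p / √d(x)

where t′_γ,df(δ) is the γ-quantile of the noncentral t distribution with
df = n − 2 degrees of freedom. The EMA SCLR method uses p = 0.95, γ = 0.95;
the FDA calculation uses p = 0.99, γ = 0.95 and requires ≥ 10 animals with
triplicate measurements — a contract met by Monte Carlo augmentation
(replicates from the intra-assay CV; virtual animals from per-time-point
means and SDs). Continuous estimates are rounded up to the next milking
(12-h intervals by default).

Upstream, NCA uses the linear-up/log-down trapezoidal rule with
Clast/λz tail extrapolation, best-adjusted-R² terminal-slope selection,
CL = Dose/AUC∞, Vz = CL/λz, MRT = AUMC∞/AUC∞, Vss = CL·MRT (IV),
whole-body extraction ratio E = CL / (60·180·BW⁻⁰·¹⁹), and crossover
bioavailability F = AUC∞(SC)/AUC∞(IV) within animal. ELISA plates are
calibrated with a four-parameter logistic curve; the LOD is the averaged
IC10 and the working range IC15–IC85, dilution-adjusted.

## Worked example

Estimate both regulatory withdrawal intervals from a synthetic 8-doe milk
depletion dataset (initial level 100 ng/ml, depletion half-life 6 h,
ln-scale residual SD 0.15):

```python
import numpy as np, pandas as pd
from flunipk import (AugmentationSpec, build_depletion_dataset, ema_sclr,
                     fda_milk_discard)

rng = np.random.default_rng(42)
times = [2, 4, 6, 8, 12, 18, 24]
rows = [{"animal_id": f"goat-{a:02d}", "time_h": t,
         "conc_ng_ml": float(np.exp(np.log(100) - 0.1155 * t
                                    + rng.normal(0, 0.15)))}
        for a in range(1, 9) for t in times]
dataset = build_depletion_dataset(pd.DataFrame(rows), mrl=0.4)

ema = ema_sclr(dataset)
fda = fda_milk_discard(dataset, AugmentationSpec(seed=0))
print(f"EMA 95/95: continuous {ema.continuous_wdt:.1f} h -> "
      f"rounded {ema.rounded_wdt:.0f} h")
print(f"FDA 99/95: continuous {fda.continuous_wdt:.1f} h -> "
      f"rounded {fda.rounded_wdt:.0f} h "
      f"({fda.diagnostics['n_animals']} animals after augmentation)")
print(f"fitted depletion: slope {ema.fit.slope:.4f} /h, "
      f"half-life {np.log(2)/-ema.fit.slope:.1f} h, s {ema.fit.residual_sd:.3f}")
```

prints

```
EMA 95/95: continuous 51.1 h -> rounded 60 h
FDA 99/95: continuous 51.0 h -> rounded 60 h (10 animals after augmentation)
fitted depletion: slope -0.1150 /h, half-life 6.0 h, s 0.117
```

The fitted slope recovers the simulated depletion rate (−0.1155/h); both
tolerance-limit crossings land above the noise-free mean-line crossing
ln(100/0.4)/0.1155 = 47.8 h because the bound must cover the upper
percentile of the animal population, and each is then rounded up to a whole
milking. The FDA estimate can sit near the EMA one when the extra stringency
of the 99th percentile is offset by the larger augmented n.

The full study replay (simulate → NCA → cohort comparison → withdrawal) is
one call or one command:

```sh
flunipk run --seed 3 --out-dir out/ --method both
```

which writes the cohort CSVs and a JSON report mirroring the PK-parameter
and withdrawal tables of a depletion study.

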