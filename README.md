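# enzkin

Enzyme inhibition kinetics from microplate absorbance time courses.

`enzkin` analyses chromogenic enzyme assays of the kind used to profile
α-amylase inhibitors (flavonoids, acarbose): a 96-well plate is read at
405 nm while the enzyme hydrolyses a chromogenic substrate (e.g. CNPG3 →
2-chloro-nitrophenol), at several substrate concentrations and an
inhibitor dilution ladder. From the raw traces the package extracts
initial velocities, computes percent inhibition and IC50, discriminates
among the five classical Michaelis–Menten inhibition mechanisms, and
attaches jackknife errors to the fitted constants. A seeded
synthetic-plate simulator with known ground truth makes the whole chain
testable end to end.

## The model

The initial velocity in the presence of a reversible inhibitor is

$$v = \frac{V_{max}\,[S]}{K_m\left(1 + \frac{[I]}{K_{ic}}\right) + [S]\left(1 + \frac{[I]}{K_{iu}}\right)}$$

with substrate $[S]$ in mM, inhibitor $[I]$ and the inhibition constants
$K_{ic}$ (competitive, binding free enzyme) and $K_{iu}$ (uncompetitive,
binding the ES complex) in µM. Dropping terms yields the nested family:
no inhibition (2 parameters), competitive / uncompetitive /
noncompetitive ($K_{ic}=K_{iu}=K_i$; 3 parameters each) and mixed
(4 parameters).

Each mechanism is fitted by nonlinear least squares to the *individual*
velocity observations (never condition means), simplest model first,
each fit warm-started from its nested predecessor. Mechanisms are then
discriminated with the extra sum-of-squares F test along every nesting
edge and the corrected Akaike criterion
$AIC_c = N\ln(SSR/N) + 2K + \frac{2K(K+1)}{N-K-1}$,
and the constants of the winning mechanism get leave-one-out jackknife
standard deviations. IC50s come from a two-parameter log-logistic fit of
percent inhibition, with compounds that never reach 50% inhibition
reported as "% inhibition at the highest tested concentration".

## Worked example

Simulate one plate for the reference flavonoid inhibitor B4
(ground truth: competitive, $V_{max}=12$ µmol/min, $K_m=1.2$ mM,
$K_{ic}=132$ µM) and analyse it:

```sh
$ enzkin run --compound B4 --seed 11
compound: B4
IC50: 187 +/- 0.0001733 uM (hill 1)
mechanism: competitive (alpha 0.05)
  Vmax (umol/min): 12 +/- 9e-07
  Km (mM): 1.2 +/- 1.4e-07
  Kic (uM): 132 +/- 1.2e-05
AICc:
            none  ssr 19.55  aicc -30.93  delta 1172.36
     competitive  ssr 8.982e-11  aicc -1203.29  delta 0.00
  noncompetitive  ssr 0.2121  aicc -232.09  delta 971.20
   uncompetitive  ssr 2.035  aicc -130.32  delta 1072.97
           mixed  ssr 8.982e-11  aicc -1200.76  delta 2.54
provenance: seed 11 config 3916125e5a08 version 0.1.0
```

Reading the output: the competitive model has the lowest SSR and the
lowest AICc; mixed matches its SSR but pays the extra-parameter penalty
(ΔAICc 2.54), and the F test finds no significant improvement, so
competitive is selected. The recovered constants match the simulation
ground truth, and the IC50 at 0.5 mM substrate (187 µM) equals the
Cheng–Prusoff value $K_{ic}(1+[S]/K_m) = 132 \times (1+0.5/1.2)$ for a
competitive inhibitor. The tiny ± values are jackknife SDs at the
default read noise (0.002 AU).

The same pipeline runs on measured data from a pair of CSVs
(`enzkin run --plate plate.csv --layout layout.csv`); see
`enzkin --help` for the stage-by-stage subcommands (`simulate`, `rates`,
`dose`, `kinetics`) and `docs/methods.md` for the file formats and every
numerical convention.

Library use mirrors the CLI:

```python
from enzkin.pipeline import RunConfig, run_pipeline
report = run_pipeline(RunConfig(compound="acarbose", seed=11))
print(report.selection.chosen)        # Mechanism.MIXED
print(report.jackknife.sd)
```

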