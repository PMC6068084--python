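# fabthermo

Kinetic and thermodynamic analysis of antibody–antigen binding measured by
surface plasmon resonance (SPR), built for studying how charged-residue
framework mutations change a Fab's affinity for its antigen.

Affinity engineering by charge introduction — for example replacing a set of
light-chain framework-3 serines with arginines or lysines — changes both how
fast a Fab finds its antigen (kon) and how long the complex lives (1/koff).
Telling those mechanisms apart requires the full chain of analysis this
package implements:

1. **1:1 Langmuir sensorgram modelling** — the binding response obeys
   `dR/dt = kon·C·(Rmax − R) − koff·R`, with closed-form association
   (`R(t) = Req·(1 − e^(−kobs·t))`, `kobs = kon·C + koff`,
   `Req = Rmax·C/(C + Kd)`) and dissociation (`R(t) = R0·e^(−koff·t)`)
   phases, plus a numerical ODE oracle.
2. **Global fitting** — one `(kon, koff, Rmax)` triple fitted jointly across
   a blank-subtracted concentration series, with standard errors; `Kd = koff/kon`.
3. **Equilibrium thermodynamics** — `ΔG = RT·ln Kd`, fitted across
   temperature with the nonlinear van't Hoff model
   `ΔG(T) = ΔH − TΔS + ΔCp(T − T₀) − ΔCp·T·ln(T/T₀)` (T₀ = 293.15 K).
4. **Transition-state analysis** — the Eyring relation
   `ln(kon/T) = −ΔH‡/RT + ΔS‡/R + ln(kB/h)` gives the activation enthalpy
   and entropy of association.
5. **Charge bookkeeping** — mutant construction from `S63R`-style specs, and
   Henderson–Hasselbalch net charge / isoelectric point with selectable pKa
   tables.

Because raw sensorgrams for the motivating Fab panel were never deposited,
the package ships a synthetic-data generator whose ground truths are
**thermodynamically self-consistent across temperature**: rate constants are
derived jointly from van't Hoff and Eyring parameters, so the cycle
`RT·ln(koff(T)/kon(T)) = ΔG(T)` closes exactly and every stage of the
pipeline can be validated by parameter recovery.

## Worked example

Reported rate constants for three Fab variants at 25 °C, run through the
fit-bypass reporting mode (no sensorgrams needed):

```python
from fabthermo import run_pipeline, format_report
from fabthermo.reference import KINETICS_25C

config = {
    "reference": "wild-type",
    "report_temperature_K": 298.15,
    "variants": [
        {"name": v, "rates": [{"temperature_K": 298.15,
                               "kon": KINETICS_25C[v]["kon"],
                               "koff": KINETICS_25C[v]["koff"],
                               "kon_se": KINETICS_25C[v]["kon_se"],
                               "koff_se": KINETICS_25C[v]["koff_se"]}]}
        for v in ("wild-type", "R5", "K5")
    ],
}
print(format_report(run_pipeline(config)))
```

prints

```
wild-type:
  Kd = 2.21e-10 M   kon = 2.48e+06 +/- 1e+04 M^-1 s^-1   koff = 0.000549 +/- 1e-06 s^-1
  fold vs reference: kon x1, koff x1
R5:
  Kd = 2.03e-12 M   kon = 7.19e+06 +/- 5e+04 M^-1 s^-1   koff = 1.46e-05 +/- 1e-07 s^-1
  fold vs reference: kon x2.9, koff x0.027
K5:
  Kd = 8.03e-12 M   kon = 5.44e+07 +/- 4e+05 M^-1 s^-1   koff = 0.000437 +/- 1e-06 s^-1
  fold vs reference: kon x22, koff x0.8
```

The two basic five-residue mutants improve affinity by two orders of
magnitude but through different routes: K5 binds 22× faster than the wild
type with an unchanged off-rate, while R5 gains most of its affinity from a
~40× slower dissociation — exactly the kind of mechanistic split the
downstream van't Hoff and Eyring analyses quantify.

A command-line interface mirrors the library
(`fabthermo simulate | fit | thermo | eyring | charge | report`); e.g.

```sh
fabthermo simulate --variant wild-type --noise-sd 1 --seed 7 --out-dir campaign/
fabthermo fit campaign/T298.15_C*.csv --blank campaign/T298.15_blank.csv
```

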