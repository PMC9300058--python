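# goslinggrowth

Growth-curve analysis of barnacle goose (*Branta leucopsis*) goslings
across a latitudinal gradient, for avian ecologists studying postnatal
growth, photoperiod effects and the plasticity-vs-microevolution question
in range-expanding populations.

Barnacle geese traditionally bred only in the Arctic, but over the last
decades established new colonies in the Baltic and along the North Sea.
Cross-sectional biometrics of goslings (each bird measured once, at a
known age) from three such colonies — Barents Sea (68.6°N), Baltic/Gotland
(57.4°N) and North Sea/Netherlands (51.7°N) — let one ask whether Arctic
goslings grow faster, and why.

## The model

Growth follows a fixed-endpoint Gompertz curve,

```
size(t) = A · exp( ln(I/A) · exp(−k·t) )
```

pinned to the hatch size `I` at `t = 0` and the adult asymptote `A`
(both fixed from hatchling and adult measurements), so only the growth
coefficient `k` is estimated.  Because siblings share genes and rearing
conditions, and years differ in phenology, `k` carries Gaussian random
effects for cohort (year) and for nest nested within cohort:

```
size = A · exp( ln(I/A) · exp(−(k + k_i + k_ij)·t) )
```

The package fits this nonlinear mixed model by maximum likelihood with a
Laplace approximation (damped-Newton inner solver exploiting the nested
block structure, quasi-Newton outer optimisation).  Treatment-coded
population offsets on `k` give Wald t tests of between-colony
differences.  The growth clock `t` is either age in days or the
accumulated dawn-to-dusk daylight (civil-twilight solar computation from
colony coordinates) — if day length drives growth, colony differences
should shrink on the daylight axis.

Around the core fit the package provides: a synthetic-data generator
reproducing the three colonies' sampling structure (nest/cohort
clustering, capture-age distributions, instrument rounding), residual
analyses of hatch-date effects with backward AIC selection, across-year
trends, and haldane rates `h = (X2/Sp − X1/Sp)/g` placing population
differences on an evolutionary timescale.

## Worked example

```python
import pandas as pd, goslinggrowth as gg

presets = gg.load_all_presets()
frames = {n: gg.generate_scenario(c, seed=2) for n, c in presets.items()}
spec = presets["barents"].trait("mass_g")
fit = gg.fit_random_gompertz(frames["barents"], "mass_g", "male",
                             spec.adult_A["male"], spec.hatch_I)
print(fit.k, fit.standard_errors["k"])

pooled = pd.concat(frames.values(), ignore_index=True)
_, contrast = gg.fit_population_contrast(
    pooled, "mass_g", "male", spec.adult_A["male"], spec.hatch_I,
    reference="barents")
print(contrast.rows)
```

prints (seed 2):

```
population  sex     k (1/day)   SE        sd_cohort  sd_nest
barents     male    0.0524     0.0023    0.0053     0.0063
...
   pop_a    pop_b  estimate       se         t  df            p
  baltic  barents -0.013104 0.002000 -6.553677 374 1.863757e-10
northsea  barents -0.017067 0.002712 -6.292858 374 8.725183e-10
  baltic northsea  0.003963 0.002371  1.670947 374 9.556865e-02
```

The Arctic colony's male body-mass growth coefficient (~0.052/day here)
exceeds the Baltic's by ~0.013/day and the North Sea's by ~0.017/day,
both highly significant — Arctic goslings gain mass fastest, and the
ordering follows latitude.  The `examples/` scripts walk through each
capability (simulation, growth fits, the daylight axis, hatch-date
effects, haldane rates) with commentary.

A thin CLI mirrors the library:

```
goslinggrowth simulate --preset barents --seed 1 --out barents.csv
goslinggrowth fit --data barents.csv --trait mass_g --sex male -A 2100 -I 65
goslinggrowth daylight --lat 68.583 --lon 52.333 --start 2010-07-10 --end 2010-08-10
goslinggrowth run-all --seed 1 --out report/
```

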