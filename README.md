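# pollenlra

Pollen–vegetation modelling for quantitative land-cover reconstruction:
Extended R-value (ERV) estimation of relative pollen productivities,
REVEALS estimation of regional plant cover, and the validation machinery to
decide whether a set of productivity estimates can be trusted.

## The problem

Pollen assemblages distort the vegetation that produced them: some taxa
produce far more pollen per unit cover than others, and grains disperse
differently depending on their fall speed. Quantitative reconstruction
corrects for both using two linked models.

The **ERV model** relates pollen counts `n_ik` (taxon *i*, site *k*) to
distance-weighted plant abundance `x_ik` around each site:

    E[p_ik] = (α_i·x_ik + ω_i) / Σ_j (α_j·x_jk + ω_j)

where `α_i` is the relative pollen productivity (RPP, with a reference
taxon — here Poaceae — fixed at 1) and `ω_i` background pollen from beyond
the survey. `x_ik` weights vegetation by a Sutton Gaussian-plume deposition
kernel `g(z) = b·γ·z^(γ−1)·exp(−b·z^γ)` with `b ∝ v_g` (the taxon's fall
speed). Fitting is by multinomial maximum likelihood; the distance at which
the log-likelihood–distance curve flattens is the relevant source area of
pollen (RSAP), found by moving-window regression.

The **REVEALS model** inverts the correction at regional scale:

    V̂_i = (n_i/(α_i·K_i)) / Σ_j (n_j/(α_j·K_j)),   K_i = ∫_R^{Zmax} g_i(z) dz

turning pollen counts into cover fractions with delta-method standard
errors. Validation compares the REVEALS estimates (RV) and raw pollen
proportions (PP) against observed regional vegetation (OBV) compiled from
land-cover maps within 75–150 km buffers, using leave-one-out and
subregion-splitting schemes.

Because survey datasets of this kind are rarely public, the package
includes a synthetic landscape generator with a recorded truth — every
stage of the pipeline is testable end to end. See `docs/methods.md` for
the full model description and design choices.

## Worked example

```python
import pandas as pd
from pollenlra import (ScenarioConfig, generate_scenario, fit_erv,
                       PollenSample, reveals_multi)
from pollenlra.validation import pollen_proportions, compare

cfg = ScenarioConfig(seed=1)          # 36 sites, 10 taxa, 1,000 grains/site
sc = generate_scenario(cfg)

fit = fit_erv(sc.data, cutoff=cfg.extent)
print(pd.DataFrame({"true_rpp": sc.truth["rpp"],
                    "fitted": fit.rpp.round(2),
                    "sd": fit.rpp_sd.round(2)}))
```

```
                 true_rpp  fitted    sd
Artemisia            27.0   26.34  2.26
Pinus                12.0   11.80  0.99
Humulus               9.0    8.47  0.76
Castanea              5.0    4.59  0.43
Quercus               2.5    2.33  0.23
Cichorioideae         1.5    1.45  0.14
Poaceae               1.0    1.00  0.00
Caryophyllaceae       0.9    0.91  0.09
Robinia               0.9    0.95  0.10
Ulmus                 0.7    0.62  0.13
```

The fitted RPPs recover the generating values within roughly one standard
deviation each; the reference taxon is pinned at 1 with SD 0 by
construction. Applying REVEALS with the fitted productivities and comparing
against the observed regional vegetation at the 100-km buffer:

```python
samples = [PollenSample(s, sc.data.pollen.loc[s]) for s in sc.data.sites]
rv = reveals_multi(samples, fit.rpp, sc.data.kernels,
                   z_max=cfg.z_max, rpp_sd=fit.rpp_sd)
pp = pollen_proportions(sc.data.pollen)
print(compare(pp, rv, [sc.obvs[100.0]])[["pp", "rv", "rv_se", "obv_100", "fold"]].round(3))
```

```
                    pp     rv  rv_se  obv_100   fold
taxon
Artemisia        0.545  0.134  0.015    0.131  1.025
Pinus            0.179  0.097  0.013    0.097  1.000
Humulus          0.100  0.070  0.013    0.071  1.015
Castanea         0.061  0.083  0.015    0.067  1.228
Quercus          0.020  0.058  0.013    0.051  1.129
Cichorioideae    0.022  0.112  0.019    0.124  1.104
Poaceae          0.038  0.241  0.015    0.256  1.064
Caryophyllaceae  0.018  0.103  0.016    0.108  1.053
Robinia          0.014  0.076  0.014    0.074  1.034
Ulmus            0.003  0.027  0.007    0.021  1.277
```

Raw pollen proportions overstate the high producer *Artemisia* fourfold
(0.545 against a true cover of 0.131) and bury the low producers; the
REVEALS estimates land within a few points of the observed cover for every
taxon (fold ≤ 1.3). Summed over taxa, the RV deviation from truth is 0.067
against 1.053 for PP.

The same pipeline is scriptable from the shell:

```
pollenlra simulate --seed 1 --out data/
pollenlra fit-erv --pollen data/counts.csv --veg data/rings.csv \
    --fsp data/fsp.csv --reference Poaceae --cutoff 1500
pollenlra rsap --pollen data/counts.csv --veg data/rings.csv --fsp data/fsp.csv
pollenlra reveals --counts data/counts.csv --rpp erv_fit.csv --fsp data/fsp.csv
pollenlra validate-loo --pollen data/counts.csv --veg data/rings.csv \
    --fsp data/fsp.csv --out loo_out/
pollenlra compare --counts data/counts.csv --rv reveals_estimate.csv \
    --composition data/composition.csv --buffer-areas data/buffer_areas.csv
pollenlra report --comparison comparison.csv --out figures/
```

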