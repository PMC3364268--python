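# marshpulse

Quantifying the consumer resource subsidy that a managed riverine flood
pulse delivers to an estuarine marsh, measured as the share of resident
nekton standing stock — density (ind m⁻²), dry-weight biomass (g DW m⁻²)
and energy density (cal m⁻²) — on the flooded marsh surface that is
attributable to the pulse rather than to ordinary tidal and meteorological
flooding.

The package is written for estuarine ecologists working with paired
water-level recorders, drop-sampler catch tables, wet/dry weighings and
bomb-calorimetry pellets. A synthetic-data module generates all inputs with
known ground truth, so the full pipeline runs, and can be validated, with
no field data.

## The method

Two marsh areas are compared: an **inflow** area flooded by controlled
river pulses from a diversion structure, and a hydrologically separated
**reference** area flooded only by tides and weather. Drop samples (1 m²)
taken in the inflow area during two pulse windows are classified as
**subsidized** when their flooding cannot be explained by reference
hydrology:

1. the reference marsh was not flooded at the sample time, or
2. the reference marsh was flooded, but the inflow area's daily mean water
   depth exceeded the maximum daily mean depth of flooding observed in the
   reference area over the pulse window.

For each metric *X* ∈ {density, biomass, energy}, the subsidized
proportion per pulse is the ratio of totals
*p* = *X*(subsidized samples) / *X*(all samples). Proportions are averaged
across pulses to *Y* (%) with SE, and applied to the pooled inflow mean
*X̄* to give the scaled subsidy

    Z = X̄ · Y / 100,    Z_err = Z · sqrt((X_err/X̄)² + (Y_err/Y)²)

(quadrature is the default error rule; `product` and `mean-only` are
available). Pooled wet weights convert to dry biomass through per-species
linear wet:dry regressions fitted on individuals, with the intercept
retained only when significantly different from zero (two-sided t-test,
α = 0.05); energy uses per-species mean pellet energy densities
(cal g⁻¹ DW) over bomb-calorimeter replicates.

## Worked example

```sh
python examples/05_full_run.py
```

prints, for the default synthetic configuration at seed 1:

```
 February: inflow flooded 86%, reference 19%
    March: inflow flooded 82%, reference 20%
subsidized samples: 132/146 (90%)

metric       inflow mean (SE)   subsid. % (SE)     subsidy (SE)
density          33.3 (3.5)      96.0 (1.3)      32.0 (3.4)
biomass           1.1 (0.1)      96.8 (1.0)       1.1 (0.1)
energy         6885.2 (754.3)      96.7 (1.0)    6658.3 (732.7)
```

Reading the density row: inflow samples held on average 33.3 resident
nekton per m² of flooded marsh; 96.0% of the total catch sat in samples
whose flooding is attributable to the river pulse; so an estimated
32.0 ± 3.4 ind m⁻² of standing stock is the pulse subsidy available for
trophic transfer when the water recedes. The other examples
(`examples/01…04`) exercise the hydrology, classification, allometry and
energetics steps individually.

A thin CLI wraps the same library:

```sh
marshpulse run-all --seed 1 --out out/
marshpulse classify --water-levels out/water_levels.csv \
    --samples out/samples.csv --pulses pulses.csv
```

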