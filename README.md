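# seafloorbgc

Quantitative tools for subseafloor biogeochemistry: electron-equivalent
bookkeeping of global burial fluxes, porewater reaction-rate inversion,
an affinity-limited reaction–transport model of organic oxidation,
seawater CO2-system speciation, and global seafloor habitability /
redox-zonation mapping — all exercisable on synthetic or user-supplied
data.

## Modules

| module | what it does |
| --- | --- |
| `seafloorbgc.ledger` | Low/high flux ranges propagated endpoint-wise: elemental burial fluxes to electron equivalents, pyrite alkalinity production, O2/H2/e- equivalent conversions, dissolved-acid turnover times. |
| `seafloorbgc.carbonate` | Total-alkalinity + DIC speciation (carbonate/borate/water alkalinity, total pH scale, Weiss/Lueker/Dickson/Millero constants), pCO2, and the pCO2 response to alkalinity increases. |
| `seafloorbgc.rates` | Net consumption-rate profiles from porewater concentration data: Akima-spline fit, analytic spline derivatives, temperature/porosity-corrected diffusivities, Monte-Carlo uncertainty. |
| `seafloorbgc.affinity` | Minimum-affinity diffusion-limited production model: closed-form concentration/rate profiles, e-folding length, finite-difference oracle, energy-per-electron harvestability check. |
| `seafloorbgc.geomap` | Two-layer conductive geotherm to the 122 °C isotherm, spherical-area volume integration, basement pore columns, sedimentation rates, and the thickness/rate redox-zone classifier. |
| `seafloorbgc.synthetic` | Deterministic synthetic porewater profiles (forward diffusion–consumption model + noise) and smooth random global grids, so everything above is testable offline. |
| `seafloorbgc.profiles`, `seafloorbgc.gridio` | Text-based formats: profile CSV, CF-style netCDF (classic), ESRI ASCII grids. |

## Command line

The `seafloorbgc` entry point exposes subcommands; `--help` on each for
details.

```sh
# flux ledger from an organic-C burial range
seafloorbgc ledger --c-low 1.6e13 --c-high 6.5e13

# carbonate-system speciation
seafloorbgc co2sys --alkalinity 2.3e-3 --dic 2.0e-3 --temperature 25

# synthetic profile -> rate inversion with Monte-Carlo uncertainty
seafloorbgc synth-profile --rate0 2e-6 --n-samples 60 --seed 1 --out prof.csv
seafloorbgc invert-rates --profile prof.csv --mc 50 --seed 1 --out rates.csv

# affinity-model depth profiles (analytic + finite-difference)
seafloorbgc affinity-model --p-max 1e-4 --c-a-min 1.0 --diffusivity 0.01

# synthetic global grids -> isotherm depths, volumes, zone areas
seafloorbgc synth-grids --resolution 2 --seed 1 --outdir grids/
seafloorbgc map --heatflow grids/heatflow.nc --thickness grids/thickness.nc --age grids/age.nc
```

## Conventions

- Depths are meters below seafloor, positive down, zero at the
  sediment–water interface.
- Porewater concentrations are per volume of porewater; inversion rates
  are reported in mol (L porewater)^-1 yr^-1.
- Net rates are positive where the dissolved species is consumed.
- Flux ranges are (low, high) pairs propagated endpoint-wise with no
  distributional assumption.
- All randomness flows through explicit `numpy` generators seeded by the
  caller; the same seed gives byte-identical outputs.
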