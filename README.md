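# stormflux

Diagnostics for the impact of intense tropical cyclones on the surface-ocean
carbon cycle, for ocean-biogeochemistry and air–sea-exchange researchers
working with gridded model output. The package covers the full chain from
raw 2-D surface fields to interpretation-ready numbers:

- **Cyclone tracking** — MSLP-minimum candidate detection with 800-km
  masking, greedy space–time stitching (100 km / 24 h, lowest-pressure tie
  break), and strict lifetime/intensity filtering.
- **Carbonate chemistry & CO₂ flux** — F = k_w·S_CO2·(pCO₂ᵒᶜ − pCO₂ᵃᵗᵐ)
  with k_w ∝ u₁₀²·(Sc/660)^(−1/2), Weiss solubility, and surface pCO₂
  solved from DIC and total alkalinity (OMIP-style constants, total scale).
- **Along-track composites** — 200-km circle averages, wake deltas
  (+24 h minus −24 h), along-track time diagrams, fold-increase over a
  non-storm baseline, track-region carbon integrals in TgC, mixed-layer
  depth, N², inertial period.
- **pCO₂ decomposition** — δpCO₂ = γ_SST·pCO₂ʳ·δSST + γ_SSS·pCO₂ʳ·δSSS/SSSʳ
  + γ_DIC·pCO₂ʳ·δDIC/DICʳ + γ_Alk·pCO₂ʳ·δAlk/Alkʳ, with γ_SST = 0.0423 °C⁻¹
  and the analytic Revelle-factor pair γ_DIC + γ_Alk = 1.
- **Budgets** — tracer-tendency closure, Q10 remineralization with a
  fixed-temperature counterfactual, export ratios.
- **Synthetic scenarios** — a seeded generator (Holland vortex over a slab
  mixed layer with entrainment and NPZ-lite biology) that reproduces the
  qualitative TC–ocean response — rightward-shifted 1–2 °C cold wake,
  tens-of-meters mixed-layer deepening, nutrient pulse and delayed bloom,
  outgassing burst followed by cooling-driven uptake — with planted ground
  truth for tracker validation.

See `docs/methods.md` for the model equations, parameter defaults, and
known limitations.

## Worked example

```python
import numpy as np
from stormflux import scenario as sc, tracking as tk, diagnostics as dg

cfg = sc.default_config(seed=1)            # category-4 storm, 18 days, 0.5 deg
res = sc.generate_scenario(cfg)

tracks = tk.track_fields(res.fields)       # detect + stitch + filter
tr = tracks[0]
print(len(tracks), tr.category, round(tr.lifetime_h), round(tr.lmi_ms, 1))

truth = res.truth.tracks                   # planted track, hurricane points
hur = truth[truth.vmax_ms > 33].iloc[::6]
wake = dg.wake_delta(res.fields, "sst", hur)
print(round(float(np.nanmean(wake["delta"])), 2))

t0 = res.fields.times[0]
fold = dg.fold_increase(res.fields, "co2_flux", hur,
                        (t0, t0 + np.timedelta64(47, "h")))
print(round(float(np.nanmax(fold["fold"])), 1))
```

prints

```
1 category 4 192 63.2
-1.28
34.9
```

i.e. the tracker recovers exactly one hurricane (category 4, 192-h
lifetime, 63.2 m s⁻¹ peak wind — the planted storm, no spurious tracks);
the 200-km circle around hurricane-strength track points cools by 1.3 °C on
average between 24 h before and 24 h after passage; and the air–sea CO₂
flux at passage peaks ~35× its calm pre-storm baseline.

A command-line interface wraps the same stages:

```sh
stormflux run --seed 1 --outdir out/         # synthesize → track → diagnose → decompose
stormflux track --in fields.nc --out tracks.csv
```

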