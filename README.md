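# tcbloom

Diagnostics for tropical-cyclone-driven upper-ocean responses: wind-stress-curl
Ekman pumping, relative vorticity of current fields, profile stratification
(buoyancy frequency, thermocline, mixed layer), and box-averaged lagged
time-series metrics (chlorophyll bloom lag and fold increase, SST-cooling
magnitude and persistence). Everything runs on a bundled synthetic-data
generator with known ground truth, so the whole pipeline is testable offline.

## Modules

| module | contents |
| --- | --- |
| `tcbloom.synthetic` | translating Rankine cyclone winds, Gaussian cyclonic eddies (SSH + geostrophic currents), tanh-thermocline T/S profiles, lagged cloud-masked chlorophyll, SST/PAR/precipitation responses |
| `tcbloom.track` | best-track CSV parsing, great-circle translation speed, wind-band intensity classification |
| `tcbloom.wind` | bulk wind stress, spherical wind-stress curl, Ekman pumping velocity |
| `tcbloom.vorticity` | spherical relative vorticity, box-averaged positive-vorticity statistics |
| `tcbloom.profiles` | density (linear EOS / TEOS-10 via `gsw` if installed), buoyancy frequency, thermocline depth, mixed layer depth |
| `tcbloom.boxes` | cos-latitude-weighted box means, gap-aware two-day composites, bloom and cooling metrics |
| `tcbloom.scenario` | end-to-end synthetic scenarios: generate inputs, run the full chain, compare to ground truth |
| `tcbloom.io` | CF-style NetCDF reading/writing (xarray, scipy backend) |

## CLI

```bash
tcbloom simulate --out simdir --seed 3            # write all synthetic inputs
tcbloom track simdir/track.csv --year 2017        # speeds + categories
tcbloom epv --wind simdir/wind.nc --out epv.nc    # wind-stress curl + EPV
tcbloom vorticity --currents simdir/ocean.nc --box 11,14,67,70 --out vort.nc
tcbloom profile --in simdir/profile.txt           # stratification summary JSON
tcbloom boxseries --field simdir/surface.nc --var chl \
    --box 11,14,67,70 --composite 2 --out chl.csv
tcbloom report --seed 1 --out metrics.csv         # full scenario end-to-end
```

`simulate`/`report` accept `--config <yaml>` with flat keys mirroring
`tcbloom.scenario.ScenarioConfig` (grid bounds, track endpoints, vortex/eddy/
stratification/bloom parameters, study box).

## Conventions

- Regular ascending lat/lon grids; missing data are NaN.
- Sphere radius 6371 km; Coriolis f = 2Ω·sinφ with Ω = 7.2921e-5 s⁻¹;
  seawater density 1024 kg·m⁻³.
- Positive Ekman pumping = upwelling (NH); positive vorticity = cyclonic (NH).
- Depth positive down; stable stratification gives N > 0.
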