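# apa-htp

Deterministic SAR-based treatment planning for phased-array microwave
hyperthermia, at desk scale. The package voxelizes a layered cylindrical
phantom, builds (or imports) the stacked matrix of unit-excitation antenna
fields, and shapes the deposited power with an alternating-projections loop
against a two-level intensity mask: a floor `thlow` inside the tumor, a cap
`thup` in the outer healthy tissue, and an unconstrained transition shell in
between. An adaptive threshold search derives `(sigma0, thlow)` for each
candidate `thup` from a Gaussian focal profile, sweeps the candidates, and
picks the operating point at the knee of the (V10%H, V50%H) Pareto front. A
seeded particle-swarm optimizer provides the meta-heuristic benchmark, and a
steady-state Pennes bioheat solver turns SAR maps into temperature fields
with T90/T50/T10 estimators and input-power calibration to a target tumor
temperature.

Full-wave electromagnetic solving is out of scope: a documented analytic
surrogate (spherical spreading, exponential attenuation in an effective
homogeneous medium, dominant vertical polarization with ~10% leakage) stands
in for solver exports, and externally simulated field matrices can be
imported through the HDF5 container.

## Layout

| module | contents |
|---|---|
| `apa_htp.phantom` | voxel grid, tissue table, layered-cylinder voxelization, tumor/transition/healthy partition |
| `apa_htp.fields` | antenna ring, surrogate fields, stacked 3M×N field matrix, superposition, HDF5 container I/O |
| `apa_htp.sar_metrics` | SAR from fields, hotspot-to-target quotient (HTQ), Vχ%H spillover curves |
| `apa_htp.apa` | pseudo-inverse projector, power normalization, mask clipping, the alternating-projections loop |
| `apa_htp.threshold_search` | Gaussian target closed forms, focal intensity bound, candidate sweep, Pareto knee |
| `apa_htp.pso_benchmark` | seeded global-best PSO over amplitudes/phases minimizing HTQ |
| `apa_htp.bioheat` | steady-state Pennes finite-volume solver, Robin boundaries, T90/T50/T10, power calibration |
| `apa_htp.workbench` | reference fixture, run configuration, end-to-end pipeline |
| `apa_htp.cli` | `apa-htp` command-line interface |

## CLI

```sh
apa-htp fields synth --out EN.h5                 # surrogate field container
apa-htp fields import --path EN.h5               # validate an external export
apa-htp optimize sweep --a0 1e4 --out sweep.csv  # threshold sweep + knee
apa-htp optimize apa --thlow 9081 --thup 4200 --out apa.json
apa-htp optimize pso --swarm 100 --seed 1 --out pso.json
apa-htp metrics report                           # HTQ and Vχ curve (baseline feeding)
apa-htp thermal --bc exterior:h=82,text=20 --target-t90 42 --out temps.csv
apa-htp pipeline run --seed 1 --out-dir out/     # full chain with all artifacts
```

Exit codes: 0 success, 2 configuration error, 3 numerical failure.

Phantom configs are TOML (`layers` as ordered `[radius_mm, tissue]` pairs,
tissue table as CSV with header
`name,eps_r,sigma_S_per_m,rho_kg_per_m3,k_W_per_mC,cp_J_per_kgC,omega_ml_per_min_kg`);
see `tests/test_workbench.py::TestCli::test_phantom_build_from_config` for a
worked example.

## Conventions

- Lengths are mm everywhere except inside the bioheat assembly (SI).
- SAR uses the peak-phasor convention (`0.5 σ|E|²/ρ`) unless `rms` is requested.
- Power normalization fixes `‖b‖²/(2 R0) = P0`; `R0` defaults to 50 Ω.
- The HTQ healthy set includes the transition shell; the Vχ%H denominator
  scope is selectable (`healthy_only` vs `healthy_plus_transition`, default
  the latter) and is labeled in every report.
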