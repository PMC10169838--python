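# ternabind

Mass-action modelling of adaptor-antibody **ternary complex** formation.

An engineered effector-cell receptor (`Tc`), a bridging adaptor antibody
(`Ab`) and a target-cell antigen (`Tu`) assemble a three-body complex through
four reversible binding reactions:

```
Tc + Ab    <->  Tc.Ab         (kf1 / kr1)
Ab + Tu    <->  Ab.Tu         (kf2 / kr2)
Tc.Ab + Tu <->  Tc.Ab.Tu      (kf3 / kr3)
Tc + Ab.Tu <->  Tc.Ab.Tu      (kf4 / kr4)
```

The equilibrium ternary-complex concentration as a function of antibody dose
is bell-shaped ("hook"/prozone effect): excess antibody saturates both
receptor pools separately and blocks bridging. The package provides:

- **`ternabind.model`** — domain types (`BindingParameters`, `SystemState`,
  `ExperimentSetup`), the eight mass-action rate expressions, the six-species
  ODE right-hand side, and unit conversions (µg/mL doses and cells x
  sites/cell to nM).
- **`ternabind.equilibrium`** — stiff kinetic integration (`simulate_kinetics`),
  an independent algebraic steady-state solver (`steady_state_solve`),
  equilibrium dose-response curves and hook metrics (peak dose, half-maximum
  dose window, hook detection). The two routes are cross-checked to 1e-6.
- **`ternabind.fitting`** — normalization of observed MFI readouts against
  simulated curves, the SSE objective, and deterministic bounded
  least-squares parameter estimation (literature start, each rate bounded
  within one order of magnitude).
- **`ternabind.scans`** — 1-D log-spaced parameter scans (rates, dissociation
  constants, antigen density; default 30 x 30 = 900 simulations) with global
  normalization and plateau-threshold detection.
- **`ternabind.synthetic`** — seeded synthetic dose-response bundles (4
  antibodies x 2 receptor types, affine MFI map + configurable noise) for
  end-to-end testing without any external data.
- **`ternabind.cli` / `ternabind.io`** — a `ternabind` command-line tool and
  strict CSV/JSON/YAML readers and writers; every run writes a replayable
  manifest with input and artifact hashes.

Bundled literature-derived kinetic configurations for four clinically
relevant antibodies (FMC63/CD19, Rituximab/CD20, Herceptin/HER2,
Cetuximab/EGFR; see `src/ternabind/configs/`) reproduce the reported
behavior: the FMC63/CD19 curve peaks near 0.03 µg/mL (within one order of
magnitude of the experimental 0.25 µg/mL) and collapses by 10 µg/mL, and the
receptor-antibody on-rate scan plateaus near 1e-3 nM⁻¹s⁻¹.

## CLI

```bash
# kinetic time course at one dose
ternabind simulate --pair fmc63_synnotch --dose 0.25 -o out/sim

# equilibrium dose-response + hook metrics
ternabind dose-response --pair fmc63_synnotch -o out/dr

# 900-simulation parameter scan with a PNG heatmap
ternabind scan --pair fmc63_synnotch --name kf1 --low 1e-6 --high 1e-1 \
    --heatmap -o out/scan

# synthetic 8-pair bundle, then bounded SSE fitting against it
ternabind synth --seed 1 -o out/bundle
ternabind fit --observed out/bundle/observed.csv -o out/fit
```

Custom systems use `--params params.yaml --setup setup.yaml` instead of
`--pair` (schemas: keys `kf1..kf4, kr1..kr4` in nM⁻¹s⁻¹ / s⁻¹; setup keys
with explicit units, e.g. `volume_ml`, `antibody_mw_g_per_mol`,
`dose_grid_ug_per_ml`).

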