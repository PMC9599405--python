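# strandflow

Reduced-order, desk-scale modelling of concentration-gradient formation when
two hydrogel blocks (an "AB block system") are extruded from a single printer
cartridge. The package covers:

- **rheology** — Ostwald–de Waele power law `tau = k * gdot**n`: evaluation,
  apparent viscosity, closed-form log–log least-squares fitting of flow-curve
  data restricted to a shear-rate window, and a Metzner–Reed generalized
  Reynolds number for laminar-regime sanity checks.
- **flowfield** — axisymmetric cartridge geometry (barrel + conical
  contraction, needle-gauge outlet presets) and a quasi-steady, mass-conserving
  lubrication velocity field with free-slip (plug) or no-slip (power-law tube
  profile) walls, plus RK4 streamline tracing.
- **simulate** — transient extrusion of a flat A/B interface using a
  Lagrangian interface-marker engine on a flux-uniform radial grid, producing
  the outlet concentration time series `C_A(t)`/`C_B(t)`, outlet cross-section
  snapshots (core–shell segregation under no-slip walls), the mapping of the
  outlet series onto printed-strand arc length, and residual-material
  diagnostics.
- **upwind** — an independent first-order upwind finite-volume advection
  engine used solely to cross-validate the marker engine.
- **metrics** — gradient quantification: transition midpoint, 10–90 % width on
  a monotone (isotonic) envelope, monotonicity, plateau/decline detection, and
  a signed core–shell statistic.
- **fluorescence** — inner-filter forward model `F = alpha*C*exp(-beta*C)`
  mapping labeled-material fraction to measured intensity.
- **synth** — seeded generators for every pipeline input: noisy power-law flow
  curves and replicated strand fluorescence samples at equal spacing.

## Command-line interface

```sh
# fit power-law parameters from a flow-curve CSV (columns shear_rate_per_s,
# shear_stress_Pa or viscosity_Pa_s; '#' comments allowed)
strandflow fit-rheology curve.csv --range 0.1 10 --out params.json

# run the extrusion simulation from a YAML config (mm-denominated keys:
# barrel_radius_mm, barrel_length_mm, cone_length_mm, outlet_radius_mm or
# needle_gauge, piston_speed_mm_s, time_step_s, wall_mode, print_speed_mm_s,
# block_A_mm, block_B_mm)
strandflow simulate --config run.yaml --out outdir/

# map the outlet series onto the printed strand and quantify the gradient
strandflow strand --series outdir/outlet.csv --print-speed 20 --out strand.csv
strandflow metrics --strand strand.csv --out metrics.json

# synthetic data
strandflow synth rheology --seed 42 --out curve.csv
strandflow synth strand --seed 42 --out samples.csv
```

## Notes on the model

The velocity field is a locally fully developed (lubrication) closure rather
than a full momentum solve: the piston drives `Q = v * pi * R_b**2`, the axial
profile is plug (slip) or the standard power-law tube profile (no-slip), and
continuity makes streamlines lines of constant normalized radius. This is
valid in the creeping-flow regime (generalized Reynolds number « 1 at the
default operating point) and reproduces the two mechanisms of interest:
residence-time back-mixing across the cross-section and core–shell
segregation of the first material near no-slip walls. After the piston
reaches the cone entrance, a drain phase models the conical piston sweeping
the contraction (flow rate shrinking with the swept area) so the full fill
volume is extruded; markers overtaken by the piston ride its face and leave
at the very end, which is how the model renders residual first-material at
the walls being extruded last.
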