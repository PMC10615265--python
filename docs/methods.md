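# Methods

This note records the models, parameter choices and numerical decisions
behind `fincount`, in enough detail to re-derive or challenge them.

## 1. Measurement model

The tank is a rectangular water volume, 400 × 240 × 200 mm (x × y × z, z up),
with one vertical strip electrode centered on each of the two 400 mm walls
(y = 0 and y = 240 mm), 20 mm wide by default and spanning the full water
depth. The interleaved pick-up / current-carrying comb pair on each wall is
collapsed into a single equivalent electrode, which is valid as long as
electrode-interface (double-layer) effects are ignored; at the 50 kHz
excitation assumed throughout, that is a reasonable approximation.

The quasi-static potential solves `div(σ grad V) = 0` with one electrode
driven at `v_drive` (1 V default), the other grounded, and zero normal
current on all other boundaries. Measured resistance is `R = v_drive / I`.
The per-voxel impedance sensitivity is `S = (J_PU · J_CC)/I² [1/m⁴]`; in the
collapsed two-electrode approximation the pick-up and current-carrying fields
coincide and `S = |J|²/I² ≥ 0`. Integrating `ρ S` over the volume recovers
`R` (exactly, in the discrete scheme, for full-wall electrodes).

## 2. Discretization

Cell-centered 7-point finite differences on a uniform voxel grid of spacing
`h`. Conductivity is averaged harmonically across cell faces (correct for
series resistances, and it makes embedded high-contrast inclusions behave).
Electrode Dirichlet values enter through half-cell face conductances `2hσ`,
which renders the scheme *exact* for the parallel-plate configuration: with
full-wall electrodes the solver reproduces the closed form
`R = d/(σA) = 0.24/(0.05 · 0.4 · 0.2) = 60 Ω` to machine precision, `S` is
uniformly `1/A² = 156.25 m⁻⁴`, and `Σ ρS h³ = R` exactly. These closed forms,
plus reciprocity (swapping driven and grounded electrodes) and the discrete
power identity `∫σ|∇V|² dV = V·I` (evaluated from face fluxes, where it holds
to solver tolerance), are the correctness oracles in the test suite.

Systems up to 30 000 unknowns are factorized directly (`splu`); larger ones
use Jacobi-preconditioned conjugate gradients (relative tolerance 1e-8)
warm-started with the parallel-plate ramp or with a solution prolongated from
a coarser grid.

**Grid resolution.** Strip-electrode resistance at σ = 0.05 S/m:
246.03 / 231.32 / 224.99 / 222.02 Ω at h = 10 / 5 / 2.5 / 1.25 mm. The
relative change on halving is 2.74 % at 5→2.5 mm and 1.32 % at 2.5→1.25 mm,
so 2.5 mm is the spacing at which halving changes R by < 2 % (the edge
singularity of the strip electrodes makes convergence slow). For sensitivity
*maps and profiles*, whose shape is what matters, 5 mm is ample and is the
CLI default; the synthetic-data surrogate uses 10 mm (see §4).

## 3. Fish model and linearized resistance change

The fish is a homogeneous conductive ellipsoid, full axes 50 × 20 × 10 mm,
σ_fish = 1 S/m (about 20× the 0.05 S/m water), long axis along the heading.

The textbook lead-field linearization
`ΔR = Σ_fish (1/σ_fish − 1/σ_water) S h³` assumes the local field is
undisturbed by the inclusion. At a conductivity contrast of 20 that is badly
wrong — a conductive body concentrates current into itself — and the plain
formula overestimates |ΔR| by roughly a factor 3. `delta_R_linearized`
therefore applies, per voxel, the analytic interior-field factor of an
ellipsoid in a locally uniform field:

    ΔR = − Σ_v S_v h³ (Δσ/σ_w²) Σ_j e_j² / (1 + L_j Δσ/σ_w)

with `L_j` the depolarization factors (from Carlson's R_D integral,
ΣL_j = 1), `e_j` the local unit-current components in the body frame and
`Δσ = σ_fish − σ_w`. Against paired full solves at h = 5 mm this corrected
estimate agrees to ~5 % (tested at 30 %); the plain formula is retained
behind `corrected=False`. ΔR is negative wherever the fish conducts better
than the water, and its magnitude grows toward the electrodes — the physical
basis of both the detector and its distance-dependent misses.

## 4. Synthetic benchmark generator

Per-item seeds derive deterministically from the master seed via
`SeedSequence([seed, index])` and are recorded in the manifest, so benchmarks
regenerate byte-identically.

**Trajectories.** Natural cubic splines through random waypoints, sampled at
20 Hz. *Passes* start and end within 10–40 mm of opposite side walls (so they
satisfy the pass label by construction: crossing between the two 50 mm
side-wall zones); speeds 0.05–0.15 m/s, depths 0.05–0.15 m. Lateral waypoint
positions follow a Beta(½, ½) (arcsine) distribution across the tank width:
small fish in bare tanks are strongly thigmotactic (wall-following), so
crossings concentrate near the long walls — which also carry the electrodes.
*Dwells* stay within 50 mm of one side wall for 12–30 s.

**Impedance rendering.** One fish-free solve at h = 10 mm tabulates the
corrected linearized ΔR over all fish-center positions (the corrected
integrand correlated with the ellipsoid's fractional-occupancy footprint),
clipped to ≤ 0 and interpolated trilinearly along the trajectory — this is
the surrogate that makes 80-stream benchmarks take seconds. The stream is

    re(t) = R_baseline + ΔR(position) + drift + gaussian + spikes
    im(t) = im_baseline + 10⁻³·(ΔR + drift + spikes) + gaussian_im

with a 20 s fish-free warm-up (two buffer lengths) so the detector can leave
its initial state, as it would in a continuous recording.

**Nominal noise.** Gaussian sd 5 mΩ, sinusoidal drift 0.2 Ω over 600 s,
positive 0.15 Ω spikes at 0.05 s⁻¹; reactance noise 5 µΩ around −5 mΩ. These
values satisfy two self-consistency constraints that any "nominal" setting
must meet: (i) the drift's maximum slope 2π·0.2/600 ≈ 2.1 mΩ/s stays below
the 2.5 mΩ/s stability limit, so a fish-free stream is *stable*, and (ii) the
expected range of 200 Gaussian samples (≈ 5.5 sd ≈ 28 mΩ) stays below the
100 mΩ swing limit. They also place the detector's sensitive-to-conservative
transition in the threshold-ratio 3–4 region: the buffer noise amplitude
(max positive deviation of 200 draws ≈ 2.7 sd ≈ 13.5 mΩ, floored at 10 mΩ)
times `2·ratio` gives required dips of ~80–110 mΩ, comparable to the
0.1–0.3 Ω decays of distant passes. A generator self-check asserts (i).

## 5. Detector

States: 0 initial/unstable, 1 stable, 2 noisy (thresholds frozen), 3 fish.
Defaults: buffer 200 samples; swing limits 100 mΩ / 100 µΩ; slope limits
2.5 mΩ/s / 10 µΩ/s; noise floors 10 mΩ / 10 µΩ; threshold ratio 3; stream
gaps > 0.25 s trigger an internal reset. In the fused modes (or/and) the
stability criterion requires *both* channels stable, while the detection
condition fuses by the mode's own logic. Thresholds are computed from the
buffer as a sample arrives (the buffer the detector held before it), are
frozen on entering the noisy or fish state, and thaw only after a stable
buffer re-forms — so a fish's own dip can never raise the threshold against
the next fish.

The vectorized replay precomputes sliding-window medians, amplitudes and
stability flags once per stream (they are independent of mode and ratio) and
runs the identical transition function over them; tests assert exact
event-level equality with the sample-by-sample engine in all four modes.

## 6. Evaluation

A pass-labelled track counts as a true positive if its stream produces at
least one fish-state interval (per-track judging; multi-event passes count
once); a dwell counts as a false positive if any interval occurs. Sensitivity
and specificity follow the standard definitions; undefined ratios are
reported as missing, never as 0 or 1. Sweeps replay identical streams for
every (mode, ratio) cell. Distance stratification uses each track's minimum
distance to the nearer electrode center; spatial maps aggregate joined
resistance values into half-open 10 × 10 mm xy bins (unvisited bins are
empty).

## 7. Triangulation

Two cameras (top and side), each calibrated by four coplanar markers on each
of two parallel reference planes. A pixel maps through the two plane
homographies (DLT from the four correspondences) to two world points, which
define the viewing ray; the 3D position is the midpoint of the shortest
segment between the two cameras' rays, and the segment length is reported as
a residual. Noiseless synthetic projections are recovered to < 1 mm; points
on a reference plane are recovered exactly.

## 8. Known limitations

- The surrogate linearizes around the fish-free field; two fish, or a fish
  touching an electrode, are outside its validity. The slow `full_solve`
  path re-solves the field per sample for cross-checks.
- The collapsed two-electrode approximation ignores double-layer impedance,
  so absolute reactance levels are schematic (the reactance channel is
  rendered as a scaled copy of the resistance physics).
- Strip-electrode resistance converges slowly in `h` (edge singularity);
  absolute R values carry a few percent discretization bias at 5 mm, while
  ΔR and S shapes are much less sensitive.
- Headline scores on the synthetic benchmark are stochastic; the minimum
  sensitivity over the six reported cells sits near 90 % and varies by a few
  points with the master seed.
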