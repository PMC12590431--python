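# Methods

This document describes the reduced-order model, its numerical scheme, the
calibration procedure and the machine-learning pipeline, together with the
assumptions and known limitations. All quantities quoted here are computed by
the code in this repository.

## 1. What the simulator emulates — and what it does not

The simulator is a *reduced-order emulator* of the thermal fate of a single
cylindrical tablet during double-stroke compaction. It is designed to
reproduce tablet-level survival statistics, not local stress or density
fields:

* It **does** capture: press kinematics (stroke durations from punch travel
  and speed, unloads, a fixed 0.2 s turnover gap between pre- and main
  compression), plastic-work heating, die-wall frictional heating, radial
  conduction, heat loss to the tooling, and log-linear thermal inactivation.
* It does **not** perform a return-mapping elasto-plastic solve. The
  Drucker–Prager Cap yield surfaces are implemented as stress-space functions
  (`dpc_surfaces`) for reference and testing only; densification follows a
  calibrated exponential pressure law instead.
* The thermal problem is one-dimensional (radial). Axial gradients are not
  resolved; axial heat loss to the punches is lumped into a volumetric sink
  (see §3). Moisture transport, mechanical (non-thermal) cell damage and
  strain-rate-dependent material behaviour are out of scope.

## 2. Compaction schedule

Relative density follows

```
RD(P) = RD_max − (RD_max − RD_0) · exp(−P / P_c)
```

with fill density `RD_0 = 0.45`, asymptote `RD_max = 0.95` and pressure scale
`P_c = 130 MPa`. For a stroke to target pressure `P*`, the punch moves at the
set speed from height `h0 = h_solid / RD_start` to `h1 = h_solid / RD(P*)`;
the instantaneous pressure along the stroke is read off the densification law
at the current height. The volumetric plastic strain rate is
`dε_v/dt = v / h(t)`. Unloads retract the punch by 5 % of the compact height
with a linearly decaying pressure and zero plastic strain rate (elastic);
sliding against the still-loaded wall continues. A zero-speed input is
clamped to a 1 mm/min floor. Segment samples are taken at step midpoints
(second-order energy deposition), with the final ramp sample pinned to the
target pressure so the peak is exact.

Geometry: 6 mm diameter die, 130 mg tablet, true density 1500 kg/m³.

## 3. Thermal model

Energy balance on radial finite-volume shells:

```
ρ C_p ∂T/∂t = (1/r) ∂/∂r (k r ∂T/∂r) + q_p
q_p = η_pl · P · |dε_v/dt|          (volumetric plastic heating, W/m³)
q_f = μ · K_rad · P · v_slip        (die-wall friction flux, W/m²)
```

Boundary conditions: symmetry at `r = 0`; at `r = R` the friction flux enters
and Robin exchange `h_wall (T − T_tool)` removes heat to the die. Axial
contact with the punches and die face is lumped as a volumetric sink
`2 h_punch (T − T_tool) / H` acting on every shell (the reduced-order
analogue of tooling contact in a full 2-D model). Initial and tooling
temperature: 25 °C.

**Discretisation.** N = 50 shells on a wall-graded mesh
(`faces = R·(1 − (1 − s)²)`) that clusters resolution in the ~0.3 mm
frictional boundary layer; Crank–Nicolson time stepping (second order,
unconditionally stable) with 300 steps per ramp and 80 per unload/gap. The
wall coupling uses a half-cell conduction correction
`c_wall = 1 / (1 + h_wall (R − r_N)/k)` applied to both the Robin term and
the friction flux, keeping the boundary second-order accurate.

**Verification (tested in `tests/test_oracle.py`):**

* an insulated solve conserves energy to machine precision (deposited work
  equals sensible heat);
* a uniform-source insulated solve reproduces the lumped solution
  `ΔT = q_p t / (ρ C_p)` exactly;
* refining to 400 shells, 4× substeps and 4× schedule resolution moves
  survival and peak temperature rise by at most ≈ 0.2 % (contract: 1 %).

## 4. Viability model

Default (`kinetics: "peak"`): each shell's survival is

```
s = s_max · 10^(−max(0, T_peak − T_crit) / z_T)
```

and tablet survival is the shell-volume-weighted mean. This treats the peak
temperature as the damage-determining exposure — appropriate because the hot
transient's duration scales with the stroke time and the z-value absorbs the
duration effect at calibration.

Optional (`kinetics: "integrated"`): first-order D–z kinetics accumulated
over the full temperature history, `D(T) = D_crit · 10^(−(T − T_crit)/z_T)`,
with log-kill = ∫ dt / D(T) above the onset. This mode is provided for
sensitivity studies and is not used by the calibrated defaults.

## 5. Parameters

| parameter | value | units | source / rationale |
|---|---|---|---|
| ρ (compact) | 1200 | kg/m³ | typical excipient compact |
| C_p | 1500 | J/(kg·K) | typical powdered organic solid |
| k | 0.2 | W/(m·K) | typical pharmaceutical compact |
| η_pl | 0.9 | – | Taylor–Quinney-like fraction of plastic work → heat |
| μ (wall friction) | **0.14126** | – | calibrated; typical lubricated-die range |
| K_rad | 0.4 | – | radial/axial stress transmission ratio |
| h_wall | 300 | W/(m²·K) | powder–die lateral contact |
| h_punch | **4707.86** | W/(m²·K) | calibrated; metal contact range 10³–10⁴ |
| T_tool | 25 | °C | ambient tooling |
| RD_0 / RD_max | 0.45 / 0.95 | – | fill and asymptotic relative density |
| P_c | 130 | MPa | Heckel-scale densification pressure, mid-range |
| T_crit | **41.8916** | °C | calibrated inactivation onset |
| z_T | **12.1283** | K | calibrated; dry-heat z for freeze-dried lactobacilli ≈ 10–30 K |
| s_max | 1.0 | – | survival plateau |

Bold values are the four calibration degrees of freedom; everything else is a
fixed engineering default. The shipped values live in
`src/probitab/oracle_params.json`.

**Calibration.** Bounded least squares (`scipy.optimize.least_squares`) on
relative residuals of four anchors: (i) minimum survival 4 % over the
400 MPa, 4000–5000 mm/min, 0–50 MPa-pre window; (ii) +3 pp precompression
benefit at 250 MPa (mean over three high speeds); (iii) +0.2 log₁₀ cycles
from a 133 MPa pre-stroke before 374 MPa at 180 mm/min; (iv) a one-sided
hinge requiring ≥ 99 % survival at a gentle condition (100 mm/min,
20/110 MPa). All four residuals converge to zero; `probitab
calibrate-oracle` reproduces the shipped file deterministically.

## 6. Gaussian-process surrogate

Exact GP regression with the squared-exponential kernel
`k(x,x') = σ² exp(−‖x−x'‖²/(2ℓ²))` (optionally ARD with a per-dimension ℓ)
on unit-cube-normalised inputs and mean-centred survival fractions. The
implementation is from first principles: Cholesky factorisation with jitter
escalation, latent-function predictive standard deviations (observation noise
optionally included), closed-form log marginal likelihood, JSON
serialisation. Correctness is pinned against dense linear-algebra
brute-force solutions, textbook one-point posteriors and prior-reversion
limits in `tests/test_gp.py`.

Hyperparameters (ℓ, σ², σ_n²) are selected by maximising the log marginal
likelihood over a log₁₀ box (ℓ ∈ [10⁻², 10], σ² ∈ [10⁻⁴, 10²],
σ_n² ∈ [10⁻⁸, 1]) with a small Bayesian-optimisation loop: 8 scrambled-Sobol
seed evaluations, then 30 expected-improvement acquisitions with an
over-exploitation escape (fivefold kernel-variance inflation when the
incumbent's posterior std collapses). A multistart L-BFGS-B maximiser
(`tune_hyperparams_mle`) serves as a cross-check. On evidence surfaces this
sharp, the 38-evaluation BO search can land well below the gradient
optimum's LML; the active-learning results are insensitive to which tuner is
used (both were measured, see repository notes).

## 7. Active learning and region extraction

The loop labels a 30-point scrambled-Sobol design, fits the GP, then for 78
iterations draws a fresh 4096-point uniform random pool (rejecting points
with precompression above main pressure), queries the pool point with the
largest posterior standard deviation, labels it with the simulator and
refits (hyperparameters retuned every iteration). Validation uses an
independent 100-point Sobol design; R² and RMSE are logged per iteration.
One global seed is split into validation/pool/tuner streams through fixed
offsets, making every artefact bit-reproducible.

The near-optimal region is extracted by scoring 5000 random candidates with
the fitted surrogate, retaining those within 99 % of the maximum predicted
survival, and wrapping them in a 3-D alpha shape (union of Delaunay
tetrahedra with circumradius ≤ α, computed in normalised coordinates; by
default α is the smallest radius keeping the retained cloud in one connected
component). `α = ∞` reduces to the convex hull, which is verified against
`scipy.spatial.ConvexHull`.

## 8. Laboratory survival arithmetic

Viable counts per tablet follow the serial-dilution convention
`S = NP · VI / (r · VF)` (colonies × initial volume / (cumulative dilution ×
plated volume)); survival rate is `100 · S / S_baseline` with a baseline of
3.9 × 10⁷ CFU per tablet. Replicate plates sharing a sample id are averaged
at the colony-count level. Rates above 100 % are allowed (rehydration
activation).

## 9. Known limitations

* **Surrogate accuracy under max-uncertainty sampling.** Against this
  simulator, max-std acquisition spends ~⅓ of its budget in the sharp
  low-speed boundary layer (speed ≲ 300 mm/min), which an isotropic SE
  kernel cannot resolve together with the smooth bulk; the fitted noise
  inflates and final validation R² settles near 0.91 (median over seeds
  1–5: R² 0.908, RMSE 0.109), although a same-size static Sobol design
  reaches R² ≈ 0.98. See the README's reproduction table.
* The speed response of a single-timescale radial thermal model saturates
  above a few hundred mm/min once the anchors force a multi-second heat
  retention scale; speed sensitivity at 4000–5000 mm/min is therefore
  weaker than in a full thermomechanical FE model.
* The z-value law ignores exposure duration in its default mode; the
  integrated-kinetics mode exists but is uncalibrated.
* No mechanical (pressure-only) kill pathway: survival is monotone in
  temperature exposure only.
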