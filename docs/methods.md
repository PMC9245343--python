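# Methods

## Physical model

A vesicle is modelled as a fixed sphere of radius `R_ves` resting above
a disk microelectrode.  Membrane proteins hold the membrane a gap
`g = 20 nm` off the electrode; electroporation opens a circular pore of
radius `R_p(t)` through the membrane, modelled as a cylindrical channel
of length `L = 5 nm` (the membrane thickness).  Catecholamine diffuses
(no migration, no convection) with `D_in = 6e-11 m²/s` inside the
lumen — about a tenth of the free-solution value, reflecting the
crowded vesicular matrix — and `D_out = 6e-10 m²/s` in the channel and
outside.  The electrode surface oxidizes catecholamine at the
diffusion limit, i.e. a `C = 0` Dirichlet plane; every other boundary
is impermeable.  The initial condition is a uniform lumen
concentration `C_0 = Q/(nF·(4/3)πR_ves³)` with `n = 2` electrons per
molecule, zero elsewhere; `Q` is the measured spike charge, so the
forward and inverse problems are self-consistent in total content.

Assumptions worth stating explicitly:

* **Rigid sphere, fixed geometry.**  The vesicle neither swells nor
  translates as the pore opens.  The justification is geometric: for
  pore/vesicle radius ratios below 1/3 the spherical cap cut off at
  the pore chord is under 0.8 % of the vesicle volume (our closed form
  gives 0.16 % at ratio 0.3), so the material unaccounted for by a
  fixed lumen is negligible.  `geometry.spherical_cap_fraction` and
  `geometry.angular_aperture_deg` expose these bounds.
* **Sealed domain.**  The simulated domain is lumen + pore pocket +
  gap; the bath above the membrane is omitted.  The membrane is
  impermeable and the absorbing electrode spans the entire gap floor,
  so the only path to the bath is the gap rim several micrometres
  away; in practice everything released is oxidized (conservation
  below).  This also makes integrated charge an exact bookkeeping
  check rather than a capture-efficiency measurement.
* **No electrode kinetics.**  +700 mV vs Ag/AgCl is far past the
  catecholamine oxidation wave; a pure Dirichlet condition suffices.
* **Single-phase lumen.**  Dense-core vesicles with two-compartment
  release kinetics are outside the model; the decay-shape classifier
  (`spikes.classify_decay`) exists precisely to filter them out.

## Discretization

Axisymmetric two-point-flux finite volumes on a tensor-product (r, z)
grid.  The radial and near-aperture axial grids grow geometrically
(ratio 1.1) from a 0.25 nm first cell, capped at `R_ves/8`, so the
local cell size stays roughly 10 % of the distance to the pore axis —
the resolution requirement of the access-resistance region.  The gap
and membrane slabs get 4 and 5 uniform cells.  At `R_ves = 150 nm`
this yields ≈ 2 900 active cells.

Three details matter for accuracy:

* **Cut cells.**  Lumen cells straddling the spherical surface keep
  only their volume fraction inside the sphere, and lumen–lumen faces
  the area fraction the sphere section leaves open (pocket cells and
  faces keep the complement below the dome).  Face fractions are
  floored at 5 % so no cell holding material is ever disconnected.
  Without the cut-cell treatment the staircased sphere converges too
  slowly.
* **Continuous aperture.**  The pore radius enters only through face
  transmissibilities: vertical faces of the pore column carry the open
  area fraction of their annulus, radial faces are gated by their edge
  radius.  The rim annulus — the one the pore wall currently cuts — is
  additionally throttled to the access conductance of the open annular
  slit, `T₀·x/(1−x)` with `x` the open fraction and
  `T₀ = 4π D_in r / ln(16 r/Δr)`: access to a disk gains conductance
  `4D·dr` per rim annulus and carries a large share of the total flux
  through its rim, so without the throttle the effective aperture
  radius snaps to the next grid line as soon as any fraction opens.
  Finally the wall position is blurred by half a local cell (3-point
  average of the transmissibilities over `R_p(1 ± (growth−1)/2)`),
  which suppresses the residual grid-alignment sawtooth without
  biasing the mean.  With all three, halving every cell size and the
  time step changes `I(t)` by < 1 % RMS, and static-pore currents
  agree with the lumped resistance model below (an independent
  closed form) to ≈ 5 %.
* **Exact initial mass.**  The discrete lumen volume differs from
  `(4/3)πR_ves³` by the voxelization error, so the initial field is
  scaled to hold exactly `Q/(nF)` moles; integrated simulated charge
  then matches `Q` to 0.1 % once the current has decayed (the residual
  is trapezoid error and lumen/gap holdup).

Time integration is backward Euler with step `ΔT/10 = 10 µs` (the
thin-gap problem is stiff; L-stability beats second-order accuracy
here).  The pore radius is frozen at its midpoint value within each
substep.  The linear systems (~3 k unknowns, M-matrix) are solved by
sparse LU; concentrations are clipped at zero after each solve (the
clip is inactive in practice, backward Euler preserves positivity).

## Quasi-steady reduced model

Pore-scale diffusion times (`r²/D` ≲ µs) are far below the 0.1 ms
sampling interval, so transport through the pore is quasi-steady and
the lumen is well mixed on spike timescales.  The lumped model is a
single ODE, `dN/dt = −(N/V)/R_diff(R_p(t))`, with the series
resistance

    R_diff(r) = 1/(4 D_in r) + L/(π r² D_out) + 1/(4 D_out r)

(lumen-side disk access, cylindrical channel, outer disk access; the
disk access resistance `1/(4Dr)` is the classical result).  Substeps
apply the exact exponential decay factor, so the integrator is
unconditionally stable and exact for a static pore (`τ = V·R_diff`;
at `r = 10 nm`, `R_ves = 150 nm`: `R_diff ≈ 4.85e17 s/m³`,
`τ ≈ 6.9 ms`).  The model serves three roles: an independent oracle
for the PDE (they agree within ≈ 5 % for static pores up to
`0.1·R_ves`, comfortably inside the 15 % contract), a fast forward
backend for the sequential inverse, and — inverted per sample by
bisection with running depletion — a closed-form reconstruction that
cross-checks the sequential fit along a completely different route.

## Sequential inverse

One knot per sampling interval, estimated in order.  The forward
state at `t_{k−1}` is checkpointed once per step; each candidate
radius runs on a copy (cost linear, not quadratic, in spike length).
The scalar search is Nelder–Mead (argument tolerance `10⁻¹¹ m`,
bounds `[10⁻¹¹ m, 0.8·R_ves]`, seed `10⁻¹⁰ m`) with bound handling by
clip-plus-penalty; because the current is monotone in the radius at
fixed state, a bisection fallback refines any step whose residual
stays above 1 % of the target.  Flags per step:

* `unidentifiable` — target below 3× the baseline SD; the previous
  radius is carried forward (a zero spike therefore stays at the
  effectively closed seed radius).
* `clipped` / `saturated-low` — even the fully open pore cannot supply
  the demanded current (typically Q-bookkeeping mismatch at the tail).
* `depleted` — ≥ 95 % of `Q` already released; the objective is flat
  and radii are reported but not trusted.

**Derived features.**  `R_p,max` and `t_expa` are computed from the
samples whose current is at least 20× the baseline SD (one sample's
relative radius precision is ≈ noise/current, so 20:1 resolves the
radius to ~5 %), median-filtered over 5 samples; when the filtered
trajectory has plateaued (second-half median within 10 % of its
maximum) the plateau median replaces the maximum.  Rationale: the raw
maximum over a long noisy plateau is biased upward by extreme-value
statistics, and a 95 % threshold of that maximum is then crossed only
by a noise excursion, making the expansion time meaningless.  For
noise-free input the robust estimates agree with the plain
definitions (`spikes.pore_features`, which is kept exactly at "maximum
radius; time between the 5 % and 95 % crossings").

Closed-loop performance under the study conditions (logistic
trajectories, plateau `0.2·R_ves`, midpoint 1 ms, steepness 0.3 ms;
`R_ves` 75–300 nm): noiseless recovery within 1.6 % everywhere the
released fraction is below 90 %; at 2 % peak-amplitude noise the
derived `R_p,max` is within ~5 % and `t_expa` within ~15 % of truth
across seeds.  No monotonicity constraint is imposed on `R_p(t)`
(an optional post-hoc monotone projection is off by default).

## Synthetic data

The generator emulates the statistical structure of chromaffin-vesicle
VIEC measurements: log-normal `R_ves` (median 150 nm, log-SD 0.35,
spanning ≈ 50–400 nm), log-normal spike charge (median 1 pC ≈ 0.4 M
catecholamine at 150 nm), logistic pore expansion to a plateau
(defaults 30 nm / 1 ms / 0.3 ms over 6 ms at 0.1 ms sampling),
additive Gaussian noise of 2 % of peak (1–5 % is the realistic range),
and group-specific expansion-time distributions (medians 2.08 ms for
vesicles, 0.18 ms for liposomes, log-SDs 0.9 and 0.25 set from the
reported quartile spreads).  Maximum pore radii follow either an
empirical log–log law (slope 3.43, intercept 15.26 in log₁₀-metres,
kept as reference metadata) or the membrane-section model with
constant `p_e·k_d`; section-model populations get 0.02 log₁₀ scatter,
matching the few-percent radius recovery precision of the inverse.
Records violating `R_p,max < R_ves` are rejection-resampled.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: correlated (1/f, line-frequency) noise,
baseline drift and spike-interception errors, dense-core two-phase
release, vesicle deformation beyond the fixed-sphere picture,
uncertainty in `R_ves` from the resistive-pulse sizing, and any
deviation of real pore kinetics from smooth sigmoid expansion.

## Numerical choices and degenerate inputs

* All internal units SI; TSV interchange files are SI; CLI summaries
  print nm/ms/pA/pC.
* Threshold crossings are located by linear interpolation; the spike
  rise time guards against baseline re-crossings by taking the *last*
  5 % upward crossing before the *first* 95 % crossing, while pore
  trajectories (noise-free model output) use first crossings.
* Decay classification fits `log I` by least squares on the falling
  portion (peak to first sample below 5 % of peak, ≥ 5 samples) and
  evaluates R² on the currents themselves, so a missed fast component
  is penalized; default threshold 0.95, configurable, since the
  original classification criterion is not fully specified.
* Mann–Whitney: complete enumeration (tie-aware, two-tailed
  `p = 2·min(P(U≤u), P(U≥u))` capped at 1) for groups of ≤ 8;
  tie-corrected normal approximation otherwise.
* Quartiles/medians use linear interpolation (type-7).
* Degenerate inputs raise `ValueError` with a message naming the
  offending field: non-positive lengths, non-uniform sampling,
  trajectories exceeding `0.8·R_ves`, empty baseline windows,
  zero-variance regressors.

## Problem sizes

The test suite and the acceptance script run the PDE at the default
resolution (~2 900 cells, 10 µs steps) on spikes of 1.5–6 ms, plus one
50 ms conservation run at 25 µs steps; the sequential inverse uses the
quasi-steady backend for the recovery sweeps and the full PDE for one
3 ms dual-route comparison.  These sizes reproduce every claimed
property at desk scale; the full-PDE inverse on a 10 ms spike is
~2 minutes per spike at default resolution.

## Known limitations

* The fixed-sphere aperture neglects the downward translation and cap
  merging of the real deforming vesicle; the volume argument bounds
  the error but no deformed-geometry benchmark exists here.
* The inverse is strictly sequential: depletion-bookkeeping errors
  accumulate forward in time, and the post-depletion plateau is
  unidentifiable by construction.  A joint regularized inversion would
  behave differently; it is deliberately out of scope.
* The quasi-steady resistance model assumes a well-mixed lumen; early
  in a spike from a large, slowly diffusing vesicle the PDE develops
  intralumenal gradients the lumped model cannot represent (visible as
  the few-percent disagreement at large static pores).
* `classify_decay` requires a mostly positive falling phase; heavily
  clipped or negative-going traces return an undefined classification
  rather than a guess.
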