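# poretrace

Reconstruction of membrane pore-opening dynamics of single vesicles
from amperometric current spikes.

## The problem

In vesicle impact electrochemical cytometry (VIEC) a single vesicle —
a chromaffin granule or a liposome, tens to hundreds of nanometres in
radius — adsorbs onto a polarized carbon-fiber microdisk electrode,
electroporates, and releases its catecholamine content through a
membrane pore.  The oxidation current transient (the *spike*) encodes
the pore dynamics: its charge `Q` gives the total content by Faraday's
law, and its shape reflects how the pore radius `R_p(t)` grew with
time.  `poretrace` turns a measured spike, together with the vesicle
radius `R_ves` from a resistive-pulse measurement, into the pore-radius
trajectory and its summary features — the maximum pore radius
`R_p,max` and the 5–95 % pore-expansion time `t_expa`.  It is aimed at
single-entity electrochemists and membrane biophysicists analysing
VIEC recordings, and it ships a synthetic-data generator so the whole
pipeline is testable without instrument data.

## Model and algorithm

**Forward model.** Catecholamine diffuses by Fick's second law in an
axisymmetric domain: a spherical lumen of radius `R_ves` (diffusivity
`D_in = 6e-11 m²/s`), a pore channel of length `L = 5 nm` (the
membrane thickness) and time-dependent radius `R_p(t)`, and a thin gap
(20 nm) between membrane and electrode (`D_out = 6e-10 m²/s` in pore
and gap).  The electrode plane is an absorbing boundary (C = 0,
diffusion-limited oxidation at +700 mV); all other boundaries are
no-flux.  The initial lumen concentration follows from the spike
charge,

    C_0 = Q / (n F · (4/3) π R_ves³),      n = 2, F = 96485 C/mol,

and the current is `I(t) = n F ∬ J·dS` over the pore cross-section.
The solver is a finite-volume discretization on a graded axisymmetric
grid with cut-cell treatment of the spherical lumen; the pore radius
enters through face transmissibilities, so `I` depends continuously on
`R_p` without remeshing.

**Inverse (sequential estimation).** With knots at the 0.1 ms sampling
interval, each `R_p,k` is found by one-dimensional Nelder–Mead search
(search zone `10⁻¹¹ m … 0.8·R_ves`, argument tolerance `10⁻¹¹ m`,
seed radius `R_p,0 = 10⁻¹⁰ m`) so that the simulated current at `t_k`
matches the measured sample, with all earlier knots held fixed — a
strictly sequential, causal fit.

**Quasi-steady oracle.** Because pore-scale diffusion equilibrates in
microseconds, a lumped model is accurate: molar flow =
`C_lumen / R_diff(R_p)` with the series diffusive resistance

    R_diff(r) = 1/(4 D_in r) + L/(π r² D_out) + 1/(4 D_out r).

Inverting it per sample (bisection, with running depletion) gives an
independent, closed-form reconstruction used to cross-check the
sequential fit, and a fast forward backend for routine use.

**Population analyses.**  5–95 % rise/expansion times, single-
exponential decay classification (non-dense-core filter), Mann–Whitney
group comparison, log–log scaling of `R_p,max` vs `R_ves`, and the
membrane-section model `S_p,max = p_e·k_d·S_ves`, i.e.
`R_p,max = 2 R_ves √(p_e k_d)`, which predicts a log–log slope of 1
when the electroporation probability per membrane section `p_e` and
the deformation coefficient `k_d` are size-independent.

## Worked example

Generate a synthetic spike from a logistic pore trajectory (plateau
30 nm, midpoint 1 ms, steepness 0.3 ms; `R_ves` = 150 nm, `Q` = 1 pC,
2 % peak-amplitude Gaussian noise), then invert it:

```sh
$ poretrace --seed 7 synth spike --spec run.yaml --out syn/
spike + ground truth -> syn

$ poretrace reconstruct --spike syn/spike.tsv --rves-nm 150 --q-pc 1.0 \
      --out traj.tsv --report report.json
R_p,max 28.79 nm, t_expa 1.76 ms -> traj.tsv

$ poretrace features --spike syn/spike.tsv --out features.json
I_max 304.05 pA, Q 0.888 pC, t_rise 1.313 ms -> features.json
```

The reconstruction recovers the 30 nm plateau within 4 % and the true
expansion time `t_expa = 2·(0.3 ms)·ln 19 = 1.77 ms` within 1 %; the
fit residual (`fit_rms_A` in `report.json`, ≈ 0.017 pA) is far below
the injected noise.  The spike features show the generic VIEC
signature: the current rise time `t_rise` (1.31 ms here) tracks the
pore expansion time, the integrated charge is slightly below the true
1 pC because the spike is truncated at 6 ms, and the falling phase
fits a single exponential (`r2` ≈ 0.99, `nondense_core: true`), the
criterion for including a vesicle in the pore analysis.

The trajectory TSV (`time_s`, `pore_radius_m`, `flag`) flags samples
where the current no longer constrains the pore (lumen depleted or
signal below the noise floor).

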