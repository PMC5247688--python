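# Methods

This note documents the models, numerics and design choices behind
`cardiofib`, in the package's own words. Nothing here asserts an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Myocyte model

The ventricular myocyte is the 2006 ten Tusscher–Panfilov (TP06) human
ventricular model, epicardial parameter set. The membrane equation is

    dV/dt = -(I_ion + I_stim + I_gap),      I_ion = I_Na + I_to + I_K1 +
            I_Kr + I_Ks + I_CaL + I_NaK + I_NaCa + I_pCa + I_pK + I_bCa + I_bNa

with V in mV, time in ms and all currents in pA/pF. The calcium subsystem
uses the TP06 four-compartment formulation (bulk cytosol, subspace, SR,
with the R̄ release gate). Two modifications put the cell in an
EAD-capable regime:

- the f-gate time constant of I_CaL is multiplied by `tau_f_scale = 0.5`;
- the base maximal conductance G_CaL is multiplied by
  `g_cal_ead_scale = 2.0`.

On top of this the two sweep multipliers act: effective
G_CaL = `g_cal_ead_scale · x · g_CaL` and effective G_Kr = `y · g_Kr`.
Raising x (more inward L-type current) promotes early afterdepolarizations;
raising y (more repolarization reserve) suppresses them.

Cell subtype: the epicardial TP06 set is the default (the common choice in
2D TP06 tissue studies); endo/M variants can be configured through
`MyocyteParams` (`g_to`, `g_Ks`).

Buffering: instead of the algebraic instantaneous-buffer update of the
original explicit code, the calcium derivatives use the exactly equivalent
chain-rule form `dCa/dt = (1 + B·K/(Ca+K)²)⁻¹ · (fluxes)`, so
`myocyte_rhs` is a pure state-derivative function; the two forms agree to
the order of the integrator.

## Fibroblast model

The MacCannell "active" fibroblast carries I_fKv (time- and
voltage-dependent K⁺ current, activation gate r, inactivation gate s),
the inwardly rectifying I_fK1, an Na⁺/K⁺ pump current and a background
sodium current; intracellular concentrations are fixed. The uncoupled
model relaxes to ≈ −49.5 mV, matching the published −49.6 mV resting
potential to within the acceptance tolerance (±0.3 mV).

The resting potential is retuned by a single voltage offset `kv_shift`
applied to both the activation and inactivation voltage dependences of
I_fKv (shifting only one of them is possible but the common practice this
package follows shifts the current's full gating). `calibrate_kv_shift`
root-finds the offset for a target rest; the shipped −24.5 mV profiles use
the frozen calibrated value +35.93 mV. The calibration bracket defaults to
[−30, +50] mV: below about −35 mV the s (inactivation) gate takes over and
the fixed point jumps to a depolarized branch, so the map
shift → resting V is monotone only on this bracket.

Convergence of `resting_potential`: integration until
max |d(state)/dt| < 1e−8 or 60 s simulated; the slowest time constant
(τ_s ≈ 6.8 s near rest) means the flag can report non-convergence while
the voltage is already correct to far better than 0.01 mV.

Phenotypes: "fibroblast" C_F = 6.3 pF and "myofibroblast" C_F = 50 pF.
Capacitance rescales the membrane time constant, not the fixed point.
Profiles `fibroblast1` (6.3 pF, −49.7 mV) and `fibroblast2` (50 pF,
−24.5 mV) are the two 2D study configurations.

## Gap junction and the 0D unit

The junction is ohmic: I = Gs·(V_M − V_F) in pA with Gs in nS; the
current leaves the myocyte and enters the fibroblast (charge conserved by
construction). Myocyte-side currents are normalized to pA/pF by a
whole-cell capacitance of 185 pF (TP06 convention; configurable).

N identical fibroblasts with identical initial conditions have identical
trajectories, so the unit integrates one representative fibroblast and
multiplies its load on the myocyte by N; a test verifies this against an
explicit N-fibroblast integration.

The 0D analyses couple **one** fibroblast per myocyte (N_fib = 1). The
N = 5 cluster is the 2D tissue configuration; at N = 5 and Gs ≥ 2 nS a
single myocyte is overloaded (resting potential pulled to ≈ −64 mV) and
the APD responses saturate, whereas with one fibroblast the APD and
resting-potential responses are monotone over the full 0–3 nS range, as
the single-cell results require.

## Stimulus convention

Stimuli are specified as depolarizing current densities in pA/pF; the
default is 52 pA/pF for 2 ms, a standard ≈2× diastolic-threshold TP06
stimulus, applied every 500 ms in the 0D pacing protocol. (A printed
areal current density in µA/mm² does not map to a workable pA/pF
amplitude under any of the usual surface-capacitance conventions — 2
µF/cm² gives 1000 pA/pF, immediate blow-up — so the package fixes the
functional role, reliable capture, rather than a literal unit
conversion. This is the single place the convention is documented.)

## Integration

Voltage and concentrations advance by forward Euler at dt = 0.02 ms (0D
default). Gates use Rush–Larsen exponential updates: the TP06 sodium
activation gate has τ_m ≈ 1 µs near rest, so plain-Euler gate updates
diverge at any practical dt; Rush–Larsen is what the source model's own
explicit code does. A plain-Euler gate mode remains available
(`rush_larsen=False`) for small-dt studies. Gates stay in [0, 1] by their
own dynamics; no post-hoc clipping anywhere. |V| > 200 mV raises an
integration-blow-up error naming the simulated time.

## 2D tissue

Isotropic monodomain on an L×L lattice: five-point Laplacian over
myocyte nodes only, no-flux mirrors at the outer edges and at
fibroblast-cluster nodes (no diffusive M–F coupling), forward Euler in
time. Paper-profile numerics: D = 0.00154 cm²/ms, dx = 0.25 mm,
dt = 0.02 ms, L = 1024. The CFL number D·dt/dx² is checked at
construction.

Fibroblast clusters (N = 5) couple gap-junctionally to each of their ≤4
von Neumann myocyte neighbours, per fibroblast in the cluster: a myocyte
next to a cluster receives N·Gs·(V_M − V_F); the representative
fibroblast of the cluster receives Σ_neighbours Gs·(V_M − V_F).
Fibroblast–fibroblast neighbours exchange nothing. Textures place
round(φ·L²) clusters uniformly at random, reproducibly per seed.

The tissue stepper replaces every voltage-dependent transcendental with
linearly interpolated lookup tables at 0.05 mV resolution (interpolation
error ~1e−6 relative) — the standard acceleration for explicit monodomain
codes. The 0D path and the public `myocyte_currents`/`myocyte_rhs` API
evaluate exactly, and the golden tests pin both ionic transcriptions to
an independent reference at 1e−12.

### Reduced-scale profile

Full reproduction scale (L = 1024, multi-second runs, 40–80-run
ensembles) is far beyond a desk budget. Desk-scale runs therefore use:

- smaller lattices (L = 24–128), always labelled `scaled` in recording
  metadata;
- optionally a reduced diffusion coefficient D/64, which rescales space
  by 8× so that an L = 128 lattice hosts the wave dynamics of an
  effective 1024-node domain (at the cost of under-resolving the front:
  propagation on the lattice remains robust, conduction velocity becomes
  lattice-limited);
- dt = 0.05–0.1 ms with Rush–Larsen gates (0D APD90 shifts by < 1 ms
  between dt = 0.02 and dt = 0.1 at 2 Hz pacing).

What scaled runs do and do not show: they exercise the full model
pipeline and preserve ordering/sign properties (which coupling
configuration is more arrhythmogenic), but absolute regime boundaries in
(x, y) shift relative to the full-scale maps, and a stable rotating
spiral at its published (x, y) location requires the full-scale domain.
Two specific reduced-scale artefacts matter for the 2D checks:

- on the space-rescaled lattice the S2 rotor anchors to the domain
  boundary, so it produces no interior phase singularity and its probe
  periodicity stays below the SW threshold — the low-x ramp dwell is
  therefore recognized as "organized rotation" (sustained, at most one
  median phase singularity) rather than by the literal SW label;
- the reduced first-ectopic ensemble runs at x = 5.0–6.0 (y = 0.4, 20%
  texture, fully quiescent preconditioned medium): there the full-scale
  structure survives at desk scale — homogeneous and weakly coupled
  (Gs = 0.5 nS) media stay quiet after the focal wave, while strong
  coupling (Gs = 2 nS) generates ectopic foci including interior ones,
  i.e. the interior-origin fraction grows with coupling strength.
  Preconditioning always integrates past the last pacing wave until
  every node has repolarized below −70 mV, since a residual wave at P1
  onset would masquerade as ectopy.

## Protocols

- **Preconditioning (P1):** n plane waves at 1 Hz through the
  fibroblast-free medium at x = y = 1 (50 at full scale; reduced n for
  desk runs), returning the post-train state field.
- **P1:** one focal stimulus over a 6 × 200-node rectangle (scaled with
  L/1024), vertically centred, displaced +L/8 columns from the domain
  centre (the displacement is a package choice; only "slightly off
  center" is prescribed).
- **P2:** S1 plane wave from the left edge; when the front reaches the
  mid column (any myocyte node > −20 mV), S2 is applied over the
  upper-left quarter. The trigger fires exactly once; if the front never
  crosses, the run is labelled a protocol failure.
- **Ramp:** starting from the P2 spiral at x = 1.75, x increases by 0.25
  every 4 s (defaults; desk runs use larger steps and shorter dwells),
  carrying the tissue state across steps.

## Classification

Thresholds (package choices; the source regimes are described from
pseudocolor maps, so any operationalization is a decision):

- active node: V > −20 mV; full repolarization: V < −70 mV;
  OSC floor: −55 mV;
- sustained activity: any myocyte node active during the final 500 ms;
- gate activity: max m³hj (resp. d·f·f₂·f_Cass) > 0.1 on > 5% of myocyte
  nodes over the window;
- classification window: final 2 s (shorter recordings are
  inconclusive).

Cascade: protocol failure → PROTOCOL_FAILURE; activity dies →
NO_EAD/EAD by EAD count on the point traces; sustained + exactly one
median phase singularity + periodic probes (autocorrelation peak > 0.9)
→ SW (P2 only); ≥ 95% of myocyte nodes never below −55 mV in the final
1 s → OSC; full repolarization + sodium-gate activity → SF_B; otherwise
→ SF_A. OSC is tested *before* the SF branches: a medium where
(almost) no cell ever leaves the plateau band is a phase-wave state even
though it also satisfies "incomplete repolarization". For the same
reason the SF_A surrogate keeps its voltage floor at −62 mV (between
full repolarization and the OSC floor) rather than −50 mV, which would
be indistinguishable from OSC under these thresholds.

Phase singularities: per-node phase from the Hilbert transform (in time)
of the mean-subtracted voltage; a singularity is a 2×2 plaquette with
winding number ±1; plaquettes touching fibroblast nodes are ignored.

EAD detection (0D and point traces): local minima followed by a rise
≥ 1 mV, while V > −40 mV, between 50 ms after the upstroke (excluding
the epicardial spike-notch-dome) and the first crossing below −70 mV.
EAD-boundary scans pace 20 beats and count EADs on the last 5 (the
near-threshold EAD pattern is beat-to-beat irregular; a single-beat
criterion makes the boundary noisy), then scanned linearly in x
(default resolution 0.05, finer for the shift analyses) inside the
bracketing coarse interval (the indicator is
not monotone near onset, so bisection is not well defined).

Ectopic origins (P1): a re-activation is an upward crossing of −20 mV by
a node that had repolarized below −70 mV after its primary activation;
the simulation kernel tracks these at full time resolution (stimulus
regions excluded while the stimulus is on). The first event's site is
classified boundary/middle with a boundary band of 16/1024 of the side
(minimum 1 node). Frame-based reconstruction (used for surrogate
recordings) takes the centroid of the earliest frame's crossings.

## Sweeps

Phase diagrams classify one fresh run per (x, y) cell (P2 cells initiate
their own spiral; the ramp-inherited alternative exists via `run_ramp` —
fresh-per-cell is the default and is flagged in metadata). Completed
sweeps are cached on disk by a hash of the full configuration. The
pathological fraction reports N1 (P2), N2 (P1) — counts of SF_A/SF_B/OSC
cells — and their shares of the grid, rather than a single ratio, since
the exact plotted ratio of the source figure is not recoverable from its
caption.

## Known limitations

- Desk-scale lattices cannot host a full-wavelength TP06 spiral without
  the D-rescaling described above; absolute (x, y) regime boundaries are
  scale-dependent.
- The identical-fibroblast cluster reduction assumes homogeneous
  clusters; heterogeneous fibroblast populations are out of scope.
- The SF_A/SF_B discrimination thresholds are a package
  operationalization of a visual description.
- No anisotropy, bidomain, 3D, or mechano-electric feedback.
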