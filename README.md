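# cardiofib

Mechanistic simulation of how gap-junctional myocyte–fibroblast (M–F)
coupling modulates early afterdepolarizations (EADs) and the onset of
fibrillation-like states, in single-cell (0D) units and 2D human
ventricular tissue.

**Who it is for:** computational cardiac electrophysiologists studying
diffuse fibrosis as an arrhythmia substrate — in particular the role of
the fibroblast resting potential V_FR and coupling conductance Gs in
promoting or suppressing EAD-driven ectopy.

## Model

Myocytes follow the ten Tusscher–Panfilov 2006 (TP06) human ventricular
ionic model (epicardial set),

  dV/dt = −(I_ion + I_stim + I_gap),  I_ion = I_Na + I_to + I_K1 + I_Kr +
          I_Ks + I_CaL + I_NaK + I_NaCa + I_pCa + I_pK + I_bCa + I_bNa,

made EAD-capable by halving τ_f of the L-type Ca²⁺ f-gate and doubling
base G_CaL. Two multipliers span the regime maps: x on G_CaL and y on
G_Kr. Fibroblasts follow the MacCannell "active" model (I_fKv, I_fK1,
I_fNaK, I_bNa; uncoupled rest ≈ −49.6 mV), with a gating-shift
calibration that produces the depolarized −24.5 mV variant, and two
phenotypes: fibroblast (C_F = 6.3 pF) and myofibroblast (C_F = 50 pF).
Junctions are ohmic, I_MtoF = Gs·(V_M − V_F).

2D tissue is an isotropic monodomain L×L lattice (five-point Laplacian,
no-flux boundaries, forward Euler; D = 0.00154 cm²/ms, dx = 0.25 mm,
dt = 0.02 ms) in which a fraction φ of nodes holds clusters of N = 5
fibroblasts, placed uniformly at random. Clusters exchange only
gap-junctional current with their von Neumann myocyte neighbours.
Stimulation protocols P1 (paced preconditioning + one focal stimulus) and
P2 (S1–S2 cross-field spiral initiation, optional slow ramp of x) feed a
classifier that labels the dynamics NO_EAD, EAD, SW (stable spiral), SF_B
(sodium-driven fibrillation), SF_A (calcium-driven fibrillation) or OSC
(phase waves), and locates first ectopic origins (boundary vs interior).

See `docs/methods.md` for equations, thresholds, numerics and the
reduced-scale desk profile.

## Worked example

```python
from cardiofib import MyocyteParams, CouplingConfig, pace_unit, apd90
from cardiofib.profiles import fibroblast_profile

mp = MyocyteParams(x=3.0, y=0.75)          # no EADs when uncoupled
base = apd90(pace_unit(mp))[0]["apd90"]

for name in ("fibroblast_-49.7", "fibroblast_-24.5"):
    fp = fibroblast_profile(name)
    tr = pace_unit(mp, fp, CouplingConfig(Gs=2.0, N_fib=1))
    print(name, round(apd90(tr)[0]["apd90"], 1))
print("uncoupled", round(base, 1))
```

prints

```
fibroblast_-49.7 326.1
fibroblast_-24.5 336.6
uncoupled 329.6
```

i.e. coupling to a hyperpolarized fibroblast (V_FR = −49.7 mV) *shortens*
the myocyte action potential (faster repolarization, APD90 329.6 → 326.1
ms at Gs = 2 nS) while a depolarized fibroblast (V_FR = −24.5 mV)
*prolongs* it (329.6 → 336.6 ms) — the sign of the coupling effect is set
by the fibroblast resting potential, and its magnitude grows with Gs and
with the myofibroblast capacitance.

A 2D run from the shell:

```
cardiofib tissue run --config examples/p1.yaml --seed 1 --out rec.h5
cardiofib cell scan-boundary --y 0.8 --gs 0 --gs 2
```

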