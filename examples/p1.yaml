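# Reduced-scale P1 run: focal stimulation of a preconditioned medium
# with 10% fibroblast-1 texture.  Full-scale values: L: 1024, D: 0.00154,
# dt: 0.02.
grid:
  L: 64
  phi: 0.1
  D: 0.00009625      # D/16: space rescaled 4x
  dx: 0.25
  dt: 0.1
myocyte:
  x: 3.0
  y: 0.4
fibroblast:
  C_F: 6.3
  kv_shift: 0.0
  V_FR_target: -49.7
coupling:
  Gs: 0.5
  N_fib: 5
protocol:
  name: P1
  t_end: 2300.0
  n_precond_waves: 2
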