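# Bundled A + BC exchange study: one H2 molecule, one carbon atom and six
# helium energy-transfer atoms in a breathing sphere, on the LEPS toy
# surface.  The discovery direction is the endothermic abstraction
# C + H2 -> CH + H (forward dE ~ +19 kJ/mol, barrier ~ 83 kJ/mol);
# read in reverse it is the exothermic H + CH -> H2 + C route with a
# ~64 kJ/mol entrance barrier and a genuine first-order saddle.
seed: 7
output_dir: nanoreactor_out
pack:
  sphere_radius: 5.0
  min_separation: 2.0
  templates:
    - label: H2
      elements: [H, H]
      positions: [[0.0, 0.0, 0.0], [0.0, 0.0, 0.741]]
      count: 1
    - label: C
      elements: [C]
      positions: [[0.0, 0.0, 0.0]]
      count: 1
    - label: He
      elements: [He]
      positions: [[0.0, 0.0, 0.0]]
      count: 6
dynamics:
  provider: leps
  dt: 0.5
  thermostat: langevin
  temperature: 1500.0
  damping_time: 300.0
  n_steps: 100000
  snapshot_stride: 10
piston:
  r1: 6.0
  r2: 2.5
  t1: 300.0
  t2: 200.0
  k1: 0.002
  k2: 0.004
detect:
  persistence_frames: 25
  form_factor: 1.3
  break_factor: 1.45
refine:
  n_images: 11
  spring_k: 1.0
  grad_tol: 1.0e-5
  neb_tol: 1.0e-3
  max_step: 0.015
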