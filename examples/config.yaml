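seed: 1
mechanics:
  eta: 1.0
  ii:
    u0: 0.35
    r_eq: 0.6
    xi: 0.25
    cutoff: 0.6
    repulsive_only: true
  mi:
    u0: 0.3
    r_eq: 0.7
    xi: 0.3
    cutoff: 0.7
    repulsive_only: true
  adh:
    u0: 0.08
    r_eq: 0.18
    xi: 0.15
    cutoff: 0.8
    repulsive_only: false
  mmd:
    u0: 0.5
    r_eq: 0.15
    xi: 0.08
    cutoff: 0.15
    repulsive_only: true
  mms:
    k: 10.0
    l0: 0.2
  dt_mech: 0.02
  max_displacement: 0.25
  g0_max: 0.005
  growth_jitter: 0.25
  generation_decay: 0.9
  decay_law: generation
  time_decay_rate: 0.0
  growth_cap_factor: 2.0
  mitotic_duration: 20.0
  rounding_mms_factor: 3.0
  rounding_mi_factor: 1.5
  neighbor_skin: 0.3
  rebuild_every: 10
mesh:
  neighbor_threshold: 0.45
  l_intersect: 0.2
  min_angle_deg: 15.0
  pairing_factor: 1.5
  split_pass: false
  max_repair_iter: 50
  drop_sliver_angle_deg: 5.0
signaling:
  D_Dpp: 2.0
  d_Dpp: 0.5
  v_Dpp: 1.0
  r_s: 0.2
  n_s: 4.0
  d_Tkv: 1.0
  d_Dpp_Tkv: 1.0
  d_P: 1.0
  v_P: 1.0
  v_min: 1.0
  v_max: 10.0
  k_on: 0.2
  k_off: 0.1
  k_P: 1.0
  k_Dpp_Tkv: 0.5
  n_1: 2.0
  n_2: 2.0
  pmad_hill: repressive
  dt_chem: null
  dt_safety: 0.7
  tol: 0.0001
  bc: absorbing
  mode: simplified
  dialect: default
  degradation: auto
  max_iter: 200000
coupling:
  exchange_interval: 25.0
  rule_signal: auto
  rule_threshold: 0.5
  L_update: true
  t_end: 200.0
  max_cells: 100000
  save_every: 1
  growth_substep: 1.0
tissue:
  n_cells: 12
  nodes_per_cell_membrane: 14
  internal_nodes_per_cell: 6
  cell_radius: 1.0
  relax_steps: 1000
output:
  outdir: out_example
  save_nodes: false
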