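# Default model parameters (relative concentration units; one step = 15 min).
#
# geometry: the crypt-villus unit template and the desk-scale unit lattice;
#   set diameter_cm/length_cm to tile an anatomic cylinder instead.
# rules: cell-cycle lengths (steps), morphogen thresholds, conveyor and
#   shedding rates, inflammation-mediated death coefficients, and the
#   metaplasia (villus-shortening) response.
# signaling: per-mediator diffusivity D (sites^2/step; 4*D <= 1), decay lam
#   (fraction/step), positional emission, constitutive basal production,
#   and the signed stimulation(+1)/inhibition(-1) edge list.
# stool: fill/empty cycle (16 steps = 4 h), inflammatory-potential gain
#   delta_ip per step of residence, and the fill direction.
#
# Any block may be overridden from a scenario config file.
equilibration_steps: 500
geometry:
  cap_rows: 1
  cell_diameter_um: 10.0
  crypt_depth: 12
  diameter_cm: null
  face_width: 6
  length_cm: null
  n_faces: 4
  sim_n_axial: 8
  sim_n_circ: 8
  unit_spacing_mm: 0.5
  villus_height: 48
perturbation:
  bolus_ros: 5.0
  bolus_tnfa: 5.0
  inflammation_ros: 0.1
  inflammation_start: 500
  inflammation_steps: 80
  inflammation_tnfa: 0.1
  knockout_step: 500
  knockouts:
  - WNT
  ulcer_center_row: null
  ulcer_radius: 6
  ulcer_step: 500
rules:
  atrophic_shed_prob: 0.05
  cycle_len_progenitor: 48
  cycle_len_stem: 96
  death_coeff_ros: 0.01
  death_coeff_tnfa: 0.01
  metaplasia_exposure_threshold: 150.0
  metaplasia_height_per_exposure: 11.0
  metaplasia_reversible: false
  migration_prob: 0.2
  shed_prob: 0.007
  shed_rows: 1
  stem_zone_rows: 3
  theta_bmp: 0.5
  theta_wnt: 0.1
  villus_min_height: 12
signaling:
  crypt_source_rows: 3
  edges:
  - - TLR_ACT
    - NFKB
    - 1
    - 0.3
  - - TNFA
    - NFKB
    - 1
    - 0.1
  - - NFKB
    - TNFA
    - 1
    - 0.1
  - - NFKB
    - IL6
    - 1
    - 0.1
  - - NFKB
    - ROS
    - 1
    - 0.1
  - - IFNG
    - RIPK
    - 1
    - 0.3
  - - RIPK
    - ROS
    - 1
    - 0.1
  - - IL6
    - JAK
    - 1
    - 0.3
  - - JAK
    - STAT3
    - 1
    - 0.3
  - - IL10
    - NFKB
    - -1
    - 0.3
  - - PTEN
    - PI3K
    - -1
    - 0.3
  - - PI3K
    - AKT
    - 1
    - 0.3
  - - IL13
    - NFKB
    - -1
    - 0.0
  - - IL15
    - NFKB
    - 1
    - 0.0
  fields:
    AKT:
      D: 0.0
      basal: 0.0
      emission: 0.0
      lam: 0.2
    BMP:
      D: 0.2
      basal: 0.0
      emission: 1.0
      lam: 0.1
    HH:
      D: 0.2
      basal: 0.0
      emission: 1.0
      lam: 0.1
    IFNG:
      D: 0.1
      basal: 0.0
      emission: 0.0
      lam: 0.3
    IL10:
      D: 0.1
      basal: 0.0
      emission: 0.0
      lam: 0.3
    IL13:
      D: 0.1
      basal: 0.0
      emission: 0.0
      lam: 0.3
    IL15:
      D: 0.1
      basal: 0.0
      emission: 0.0
      lam: 0.3
    IL6:
      D: 0.1
      basal: 0.0
      emission: 0.0
      lam: 0.3
    JAK:
      D: 0.0
      basal: 0.0
      emission: 0.0
      lam: 0.2
    NFKB:
      D: 0.0
      basal: 0.0
      emission: 0.0
      lam: 0.2
    PI3K:
      D: 0.0
      basal: 0.1
      emission: 0.0
      lam: 0.2
    PTEN:
      D: 0.0
      basal: 0.1
      emission: 0.0
      lam: 0.2
    RIPK:
      D: 0.0
      basal: 0.0
      emission: 0.0
      lam: 0.2
    ROS:
      D: 0.1
      basal: 0.0
      emission: 0.0
      lam: 0.3
    STAT3:
      D: 0.0
      basal: 0.0
      emission: 0.0
      lam: 0.2
    TLR_ACT:
      D: 0.0
      basal: 0.0
      emission: 0.0
      lam: 0.3
    TNFA:
      D: 0.1
      basal: 0.0
      emission: 0.0
      lam: 0.3
    WNT:
      D: 0.2
      basal: 0.0
      emission: 1.0
      lam: 0.1
  knockouts: []
  villus_source_rows: 4
  w_stat3: 0.5
stool:
  delta_ip: 0.0
  fill_steps: 16
  ip0: 0.0
  k_tlr: 1.0
  per_parcel: true
  terminal_first: true
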