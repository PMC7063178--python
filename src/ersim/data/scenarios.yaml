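# Battery definition: solver defaults, the two controller blocks, the
# expected low/high verdict table for the twelve controlled conditions, and
# the calibration search space.  Reference levels and verdict thresholds
# are calibration outputs and ship in calibrated.yaml.

simulation:
  duration: 70000.0
  n_points: 401
  sample_interval: 350.0
  solver: LSODA
  rel_tol: 1.0e-6
  abs_tol: 1.0e-8
  clip_states: true

controllers:
  loop1:                      # senses pPERK, actuates the stress drive u1
    kp: 0.0
    ki: 0.0691
    kd: 0.0
    error_mode: signed
    output_limits: [0.0, 50000.0]
    anti_windup: true
    preload: dio_u1           # start from the DIO drive being reined in
  loop2:                      # senses the insulin-arm marker, actuates u2
    kp: 0.2134
    ki: 0.10329
    kd: -0.1082
    error_mode: signed
    output_limits: [0.0, 50000.0]
    anti_windup: true
    preload: open_loop_u2

expected_verdicts:
  I:
    i:   {er_stress: high, insulin_sensitivity: low,  upr_ratios: high}
    ii:  {er_stress: high, insulin_sensitivity: low,  upr_ratios: high}
    iii: {er_stress: low,  insulin_sensitivity: high, upr_ratios: low}
    iv:  {er_stress: low,  insulin_sensitivity: low,  upr_ratios: low}
  II:
    i:   {er_stress: high, insulin_sensitivity: low,  upr_ratios: high}
    ii:  {er_stress: high, insulin_sensitivity: low,  upr_ratios: high}
    iii: {er_stress: low,  insulin_sensitivity: high, upr_ratios: low}
    iv:  {er_stress: low,  insulin_sensitivity: low,  upr_ratios: low}
  III:
    i:   {er_stress: high, insulin_sensitivity: low,  upr_ratios: high}
    ii:  {er_stress: high, insulin_sensitivity: high, upr_ratios: high}
    iii: {er_stress: low,  insulin_sensitivity: high, upr_ratios: low}
    iv:  {er_stress: low,  insulin_sensitivity: low,  upr_ratios: low}

calibration:
  seed: 20200222
  max_trials: 40
  anchor_rel_tol: 0.15
  anchors:
    sens_high: 4.7            # insulin sensitivity plateau, case III (iii)
    sens_low: 1.7             # insulin sensitivity plateau, case III (iv)
    ratio_high: 0.8           # UPR ratio plateau under a high pPERK reference
    ratio_low: 0.5            # UPR ratio plateau under a low pPERK reference
    flux_drop_time: 6000.0    # time the stress flux goes quiet, case I (iv)
  anchor_parameters:
    - amplify1
    - ref_pPERK_high
    - ref_pPERK_low
    - ref_pAKT_high
    - ref_pAKT_low
  free_parameters:
    amplify1:        [3.0, 12.0]
    ref_pPERK_high:  [2.5, 5.0]
    ref_pPERK_low:   [0.5, 2.0]
    ref_IRpY_high:   [2.5, 5.0]
    ref_IRpY_low:    [0.3, 1.5]
    ref_IRSpY_high:  [2.8, 5.0]
    ref_IRSpY_low:   [0.3, 1.5]
    ref_pAKT_high:   [3.0, 5.5]
    ref_pAKT_low:    [0.8, 2.5]
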