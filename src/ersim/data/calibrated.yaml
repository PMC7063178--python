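# Output of the seeded calibration search (regenerable via
# `ersim calibrate`): stress amplification, controller reference
# levels, and low/high verdict thresholds.
amplify1: 7.261049199476299
references:
  IRSpY:
    high: 4.01842878220978
    low: 1.4617173314641423
  IRpY:
    high: 4.667140336741639
    low: 1.3080546496404404
  pAKT:
    high: 4.71035466371248
    low: 1.6914329827749306
  pPERK:
    high: 3.9774220484839193
    low: 1.002310279788828
seed: 20200222
thresholds:
  insulin_sensitivity: 2.1094731367339015
  upl_flux: 0.05599665410340934
  upr_ratio: 0.5807692307692307
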