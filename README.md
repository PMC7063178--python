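# ersim

A state-space ODE simulator of the integrated ER-stress (unfolded protein
response) and insulin-signaling network, with discrete PID controllers
closed around the model to probe which markers must be driven low or high
to obtain low ER stress together with high insulin sensitivity.

The package ships:

- a declarative 32-species network (`src/ersim/data/model_default.yaml`)
  expressed in a three-shape rate-term grammar (input drive, modulated
  activation, modulated decay) compiled to a fast ODE right-hand side;
- equilibrium-derived external inputs: the ER-stress drive `u1` and the
  insulin drive `u2`, with configurable amplification (the DIO condition
  amplifies `u1`; the NCD control holds `u1 = 0`);
- a stiff-solver simulation layer with state bounds, ratio/flux readouts
  and steady-value extraction;
- two PID controllers (integral-only loop on pPERK actuating `u1`; PID
  loop with negative derivative gain on an insulin-arm marker actuating
  `u2`) and a zero-order-hold closed-loop simulator;
- the scenario battery: NCD, DIO, and twelve closed-loop "thought
  experiment" conditions (cases I-III x four high/low reference
  combinations), with low/high verdict classification;
- a seeded calibration search that fixes the free quantities (stress
  amplification, controller references, verdict thresholds) against the
  qualitative DIO-vs-NCD pattern table and quantitative steady-value
  anchors, frozen in `src/ersim/data/calibrated.yaml`;
- a synthetic-data module generating densitometry-style replicate
  observations (n = 4, positive, lognormal noise) that embody the pattern
  table;
- optional SBML Level 3 export (species + rate rules).

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, including a full
re-run of the seeded calibration (several minutes); everything else is
fast.

## CLI

```bash
ersim simulate --scenario NCD --out out/          # one scenario -> CSV
ersim battery  --out out/                         # all 14 scenarios + verdicts + manifest
ersim control  --case III --condition iv --out out/
ersim calibrate --out calibrated.yaml             # regenerate the calibration
ersim synth-blots --out blots.csv --seed 1
ersim export-sbml --out model.sbml
```

Trajectory CSVs have one row per time point with columns `time`, every
species, the inputs, the readouts, and (for closed-loop runs) controller
error/actuation traces.

## Layout

```
src/ersim/
  model.py       term grammar, validation, RHS compilation
  inputs.py      equilibrium-derived u1/u2 and input policies
  simulate.py    stiff integration, readouts, steady values
  control.py     PID controllers and closed-loop simulation
  scenarios.py   scenario battery, verdicts, calibration
  patterns.py    pattern table + synthetic replicate generator
  sbml.py        SBML L3 export
  cli.py         command-line pipeline
  data/          model roster, battery, calibrated values, pattern table
```
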