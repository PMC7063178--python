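"""Shared fixtures: tiny analytic models and the (expensive) battery run."""

from __future__ import annotations

import pytest

from ersim.model import parse_model_spec
from ersim.scenarios import (
    load_default_battery,
    load_default_model,
    load_pattern_table,
    run_battery,
)

# Minimal stress-entry pair: the canonical two-term equation plus a
# chaperone pool, enough to exercise input derivation and steady state.
EQ1_PAIR_YAML = """
species:
  - {name: UPL, role: stress_input_proxy}
  - {name: BiP, role: upr_effector}
inputs: [u1]
terms:
  UPL:
    - {shape: input_drive, k: k1, driver: u1}
    - {shape: decay, k: k2, of: UPL, factors: [BiP]}
  BiP:
    - {shape: activation, k: k_syn}
    - {shape: decay, k: k_dec, of: BiP}
parameters:
  rate_constants: {k1: 1.0, k2: 1.0, k_syn: 0.05, k_dec: 0.05}
  binding_constants: {}
  amplify1: 1.0
  amplify2: 1.0
readouts:
  UPL: {kind: species, species: UPL}
  upl_flux: {kind: input_flux, species: UPL}
"""

# Receptor-entry fragment: drive + inhibited decay, exercising u2.
EQ3_FRAGMENT_YAML = """
species:
  - {name: IR, role: insulin_cascade}
  - {name: pAKT, role: readout_phospho}
  - {name: pFoxO1, role: insulin_cascade}
inputs: [u2]
terms:
  IR:
    - {shape: input_drive, k: k53, driver: u2}
    - {shape: decay, k: k52, of: IR, inhibitors: [[pAKT, F3], [pFoxO1, F4]]}
  pAKT:
    - {shape: decay, k: k_hold, of: pAKT}
  pFoxO1:
    - {shape: decay, k: k_hold, of: pFoxO1}
parameters:
  rate_constants: {k53: 1.0, k52: 1.0, k_hold: 0.0}
  binding_constants: {F3: 0.5, F4: 0.5}
  amplify1: 1.0
  amplify2: 1.0
"""

SINGLE_DECAY_YAML = """
species:
  - {name: X, role: insulin_cascade, init: 1.05, bounds: [0.0, 100.0]}
terms:
  X:
    - {shape: decay, k: k, of: X}
parameters:
  rate_constants: {k: 1.0}
inputs: []
"""

# First-order plant x' = u - x for control-loop oracles.
PLANT_YAML = """
species:
  - {name: X, role: insulin_cascade, init: 0.0, bounds: [0.0, 1000.0]}
inputs: [u1]
terms:
  X:
    - {shape: input_drive, k: ku, driver: u1}
    - {shape: decay, k: kx, of: X}
parameters:
  rate_constants: {ku: 1.0, kx: 1.0}
readouts:
  X: {kind: species, species: X}
"""


@pytest.fixture(scope="session")
def eq1_pair():
    return parse_model_spec(EQ1_PAIR_YAML)


@pytest.fixture(scope="session")
def eq3_fragment():
    return parse_model_spec(EQ3_FRAGMENT_YAML)


@pytest.fixture(scope="session")
def single_decay():
    return parse_model_spec(SINGLE_DECAY_YAML)


@pytest.fixture(scope="session")
def plant():
    return parse_model_spec(PLANT_YAML)


@pytest.fixture(scope="session")
def default_model():
    return load_default_model()


@pytest.fixture(scope="session")
def default_battery():
    return load_default_battery()


@pytest.fixture(scope="session")
def pattern_table():
    return load_pattern_table()


@pytest.fixture(scope="session")
def battery_outcome(default_model, default_battery, pattern_table):
    """One full battery run shared by the qualitative/verdict/anchor tests."""
    return run_battery(default_model, default_battery, pattern_table)
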