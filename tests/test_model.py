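import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ersim.model import (
    ModelSpec,
    ModelValidationError,
    ParameterSet,
    RateTerm,
    SpeciesState,
    build_rhs,
    evaluate_term,
    parse_model_spec,
)

MINIMAL_DOC = """
species: [{name: x1}, {name: x2}]
inputs: [u1]
terms:
  x1:
    - {shape: input_drive, k: k1, driver: u1}
    - {shape: decay, k: k2, of: x1, factors: [x2]}
  x2:
    - {shape: decay, k: k2, of: x2}
parameters:
  rate_constants: {k1: 1.0, k2: 1.0}
"""


class TestParsing:
    def test_minimal_two_species_document(self):
        model = parse_model_spec(MINIMAL_DOC)
        assert len(model.species) == 2
        assert len(model.terms["x1"]) == 2
        assert model.terms["x1"][0].shape == "input_drive"

    def test_default_roster_passes_all_invariants(self, default_model):
        # the shipped 32-species config parses and re-validates cleanly
        assert len(default_model.species) == 32
        default_model.validate()
        required = {
            "pPERK_ratio", "pIRE1a_ratio", "peIF2a_ratio",
            "insulin_sensitivity", "upl_flux", "IRpY", "IRSpY", "PIP3",
            "pJNK", "pIKKb", "pNFkB", "pFoxO1", "ATF6a",
        }
        assert required <= set(default_model.readout_definitions)

    def test_undeclared_species_is_cited(self):
        doc = MINIMAL_DOC.replace("factors: [x2]", "factors: [x99]")
        with pytest.raises(ModelValidationError, match="x99"):
            parse_model_spec(doc)

    def test_duplicate_species_rejected(self):
        doc = MINIMAL_DOC.replace("{name: x2}", "{name: x1}")
        with pytest.raises(ModelValidationError, match="duplicate"):
            parse_model_spec(doc)

    def test_unknown_term_shape_rejected(self):
        doc = MINIMAL_DOC.replace("shape: input_drive", "shape: michaelis")
        with pytest.raises(ModelValidationError, match="michaelis"):
            parse_model_spec(doc)

    def test_orphan_species_rejected(self):
        doc = """
species: [{name: a}, {name: b}]
terms:
  a: [{shape: decay, k: k, of: a}]
parameters: {rate_constants: {k: 1.0}}
"""
        with pytest.raises(ModelValidationError, match="orphan"):
            parse_model_spec(doc)

    def test_parameter_outside_interval_rejected(self):
        doc = MINIMAL_DOC.replace("k1: 1.0", "k1: 7.5")
        with pytest.raises(ModelValidationError, match="k1"):
            parse_model_spec(doc)

    def test_undeclared_input_rejected(self):
        doc = MINIMAL_DOC.replace("inputs: [u1]", "inputs: [u9]")
        with pytest.raises(ModelValidationError, match="u1"):
            parse_model_spec(doc)


class TestSpeciesState:
    def test_unknown_role_rejected(self):
        with pytest.raises(ModelValidationError):
            SpeciesState(name="x", role="enzyme")

    def test_value_outside_bounds_rejected(self):
        with pytest.raises(ModelValidationError):
            SpeciesState(name="x", value=30.0, upper_bound=25.0)


class TestEvaluateTerm:
    PARAMS = ParameterSet(
        rate_constants={"k1": 1.0, "k40": 1.0, "k52": 2.0},
        binding_constants={"F2": 1.0, "F3": 1.0, "F4": 0.0},
    )

    def test_input_drive_arithmetic(self):
        term = RateTerm(shape="input_drive", rate_constant="k1", driver="u1")
        value = evaluate_term(term, {}, {"u1": 1.1025}, self.PARAMS)
        assert value == pytest.approx(1.1025, abs=1e-15)

    def test_modulated_activation_arithmetic(self):
        term = RateTerm(
            shape="activation",
            rate_constant="k40",
            factors=("x19", "x1", "x2"),
            accelerators=(("x18", "F2"),),
        )
        state = {"x19": 1.0, "x18": 1.0, "x1": 1.0, "x2": 1.0}
        assert evaluate_term(term, state, {}, self.PARAMS) == pytest.approx(2.0)

    def test_inhibited_decay_arithmetic(self):
        term = RateTerm(
            shape="decay",
            rate_constant="k52",
            decay_of="x26",
            decay_inhibitors=(("x30", "F3"), ("x32", "F4")),
        )
        state = {"x26": 1.0, "x30": 1.0, "x32": 1.0}
        assert evaluate_term(term, state, {}, self.PARAMS) == pytest.approx(-1.0)

    def test_missing_species_raises_lookup_error(self):
        term = RateTerm(shape="decay", rate_constant="k52", decay_of="x26")
        with pytest.raises(KeyError, match="x26"):
            evaluate_term(term, {}, {}, self.PARAMS)

    def test_missing_input_raises_lookup_error(self):
        term = RateTerm(shape="input_drive", rate_constant="k1", driver="u1")
        with pytest.raises(KeyError, match="u1"):
            evaluate_term(term, {}, {}, self.PARAMS)


class TestBuildRhs:
    def test_steady_state_by_construction(self, eq1_pair):
        # u1 from the equilibrium relation (amplify1 = 1) nulls dUPL/dt
        from ersim.inputs import derive_u1

        state = eq1_pair.initial_state()
        u1 = derive_u1(state, eq1_pair.parameters)
        rhs = build_rhs(eq1_pair, lambda t, y: {"u1": u1})
        y0 = np.array([state[n] for n in eq1_pair.species_names])
        dy = rhs(0.0, y0)
        assert abs(dy[eq1_pair.species_index()["UPL"]]) < 1e-14

    def test_zero_rate_constants_zero_field(self):
        doc = MINIMAL_DOC.replace("k1: 1.0, k2: 1.0", "k1: 0.0, k2: 0.0")
        model = parse_model_spec(doc)
        rhs = build_rhs(model, lambda t, y: {"u1": 3.0})
        assert np.allclose(rhs(0.0, np.array([1.05, 1.05])), 0.0)

    def test_modulated_activation_species_derivative(self):
        doc = """
species: [{name: x18}, {name: x19}, {name: x20}, {name: x1}, {name: x2}]
terms:
  x18: [{shape: decay, k: k0, of: x18}]
  x19: [{shape: decay, k: k0, of: x19}]
  x1: [{shape: decay, k: k0, of: x1}]
  x2: [{shape: decay, k: k0, of: x2}]
  x20:
    - {shape: activation, k: k40, factors: [x19, x1, x2], accelerators: [[x18, F2]]}
    - {shape: decay, k: k41, of: x20}
parameters:
  rate_constants: {k0: 0.0, k40: 1.0, k41: 1.0}
  binding_constants: {F2: 1.0}
"""
        model = parse_model_spec(doc)
        rhs = build_rhs(model)
        idx = model.species_index()
        y = np.ones(5)
        dy = rhs(0.0, y)
        assert dy[idx["x20"]] == pytest.approx(2.0 - 1.0)

    def test_compiled_and_interpreted_paths_agree(self, default_model):
        rng = np.random.default_rng(7)
        fast = build_rhs(default_model, lambda t, y: {"u1": 2.0, "u2": 3.0})
        slow = build_rhs(
            default_model, lambda t, y: {"u1": 2.0, "u2": 3.0}, compiled=False
        )
        for _ in range(20):
            y = rng.uniform(0.0, 10.0, size=32)
            np.testing.assert_allclose(fast(0.0, y), slow(0.0, y), rtol=1e-12)

    def test_term_additivity_against_naive_sum(self, default_model):
        # brute-force oracle: per-species sum of independently evaluated terms
        rng = np.random.default_rng(11)
        y = rng.uniform(0.1, 5.0, size=32)
        state = dict(zip(default_model.species_names, y))
        inputs = {"u1": 1.7, "u2": 0.4}
        rhs = build_rhs(default_model, lambda t, yy: inputs)
        dy = rhs(0.0, y)
        for i, name in enumerate(default_model.species_names):
            expected = sum(
                evaluate_term(t, state, inputs, default_model.parameters)
                for t in default_model.terms[name]
            )
            assert dy[i] == pytest.approx(expected, rel=1e-12, abs=1e-15)


@settings(max_examples=50, deadline=None)
@given(
    scale=st.floats(0.0, 5.0, allow_nan=False),
    x=st.floats(0.01, 20.0),
    u=st.floats(0.0, 10.0),
)
def test_homogeneity_in_rate_constant(scale, x, u):
    """Scaling k by c scales every term shape's contribution by exactly c."""
    base = ParameterSet(rate_constants={"k": 1.0}, binding_constants={"F": 0.3})
    scaled = ParameterSet(
        rate_constants={"k": scale}, binding_constants={"F": 0.3}
    )
    state = {"a": x, "b": 2.0}
    terms = [
        RateTerm(shape="input_drive", rate_constant="k", driver="u1"),
        RateTerm(shape="activation", rate_constant="k", factors=("a", "b")),
        RateTerm(
            shape="decay",
            rate_constant="k",
            decay_of="a",
            decay_inhibitors=(("b", "F"),),
        ),
    ]
    for term in terms:
        v1 = evaluate_term(term, state, {"u1": u}, base)
        v2 = evaluate_term(term, state, {"u1": u}, scaled)
        assert v2 == pytest.approx(scale * v1, rel=1e-12, abs=1e-300)


def test_parameter_set_rejects_nonfinite():
    with pytest.raises(ModelValidationError):
        ParameterSet(rate_constants={"k": math.inf})


def test_with_parameters_revalidates(eq1_pair):
    new = eq1_pair.parameters.copy()
    new.rate_constants["k1"] = 2.5
    other = eq1_pair.with_parameters(new)
    assert other.parameters.rate_constants["k1"] == 2.5
    assert eq1_pair.parameters.rate_constants["k1"] == 1.0
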