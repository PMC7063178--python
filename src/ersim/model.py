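"""Declarative reaction-network model and compilation to an ODE right-hand side.

The network is expressed as a roster of species plus, for every species, a
list of additive rate terms drawn from a three-shape grammar:

``input_drive``
    ``+k * u(driver)`` -- an external input feeding a species.
``activation``
    ``+k * prod(factors) * prod(1 + F_i * x_i)`` -- mass-action activation,
    optionally accelerated by bound modifiers.
``decay``
    ``-k * x_of * prod(factors) / prod(1 + F_j * x_j)`` -- first-order loss,
    optionally driven by extra factors (mixed decay) and slowed by
    saturable inhibitors of degradation.

Rate constants and binding constants are referenced *by name* and resolved
against a :class:`ParameterSet`, so a calibrated parameter vector can be
swapped without rebuilding terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "SPECIES_ROLES",
    "TERM_SHAPES",
    "ModelValidationError",
    "SpeciesState",
    "RateTerm",
    "ParameterSet",
    "ReadoutDef",
    "ModelSpec",
    "parse_model_spec",
    "evaluate_term",
    "build_rhs",
]

SPECIES_ROLES = frozenset(
    {
        "stress_input_proxy",
        "upr_sensor",
        "upr_effector",
        "inflammatory",
        "insulin_cascade",
        "lipid_second_messenger",
        "readout_total",
        "readout_phospho",
    }
)

TERM_SHAPES = frozenset({"input_drive", "activation", "decay"})

READOUT_KINDS = frozenset({"species", "phospho_ratio", "raw_ratio", "input_flux"})


class ModelValidationError(ValueError):
    """A model document violates a structural invariant."""


@dataclass(frozen=True)
class SpeciesState:
    """One state component: a signaling molecule abundance in AU."""

    name: str
    role: str = "insulin_cascade"
    value: float = 1.05
    lower_bound: float = 0.0
    upper_bound: float = 25.0

    def __post_init__(self) -> None:
        if self.role not in SPECIES_ROLES:
            raise ModelValidationError(
                f"species {self.name!r}: unknown role {self.role!r}"
            )
        if not (self.lower_bound <= self.value <= self.upper_bound):
            raise ModelValidationError(
                f"species {self.name!r}: value {self.value} outside "
                f"[{self.lower_bound}, {self.upper_bound}]"
            )


@dataclass(frozen=True)
class RateTerm:
    """One additive contribution to a species' time derivative.

    ``rate_constant``, the accelerator/inhibitor binding constants and the
    term shape are stored symbolically; numeric values come from the
    :class:`ParameterSet` at evaluation time.
    """

    shape: str
    rate_constant: str
    driver: str | None = None
    factors: tuple[str, ...] = ()
    accelerators: tuple[tuple[str, str], ...] = ()
    decay_of: str | None = None
    decay_inhibitors: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.shape not in TERM_SHAPES:
            raise ModelValidationError(f"unknown term shape {self.shape!r}")
        if self.shape == "input_drive" and not self.driver:
            raise ModelValidationError("input_drive term requires a driver input")
        if self.shape == "decay" and not self.decay_of:
            raise ModelValidationError("decay term requires decay_of")
        if self.shape == "activation" and self.decay_of:
            raise ModelValidationError("activation term must not set decay_of")

    def referenced_species(self) -> set[str]:
        names = set(self.factors)
        names.update(s for s, _ in self.accelerators)
        names.update(s for s, _ in self.decay_inhibitors)
        if self.decay_of:
            names.add(self.decay_of)
        return names

    def referenced_parameters(self) -> set[str]:
        names = {self.rate_constant}
        names.update(f for _, f in self.accelerators)
        names.update(f for _, f in self.decay_inhibitors)
        return names


@dataclass
class ParameterSet:
    """Named rate constants (k) and binding constants (F) with a sampling box.

    All k and F values must fall inside ``interval`` (default ``[0, 5]``);
    the two input amplification factors are unconstrained positive reals.
    """

    rate_constants: dict[str, float] = field(default_factory=dict)
    binding_constants: dict[str, float] = field(default_factory=dict)
    amplify1: float = 1.5
    amplify2: float = 1.5
    interval: tuple[float, float] = (0.0, 5.0)

    def __post_init__(self) -> None:
        lo, hi = self.interval
        for group_name, group in (
            ("rate", self.rate_constants),
            ("binding", self.binding_constants),
        ):
            for name, value in group.items():
                if not math.isfinite(value):
                    raise ModelValidationError(
                        f"{group_name} constant {name!r} is not finite"
                    )
                if not (lo <= value <= hi):
                    raise ModelValidationError(
                        f"{group_name} constant {name!r}={value} outside "
                        f"sampling interval [{lo}, {hi}]"
                    )
        if self.amplify1 <= 0 or self.amplify2 <= 0:
            raise ModelValidationError("amplify1/amplify2 must be positive")

    def rate(self, name: str) -> float:
        try:
            return self.rate_constants[name]
        except KeyError:
            raise KeyError(f"unknown rate constant {name!r}") from None

    def binding(self, name: str) -> float:
        try:
            return self.binding_constants[name]
        except KeyError:
            raise KeyError(f"unknown binding constant {name!r}") from None

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            rate_constants=dict(self.rate_constants),
            binding_constants=dict(self.binding_constants),
            amplify1=self.amplify1,
            amplify2=self.amplify2,
            interval=self.interval,
        )


@dataclass(frozen=True)
class ReadoutDef:
    """Derived trajectory: a species, a ratio of species, or an input flux.

    ``phospho_ratio`` is phospho / (phospho + total_partner); ``raw_ratio``
    is numerator / denominator as printed (may exceed 1); ``input_flux`` is
    the instantaneous value of a named species' input_drive term.
    """

    kind: str
    species: str | None = None
    phospho: str | None = None
    total_partner: str | None = None
    numerator: str | None = None
    denominator: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in READOUT_KINDS:
            raise ModelValidationError(f"unknown readout kind {self.kind!r}")

    def referenced_species(self) -> set[str]:
        return {
            s
            for s in (
                self.species,
                self.phospho,
                self.total_partner,
                self.numerator,
                self.denominator,
            )
            if s
        }


@dataclass
class ModelSpec:
    """A validated network: species registry, terms, parameters, readouts."""

    species: list[SpeciesState]
    terms: dict[str, list[RateTerm]]
    parameters: ParameterSet
    inputs: set[str] = field(default_factory=lambda: {"u1", "u2"})
    readout_definitions: dict[str, ReadoutDef] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- registry helpers -------------------------------------------------
    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def species_index(self) -> dict[str, int]:
        return {s.name: i for i, s in enumerate(self.species)}

    def species_by_name(self, name: str) -> SpeciesState:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(f"unknown species {name!r}")

    def initial_state(self) -> dict[str, float]:
        return {s.name: s.value for s in self.species}

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([s.lower_bound for s in self.species])
        hi = np.array([s.upper_bound for s in self.species])
        return lo, hi

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        names = self.species_names
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ModelValidationError(f"duplicate species: {dupes}")
        registry = set(names)

        for sp_name in self.terms:
            if sp_name not in registry:
                raise ModelValidationError(
                    f"terms declared for unknown species {sp_name!r}"
                )
        for sp in self.species:
            term_list = self.terms.get(sp.name, [])
            if not term_list:
                raise ModelValidationError(
                    f"species {sp.name!r} has no rate terms (orphan state)"
                )
            for term in term_list:
                unknown = term.referenced_species() - registry
                if unknown:
                    raise ModelValidationError(
                        f"term {term.rate_constant!r} of species {sp.name!r} "
                        f"references undeclared species {sorted(unknown)}"
                    )
                if term.shape == "input_drive" and term.driver not in self.inputs:
                    raise ModelValidationError(
                        f"term {term.rate_constant!r} of species {sp.name!r} "
                        f"references undeclared input {term.driver!r}"
                    )
                for pname in term.referenced_parameters():
                    if (
                        pname not in self.parameters.rate_constants
                        and pname not in self.parameters.binding_constants
                    ):
                        raise ModelValidationError(
                            f"term of species {sp.name!r} references "
                            f"undeclared parameter {pname!r}"
                        )
        for rname, rdef in self.readout_definitions.items():
            unknown = rdef.referenced_species() - registry
            if unknown:
                raise ModelValidationError(
                    f"readout {rname!r} references undeclared species "
                    f"{sorted(unknown)}"
                )
            if rdef.kind == "input_flux":
                flux_terms = [
                    t
                    for t in self.terms.get(rdef.species or "", [])
                    if t.shape == "input_drive"
                ]
                if not flux_terms:
                    raise ModelValidationError(
                        f"readout {rname!r}: species {rdef.species!r} has no "
                        "input_drive term to report as a flux"
                    )

    def with_parameters(self, parameters: ParameterSet) -> "ModelSpec":
        return ModelSpec(
            species=list(self.species),
            terms={k: list(v) for k, v in self.terms.items()},
            parameters=parameters,
            inputs=set(self.inputs),
            readout_definitions=dict(self.readout_definitions),
        )


# ---------------------------------------------------------------------------
# term evaluation
# ---------------------------------------------------------------------------

def evaluate_term(
    term: RateTerm,
    state: Mapping[str, float],
    inputs: Mapping[str, float],
    params: ParameterSet,
) -> float:
    """Signed contribution of one term (AU per time); decay terms < 0.

    Pure function of its arguments; raises ``KeyError`` on a missing
    species or input.
    """
    k = params.rate(term.rate_constant)
    if term.shape == "input_drive":
        try:
            u = inputs[term.driver]
        except KeyError:
            raise KeyError(f"missing input {term.driver!r}") from None
        return k * u
    if term.shape == "activation":
        value = k
        for name in term.factors:
            value *= _lookup(state, name)
        for name, f_name in term.accelerators:
            value *= 1.0 + params.binding(f_name) * _lookup(state, name)
        return value
    # decay
    value = k * _lookup(state, term.decay_of)
    for name in term.factors:
        value *= _lookup(state, name)
    for name, f_name in term.decay_inhibitors:
        value /= 1.0 + params.binding(f_name) * _lookup(state, name)
    return -value


def _lookup(state: Mapping[str, float], name: str) -> float:
    try:
        return state[name]
    except KeyError:
        raise KeyError(f"missing species {name!r}") from None


# ---------------------------------------------------------------------------
# RHS compilation
# ---------------------------------------------------------------------------

InputFunction = Callable[[float, np.ndarray], Mapping[str, float]]


def build_rhs(
    model: ModelSpec,
    input_fn: InputFunction | None = None,
    compiled: bool = True,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Compile the model into ``f(t, y) -> dy/dt`` over the species vector.

    ``input_fn(t, y)`` must return a mapping of input name to value; when
    omitted every input is held at zero.  The derivative of each species is
    the plain sum of its terms, so evaluation order is irrelevant.

    The default path generates straight-line source for the whole vector
    field (one expression per species) and ``exec``-compiles it; with
    ``compiled=False`` a term-by-term interpreter is used instead.  Both
    evaluate the identical term grammar and are cross-checked in the test
    suite.
    """
    if compiled:
        return _build_rhs_codegen(model, input_fn)
    return _build_rhs_interpreted(model, input_fn)


def _build_rhs_interpreted(
    model: ModelSpec,
    input_fn: InputFunction | None = None,
) -> Callable[[float, np.ndarray], np.ndarray]:
    index = model.species_index()
    names = model.species_names
    params = model.parameters
    n = len(names)

    # Pre-resolve term structure into index-based closures for speed.
    compiled: list[list[tuple]] = [[] for _ in range(n)]
    for sp_name, term_list in model.terms.items():
        i = index[sp_name]
        for term in term_list:
            k = params.rate(term.rate_constant)
            if term.shape == "input_drive":
                compiled[i].append(("u", k, term.driver))
            elif term.shape == "activation":
                fac = tuple(index[f] for f in term.factors)
                acc = tuple(
                    (index[s], params.binding(f)) for s, f in term.accelerators
                )
                compiled[i].append(("a", k, fac, acc))
            else:
                fac = tuple(index[f] for f in term.factors)
                inh = tuple(
                    (index[s], params.binding(f)) for s, f in term.decay_inhibitors
                )
                compiled[i].append(("d", k, index[term.decay_of], fac, inh))

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        u = input_fn(t, y) if input_fn is not None else {}
        dy = np.zeros(n)
        for i in range(n):
            total = 0.0
            for entry in compiled[i]:
                kind = entry[0]
                if kind == "u":
                    _, k, driver = entry
                    total += k * u.get(driver, 0.0)
                elif kind == "a":
                    _, k, fac, acc = entry
                    v = k
                    for j in fac:
                        v *= y[j]
                    for j, f in acc:
                        v *= 1.0 + f * y[j]
                    total += v
                else:
                    _, k, j0, fac, inh = entry
                    v = k * y[j0]
                    for j in fac:
                        v *= y[j]
                    for j, f in inh:
                        v /= 1.0 + f * y[j]
                    total -= v
            if not math.isfinite(total):
                raise FloatingPointError(
                    f"non-finite derivative for species {names[i]!r} at t={t}"
                )
            dy[i] = total
        return dy

    return rhs


# Compiled kernels are cached by generated source, which depends only on
# the term *structure*; swapping parameter values reuses the same kernel
# (crucial during calibration, where numba would otherwise recompile per
# candidate).
_KERNEL_CACHE: dict[str, Callable] = {}
_NUMBA_MIN_SPECIES = 16


def _generate_kernel(model: ModelSpec) -> tuple[str, list[float], list[str]]:
    """Emit ``_rhs(t, y, u, p, out)`` source plus the packed parameter
    vector and the sorted driver order for the ``u`` array."""
    index = model.species_index()
    names = model.species_names
    params = model.parameters
    drivers = sorted(
        {
            term.driver
            for terms in model.terms.values()
            for term in terms
            if term.shape == "input_drive"
        }
    )
    driver_pos = {d: i for i, d in enumerate(drivers)}
    packed: list[float] = []

    def p(value: float) -> str:
        packed.append(float(value))
        return f"p[{len(packed) - 1}]"

    lines = ["def _rhs(t, y, u, p, out):"]
    for i, sp_name in enumerate(names):
        pieces = []
        for term in model.terms.get(sp_name, []):
            k = p(params.rate(term.rate_constant))
            if term.shape == "input_drive":
                pieces.append(f"{k}*u[{driver_pos[term.driver]}]")
            elif term.shape == "activation":
                expr = [k]
                expr += [f"y[{index[f]}]" for f in term.factors]
                expr += [
                    f"(1.0+{p(params.binding(fn))}*y[{index[s]}])"
                    for s, fn in term.accelerators
                ]
                pieces.append("*".join(expr))
            else:
                expr = [k, f"y[{index[term.decay_of]}]"]
                expr += [f"y[{index[f]}]" for f in term.factors]
                numer = "*".join(expr)
                if term.decay_inhibitors:
                    denom = "*".join(
                        f"(1.0+{p(params.binding(fn))}*y[{index[s]}])"
                        for s, fn in term.decay_inhibitors
                    )
                    pieces.append(f"-({numer})/({denom})")
                else:
                    pieces.append(f"-({numer})")
        joined = " + ".join(pieces) if pieces else "0.0"
        lines.append(f"    out[{i}] = {joined}")
    lines.append("    return out")
    return "\n".join(lines), packed, drivers


def _compile_kernel(source: str, n_species: int) -> Callable:
    kernel = _KERNEL_CACHE.get(source)
    if kernel is not None:
        return kernel
    namespace: dict = {}
    exec(source, namespace)  # noqa: S102 - generated from validated terms
    kernel = namespace["_rhs"]
    if n_species >= _NUMBA_MIN_SPECIES:
        try:
            import numba

            kernel = numba.njit(cache=False)(kernel)
        except ImportError:  # pragma: no cover - numba is a soft dependency
            pass
    _KERNEL_CACHE[source] = kernel
    return kernel


def _build_rhs_codegen(
    model: ModelSpec,
    input_fn: InputFunction | None = None,
) -> Callable[[float, np.ndarray], np.ndarray]:
    names = model.species_names
    n = len(names)
    source, packed, drivers = _generate_kernel(model)
    kernel = _compile_kernel(source, n)
    p_vec = np.array(packed)
    n_drivers = len(drivers)
    zero_u = np.zeros(n_drivers)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        if input_fn is None or n_drivers == 0:
            u_vec = zero_u
        else:
            u = input_fn(t, y)
            u_vec = np.empty(n_drivers)
            for i, d in enumerate(drivers):
                u_vec[i] = u.get(d, 0.0)
        out = np.empty(n)
        kernel(t, y, u_vec, p_vec, out)
        # cheap screen: any NaN/Inf component makes the sum non-finite
        if not math.isfinite(out.sum()):
            bad = names[int(np.argmax(~np.isfinite(out)))]
            raise FloatingPointError(
                f"non-finite derivative for species {bad!r} at t={t}"
            )
        return out

    return rhs


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def parse_model_spec(document: str | Path | Mapping) -> ModelSpec:
    """Parse and validate a YAML model document (text, path, or mapping)."""
    data = _load_document(document)
    for section in ("species", "terms", "parameters"):
        if section not in data:
            raise ModelValidationError(f"model document missing {section!r} section")

    species = [_parse_species(entry) for entry in data["species"]]
    terms = {
        sp_name: [_parse_term(sp_name, t) for t in term_list]
        for sp_name, term_list in data["terms"].items()
    }
    parameters = _parse_parameters(data["parameters"])
    inputs = set(data.get("inputs", ["u1", "u2"]))
    readouts = {
        name: _parse_readout(name, entry)
        for name, entry in data.get("readouts", {}).items()
    }
    return ModelSpec(
        species=species,
        terms=terms,
        parameters=parameters,
        inputs=inputs,
        readout_definitions=readouts,
    )


def _load_document(document: str | Path | Mapping) -> dict:
    if isinstance(document, Mapping):
        return dict(document)
    if isinstance(document, Path):
        text = document.read_text()
    else:
        text = str(document)
        candidate = Path(text)
        try:
            if candidate.exists() and candidate.is_file():
                text = candidate.read_text()
        except OSError:
            pass
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ModelValidationError("model document is not a mapping")
    return data


def _parse_species(entry: Mapping) -> SpeciesState:
    if isinstance(entry, str):
        return SpeciesState(name=entry)
    bounds = entry.get("bounds", [0.0, 25.0])
    return SpeciesState(
        name=entry["name"],
        role=entry.get("role", "insulin_cascade"),
        value=float(entry.get("init", 1.05)),
        lower_bound=float(bounds[0]),
        upper_bound=float(bounds[1]),
    )


def _parse_pairs(raw: Iterable) -> tuple[tuple[str, str], ...]:
    pairs = []
    for item in raw:
        if isinstance(item, Mapping):
            pairs.append((item["species"], item["F"]))
        else:
            sp, f = item
            pairs.append((str(sp), str(f)))
    return tuple(pairs)


def _parse_term(sp_name: str, entry: Mapping) -> RateTerm:
    shape = entry.get("shape")
    if shape not in TERM_SHAPES:
        raise ModelValidationError(
            f"species {sp_name!r}: unknown term shape {shape!r}"
        )
    return RateTerm(
        shape=shape,
        rate_constant=entry["k"],
        driver=entry.get("driver"),
        factors=tuple(entry.get("factors", ())),
        accelerators=_parse_pairs(entry.get("accelerators", ())),
        decay_of=entry.get("of") if shape == "decay" else None,
        decay_inhibitors=_parse_pairs(entry.get("inhibitors", ())),
    )


def _parse_parameters(entry: Mapping) -> ParameterSet:
    interval = tuple(entry.get("interval", (0.0, 5.0)))
    return ParameterSet(
        rate_constants={k: float(v) for k, v in entry.get("rate_constants", {}).items()},
        binding_constants={
            k: float(v) for k, v in entry.get("binding_constants", {}).items()
        },
        amplify1=float(entry.get("amplify1", 1.5)),
        amplify2=float(entry.get("amplify2", 1.5)),
        interval=(float(interval[0]), float(interval[1])),
    )


def _parse_readout(name: str, entry: Mapping) -> ReadoutDef:
    if isinstance(entry, str):
        return ReadoutDef(kind="species", species=entry)
    return ReadoutDef(
        kind=entry["kind"],
        species=entry.get("species"),
        phospho=entry.get("phospho"),
        total_partner=entry.get("total"),
        numerator=entry.get("numerator"),
        denominator=entry.get("denominator"),
    )
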