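"""Compartmental model definitions.

The centrepiece is the deterministic SEIR system with recruitment and
natural/disease-induced mortality under frequency-dependent incidence:

    dS/dt = Omega - beta*I*S/N - mu*S
    dE/dt = beta*I*S/N - (alpha + mu)*E
    dI/dt = alpha*E - (gamma + sigma + mu)*I
    dR/dt = gamma*I - mu*R

where ``N`` is the population size appearing in the incidence denominator.
Two conventions for ``N`` are supported: frozen at its initial value (the
default, matching the common practice of computing ``N = S+E+I+R`` once
before integrating) or recomputed dynamically at every evaluation.

Beyond the hand-coded SEIR right-hand side, the module provides a small
flow-based model builder (:class:`ModelSpec`, :func:`compile_model`) covering
the classic family SI, SIS, SIR, SIRV and SEIR, so that users can declare
their own compartment/flow structures without writing derivative code.
"""

from __future__ import annotations

import ast
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .errors import DomainError, ModelSpecError

__all__ = [
    "BIRTH",
    "DEATH",
    "CompartmentalModel",
    "Flow",
    "ModelSpec",
    "ParameterSet",
    "StateVector",
    "builtin_models",
    "get_model",
    "get_parameter_set",
    "PARAMETER_SETS",
    "seir_rhs",
]

#: Pseudo-compartments marking demographic inflow and outflow in a ModelSpec.
BIRTH = "BIRTH"
DEATH = "DEATH"

#: Slack allowed on "non-negative" state components; adaptive integration can
#: legitimately undershoot zero by rounding-level amounts.
NEGATIVE_SLACK = -1e-9


@dataclass(frozen=True)
class ParameterSet:
    """Rates of the SEIR system, all per day and non-negative.

    Attributes
    ----------
    recruitment : float
        Inflow of new susceptibles, Omega (individuals/day).
    transmission : float
        Effective contact rate beta (1/day).
    natural_death : float
        Background mortality mu applied to every compartment (1/day).
    progression : float
        Rate alpha at which exposed individuals become infectious (1/day).
    recovery : float
        Recovery rate gamma of infectious individuals (1/day).
    disease_death : float
        Disease-induced mortality sigma on the infectious class (1/day).
    """

    recruitment: float = 0.0
    transmission: float = 0.0
    natural_death: float = 0.0
    progression: float = 0.0
    recovery: float = 0.0
    disease_death: float = 0.0

    def __post_init__(self):
        for name, value in self.symbols().items():
            if not math.isfinite(value):
                raise DomainError(f"parameter {name} must be finite, got {value!r}")
            if value < 0:
                raise DomainError(f"parameter {name} must be >= 0, got {value!r}")

    def symbols(self) -> dict[str, float]:
        """Mapping from conventional symbol names to values, usable in flow
        rate expressions (``Omega, beta, mu, alpha, gamma, sigma``)."""
        return {
            "Omega": float(self.recruitment),
            "beta": float(self.transmission),
            "mu": float(self.natural_death),
            "alpha": float(self.progression),
            "gamma": float(self.recovery),
            "sigma": float(self.disease_death),
        }


#: Named parameter sets. ``code_default`` carries the reference-script values
#: that produced the published trajectories; ``table1`` the tabulated values
#: (which differ in recruitment and transmission rate). Both ship because the
#: source material is internally inconsistent; picking one silently would hide
#: that.
PARAMETER_SETS: dict[str, ParameterSet] = {
    "code_default": ParameterSet(
        recruitment=20.0,
        transmission=0.3,
        natural_death=0.00004252912,
        progression=0.3,
        recovery=0.1,
        disease_death=0.003286,
    ),
    "table1": ParameterSet(
        recruitment=29.08,
        transmission=0.9,
        natural_death=0.4252912e-4,
        progression=0.3,
        recovery=0.1,
        disease_death=0.003286,
    ),
}


def get_parameter_set(name: str) -> ParameterSet:
    """Look up a named parameter set (``"code_default"`` or ``"table1"``)."""
    try:
        return PARAMETER_SETS[name]
    except KeyError:
        raise KeyError(
            f"unknown parameter set {name!r}; available: {sorted(PARAMETER_SETS)}"
        ) from None


@dataclass(frozen=True)
class StateVector:
    """Compartment sizes (S, E, I, R) as continuous non-negative reals."""

    S: float
    E: float
    I: float
    R: float

    def __post_init__(self):
        for name in ("S", "E", "I", "R"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise DomainError(f"state component {name} must be finite, got {v!r}")
            if v < NEGATIVE_SLACK:
                raise DomainError(f"state component {name} must be >= 0, got {v!r}")

    @property
    def total(self) -> float:
        return self.S + self.E + self.I + self.R

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.E, self.I, self.R], dtype=float)


def _as_state_array(state) -> np.ndarray:
    if isinstance(state, StateVector):
        return state.as_array()
    arr = np.asarray(state, dtype=float)
    if arr.shape != (4,):
        raise DomainError(f"SEIR state must have 4 components, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise DomainError(f"state must be finite, got {arr!r}")
    if np.any(arr < NEGATIVE_SLACK):
        raise DomainError(f"state components must be >= {NEGATIVE_SLACK}, got {arr!r}")
    return arr


def seir_rhs(t: float, state, params: ParameterSet, n_ref: float) -> np.ndarray:
    """Time derivative of the SEIR system.

    Parameters
    ----------
    t : float
        Time in days. The system is autonomous; ``t`` does not enter the
        result but is accepted for ODE-solver compatibility.
    state : StateVector or array-like of shape (4,)
        Current compartment sizes (S, E, I, R).
    params : ParameterSet
        The six rates.
    n_ref : float
        Population size used in the incidence denominator; must be positive.

    Returns
    -------
    numpy.ndarray
        ``(dS, dE, dI, dR)`` in individuals/day.
    """
    if not (math.isfinite(n_ref) and n_ref > 0):
        raise DomainError(f"n_ref must be positive and finite, got {n_ref!r}")
    S, E, I, R = _as_state_array(state)
    p = params.symbols()
    incidence = p["beta"] * I * S / n_ref
    dS = p["Omega"] - incidence - p["mu"] * S
    dE = incidence - (p["alpha"] + p["mu"]) * E
    dI = p["alpha"] * E - (p["gamma"] + p["sigma"] + p["mu"]) * I
    dR = p["gamma"] * I - p["mu"] * R
    return np.array([dS, dE, dI, dR])


# ---------------------------------------------------------------------------
# Flow-based model builder
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Flow:
    """A single flow between compartments (or BIRTH/DEATH) at a given rate.

    ``rate`` is an arithmetic expression over declared compartment labels,
    declared parameter names, and ``N`` (the incidence population size).
    """

    source: str
    target: str
    rate: str


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of a compartmental model as a list of flows."""

    name: str
    compartments: tuple[str, ...]
    parameters: tuple[str, ...]
    flows: tuple[Flow, ...]
    incidence_n_mode: str = "fixed_at_initial"  # or "dynamic"

    def __post_init__(self):
        object.__setattr__(self, "compartments", tuple(self.compartments))
        object.__setattr__(self, "parameters", tuple(self.parameters))
        object.__setattr__(self, "flows", tuple(self.flows))
        self.validate()

    def validate(self) -> None:
        if len(set(self.compartments)) != len(self.compartments):
            raise ModelSpecError(f"duplicate compartment label in {self.compartments}")
        if self.incidence_n_mode not in ("fixed_at_initial", "dynamic"):
            raise ModelSpecError(
                f"incidence_n_mode must be 'fixed_at_initial' or 'dynamic', "
                f"got {self.incidence_n_mode!r}"
            )
        reserved = {BIRTH, DEATH, "N", "t"}
        clash = reserved & set(self.compartments) | reserved & set(self.parameters)
        if clash:
            raise ModelSpecError(f"reserved names used as labels/parameters: {clash}")
        allowed = set(self.compartments) | set(self.parameters) | {"N", "t"}
        for flow in self.flows:
            for endpoint in (flow.source, flow.target):
                if endpoint not in (BIRTH, DEATH) and endpoint not in self.compartments:
                    raise ModelSpecError(
                        f"flow endpoint {endpoint!r} is not a declared compartment"
                    )
            if flow.source == BIRTH and flow.target == DEATH:
                raise ModelSpecError("flow from BIRTH to DEATH is meaningless")
            for symbol in _expression_symbols(flow.rate):
                if symbol not in allowed:
                    raise ModelSpecError(
                        f"undeclared symbol {symbol!r} in rate expression {flow.rate!r}"
                    )


_ALLOWED_AST_NODES = (
    ast.Expression, ast.BinOp, ast.UnaryOp, ast.Constant, ast.Name, ast.Load,
    ast.Add, ast.Sub, ast.Mult, ast.Div, ast.Pow, ast.USub, ast.UAdd,
)


def _expression_symbols(expr: str) -> set[str]:
    """Names referenced by a rate expression; rejects anything but arithmetic."""
    try:
        tree = ast.parse(expr, mode="eval")
    except SyntaxError as exc:
        raise ModelSpecError(f"invalid rate expression {expr!r}: {exc}") from None
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_AST_NODES):
            raise ModelSpecError(
                f"rate expression {expr!r} uses disallowed syntax "
                f"({type(node).__name__}); only +,-,*,/,** and names are allowed"
            )
    return {n.id for n in ast.walk(tree) if isinstance(n, ast.Name)}


@dataclass
class CompartmentalModel:
    """A compiled model: labels plus an evaluable right-hand side.

    The compiled function has signature ``f(t, y, pvals, N) -> tuple`` where
    ``y`` iterates compartment values in label order and ``pvals`` parameter
    values in declared order. Use :meth:`rhs` for a validated array interface
    or :meth:`bind` to close over parameters for an integrator hot loop.
    """

    spec: ModelSpec
    _compiled: Callable = field(repr=False)

    @property
    def labels(self) -> tuple[str, ...]:
        return self.spec.compartments

    @property
    def dimension(self) -> int:
        return len(self.spec.compartments)

    def _param_values(self, params) -> tuple[float, ...]:
        if isinstance(params, ParameterSet):
            mapping: Mapping[str, float] = params.symbols()
        elif params is None:
            mapping = {}
        else:
            mapping = params
        try:
            return tuple(float(mapping[name]) for name in self.spec.parameters)
        except KeyError as exc:
            raise DomainError(
                f"missing parameter {exc.args[0]!r} for model {self.spec.name!r}"
            ) from None

    def rhs(self, t: float, y, params, n_ref: float | None = None) -> np.ndarray:
        """Evaluate the right-hand side at ``(t, y)``.

        ``n_ref=None`` uses the current total population (dynamic N).
        """
        arr = np.asarray(y, dtype=float)
        n = float(arr.sum()) if n_ref is None else float(n_ref)
        if "N" in self._needs_n and n <= 0:
            raise DomainError(f"incidence population N must be positive, got {n!r}")
        return np.array(self._compiled(t, tuple(arr), self._param_values(params), n))

    @property
    def _needs_n(self) -> set[str]:
        return {
            s for f in self.spec.flows for s in _expression_symbols(f.rate)
        } & {"N"}

    def bind(self, params, n_ref: float | None = None) -> Callable[[float, np.ndarray], np.ndarray]:
        """Return ``f(t, y) -> ndarray`` with parameters fixed.

        If ``n_ref`` is None and the model's ``incidence_n_mode`` is
        ``"dynamic"``, N is recomputed as ``sum(y)`` at every evaluation;
        otherwise the caller must fix it (``integrate`` fixes it to the
        initial total for ``fixed_at_initial`` models).
        """
        pvals = self._param_values(params)
        compiled = self._compiled
        if n_ref is not None:
            n = float(n_ref)
            if n <= 0:
                raise DomainError(f"n_ref must be positive, got {n_ref!r}")

            def f(t, y, _c=compiled, _p=pvals, _n=n):
                return np.array(_c(t, tuple(y), _p, _n))
        else:
            def f(t, y, _c=compiled, _p=pvals):
                return np.array(_c(t, tuple(y), _p, float(np.sum(y))))
        return f


def compile_model(spec: ModelSpec) -> CompartmentalModel:
    """Compile a :class:`ModelSpec` into an evaluable model.

    The derivative of each compartment is the sum of its in-flow rates minus
    the sum of its out-flow rates; BIRTH flows only add, DEATH flows only
    subtract.
    """
    spec.validate()
    terms: dict[str, list[str]] = {c: [] for c in spec.compartments}
    for flow in spec.flows:
        rate = f"({flow.rate})"
        if flow.source != BIRTH:
            terms[flow.source].append(f"- {rate}")
        if flow.target != DEATH:
            terms[flow.target].append(f"+ {rate}")

    body = ", ".join(
        " ".join(ts) if ts else "0.0" for ts in (terms[c] for c in spec.compartments)
    )
    unpack_y = ", ".join(spec.compartments) if spec.compartments else "*_unused_y"
    unpack_p = ", ".join(spec.parameters) if spec.parameters else "*_unused_p"
    src = (
        f"def _rhs(t, _y, _p, N):\n"
        f"    ({unpack_y},) = _y\n"
        f"    ({unpack_p},) = _p\n"
        f"    return ({body}{',' if spec.compartments else ''})\n"
    )
    namespace: dict = {}
    exec(compile(src, f"<model:{spec.name}>", "exec"), namespace)  # noqa: S102
    return CompartmentalModel(spec=spec, _compiled=namespace["_rhs"])


def _demography(compartments: tuple[str, ...]) -> list[Flow]:
    """Recruitment into the first compartment, natural death from all."""
    flows = [Flow(BIRTH, compartments[0], "Omega")]
    flows += [Flow(c, DEATH, f"mu * {c}") for c in compartments]
    return flows


def builtin_models() -> dict[str, ModelSpec]:
    """The classic compartmental family as flow specifications.

    All models use frequency-dependent incidence ``beta*S*I/N``, recruitment
    ``Omega`` into S and natural death ``mu`` from every compartment;
    infectious individuals additionally die at rate ``sigma``. ``seir`` is
    the reference system of this package; the others are conventional
    textbook forms. ``sirv`` adds vaccination of susceptibles at rate ``nu``.
    """
    base_params = ("Omega", "beta", "mu", "alpha", "gamma", "sigma")
    incidence = Flow("S", "I", "beta * S * I / N")

    si = ModelSpec(
        name="si",
        compartments=("S", "I"),
        parameters=base_params,
        flows=tuple(_demography(("S", "I")) + [incidence, Flow("I", DEATH, "sigma * I")]),
    )
    sis = ModelSpec(
        name="sis",
        compartments=("S", "I"),
        parameters=base_params,
        flows=tuple(
            _demography(("S", "I"))
            + [incidence, Flow("I", "S", "gamma * I"), Flow("I", DEATH, "sigma * I")]
        ),
    )
    sir = ModelSpec(
        name="sir",
        compartments=("S", "I", "R"),
        parameters=base_params,
        flows=tuple(
            _demography(("S", "I", "R"))
            + [incidence, Flow("I", "R", "gamma * I"), Flow("I", DEATH, "sigma * I")]
        ),
    )
    sirv = ModelSpec(
        name="sirv",
        compartments=("S", "I", "R", "V"),
        parameters=base_params + ("nu",),
        flows=tuple(
            _demography(("S", "I", "R", "V"))
            + [
                incidence,
                Flow("I", "R", "gamma * I"),
                Flow("I", DEATH, "sigma * I"),
                Flow("S", "V", "nu * S"),
            ]
        ),
    )
    seir = ModelSpec(
        name="seir",
        compartments=("S", "E", "I", "R"),
        parameters=base_params,
        flows=tuple(
            _demography(("S", "E", "I", "R"))
            + [
                Flow("S", "E", "beta * S * I / N"),
                Flow("E", "I", "alpha * E"),
                Flow("I", "R", "gamma * I"),
                Flow("I", DEATH, "sigma * I"),
            ]
        ),
    )
    return {m.name: m for m in (si, sis, sir, sirv, seir)}


def get_model(name: str, incidence_n_mode: str | None = None) -> CompartmentalModel:
    """Compile a built-in model by name, optionally overriding the N mode."""
    specs = builtin_models()
    try:
        spec = specs[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(specs)}"
        ) from None
    if incidence_n_mode is not None and incidence_n_mode != spec.incidence_n_mode:
        spec = ModelSpec(
            name=spec.name,
            compartments=spec.compartments,
            parameters=spec.parameters,
            flows=spec.flows,
            incidence_n_mode=incidence_n_mode,
        )
    return compile_model(spec)
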