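"""Decision-making topologies and stress-phase generator matrices.

Three schemes describe how a population of *Bacillus subtilis* cells
progresses from the vegetative state to the spore state:

``irreversible_only``
    Cells decide in a single irreversible step: V -> D -> S.
``reversible_only``
    Cells drift through reversible intermediates all the way to the
    decided state: V <-> I1 <-> I2 <-> D, then D -> S.
``hybrid``
    Reversible early progression with an irreversible commitment step:
    V <-> I1 <-> I2, then I2 -> D -> S (both irreversible).

Each scheme, together with stress-phase-specific rates, defines a linear
ODE ``dN/dt = M N`` for the vector of per-state cell counts.  ``M`` is a
Metzler matrix (nonnegative off-diagonal), so nonnegative populations stay
nonnegative; its column sums equal the per-state net growth rate, the only
non-conservative term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "PHASES",
    "MODEL_NAMES",
    "Edge",
    "ModelTopology",
    "RateParameters",
    "GeneratorMatrix",
    "make_topology",
    "default_parameters",
    "build_generator",
    "validate_parameters",
    "perturb_parameters",
    "params_to_dict",
    "params_from_dict",
    "save_parameters",
    "load_parameters",
]

#: Stress phases of the dichotomic environment.
PHASES = ("high", "low")

MODEL_NAMES = ("irreversible_only", "reversible_only", "hybrid")

SPORE_STATE = "S"


@dataclass(frozen=True)
class Edge:
    """A directed transition between two cell states."""

    src: str
    dst: str
    reversible: bool = False

    @property
    def key(self) -> str:
        return f"{self.src}->{self.dst}"


@dataclass(frozen=True)
class ModelTopology:
    """Named decision scheme: ordered states plus directed transitions."""

    name: str
    states: tuple[str, ...]
    edges: tuple[Edge, ...]

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise ValueError("state labels must be unique")
        declared = set(self.states)
        for e in self.edges:
            if e.src not in declared or e.dst not in declared:
                raise ValueError(f"edge {e.key} references an undeclared state")
            if e.src == SPORE_STATE or (e.reversible and e.dst == SPORE_STATE):
                raise ValueError("the spore state S must be absorbing")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        return self.states.index(state)


_TOPOLOGIES = {
    "irreversible_only": ModelTopology(
        "irreversible_only",
        ("V", "D", "S"),
        (Edge("V", "D"), Edge("D", "S")),
    ),
    "reversible_only": ModelTopology(
        "reversible_only",
        ("V", "I1", "I2", "D", "S"),
        (
            Edge("V", "I1", reversible=True),
            Edge("I1", "I2", reversible=True),
            Edge("I2", "D", reversible=True),
            Edge("D", "S"),
        ),
    ),
    "hybrid": ModelTopology(
        "hybrid",
        ("V", "I1", "I2", "D", "S"),
        (
            Edge("V", "I1", reversible=True),
            Edge("I1", "I2", reversible=True),
            Edge("I2", "D"),
            Edge("D", "S"),
        ),
    ),
}


def make_topology(name: str) -> ModelTopology:
    """Return one of the three decision-making topologies by name.

    Raises
    ------
    ValueError
        If ``name`` is not one of :data:`MODEL_NAMES`.
    """
    try:
        return _TOPOLOGIES[name]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; valid names: {', '.join(MODEL_NAMES)}"
        ) from None


RateMap = dict[str, dict[str, float]]  # edge-key or state -> phase -> 1/h


@dataclass
class RateParameters:
    """Stress-phase-dependent rates for one topology.

    All entries are per hour.  ``forward[edge][phase]`` is the rate of the
    edge's forward direction, ``backward[edge][phase]`` the reverse rate
    (reversible edges only), ``growth[state][phase]`` the net per-capita
    growth-minus-death rate.  Spores neither grow nor die: ``growth["S"]``
    is fixed at zero in both phases.
    """

    forward: RateMap
    backward: RateMap = field(default_factory=dict)
    growth: RateMap = field(default_factory=dict)

    def copy(self) -> "RateParameters":
        return RateParameters(
            forward={k: dict(v) for k, v in self.forward.items()},
            backward={k: dict(v) for k, v in self.backward.items()},
            growth={k: dict(v) for k, v in self.growth.items()},
        )


def default_parameters(
    topology: ModelTopology,
    *,
    forward_high: float = 0.3,
    forward_low: float = 0.1,
    backward_low: float = 1.0,
    backward_high: float = 0.05,
    commitment_high: float | None = None,
    commitment_low: float | None = None,
    spore_rate: float = 1.0,
    growth_low: float = 0.5,
    growth_high: float = -0.5,
) -> RateParameters:
    """Reference parameterization for a topology.

    Stress coupling: forward (toward-spore) rates are fast under high
    stress and slow under low stress; backward rates the reverse; net
    growth is positive in the low-stress (rich) phase and negative in the
    high-stress (poor) phase for every non-spore state.  The decided-state
    D -> S conversion proceeds at ``spore_rate`` in both phases.

    The final step into the decided state D may carry its own rate
    (``commitment_high``/``commitment_low``; defaults fall back to the
    per-step forward rate): commitment is the decisive step and can be
    slower than the drift through the early reversible states.

    The irreversible-only scheme collapses the multi-step chain into a
    single V -> D step whose rate matches the chain's forward mean
    first-passage time under sustained stress of the same phase (for a
    uniform three-step chain this is one third of the per-step rate).
    """
    if commitment_high is None:
        commitment_high = forward_high
    if commitment_low is None:
        commitment_low = forward_low
    forward: RateMap = {}
    backward: RateMap = {}
    # MFPT-matched single-step rates for the collapsed chain; a zero rate
    # anywhere in the chain means an infinite passage time (rate 0)
    def _collapsed(step: float, commit: float) -> float:
        if step <= 0.0 or commit <= 0.0:
            return 0.0
        return 1.0 / (2.0 / step + 1.0 / commit)

    collapsed = {
        "high": _collapsed(forward_high, commitment_high),
        "low": _collapsed(forward_low, commitment_low),
    }
    for e in topology.edges:
        if e.dst == SPORE_STATE:
            forward[e.key] = {"high": spore_rate, "low": spore_rate}
        elif topology.name == "irreversible_only":
            forward[e.key] = dict(collapsed)
        elif e.dst == "D":
            forward[e.key] = {"high": commitment_high, "low": commitment_low}
        else:
            forward[e.key] = {"high": forward_high, "low": forward_low}
        if e.reversible:
            backward[e.key] = {"high": backward_high, "low": backward_low}
    growth: RateMap = {
        s: {"high": growth_high, "low": growth_low}
        for s in topology.states
        if s != SPORE_STATE
    }
    growth[SPORE_STATE] = {"high": 0.0, "low": 0.0}
    return RateParameters(forward=forward, backward=backward, growth=growth)


@dataclass(frozen=True)
class GeneratorMatrix:
    """The rate matrix M of dN/dt = M N for one topology and stress phase.

    ``matrix[i, j]`` is the flow rate into state ``states[i]`` from state
    ``states[j]``; diagonal entries carry net growth minus total outflow,
    so the column sum for state j equals its net growth rate.
    """

    states: tuple[str, ...]
    matrix: np.ndarray
    phase: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (len(self.states), len(self.states)):
            raise ValueError("matrix shape does not match the state list")


def build_generator(
    topology: ModelTopology, params: RateParameters, phase: str
) -> GeneratorMatrix:
    """Assemble the generator matrix for one stress phase.

    Raises
    ------
    KeyError
        If a rate for some edge (or the reverse of a reversible edge) is
        missing for ``phase``; the message names the edge.
    """
    if phase not in PHASES:
        raise ValueError(f"phase must be one of {PHASES}, got {phase!r}")
    n = topology.n_states
    m = np.zeros((n, n))
    for e in topology.edges:
        i, j = topology.index(e.dst), topology.index(e.src)
        try:
            m[i, j] += params.forward[e.key][phase]
        except KeyError:
            raise KeyError(f"missing forward rate for edge {e.key}, phase {phase}")
        if e.reversible:
            try:
                m[j, i] += params.backward[e.key][phase]
            except KeyError:
                raise KeyError(
                    f"missing backward rate for edge {e.key}, phase {phase}"
                )
    for j, s in enumerate(topology.states):
        outflow = m[:, j].sum() - m[j, j]
        g = params.growth.get(s, {}).get(phase, 0.0)
        m[j, j] = g - outflow
    return GeneratorMatrix(states=topology.states, matrix=m, phase=phase)


def validate_parameters(
    topology: ModelTopology, params: RateParameters
) -> list[str]:
    """Diagnostic check of the rate-parameter invariants.

    Returns a list of human-readable violations; empty iff the parameter
    set is valid.  Checked: nonnegative transition rates, backward rates
    only on reversible edges, negative net growth of non-spore states
    under high stress, and the stress-coupling direction (forward rates at
    least their low-phase value in the high phase, backward rates at least
    their high-phase value in the low phase).
    """
    problems: list[str] = []
    reversible_keys = {e.key for e in topology.edges if e.reversible}
    edge_keys = {e.key for e in topology.edges}
    for name, table in (("forward", params.forward), ("backward", params.backward)):
        for key, per_phase in table.items():
            if key not in edge_keys:
                problems.append(f"{name} rate for unknown edge {key}")
            for phase, rate in per_phase.items():
                if rate < 0:
                    problems.append(
                        f"negative {name} rate {rate} on edge {key}, phase {phase}"
                    )
    for key in params.backward:
        if key in edge_keys and key not in reversible_keys:
            problems.append(f"backward rate given for irreversible edge {key}")
    for e in topology.edges:
        if e.key not in params.forward:
            problems.append(f"missing forward rate for edge {e.key}")
        elif set(params.forward[e.key]) != set(PHASES):
            problems.append(f"forward rate for edge {e.key} must cover phases {PHASES}")
        if e.reversible and e.key not in params.backward:
            problems.append(f"missing backward rate for reversible edge {e.key}")
    for s in topology.states:
        if s == SPORE_STATE:
            for phase, g in params.growth.get(s, {}).items():
                if g != 0.0:
                    problems.append(f"spore growth must be 0, got {g} in phase {phase}")
            continue
        g_high = params.growth.get(s, {}).get("high")
        if g_high is not None and g_high >= 0:
            problems.append(
                f"net growth of non-spore state {s} must be negative under high "
                f"stress (death exceeds growth), got {g_high}"
            )
    for key, per in params.forward.items():
        if key in edge_keys and per.get("high", 0.0) < per.get("low", 0.0):
            # stress pushes cells toward sporulation
            problems.append(
                f"forward rate on {key} must be >= its low-phase value in the "
                f"high phase ({per.get('high')} < {per.get('low')})"
            )
    for key, per in params.backward.items():
        if key in reversible_keys and per.get("low", 0.0) < per.get("high", 0.0):
            problems.append(
                f"backward rate on {key} must be >= its high-phase value in the "
                f"low phase ({per.get('low')} < {per.get('high')})"
            )
    return problems


def perturb_parameters(
    params: RateParameters, fraction: float, rng: np.random.Generator
) -> RateParameters:
    """Multiply every non-zero rate and growth magnitude by an independent
    factor uniform in ``[1 - fraction, 1 + fraction]``.

    Zero entries stay zero; the sign of net growth is preserved (its
    magnitude is scaled).
    """
    if not 0 <= fraction < 1:
        raise ValueError("perturbation fraction must be in [0, 1)")
    out = params.copy()
    for table in (out.forward, out.backward, out.growth):
        for per_phase in table.values():
            for phase, value in per_phase.items():
                if value != 0.0:
                    per_phase[phase] = value * rng.uniform(1 - fraction, 1 + fraction)
    return out


# -- config round-trip --------------------------------------------------------


def params_to_dict(topology: ModelTopology, params: RateParameters) -> dict:
    return {
        "model": topology.name,
        "forward": {k: dict(v) for k, v in params.forward.items()},
        "backward": {k: dict(v) for k, v in params.backward.items()},
        "growth": {k: dict(v) for k, v in params.growth.items()},
    }


def params_from_dict(data: dict) -> tuple[ModelTopology, RateParameters]:
    topology = make_topology(data["model"])
    params = RateParameters(
        forward={k: {p: float(r) for p, r in v.items()} for k, v in data["forward"].items()},
        backward={k: {p: float(r) for p, r in v.items()} for k, v in data.get("backward", {}).items()},
        growth={k: {p: float(r) for p, r in v.items()} for k, v in data.get("growth", {}).items()},
    )
    return topology, params


def save_parameters(path, topology: ModelTopology, params: RateParameters) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(topology, params), fh, sort_keys=True)


def load_parameters(path) -> tuple[ModelTopology, RateParameters]:
    with open(path) as fh:
        return params_from_dict(yaml.safe_load(fh))
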