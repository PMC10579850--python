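"""Configuration, serialization, plotting and fixture generation.

A simulation run is described by a :class:`RunConfig` (JSON on disk) with
defaults matching the reference setup: SEIR model, ``code_default``
parameters, initial state (S, E, I, R) = (1000, 0, 1, 0), a 120-day horizon
sampled daily, relative tolerance 1e-5, and the incidence denominator N
frozen at the initial population total.

Trajectories serialize to CSV with header ``time,S,E,I,R`` (column order
follows the state ordering of the model). Floats are written with
``repr``-style shortest round-trip formatting, so output bytes are
deterministic and a read-back reproduces the values exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError, DomainError
from .model import (
    PARAMETER_SETS,
    CompartmentalModel,
    ParameterSet,
    builtin_models,
    get_model,
)
from .solver import SolverConfig, Trajectory, integrate, rk4_reference, sample

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "simulate",
    "write_timeseries",
    "read_timeseries",
    "plot_compartments",
    "compartment_figure",
    "combined_figure",
    "make_fixture",
    "FIXTURE_CASES",
]

_CONFIG_KEYS = {
    "model", "parameter_set", "parameters", "S0", "E0", "I0", "R0",
    "t_max", "grid_step", "rel_tol", "abs_tol", "incidence_n_mode",
    "output_csv", "figure_dir",
}


@dataclass(frozen=True)
class RunConfig:
    """A complete, serializable simulation setup.

    ``parameters`` (a symbol->value mapping) overrides ``parameter_set``
    when given; models whose parameters extend the SEIR six (e.g. ``sirv``'s
    vaccination rate ``nu``) require it.
    """

    model: str = "seir"
    parameter_set: str = "code_default"
    parameters: dict | None = None
    S0: float = 1000.0
    E0: float = 0.0
    I0: float = 1.0
    R0: float = 0.0
    t_max: float = 120.0
    grid_step: float = 1.0
    rel_tol: float = 1e-5
    abs_tol: float = 1e-6
    incidence_n_mode: str = "fixed_at_initial"
    output_csv: str | None = None
    figure_dir: str | None = None

    def __post_init__(self):
        for key in ("S0", "E0", "I0", "R0"):
            v = getattr(self, key)
            if not (np.isfinite(v) and v >= 0):
                raise ConfigError(f"{key} must be a non-negative number, got {v!r}")
        if not self.t_max > 0:
            raise ConfigError(f"t_max must be > 0, got {self.t_max!r}")
        if not self.grid_step > 0:
            raise ConfigError(f"grid_step must be > 0, got {self.grid_step!r}")
        if not self.rel_tol > 0:
            raise ConfigError(f"rel_tol must be > 0, got {self.rel_tol!r}")
        if self.abs_tol < 0:
            raise ConfigError(f"abs_tol must be >= 0, got {self.abs_tol!r}")
        if self.incidence_n_mode not in ("fixed_at_initial", "dynamic"):
            raise ConfigError(
                f"incidence_n_mode must be 'fixed_at_initial' or 'dynamic', "
                f"got {self.incidence_n_mode!r}"
            )
        if self.model not in builtin_models():
            raise ConfigError(
                f"model must be one of {sorted(builtin_models())}, got {self.model!r}"
            )
        if self.parameters is None and self.parameter_set not in PARAMETER_SETS:
            raise ConfigError(
                f"parameter_set must be one of {sorted(PARAMETER_SETS)}, "
                f"got {self.parameter_set!r}"
            )

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ConfigError(f"config must be a JSON object, got {type(data).__name__}")
        unknown = set(data) - _CONFIG_KEYS
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return {k: v for k, v in out.items() if v is not None}

    def resolve_params(self):
        """The parameter mapping/ParameterSet this config selects."""
        if self.parameters is not None:
            return dict(self.parameters)
        return PARAMETER_SETS[self.parameter_set]

    def resolve_model(self) -> CompartmentalModel:
        return get_model(self.model, incidence_n_mode=self.incidence_n_mode)

    def initial_state(self) -> np.ndarray:
        """Initial state matching the model's compartments.

        S0/E0/I0/R0 map onto the model's labels by name; compartments the
        config does not name (e.g. V in ``sirv``) start at zero.
        """
        by_name = {"S": self.S0, "E": self.E0, "I": self.I0, "R": self.R0}
        labels = self.resolve_model().labels
        return np.array([by_name.get(lab, 0.0) for lab in labels])

    def grid(self) -> np.ndarray:
        n = int(round(self.t_max / self.grid_step))
        pts = np.arange(n + 1) * self.grid_step
        if pts[-1] < self.t_max - 1e-9:
            pts = np.append(pts, self.t_max)
        else:
            pts[-1] = self.t_max
        return pts


def load_config(path) -> RunConfig:
    """Read a JSON run configuration, applying defaults and validating."""
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"config file {path} is not valid JSON: {exc}") from None
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n")


def simulate(config: RunConfig) -> Trajectory:
    """Run the configured model and return the trajectory on the output grid."""
    model = config.resolve_model()
    solver = SolverConfig(rel_tol=config.rel_tol, abs_tol=config.abs_tol)
    dense = integrate(
        model, config.initial_state(), 0.0, config.t_max,
        params=config.resolve_params(), config=solver,
    )
    traj = sample(dense, config.grid())
    traj.provenance.update(
        model=config.model,
        parameter_set=None if config.parameters is not None else config.parameter_set,
    )
    return traj


def write_timeseries(traj: Trajectory, path) -> None:
    """Write a trajectory as CSV: header ``time,<labels...>``, one row per time.

    Values use shortest round-trip float formatting; byte output is
    deterministic for a fixed trajectory.
    """
    if len(traj) == 0:
        raise DomainError("refusing to write an empty trajectory")
    lines = ["time," + ",".join(traj.labels)]
    for t, row in zip(traj.times, traj.states):
        lines.append(",".join(repr(float(v)) for v in (t, *row)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_timeseries(path) -> Trajectory:
    """Read a CSV written by :func:`write_timeseries`."""
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    if "time" not in df.columns or df.shape[1] < 2:
        raise DomainError(f"{path} is not a time-series CSV (need a 'time' column)")
    labels = tuple(c for c in df.columns if c != "time")
    return Trajectory(
        times=df["time"].to_numpy(float),
        states=df[list(labels)].to_numpy(float),
        labels=labels,
        provenance={"source": str(path)},
    )


_FULL_NAMES = {
    "S": "Susceptible", "E": "Exposed", "I": "Infected",
    "R": "Recovered", "V": "Vaccinated",
}
_COLORS = {"S": "tab:blue", "E": "tab:green", "I": "tab:red",
           "R": "black", "V": "tab:purple"}


def _use_agg():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def compartment_figure(traj: Trajectory, label: str):
    """Figure for a single compartment's time course."""
    plt = _use_agg()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(traj.times, traj.column(label),
            color=_COLORS.get(label), label=_FULL_NAMES.get(label, label))
    ax.set_xlabel("Time (days)")
    ax.set_ylabel(f"{label}(t) (individuals)")
    ax.legend()
    fig.tight_layout()
    return fig


def combined_figure(traj: Trajectory):
    """Figure with every compartment plotted and a legend entry for each."""
    plt = _use_agg()
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for j, lab in enumerate(traj.labels):
        ax.plot(traj.times, traj.states[:, j],
                color=_COLORS.get(lab), label=_FULL_NAMES.get(lab, lab))
    ax.set_xlabel("Time (days)")
    ax.set_ylabel("Individuals")
    ax.legend()
    fig.tight_layout()
    return fig


def plot_compartments(traj: Trajectory, out_dir) -> list[Path]:
    """One PNG per compartment plus a combined figure, with a manifest.

    The combined plot carries one legend entry per compartment. Returns the
    list of figure paths; a ``manifest.json`` naming them is written
    alongside. PNG metadata is stripped so output is deterministic.
    """
    plt = _use_agg()
    if len(traj) == 0:
        raise DomainError("cannot plot an empty trajectory")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    paths: list[Path] = []
    for lab in traj.labels:
        fig = compartment_figure(traj, lab)
        p = out_dir / f"compartment_{lab}.png"
        fig.savefig(p, metadata={"Software": None})
        plt.close(fig)
        paths.append(p)

    fig = combined_figure(traj)
    p = out_dir / "all_compartments.png"
    fig.savefig(p, metadata={"Software": None})
    plt.close(fig)
    paths.append(p)

    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps([p.name for p in paths], indent=2) + "\n")
    return paths


#: Regression-fixture cases: (config, fixed-step oracle parameters).
FIXTURE_CASES = ("seir_code_default", "seir_table1", "closed_sir")


def _fixture_config(case: str) -> RunConfig:
    if case == "seir_code_default":
        return RunConfig()
    if case == "seir_table1":
        return RunConfig(parameter_set="table1")
    if case == "closed_sir":
        # Closed epidemic: no recruitment, no mortality; R0 = beta/gamma = 3.
        return RunConfig(
            model="sir",
            parameters={"Omega": 0.0, "beta": 0.3, "mu": 0.0,
                        "alpha": 0.0, "gamma": 0.1, "sigma": 0.0},
            S0=999.0, E0=0.0, I0=1.0, R0=0.0,
        )
    raise ConfigError(f"unknown fixture case {case!r}; available: {FIXTURE_CASES}")


def make_fixture(out_dir, case: str, oracle_h: float = 1e-3) -> tuple[Path, Path]:
    """Write a run config and its expected trajectory for regression tests.

    The expected CSV comes from the fixed-step 4th-order reference at step
    ``oracle_h``, sampled on the config's output grid — an independent
    oracle for the adaptive solver. Regeneration is deterministic
    (byte-identical files).
    """
    config = _fixture_config(case)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config_path = out_dir / f"{case}_config.json"
    expected_path = out_dir / f"{case}_expected.csv"
    save_config(config, config_path)
    dense = rk4_reference(
        config.resolve_model(), config.initial_state(), 0.0, config.t_max,
        h=oracle_h, params=config.resolve_params(),
    )
    write_timeseries(sample(dense, config.grid()), expected_path)
    return config_path, expected_path
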