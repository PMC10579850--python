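"""Epidemiological analysis of the SEIR system and of simulated trajectories.

The analytical quantities derive from the infected subsystem (E, I) of the
SEIR equations at the disease-free equilibrium using the next-generation
construction: new infections enter E at rate beta*S*I/N (so F has the single
entry beta), transitions out of E occur at alpha+mu and out of I at
gamma+sigma+mu, with progression alpha coupling them (matrix V). The basic
reproduction number is the spectral radius of F V^-1, which in closed form is

    R0 = alpha * beta / ((alpha + mu) * (gamma + sigma + mu)).

These quantities are conventional extensions of the simulator: they are
implied by the model equations rather than stated alongside them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .model import ParameterSet
from .solver import Trajectory

__all__ = [
    "EpidemicSummary",
    "basic_reproduction_number",
    "disease_free_equilibrium",
    "final_size_residual",
    "next_generation_matrix",
    "summarize",
]


def next_generation_matrix(params: ParameterSet) -> tuple[np.ndarray, np.ndarray]:
    """New-infection matrix F and transition matrix V over (E, I) at the DFE.

    Returns
    -------
    (F, V) : pair of 2x2 ndarrays
        ``F = [[0, beta], [0, 0]]`` (new infections enter E, driven by I);
        ``V = [[alpha+mu, 0], [-alpha, gamma+sigma+mu]]`` (outflow and
        progression). The spectral radius of ``F @ inv(V)`` is R0.
    """
    p = params.symbols()
    out_e = p["alpha"] + p["mu"]
    out_i = p["gamma"] + p["sigma"] + p["mu"]
    if out_e <= 0 or out_i <= 0:
        raise DomainError(
            "transition matrix V is singular: need alpha+mu > 0 and "
            f"gamma+sigma+mu > 0, got {out_e!r}, {out_i!r}"
        )
    F = np.array([[0.0, p["beta"]], [0.0, 0.0]])
    V = np.array([[out_e, 0.0], [-p["alpha"], out_i]])
    return F, V


def basic_reproduction_number(params: ParameterSet) -> float:
    """R0 of the SEIR system: ``alpha*beta / ((alpha+mu)*(gamma+sigma+mu))``.

    Equals the spectral radius of the next-generation matrix F V^-1.
    """
    p = params.symbols()
    denom = (p["alpha"] + p["mu"]) * (p["gamma"] + p["sigma"] + p["mu"])
    if denom <= 0:
        raise DomainError(
            "R0 undefined: need alpha+mu > 0 and gamma+sigma+mu > 0, "
            f"got alpha+mu={p['alpha'] + p['mu']!r}, "
            f"gamma+sigma+mu={p['gamma'] + p['sigma'] + p['mu']!r}"
        )
    return p["alpha"] * p["beta"] / denom


def disease_free_equilibrium(params: ParameterSet) -> np.ndarray:
    """The infection-free steady state (Omega/mu, 0, 0, 0).

    Requires ``mu > 0``; with no mortality the susceptible class grows
    without bound under recruitment and no finite equilibrium exists.
    """
    p = params.symbols()
    if p["mu"] <= 0:
        raise DomainError(
            "no finite disease-free equilibrium when natural death mu = 0"
        )
    return np.array([p["Omega"] / p["mu"], 0.0, 0.0, 0.0])


@dataclass(frozen=True)
class EpidemicSummary:
    """Headline statistics of one simulated epidemic.

    ``attack_fraction`` is (S(t0) - S(t_max)) / S(t0): the share of the
    initially susceptible population that left S over the run. It lies in
    [0, 1] for a closed epidemic (no recruitment); with recruitment it can
    be negative.
    """

    peak_infected: float
    t_peak: float
    final_state: np.ndarray
    attack_fraction: float


def summarize(traj: Trajectory) -> EpidemicSummary:
    """Peak infection size and timing, final state, and attack fraction.

    ``t_peak`` is the earliest stored time attaining the maximum of I
    (deterministic tie-break). Requires "I" and "S" columns.
    """
    if len(traj) == 0:
        raise DomainError("cannot summarize an empty trajectory")
    infected = traj.column("I")
    susceptible = traj.column("S")
    peak_idx = int(np.argmax(infected))  # argmax returns the first maximum
    s0 = susceptible[0]
    attack = (s0 - susceptible[-1]) / s0 if s0 > 0 else 0.0
    return EpidemicSummary(
        peak_infected=float(infected[peak_idx]),
        t_peak=float(traj.times[peak_idx]),
        final_state=traj.states[-1].copy(),
        attack_fraction=float(attack),
    )


def final_size_residual(r0: float, s0: float, s_inf: float, n: float) -> float:
    """Residual of the closed-epidemic final-size relation.

    For a closed SIR epidemic (no demography), the eventual susceptible
    population S_inf satisfies ``ln(S_inf/S0) = -R0 (1 - S_inf/N)``. This
    returns ``ln(S_inf/S0) + R0 (1 - S_inf/N)``, which is near zero when the
    inputs come from such an epidemic run to completion.
    """
    if not (s_inf > 0 and s0 > 0 and n > 0):
        raise DomainError(
            f"population sizes must be positive, got s0={s0!r}, "
            f"s_inf={s_inf!r}, n={n!r}"
        )
    if s_inf > s0 or s0 > n:
        raise DomainError(f"need s_inf <= s0 <= n, got {s_inf!r}, {s0!r}, {n!r}")
    return math.log(s_inf / s0) + r0 * (1.0 - s_inf / n)
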