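"""Deterministic mean-field counterpart of the contagion model.

The compartment densities obey

    ds/dt = -s i xi
    de/dt =  s i xi - (beta + eta) e
    di/dt =  beta e - gamma i
    dr/dt =  eta e + gamma i

with all rates positive and s + e + i + r = 1 conserved (the right-hand
side sums to zero identically).  Integration is fixed-step classical
RK4: reproducibility matters more than adaptive speed here.

Mapping from the agent model
----------------------------
The ODE's scalar ``xi`` aggregates the per-contact transmission
probability over a node's contacts.  For an agent run with a constant
per-contact probability p on a network with mean in-neighbor count K,
the matched coupling is ``xi = K * (-ln(1 - p))`` (per-contact hazard
times contact count); ``matched_rate`` converts any per-step probability
to its continuous hazard.  For intimacy-driven runs,
``mean_capped_intimacy`` supplies the per-contact scalar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contagion import IntimacyTable
from .generators import ConfigError

__all__ = [
    "ODEParams",
    "ODEState",
    "rhs",
    "integrate",
    "matched_rate",
    "mean_capped_intimacy",
]


@dataclass
class ODEParams:
    xi: float
    beta: float
    eta: float
    gamma: float

    def validate(self) -> None:
        for name in ("xi", "beta", "eta", "gamma"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")


@dataclass
class ODEState:
    s: float
    e: float
    i: float
    r: float

    def as_array(self) -> np.ndarray:
        return np.array([self.s, self.e, self.i, self.r], dtype=float)

    def validate(self) -> None:
        y = self.as_array()
        if (y < -1e-12).any() or (y > 1 + 1e-12).any():
            raise ConfigError("densities must lie in [0, 1]")
        if abs(y.sum() - 1.0) > 1e-9:
            raise ConfigError(f"densities sum to {y.sum()}, not 1")


def rhs(y: np.ndarray, params: ODEParams) -> np.ndarray:
    """Derivative vector; components sum to zero exactly."""
    s, e, i, _ = y
    inf = s * i * params.xi
    de = inf - (params.beta + params.eta) * e
    di = params.beta * e - params.gamma * i
    dr = params.eta * e + params.gamma * i
    return np.array([-inf, de, di, dr])


def integrate(
    initial: ODEState,
    params: ODEParams,
    t_max: float,
    dt: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step RK4 integration.

    Returns (times, Y) with Y of shape (n_steps + 1, 4), rows (s, e, i, r).
    Raises on non-finite state, naming the offending step.
    """
    if dt <= 0:
        raise ConfigError("dt must be > 0")
    params.validate()
    initial.validate()
    n_steps = int(round(t_max / dt))
    times = np.linspace(0.0, n_steps * dt, n_steps + 1)
    Y = np.empty((n_steps + 1, 4))
    y = initial.as_array()
    Y[0] = y
    for k in range(n_steps):
        k1 = rhs(y, params)
        k2 = rhs(y + 0.5 * dt * k1, params)
        k3 = rhs(y + 0.5 * dt * k2, params)
        k4 = rhs(y + dt * k3, params)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(y)):
            raise ConfigError(f"non-finite state at integration step {k + 1}")
        Y[k + 1] = y
    return times, Y


def matched_rate(p: float) -> float:
    """Continuous hazard equivalent of a per-step probability: -ln(1-p)."""
    if not 0.0 <= p < 1.0:
        raise ConfigError("probability must lie in [0, 1)")
    return float(-np.log1p(-p))


def matched_params(
    p_contact: float, mean_k: float, beta: float, eta: float, gamma: float
) -> ODEParams:
    """ODE parameters matched to a FIXED_RATE agent configuration.

    ``xi`` is the per-contact hazard times the mean in-neighbor count.
    The exposed compartment leaves at discrete per-step probability
    beta + (1-beta)*eta (the I-check precedes the dropout draw); the
    matched continuous rates preserve both the total leaving probability
    over a unit step and the I/R split.
    """
    xi = mean_k * matched_rate(p_contact)
    leave = beta + (1.0 - beta) * eta
    total = matched_rate(leave)
    frac_i = beta / leave if leave > 0 else 0.0
    return ODEParams(
        xi=xi,
        beta=frac_i * total,
        eta=(1.0 - frac_i) * total,
        gamma=matched_rate(gamma),
    )


def mean_capped_intimacy(table: IntimacyTable) -> float:
    """Scalar per-contact transmission probability: mean of min(omega, 1)."""
    return float(np.minimum(table.omega, 1.0).mean())
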