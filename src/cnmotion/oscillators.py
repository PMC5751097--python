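"""Oscillator centers: the pacemakers of the network.

A motion model is driven by a small bank of oscillators ("centers").  In the
simplest setting each center is a harmonic oscillator

    d2q/dt2 + omega**2 q = 0,        q(0) = 0,  dq/dt(0) = p0,

whose closed-form solution is used directly.  To reach arbitrary frequencies
through a single scalar control parameter, centers may instead be nonlinear
oscillators

    d2q/dt2 + z_c * f(q) = 0,        q(0) = 0,  dq/dt(0) = p0,

with f the pendulum nonlinearity sin(q) or the Duffing polynomial
a*q - b*q**3.  Their orbits are closed curves of the conserved energy

    E = p**2 / 2 + F(q),   F' = z_c * f,   F(0) = 0,

and the orbit frequency omega(z_c, p0) = 2*pi / T is computed numerically
from the first return of the orbit to q = 0 with p > 0.

Frequencies are radians/second internally; helpers accept and report Hz
(the unit used in motion-capture practice) via the 2*pi conversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .errors import (
    DomainError,
    IntegrationError,
    InvalidParameterError,
    ShapeError,
)

__all__ = [
    "Nonlinearity",
    "pendulum",
    "duffing",
    "register_nonlinearity",
    "get_nonlinearity",
    "OscillatorBank",
    "CenterStates",
    "harmonic_states",
    "simulate_nonlinear",
    "energy",
    "oscillation_frequency",
    "hz_to_rad",
    "rad_to_hz",
]

TWO_PI = 2.0 * np.pi


def hz_to_rad(f):
    """Convert frequency in Hz to angular frequency in rad/s."""
    return np.asarray(f, dtype=float) * TWO_PI


def rad_to_hz(w):
    """Convert angular frequency in rad/s to Hz."""
    return np.asarray(w, dtype=float) / TWO_PI


@dataclass(frozen=True)
class Nonlinearity:
    """Restoring nonlinearity f(q) together with its antiderivative.

    ``F`` must satisfy F' = f and F(0) = 0, so that z_c * F is the potential
    entering the conserved energy.  ``dfdq`` (f'(q)) is used to estimate the
    small-amplitude frequency sqrt(z_c * f'(0)).
    """

    name: str
    f: Callable[[np.ndarray], np.ndarray]
    F: Callable[[np.ndarray], np.ndarray]
    dfdq: Callable[[np.ndarray], np.ndarray]
    params: tuple = ()  # (key, value) pairs for serialization


def pendulum() -> Nonlinearity:
    """f(q) = sin(q); potential F(q) = 1 - cos(q)."""
    return Nonlinearity(
        name="pendulum",
        f=np.sin,
        F=lambda q: 1.0 - np.cos(q),
        dfdq=np.cos,
    )


def duffing(a: float = 1.0, b: float = 1.0) -> Nonlinearity:
    """f(q) = a*q - b*q**3; potential F(q) = a*q**2/2 - b*q**4/4."""
    return Nonlinearity(
        name="duffing",
        f=lambda q: a * q - b * q**3,
        F=lambda q: a * q**2 / 2.0 - b * q**4 / 4.0,
        dfdq=lambda q: a - 3.0 * b * q**2,
        params=(("a", float(a)), ("b", float(b))),
    )


_REGISTRY: dict[str, Callable[..., Nonlinearity]] = {
    "pendulum": pendulum,
    "duffing": duffing,
}


def register_nonlinearity(name: str, factory: Callable[..., Nonlinearity]) -> None:
    """Register a custom restoring-force factory under ``name``."""
    _REGISTRY[name] = factory


def get_nonlinearity(name: str, **params) -> Nonlinearity:
    if name not in _REGISTRY:
        raise InvalidParameterError(
            f"unknown nonlinearity {name!r}; registered: {sorted(_REGISTRY)}"
        )
    return _REGISTRY[name](**params)


@dataclass(frozen=True)
class OscillatorBank:
    """A bank of n independent oscillator centers.

    For ``kind='harmonic'`` the bank stores angular frequencies ``omega``
    (rad/s).  ``p0=None`` selects the unit-amplitude convention
    p0_i = omega_i, so q_i(t) = sin(omega_i t); any amplitude is absorbed
    by the output weight matrix, making this a pure normalization.

    For ``kind='nonlinear'`` the bank stores positive control parameters
    ``z_c`` and a shared :class:`Nonlinearity`; ``p0`` (default 1.0) sets
    the orbit amplitude.
    """

    kind: str
    omega: np.ndarray | None = None
    z_c: np.ndarray | None = None
    nonlinearity: Nonlinearity | None = None
    p0: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in ("harmonic", "nonlinear"):
            raise InvalidParameterError(f"unknown oscillator kind {self.kind!r}")
        if self.kind == "harmonic":
            if self.omega is None:
                raise InvalidParameterError("harmonic bank requires omega")
            w = np.atleast_1d(np.asarray(self.omega, dtype=float))
            if w.ndim != 1 or w.size < 1:
                raise ShapeError("omega must be a non-empty 1-d vector")
            if not np.all(np.isfinite(w)) or np.any(w <= 0):
                raise InvalidParameterError("all frequencies must be finite and > 0")
            object.__setattr__(self, "omega", w)
        else:
            if self.z_c is None or self.nonlinearity is None:
                raise InvalidParameterError(
                    "nonlinear bank requires z_c and a nonlinearity"
                )
            z = np.atleast_1d(np.asarray(self.z_c, dtype=float))
            if np.any(z <= 0) or not np.all(np.isfinite(z)):
                raise InvalidParameterError("all z_c must be finite and > 0")
            object.__setattr__(self, "z_c", z)
        if self.p0 is not None:
            p0 = np.broadcast_to(
                np.asarray(self.p0, dtype=float), (self.n,)
            ).copy()
            if not np.all(np.isfinite(p0)):
                raise InvalidParameterError("p0 must be finite")
            object.__setattr__(self, "p0", p0)

    @property
    def n(self) -> int:
        return len(self.omega) if self.kind == "harmonic" else len(self.z_c)

    def initial_momentum(self) -> np.ndarray:
        """p(0) per center: explicit p0, else the kind-specific default."""
        if self.p0 is not None:
            return self.p0
        if self.kind == "harmonic":
            return self.omega.copy()  # unit amplitude
        return np.ones(self.n)

    @classmethod
    def harmonic(cls, omega, p0=None) -> "OscillatorBank":
        return cls(kind="harmonic", omega=np.atleast_1d(omega), p0=p0)

    @classmethod
    def harmonic_hz(cls, freq_hz, p0=None) -> "OscillatorBank":
        return cls.harmonic(hz_to_rad(np.atleast_1d(freq_hz)), p0=p0)

    @classmethod
    def nonlinear(cls, z_c, nonlinearity: Nonlinearity, p0=1.0) -> "OscillatorBank":
        return cls(kind="nonlinear", z_c=np.atleast_1d(z_c),
                   nonlinearity=nonlinearity, p0=p0)


@dataclass(frozen=True)
class CenterStates:
    """Sampled center trajectories: K x n positions ``q`` and velocities ``p``."""

    times: np.ndarray
    q: np.ndarray
    p: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        q = np.atleast_2d(np.asarray(self.q, dtype=float))
        p = np.atleast_2d(np.asarray(self.p, dtype=float))
        if t.ndim != 1 or t.size == 0:
            raise ShapeError("times must be a non-empty 1-d vector")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise InvalidParameterError("times must be strictly increasing")
        if q.shape != p.shape or q.shape[0] != t.size:
            raise ShapeError(
                f"inconsistent shapes: times {t.shape}, q {q.shape}, p {p.shape}"
            )
        if not (np.all(np.isfinite(q)) and np.all(np.isfinite(p))):
            raise IntegrationError("non-finite center states")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "p", p)

    @property
    def n(self) -> int:
        return self.q.shape[1]


def _check_times(times) -> np.ndarray:
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if t.size == 0:
        raise InvalidParameterError("times must be non-empty")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise InvalidParameterError("times must be strictly increasing")
    return t


def harmonic_states(bank: OscillatorBank, times) -> CenterStates:
    """Closed-form harmonic center states.

    q_i(t) = A_i sin(omega_i t), p_i(t) = A_i omega_i cos(omega_i t), with
    A_i = p0_i / omega_i (unity under the default convention).
    """
    if bank.kind != "harmonic":
        raise InvalidParameterError("harmonic_states requires a harmonic bank")
    t = _check_times(times)
    amp = bank.initial_momentum() / bank.omega
    phase = t[:, None] * bank.omega[None, :]
    q = amp[None, :] * np.sin(phase)
    p = (amp * bank.omega)[None, :] * np.cos(phase)
    return CenterStates(times=t, q=q, p=p)


def _rhs(bank: OscillatorBank):
    n = bank.n
    f = bank.nonlinearity.f
    z = bank.z_c

    def rhs(t, y):
        q, p = y[:n], y[n:]
        with np.errstate(over="ignore", invalid="ignore"):
            # divergence shows up as non-finite states and is reported as an
            # IntegrationError after the solve
            return np.concatenate([p, -z * f(q)])

    return rhs


def simulate_nonlinear(
    bank: OscillatorBank,
    times,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    method: str = "DOP853",
) -> CenterStates:
    """Integrate the nonlinear centers from (q, p)(0) = (0, p0).

    Uses an adaptive explicit Runge-Kutta scheme (DOP853 by default) at
    tolerances tight enough that the conserved energy drifts by less than
    ~10*rtol over tens of periods.
    """
    if bank.kind != "nonlinear":
        raise InvalidParameterError("simulate_nonlinear requires a nonlinear bank")
    if rtol <= 0 or atol <= 0:
        raise InvalidParameterError("tolerances must be positive")
    t = _check_times(times)
    n = bank.n
    y0 = np.concatenate([np.zeros(n), bank.initial_momentum()])
    t0 = min(0.0, t[0])
    if t[-1] == t0:  # degenerate request: only the initial instant
        y = np.tile(y0, (t.size, 1))
        return CenterStates(times=t, q=y[:, :n], p=y[:, n:])
    sol = solve_ivp(
        _rhs(bank), (t0, t[-1]), y0, t_eval=t, method=method, rtol=rtol, atol=atol
    )
    if not sol.success:
        raise IntegrationError(f"oscillator integration failed: {sol.message}")
    y = sol.y
    if not np.all(np.isfinite(y)):
        raise IntegrationError("oscillator trajectory blew up (non-finite state)")
    return CenterStates(times=t, q=y[:n].T, p=y[n:].T)


def energy(states: CenterStates, bank: OscillatorBank) -> np.ndarray:
    """Conserved energy per sample per center: E = p**2/2 + z_c * F(q)."""
    if bank.kind != "nonlinear":
        raise InvalidParameterError("energy is defined for nonlinear banks")
    if states.n != bank.n:
        raise ShapeError(f"states have {states.n} centers, bank has {bank.n}")
    return 0.5 * states.p**2 + bank.z_c[None, :] * bank.nonlinearity.F(states.q)


def _linear_frequency(bank: OscillatorBank, i: int) -> float:
    """Small-amplitude frequency sqrt(z_c * f'(0)) used to scale horizons."""
    slope = float(bank.nonlinearity.dfdq(0.0))
    if slope <= 0:
        raise DomainError("f'(0) <= 0: no small-amplitude oscillation regime")
    return float(np.sqrt(bank.z_c[i] * slope))


def oscillation_frequency(
    bank: OscillatorBank,
    center_index: int = 0,
    rtol: float = 1e-11,
    atol: float = 1e-13,
) -> float:
    """Angular frequency omega = 2*pi/T of one nonlinear center's orbit.

    The period T is the time of first return to q = 0 with p > 0, located by
    the solver's dense-output root finder on the event function q(t).
    Raises :class:`DomainError` when the orbit is not closed (pendulum
    rotation regime, E >= 2*z_c) or no return is found.
    """
    if bank.kind != "nonlinear":
        raise InvalidParameterError("oscillation_frequency requires a nonlinear bank")
    i = int(center_index)
    if not 0 <= i < bank.n:
        raise InvalidParameterError(f"center_index {i} out of range for n={bank.n}")
    z = float(bank.z_c[i])
    p0 = float(bank.initial_momentum()[i])
    if p0 <= 0:
        raise InvalidParameterError("p0 must be positive for period detection")
    if bank.nonlinearity.name == "pendulum" and 0.5 * p0**2 >= 2.0 * z:
        raise DomainError(
            "pendulum orbit is in the rotation regime (E >= 2 z_c); "
            "no libration period exists"
        )
    w_lin = _linear_frequency(bank, i)
    nl = bank.nonlinearity

    def rhs(t, y):
        return [y[1], -z * nl.f(y[0])]

    def rising_zero(t, y):
        return y[0]

    # Non-terminal: q(0) = 0 makes the event fire trivially at t = 0, so we
    # collect all rising zeros and take the first one past t_min.
    rising_zero.direction = 1.0
    rising_zero.terminal = False

    horizon = 20.0 * TWO_PI / w_lin
    t_min = 1e-6 * TWO_PI / w_lin  # discard the trivial event at t = 0
    for _ in range(5):
        sol = solve_ivp(
            rhs, (0.0, horizon), [0.0, p0],
            events=rising_zero, rtol=rtol, atol=atol, method="DOP853",
        )
        if not sol.success:
            raise IntegrationError(f"period detection failed: {sol.message}")
        hits = sol.t_events[0]
        hits = hits[hits > t_min]
        if hits.size:
            return TWO_PI / float(hits[0])
        horizon *= 4.0
    raise DomainError(
        "no return to q=0 with p>0 found; the orbit does not appear closed"
    )
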