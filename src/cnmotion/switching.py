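"""The switching module: a multistable distar network selecting motions.

A hub variable z is bidirectionally coupled to m satellite variables
w_1..w_m (a "distar" graph: no satellite-satellite edges):

    dw_i/dt = sigma(b_i z - h_i) - w_i / kappa,
    dz/dt   = sigma( (1/kappa) sum_j a_j w_j - h ) - xi * lam * z,

with sigma a sigmoid, kappa a small satellite timescale, lam a decay rate
and xi a control gain.  At equilibrium w_i = kappa * sigma(b_i z - h_i)
exactly, so rest points are the roots of the reduced scalar equation

    sigma( S(z) - h ) = xi * lam * z,    S(z) = sum_j a_j sigma(b_j z - h_j).

With sharp satellite sigmoids S(z) is a staircase; gains can be chosen so
that, for an interval of xi, the line xi*lam*z crosses each of the m plateau
levels once, giving m stable hyperbolic rest points z_j in (j-1+beta, j+beta)
for a prescribed margin beta in (0, 1), while a large xi leaves a single
stable rest point near z = 0.  :func:`construct_switch` builds such a module
by an explicit recipe plus numeric calibration, and verifies the rest-point
structure computationally.

Each stable rest point anchors one stored motion (a frequency vector and
weight matrix); :func:`select_motion` maps a settled z to the nearest
anchor, and :func:`run_global_model` plays motions back under a schedule of
xi values, with no feedback from the generating network onto the switch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.special import logit

from .basis import sigmoid
from .errors import (
    ConfigError,
    ConstructionError,
    IntegrationError,
    InvalidParameterError,
)
from .fitting import MotionModel, predict

__all__ = [
    "SwitchingModule",
    "RestPoint",
    "RestPointReport",
    "MotionEntry",
    "MotionLibrary",
    "CalibratedSwitch",
    "switch_rhs",
    "simulate_switch",
    "find_rest_points",
    "construct_switch",
    "select_motion",
    "run_global_model",
    "GeneratedMotion",
]


@dataclass(frozen=True, eq=False)
class SwitchingModule:
    """Parameters of the distar switching network (see module docstring)."""

    a: np.ndarray  # satellite-to-hub gains a_j > 0
    b: np.ndarray  # hub-to-satellite gains b_i > 0
    h_sat: np.ndarray  # satellite thresholds h_i
    h: float  # hub threshold
    kappa: float  # satellite timescale, small and > 0
    lam: float  # hub decay rate > 0
    xi: float  # control gain
    sigmoid_kind: str = "logistic"

    def __post_init__(self):
        a = np.atleast_1d(np.asarray(self.a, dtype=float))
        b = np.atleast_1d(np.asarray(self.b, dtype=float))
        hs = np.atleast_1d(np.asarray(self.h_sat, dtype=float))
        if not (a.shape == b.shape == hs.shape):
            raise InvalidParameterError("a, b, h_sat must have equal length m")
        if np.any(a <= 0) or np.any(b <= 0):
            raise InvalidParameterError("gains a_j and b_i must be > 0")
        if not (self.kappa > 0 and self.lam > 0):
            raise InvalidParameterError("kappa and lam must be > 0")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "h_sat", hs)

    @property
    def m(self) -> int:
        return self.a.size

    def with_xi(self, xi: float) -> "SwitchingModule":
        return replace(self, xi=float(xi))


def switch_rhs(state: np.ndarray, module: SwitchingModule) -> np.ndarray:
    """Time derivatives of (w_1..w_m, z)."""
    s = np.asarray(state, dtype=float)
    w, z = s[:-1], s[-1]
    dw = sigmoid(module.b * z - module.h_sat, module.sigmoid_kind) - w / module.kappa
    drive = np.dot(module.a, w) / module.kappa - module.h
    dz = sigmoid(drive, module.sigmoid_kind) - module.xi * module.lam * z
    return np.concatenate([dw, [dz]])


def staircase(module: SwitchingModule, z) -> np.ndarray:
    """S(z) = sum_j a_j sigma(b_j z - h_j), the hub input at satellite
    quasi-equilibrium."""
    z = np.asarray(z, dtype=float)
    return (
        sigmoid(
            np.multiply.outer(z, module.b) - module.h_sat, module.sigmoid_kind
        )
        @ module.a
    )


def reduced_residual(module: SwitchingModule, z) -> np.ndarray:
    """psi(z) = sigma(S(z) - h) - xi*lam*z; its roots are the rest points."""
    z = np.asarray(z, dtype=float)
    return (
        sigmoid(staircase(module, z) - module.h, module.sigmoid_kind)
        - module.xi * module.lam * z
    )


def lift_to_state(module: SwitchingModule, z: float) -> np.ndarray:
    """Full rest state at hub value z: w_i = kappa * sigma(b_i z - h_i)."""
    w = module.kappa * sigmoid(
        module.b * z - module.h_sat, module.sigmoid_kind
    )
    return np.concatenate([w, [z]])


def simulate_switch(
    module: SwitchingModule,
    state0,
    horizon: float,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    n_out: int = 200,
):
    """Integrate the switching module; returns (times, states, final state)."""
    if not horizon > 0:
        raise InvalidParameterError("horizon must be > 0")
    y0 = np.asarray(state0, dtype=float)
    if y0.shape != (module.m + 1,):
        raise InvalidParameterError(
            f"state must have length m+1={module.m + 1}"
        )
    t_eval = np.linspace(0.0, horizon, n_out)
    sol = solve_ivp(
        lambda t, y: switch_rhs(y, module),
        (0.0, horizon),
        y0,
        t_eval=t_eval,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"switch integration failed: {sol.message}")
    if not np.all(np.isfinite(sol.y)):
        raise IntegrationError("switch state blew up")
    return sol.t, sol.y.T, sol.y[:, -1].copy()


@dataclass(frozen=True)
class RestPoint:
    z: float
    state: np.ndarray  # full (w, z) rest state
    max_real_eig: float  # largest real part of the Jacobian spectrum
    stable: bool
    hyperbolic: bool


@dataclass(frozen=True)
class RestPointReport:
    """Stable (and, for diagnostics, unstable) rest points, sorted by z."""

    stable: list[RestPoint]
    unstable: list[RestPoint]

    @property
    def stable_z(self) -> np.ndarray:
        return np.array([p.z for p in self.stable])


def _jacobian_fd(module: SwitchingModule, state: np.ndarray) -> np.ndarray:
    """Forward finite-difference Jacobian, step 1e-7 of the state scale."""
    n = state.size
    scale = max(1.0, float(np.abs(state).max()))
    eps = 1e-7 * scale
    f0 = switch_rhs(state, module)
    J = np.empty((n, n))
    for j in range(n):
        pert = state.copy()
        pert[j] += eps
        J[:, j] = (switch_rhs(pert, module) - f0) / eps
    return J


def find_rest_points(
    module: SwitchingModule,
    z_range: tuple[float, float] | None = None,
    grid: int = 4000,
    hyperbolicity_tol: float = 1e-6,
) -> RestPointReport:
    """Locate rest points by bracketing roots of the reduced scalar equation.

    The equation is scanned on a dense grid over ``z_range`` (default
    (-0.5, m + 1.5)); sign changes are refined by bisection, each root is
    lifted to the full (m+1)-dimensional state, and stability is read off
    the finite-difference Jacobian of the full system.
    """
    lo, hi = z_range if z_range is not None else (-0.5, module.m + 1.5)
    zs = np.linspace(lo, hi, int(grid))
    vals = reduced_residual(module, zs)
    roots = []
    for i in range(zs.size - 1):
        v0, v1 = vals[i], vals[i + 1]
        if v0 == 0.0:
            roots.append(float(zs[i]))
        elif v0 * v1 < 0:
            roots.append(
                float(
                    brentq(
                        lambda z: float(reduced_residual(module, z)),
                        zs[i],
                        zs[i + 1],
                        xtol=1e-14,
                        rtol=8.9e-16,
                    )
                )
            )
    if vals[-1] == 0.0:
        roots.append(float(zs[-1]))
    stable, unstable = [], []
    for z in roots:
        state = lift_to_state(module, z)
        eigs = np.linalg.eigvals(_jacobian_fd(module, state))
        max_re = float(np.max(eigs.real))
        point = RestPoint(
            z=z,
            state=state,
            max_real_eig=max_re,
            stable=max_re < 0,
            hyperbolic=bool(np.min(np.abs(eigs.real)) > hyperbolicity_tol),
        )
        (stable if point.stable else unstable).append(point)
    key = lambda p: p.z
    return RestPointReport(
        stable=sorted(stable, key=key), unstable=sorted(unstable, key=key)
    )


@dataclass(frozen=True)
class CalibratedSwitch:
    """A constructed module with the xi values realizing multistability."""

    module: SwitchingModule  # xi set to the calibrated midpoint
    xi_interval: tuple[float, float]  # m stable rest points throughout
    xi_single: float  # above this, exactly one stable rest point

    @property
    def m(self) -> int:
        return self.module.m


def _valid_multistable(module: SwitchingModule, beta: float) -> bool:
    """Exactly m stable rest points, each in (j-1+beta, j+beta)."""
    report = find_rest_points(module)
    zs = report.stable_z
    if zs.size != module.m:
        return False
    j = np.arange(1, module.m + 1)
    return bool(np.all((zs > j - 1 + beta) & (zs < j + beta)))


def construct_switch(
    m: int,
    beta: float = 0.5,
    kappa: float = 0.05,
    lam: float = 1.0,
    satellite_gain: float = 50.0,
    scan_points: int = 41,
) -> CalibratedSwitch:
    """Build an m-stable switching module by an explicit staircase recipe.

    Satellites get sharp sigmoids (gain ``satellite_gain``) with thresholds
    placed so S(z) steps upward at z = j - 1 + beta/2.  The hub gains and
    threshold are solved so that on the j-th plateau the hub output equals
    xi0*lam*t_j with t_j = j - 1/2 + 3*beta/4, putting the j-th crossing of
    the line xi0*lam*z inside (j-1+beta, j+beta).  A numeric scan then
    certifies an open xi-interval of m-stability and a larger xi with a
    single stable rest point.
    """
    if m < 1:
        raise InvalidParameterError("m must be >= 1")
    if not 0.0 < beta < 1.0:
        raise InvalidParameterError("beta must lie in (0, 1)")
    if not kappa > 0:
        raise InvalidParameterError("kappa must be > 0")
    j = np.arange(1, m + 1)
    theta = j - 1 + beta / 2.0  # step locations of the staircase
    b = np.full(m, float(satellite_gain))
    h_sat = b * theta
    targets = j - 0.5 + 0.75 * beta  # desired rest-point z on plateau j
    xi0 = 0.5 / (targets[-1] + 1.0)  # keep all plateau levels below 1/2
    v = xi0 * lam * targets  # hub output needed on each plateau
    # hub threshold: large enough for positive gains, small enough that the
    # line xi0*lam*z stays below sigma(-h) on plateau 0 (no spurious root)
    h_lo = -float(logit(v[0]))
    h_hi = float(np.log(1.0 / (xi0 * lam * beta / 2.0) - 1.0))
    if not h_lo < h_hi:
        raise ConstructionError(
            f"staircase recipe infeasible for m={m}, beta={beta}"
        )
    h = 0.5 * (h_lo + h_hi)
    cum = h + logit(v)  # required cumulative gains on each plateau
    a = np.diff(np.concatenate([[0.0], cum]))
    if np.any(a <= 0):
        raise ConstructionError("recipe produced non-positive hub gains")
    module = SwitchingModule(
        a=a, b=b, h_sat=h_sat, h=h, kappa=kappa, lam=lam, xi=xi0
    )
    if not _valid_multistable(module, beta):
        raise ConstructionError(
            f"nominal xi0={xi0:.4g} does not realize {m} stable rest points"
        )
    # certify an open interval around xi0
    factors = np.geomspace(1.0 / 1.6, 1.6, scan_points)
    valid = np.array(
        [_valid_multistable(module.with_xi(xi0 * f), beta) for f in factors]
    )
    i0 = int(np.argmin(np.abs(factors - 1.0)))
    lo_i, hi_i = i0, i0
    while lo_i > 0 and valid[lo_i - 1]:
        lo_i -= 1
    while hi_i < factors.size - 1 and valid[hi_i + 1]:
        hi_i += 1
    xi_interval = (xi0 * factors[lo_i], xi0 * factors[hi_i])
    # find a xi with a single stable rest point (Lemma-style collapse)
    xi_single = None
    xi_try = xi0 * 4.0
    for _ in range(40):
        report = find_rest_points(module.with_xi(xi_try))
        if len(report.stable) == 1:
            xi_single = xi_try
            break
        xi_try *= 1.5
    if xi_single is None:
        raise ConstructionError(
            f"no single-rest-point regime found up to xi={xi_try:.4g}"
        )
    return CalibratedSwitch(
        module=module, xi_interval=xi_interval, xi_single=xi_single
    )


# ---------------------------------------------------------------------------
# motion library and global playback


@dataclass(frozen=True, eq=False)
class MotionEntry:
    """One stored motion: the hub value anchoring it and its model."""

    z_anchor: float
    model: MotionModel


@dataclass(frozen=True, eq=False)
class MotionLibrary:
    """Stored motions keyed by strictly increasing z anchors."""

    entries: list[MotionEntry]

    def __post_init__(self):
        if not self.entries:
            raise ConfigError("motion library must be non-empty")
        anchors = [e.z_anchor for e in self.entries]
        if not all(a < b for a, b in zip(anchors, anchors[1:])):
            raise InvalidParameterError("z anchors must be strictly increasing")
        chans = self.entries[0].model.channels
        for e in self.entries[1:]:
            if e.model.channels != chans:
                raise InvalidParameterError(
                    "all library entries must share the same channel layout"
                )

    @property
    def anchors(self) -> np.ndarray:
        return np.array([e.z_anchor for e in self.entries])


def select_motion(library: MotionLibrary, z: float) -> MotionEntry:
    """Stored motion whose anchor is nearest to z (ties toward smaller z)."""
    anchors = library.anchors
    d = np.abs(anchors - float(z))
    # argmin returns the first (smallest-z) index on exact ties
    return library.entries[int(np.argmin(d))]


@dataclass(frozen=True, eq=False)
class GeneratedMotion:
    """Output of :func:`run_global_model`: possibly-empty marker channels."""

    times: np.ndarray
    channels: list[str]
    values: np.ndarray  # (K, C)
    z_path: np.ndarray  # hub value selected for each output sample


def run_global_model(
    library: MotionLibrary,
    module: SwitchingModule,
    schedule: list[tuple[float, float]],
    duration: float,
    rate: float = 120.0,
    settle_tol: float = 1e-6,
) -> GeneratedMotion:
    """Play back stored motions under a piecewise-constant xi schedule.

    ``schedule`` lists (start_time, xi) pairs; within each piece the switch
    is integrated from its current state, the settled hub value selects a
    stored motion, and that motion's outputs are generated on the piece's
    time grid (oscillator phase restarting at the piece start).  If the
    switch has not settled by the end of a piece a warning is issued and the
    nearest anchor is used.  There is no feedback from the generated outputs
    onto the switch.
    """
    channels = library.entries[0].model.channels
    if duration <= 0 or not schedule:
        return GeneratedMotion(
            times=np.empty(0),
            channels=channels,
            values=np.empty((0, len(channels))),
            z_path=np.empty(0),
        )
    starts = [t for t, _ in schedule]
    if starts != sorted(starts) or starts[0] != 0.0:
        raise ConfigError("schedule must start at t=0 and be time-ordered")
    edges = starts + [duration]
    state = np.zeros(module.m + 1)
    times_out, vals_out, z_out = [], [], []
    for (t0, xi), t1 in zip(schedule, edges[1:]):
        if t1 <= t0:
            continue
        piece = module.with_xi(xi)
        _, _, state = simulate_switch(piece, state, horizon=t1 - t0)
        if np.linalg.norm(switch_rhs(state, piece)) > settle_tol:
            warnings.warn(
                f"switch not settled by t={t1:.3f}; using nearest anchor",
                stacklevel=2,
            )
        z = float(state[-1])
        entry = select_motion(library, z)
        t_local = np.arange(int(np.round((t1 - t0) * rate))) / rate
        if t_local.size == 0:
            continue
        out = predict(entry.model, entry.model.time_origin + t_local)
        times_out.append(t0 + t_local)
        vals_out.append(out)
        z_out.append(np.full(t_local.size, z))
    if not times_out:
        return GeneratedMotion(
            times=np.empty(0),
            channels=channels,
            values=np.empty((0, len(channels))),
            z_path=np.empty(0),
        )
    return GeneratedMotion(
        times=np.concatenate(times_out),
        channels=channels,
        values=np.vstack(vals_out),
        z_path=np.concatenate(z_out),
    )
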