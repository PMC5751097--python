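"""Satellite basis functions and design matrices.

Each satellite computes one scalar feature Phi_j of the center state vector
q; a marker coordinate is a weighted sum of satellite outputs.  Three basis
families are supported:

* ``rbf`` — Gaussian radial basis functions
  Phi_j(q) = exp(-b**2 |q - qbar_j|**2 / 2) with Euclidean norm.  Localized,
  so they handle motions with sharp transitions; this is the workhorse.
* ``harmonic`` — a cosine series Phi_j(q) = cos(b_j <q, u>) with
  b_j = j*pi/x0 on the projection of q onto a unit vector u (first
  coordinate axis by default); x0 is the characteristic maximal amplitude.
* ``polynomial`` — monomials Phi_j(q) = q**(j-1), scalar q only.

For the ``rbf`` family a constant column is appended to the design matrix by
default so the linear fit can absorb channel offsets (the cosine family
already contains near-constant columns, the polynomial family contains an
exact one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import (
    DegenerateCentersError,
    InsufficientSamplesError,
    InvalidParameterError,
    ShapeError,
)
from .oscillators import CenterStates

__all__ = [
    "BasisConfig",
    "gaussian_rbf",
    "sigmoid",
    "eval_basis",
    "design_matrix",
    "place_centers",
    "place_center_indices",
    "default_sharpness",
]

FAMILIES = ("rbf", "harmonic", "polynomial")
SIGMOID_KINDS = ("logistic", "algebraic")


@dataclass(frozen=True, eq=False)
class BasisConfig:
    """Configuration of the satellite layer.

    Parameters
    ----------
    family:
        One of ``'rbf'``, ``'harmonic'``, ``'polynomial'``.
    n_satellites:
        Number of basis functions N_m (>= 1).
    sharpness:
        The RBF width parameter b (> 0).  ``None`` defers to
        :func:`default_sharpness` once centers are known.
    centers:
        (N_m, n) RBF center locations qbar_j.  ``None`` defers to
        :func:`place_centers` on the fitted trajectory.
    x0:
        Characteristic maximal amplitude for the cosine family; the
        wavenumbers are b_j = j*pi/x0.
    projection:
        Unit vector u for the cosine family's scalar projection <q, u>
        (default: first coordinate axis).
    intercept:
        Whether to append a constant design column.  ``None`` resolves to
        True for the ``rbf`` family and False otherwise.
    """

    family: str
    n_satellites: int
    sharpness: float | None = None
    centers: np.ndarray | None = None
    x0: float = 1.0
    projection: np.ndarray | None = None
    intercept: bool | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise InvalidParameterError(
                f"unknown basis family {self.family!r}; expected one of {FAMILIES}"
            )
        if int(self.n_satellites) < 1:
            raise InvalidParameterError("n_satellites must be >= 1")
        object.__setattr__(self, "n_satellites", int(self.n_satellites))
        if self.sharpness is not None and not self.sharpness > 0:
            raise InvalidParameterError("sharpness b must be > 0")
        if not self.x0 > 0:
            raise InvalidParameterError("x0 must be > 0")
        if self.centers is not None:
            c = np.atleast_2d(np.asarray(self.centers, dtype=float))
            if c.shape[0] != self.n_satellites:
                raise ShapeError(
                    f"{c.shape[0]} centers given but n_satellites={self.n_satellites}"
                )
            object.__setattr__(self, "centers", c)
        if self.projection is not None:
            u = np.asarray(self.projection, dtype=float)
            nrm = np.linalg.norm(u)
            if nrm == 0:
                raise InvalidParameterError("projection vector must be nonzero")
            object.__setattr__(self, "projection", u / nrm)

    @property
    def use_intercept(self) -> bool:
        if self.intercept is None:
            return self.family == "rbf"
        return bool(self.intercept)

    @property
    def n_columns(self) -> int:
        """Design-matrix width: satellites plus the optional constant column."""
        return self.n_satellites + (1 if self.use_intercept else 0)

    def with_geometry(self, centers: np.ndarray, sharpness: float) -> "BasisConfig":
        """A copy with resolved RBF centers and sharpness."""
        return BasisConfig(
            family=self.family,
            n_satellites=centers.shape[0],
            sharpness=float(sharpness),
            centers=centers,
            x0=self.x0,
            projection=self.projection,
            intercept=self.use_intercept,
        )


def gaussian_rbf(r):
    """Gaussian radial profile phi(r) = exp(-r**2/2) for r >= 0."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise InvalidParameterError("radius must be non-negative")
    return np.exp(-(r**2) / 2.0)


def sigmoid(h, kind: str = "logistic"):
    """Smooth step in (0, 1): logistic 1/(1+exp(-h)) or the algebraic
    form (h/sqrt(1+h**2) + 1)/2.  Overflow-safe for |h| up to ~1e300."""
    h = np.asarray(h, dtype=float)
    if kind == "logistic":
        return expit(h)
    if kind == "algebraic":
        return 0.5 * (h / np.hypot(1.0, h) + 1.0)
    raise InvalidParameterError(
        f"unknown sigmoid kind {kind!r}; expected one of {SIGMOID_KINDS}"
    )


def _as_q(q_states) -> np.ndarray:
    if isinstance(q_states, CenterStates):
        return q_states.q
    q = np.asarray(q_states, dtype=float)
    if q.ndim == 1:
        q = q[:, None]
    return q


def eval_basis(q_states, config: BasisConfig) -> np.ndarray:
    """Evaluate the K x N_m matrix of satellite outputs Phi_j(q(t_k)).

    ``q_states`` may be a :class:`CenterStates` or a (K, n) array.
    No intercept column is included here; see :func:`design_matrix`.
    """
    q = _as_q(q_states)
    K, n = q.shape
    nm = config.n_satellites
    if config.family == "rbf":
        if config.centers is None:
            raise InvalidParameterError(
                "rbf basis requires centers; use place_centers or with_geometry"
            )
        c = config.centers
        if c.shape[1] != n:
            raise ShapeError(
                f"centers have dimension {c.shape[1]} but q has {n} centers"
            )
        b = config.sharpness
        if b is None:
            b = default_sharpness(c)
        d2 = np.sum((q[:, None, :] - c[None, :, :]) ** 2, axis=-1)
        return np.exp(-(b**2) * d2 / 2.0)
    if config.family == "harmonic":
        u = config.projection
        if u is None:
            u = np.zeros(n)
            u[0] = 1.0
        elif u.shape != (n,):
            raise ShapeError(f"projection has shape {u.shape}, expected ({n},)")
        s = q @ u
        j = np.arange(1, nm + 1)
        return np.cos((j * np.pi / config.x0)[None, :] * s[:, None])
    # polynomial
    if n != 1:
        raise ShapeError("polynomial basis is defined for scalar q (n=1) only")
    j = np.arange(nm)
    return q[:, [0]] ** j[None, :]


def design_matrix(q_states, config: BasisConfig) -> np.ndarray:
    """Basis matrix with the constant column appended when configured."""
    phi = eval_basis(q_states, config)
    if config.use_intercept:
        phi = np.hstack([phi, np.ones((phi.shape[0], 1))])
    return phi


def place_center_indices(K: int, n_satellites: int) -> np.ndarray:
    """Indices of n_satellites time points equally spaced over 0..K-1,
    endpoints included."""
    if K < n_satellites:
        raise InsufficientSamplesError(
            f"{K} samples cannot host {n_satellites} satellite centers"
        )
    if n_satellites == 1:
        return np.array([0])
    return np.round(np.linspace(0, K - 1, n_satellites)).astype(int)


def place_centers(q_states, n_satellites: int, dedupe: bool = True) -> np.ndarray:
    """RBF centers taken from the trajectory itself.

    The centers are q sampled at ``n_satellites`` equally spaced time points
    (first and last included).  Placing centers on the visited states
    guarantees every basis function is active somewhere on the data.  Exact
    duplicate states are dropped when ``dedupe`` is set.
    """
    q = _as_q(q_states)
    idx = place_center_indices(q.shape[0], n_satellites)
    centers = q[idx]
    if dedupe:
        _, keep = np.unique(centers, axis=0, return_index=True)
        centers = centers[np.sort(keep)]
    return centers


def default_sharpness(centers) -> float:
    """Sharpness b = 1 / median nearest-neighbour distance among centers.

    This scales the Gaussian width to the local center spacing so that
    neighbouring satellites overlap without being redundant.  Centers closer
    than 1e-8 of the cloud diameter count as duplicates (trajectory-placed
    centers revisit states when frequencies are commensurate with the
    sampling window) and contribute no length scale — the duplicate column
    is harmless in a ridge fit.
    """
    c = np.atleast_2d(np.asarray(centers, dtype=float))
    if c.shape[0] < 2:
        raise DegenerateCentersError("need at least 2 centers to infer a scale")
    d2 = np.sum((c[:, None, :] - c[None, :, :]) ** 2, axis=-1)
    tol2 = 1e-16 * float(d2.max())
    d2[d2 <= tol2] = np.inf  # mask duplicate pairs (and the diagonal)
    nn2 = d2.min(axis=1)  # distance to the nearest *distinct* center
    finite = nn2[np.isfinite(nn2)]
    if finite.size == 0:
        raise DegenerateCentersError(
            "all satellite centers coincide; no length scale"
        )
    return 1.0 / float(np.median(np.sqrt(finite)))
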