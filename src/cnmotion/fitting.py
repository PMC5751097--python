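"""Learning motion models from marker trajectories.

The model for one output channel (a marker coordinate) is

    x_k(t) = sum_j W_kj Phi_j(q(t)),

with q(t) the oscillator center states.  For fixed oscillator frequencies the
weights W are a linear least-squares problem; the frequencies themselves are
found by minimizing the integral relative accuracy

    eps2_r,k(omega) = ( eps2_rX + eps2_rY + eps2_rZ ) / 3,

where each term is the squared L2 error of that axis divided by the axis's
raw (uncentered) second moment.  The minimization is an exhaustive grid
search for one or two centers and a seeded random search for more.  Model
size (number of centers and satellites) is compared by the small-sample
corrected Akaike criterion.

Conventions: frequency vectors are sorted ascending (centers are
exchangeable); oscillator phase is anchored at q = 0 at the start of the
fitted segment; candidate frequencies within 1e-12 of the minimum objective
are treated as ties and the lexicographically smallest vector wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .basis import BasisConfig, default_sharpness, design_matrix, place_center_indices
from .errors import (
    ConfigError,
    DataError,
    DegenerateCentersError,
    DegenerateChannelError,
    InsufficientSamplesError,
    InvalidParameterError,
    ShapeError,
    SmallSampleError,
)
from .oscillators import (
    CenterStates,
    OscillatorBank,
    harmonic_states,
    hz_to_rad,
    rad_to_hz,
    simulate_nonlinear,
)

__all__ = [
    "MarkerTrajectory",
    "MotionModel",
    "AccuracyReport",
    "Segmentation",
    "FitResult",
    "SegmentedFit",
    "GridSearch",
    "RandomSearch",
    "fit_weights",
    "default_ridge",
    "predict",
    "accuracy",
    "accuracy_report",
    "fit_at_frequencies",
    "search_frequencies",
    "average_marker_search",
    "transfer_fit",
    "fit_segmented",
    "predict_segmented",
    "aicc",
    "model_scan",
]

AXES = ("x", "y", "z")
#: candidates whose objective is within this of the minimum count as ties
TIE_TOL = 1e-12


# ---------------------------------------------------------------------------
# data containers


@dataclass(frozen=True, eq=False)
class MarkerTrajectory:
    """Time-indexed 3-D positions of named optical markers.

    ``coords`` has shape (K, M, 3) with axes ordered x, y, z, in ``units``
    (an opaque label, typically mm).  Times must be strictly increasing and
    lie on the uniform grid implied by ``sampling_rate`` to within 1e-9
    relative; gaps and NaNs must be resolved upstream.
    """

    times: np.ndarray
    markers: list[str]
    coords: np.ndarray
    sampling_rate: float
    units: str = "mm"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.coords, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise DataError("a trajectory needs at least K=2 samples")
        if not np.all(np.diff(t) > 0):
            raise DataError("times must be strictly increasing")
        if c.shape != (t.size, len(self.markers), 3):
            raise ShapeError(
                f"coords shape {c.shape} does not match "
                f"(K={t.size}, M={len(self.markers)}, 3)"
            )
        if not np.all(np.isfinite(c)):
            raise DataError("coords contain non-finite values")
        if len(set(self.markers)) != len(self.markers):
            raise DataError("duplicate marker names")
        if not self.sampling_rate > 0:
            raise InvalidParameterError("sampling_rate must be > 0")
        grid = t[0] + np.arange(t.size) / self.sampling_rate
        tol = 1e-9 * max(1.0, float(np.abs(t).max()))
        if np.abs(t - grid).max() > tol:
            raise DataError(
                "times are not consistent with sampling_rate within 1e-9"
            )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "coords", c)
        object.__setattr__(self, "markers", list(self.markers))

    @property
    def K(self) -> int:
        return self.times.size

    def marker_index(self, marker: str) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise InvalidParameterError(
                f"unknown marker {marker!r}; have {self.markers}"
            ) from None

    def marker_xyz(self, marker: str) -> np.ndarray:
        """(K, 3) coordinates of one marker."""
        return self.coords[:, self.marker_index(marker), :]

    def channel_matrix(self, markers: list[str] | None = None):
        """Stack selected markers into a (K, 3*M') matrix plus channel names."""
        names = self.markers if markers is None else list(markers)
        cols, labels = [], []
        for m in names:
            xyz = self.marker_xyz(m)
            for a, ax in enumerate(AXES):
                cols.append(xyz[:, a])
                labels.append(f"{m}/{ax}")
        return np.column_stack(cols), labels

    def subset_frames(self, start: int, stop: int) -> "MarkerTrajectory":
        """Frames start..stop-1 (0-based python slice) as a new trajectory."""
        return MarkerTrajectory(
            times=self.times[start:stop],
            markers=self.markers,
            coords=self.coords[start:stop],
            sampling_rate=self.sampling_rate,
            units=self.units,
        )


@dataclass(frozen=True, eq=False)
class MotionModel:
    """A fitted (or synthesized) oscillator-satellite model.

    ``W`` has one row per output channel (3 per marker, ordered x, y, z) and
    one column per design column (satellites plus optional intercept).
    ``time_origin`` is the absolute time at which the oscillator phase is
    zero (q = 0, p = p0).
    """

    bank: OscillatorBank
    basis: BasisConfig
    W: np.ndarray
    channels: list[str]
    time_origin: float = 0.0

    def __post_init__(self):
        w = np.atleast_2d(np.asarray(self.W, dtype=float))
        if not np.all(np.isfinite(w)):
            raise DataError("weight matrix contains non-finite values")
        if w.shape[0] != len(self.channels):
            raise ShapeError(
                f"W has {w.shape[0]} rows for {len(self.channels)} channels"
            )
        if w.shape[1] != self.basis.n_columns:
            raise ShapeError(
                f"W has {w.shape[1]} columns but the basis provides "
                f"{self.basis.n_columns}"
            )
        object.__setattr__(self, "W", w)
        object.__setattr__(self, "channels", list(self.channels))

    @property
    def marker_names(self) -> list[str]:
        seen = []
        for ch in self.channels:
            name = ch.rsplit("/", 1)[0]
            if name not in seen:
                seen.append(name)
        return seen

    def center_states(self, times) -> CenterStates:
        t = np.asarray(times, dtype=float) - self.time_origin
        if self.bank.kind == "harmonic":
            return harmonic_states(self.bank, t)
        return simulate_nonlinear(self.bank, t)


@dataclass(frozen=True)
class AccuracyReport:
    """Per-marker fit accuracies.

    ``eps2`` are absolute squared L2 errors per axis; ``eps2_rel`` divides by
    the raw second moment of the observed axis.  ``integral_rel2`` is the
    mean of the three squared relative errors and ``integral_rel`` its square
    root; both forms are exposed because either convention appears in
    practice.  ``abs_error`` is the mean per-frame Euclidean distance between
    observed and predicted 3-D position, in input units.
    """

    eps2: np.ndarray
    eps2_rel: np.ndarray
    abs_error: float

    @property
    def integral_rel2(self) -> float:
        return float(np.mean(self.eps2_rel))

    @property
    def integral_rel(self) -> float:
        return float(np.sqrt(self.integral_rel2))

    @property
    def rss(self) -> float:
        return float(np.sum(self.eps2))


@dataclass(frozen=True)
class Segmentation:
    """Frame segmentation given by 1-based boundaries T_1 < ... < T_{S+1}.

    Segment i covers frames [T_i, T_{i+1}) except the last, which is closed
    (shared boundary frames belong to the later segment; a final boundary of
    K+1 is accepted and clipped to K).
    """

    boundaries: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=int)
        if b.ndim != 1 or b.size < 2:
            raise InvalidParameterError("need at least two boundaries")
        if not np.all(np.diff(b) > 0):
            raise InvalidParameterError("boundaries must be strictly increasing")
        if b[0] < 1:
            raise InvalidParameterError("boundaries are 1-based; first must be >= 1")
        object.__setattr__(self, "boundaries", b)

    @property
    def n_segments(self) -> int:
        return self.boundaries.size - 1

    def frame_slices(self, K: int) -> list[tuple[int, int]]:
        """0-based (start, stop) python slices covering every frame once."""
        b = self.boundaries
        if b[-1] > K + 1:
            raise InvalidParameterError(
                f"last boundary {b[-1]} exceeds K+1={K + 1}"
            )
        out = []
        for i in range(self.n_segments):
            start = b[i] - 1
            stop = b[i + 1] - 1
            if i == self.n_segments - 1:
                stop = min(b[i + 1], K)  # closed last segment, clipped
            out.append((start, stop))
        return out


@dataclass(frozen=True, eq=False)
class FitResult:
    """Outcome of a frequency search: the minimizer, the refit model, the
    accuracy reports and the full search trace."""

    omega: np.ndarray  # rad/s, sorted ascending
    model: MotionModel
    reports: dict[str, AccuracyReport]
    objective: float
    trace_omegas: np.ndarray  # (C, n) rad/s candidates evaluated
    trace_objective: np.ndarray  # (C,) objective per candidate

    @property
    def omega_hz(self) -> np.ndarray:
        return rad_to_hz(self.omega)


@dataclass(frozen=True, eq=False)
class SegmentedFit:
    """Independent per-segment fits plus seam diagnostics."""

    segmentation: Segmentation
    results: list[FitResult]
    seam_jumps: np.ndarray  # (S-1,) max-over-markers predicted jump at seams


# ---------------------------------------------------------------------------
# weights and accuracy


def fit_weights(design: np.ndarray, targets: np.ndarray, ridge: float = 0.0):
    """Least-squares weights W minimizing ||targets - design @ W.T||^2
    (+ ridge * ||W||^2).

    At ridge = 0 the minimum-norm solution is returned (deterministic for
    rank-deficient designs); with ridge > 0 the regularized normal equations
    are solved.
    """
    D = np.atleast_2d(np.asarray(design, dtype=float))
    Y = np.asarray(targets, dtype=float)
    squeeze = Y.ndim == 1
    Y = np.atleast_2d(Y.T).T if squeeze else Y
    if not (np.all(np.isfinite(D)) and np.all(np.isfinite(Y))):
        raise DataError("non-finite values in design or targets")
    if D.shape[0] != Y.shape[0]:
        raise ShapeError(f"design has {D.shape[0]} rows, targets {Y.shape[0]}")
    if ridge < 0:
        raise InvalidParameterError("ridge must be >= 0")
    if ridge == 0.0:
        Wt, *_ = scipy.linalg.lstsq(D, Y, lapack_driver="gelsd")
    else:
        G = D.T @ D
        G[np.diag_indices_from(G)] += ridge
        Wt = scipy.linalg.solve(G, D.T @ Y, assume_a="pos")
    W = Wt.T
    return W[0] if squeeze else W


def default_ridge(design: np.ndarray) -> float:
    """Numerical-stability ridge: 1e-10 times the mean Gram diagonal."""
    D = np.asarray(design, dtype=float)
    return 1e-10 * float(np.mean(np.sum(D**2, axis=0)))


def predict(model: MotionModel, times) -> np.ndarray:
    """Evaluate all model channels on a time grid: (K, C) matrix."""
    states = model.center_states(np.atleast_1d(np.asarray(times, dtype=float)))
    D = design_matrix(states, model.basis)
    return D @ model.W.T


def accuracy_report(observed_xyz: np.ndarray, predicted_xyz: np.ndarray) -> AccuracyReport:
    """Accuracy functionals for one marker's (K, 3) observed vs predicted."""
    obs = np.asarray(observed_xyz, dtype=float)
    pred = np.asarray(predicted_xyz, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 2 or obs.shape[1] != 3:
        raise ShapeError(
            f"expected matching (K, 3) arrays, got {obs.shape} and {pred.shape}"
        )
    resid = obs - pred
    eps2 = np.sum(resid**2, axis=0)
    denom = np.sum(obs**2, axis=0)
    for a, ax in enumerate(AXES):
        if denom[a] == 0.0:
            raise DegenerateChannelError(
                f"axis {ax!r} has zero second moment; relative accuracy undefined"
            )
    abs_err = float(np.mean(np.linalg.norm(resid, axis=1)))
    return AccuracyReport(eps2=eps2, eps2_rel=eps2 / denom, abs_error=abs_err)


def accuracy(trajectory: MarkerTrajectory, predicted: np.ndarray, marker: str,
             channels: list[str] | None = None) -> AccuracyReport:
    """Accuracy of ``predicted`` channels against one observed marker.

    ``predicted`` is a (K, C) channel matrix; its columns are matched to the
    marker either via ``channels`` labels or, when C == 3, positionally.
    """
    obs = trajectory.marker_xyz(marker)
    pred = np.asarray(predicted, dtype=float)
    if channels is not None:
        cols = [channels.index(f"{marker}/{ax}") for ax in AXES]
        pred = pred[:, cols]
    elif pred.shape[1] != 3:
        raise ShapeError("pass channel labels to select a marker from C != 3 columns")
    return accuracy_report(obs, pred)


# ---------------------------------------------------------------------------
# frequency search


@dataclass(frozen=True)
class GridSearch:
    """Exhaustive search over a uniform frequency grid (Hz), n <= 2.

    Candidates for n = 2 are the unordered pairs of grid points (frequency
    vectors are reported sorted ascending; centers are exchangeable).
    """

    lo_hz: float = 0.05
    hi_hz: float = 5.0
    step_hz: float = 0.01

    def grid_hz(self) -> np.ndarray:
        if not (0 < self.lo_hz <= self.hi_hz and self.step_hz > 0):
            raise ConfigError("invalid frequency grid")
        n = int(np.floor((self.hi_hz - self.lo_hz) / self.step_hz + 0.5)) + 1
        return self.lo_hz + self.step_hz * np.arange(n)

    def candidates(self, n: int) -> np.ndarray:
        g = self.grid_hz()
        if g.size == 0:
            raise ConfigError("empty frequency grid")
        if n == 1:
            return g[:, None]
        if n == 2:
            i, j = np.triu_indices(g.size)
            return np.column_stack([g[i], g[j]])
        raise ConfigError(
            "exhaustive grid search supports n <= 2; use RandomSearch for larger n"
        )


@dataclass(frozen=True)
class RandomSearch:
    """Seeded uniform random search over [lo, hi]^n (Hz), for n >= 3
    (usable for any n)."""

    seed: int
    budget: int = 2000
    lo_hz: float = 0.05
    hi_hz: float = 5.0

    def candidates(self, n: int) -> np.ndarray:
        if self.budget < 1:
            raise ConfigError("random search budget must be >= 1")
        if not 0 < self.lo_hz <= self.hi_hz:
            raise ConfigError("invalid frequency range")
        rng = np.random.default_rng(self.seed)
        draws = rng.uniform(self.lo_hz, self.hi_hz, size=(self.budget, n))
        return np.sort(draws, axis=1)


def _resolve_geometry(states: CenterStates, cfg: BasisConfig):
    """Centers and sharpness actually used for a fit on these states."""
    if cfg.family != "rbf":
        return cfg
    centers = cfg.centers
    if centers is None:
        idx = place_center_indices(states.q.shape[0], cfg.n_satellites)
        centers = states.q[idx]
    b = cfg.sharpness
    if b is None:
        # a lone satellite has no neighbour spacing; unit sharpness matches
        # the unit-amplitude oscillator convention
        b = default_sharpness(centers) if centers.shape[0] > 1 else 1.0
    return cfg.with_geometry(centers, b)


def fit_at_frequencies(
    trajectory: MarkerTrajectory,
    omega,
    basis: BasisConfig,
    markers: list[str] | None = None,
    ridge: float | None = None,
    frames: tuple[int, int] | None = None,
) -> tuple[MotionModel, dict[str, AccuracyReport]]:
    """Fit satellite weights at fixed oscillator frequencies (rad/s).

    The oscillator phase is anchored at the first fitted frame.  ``ridge``
    ``None`` applies the default numerical-stability ridge; pass 0.0 for the
    exact minimum-norm least-squares solution.
    """
    w = np.sort(np.atleast_1d(np.asarray(omega, dtype=float)))
    names = trajectory.markers if markers is None else list(markers)
    start, stop = frames if frames is not None else (0, trajectory.K)
    times = trajectory.times[start:stop]
    if times.size < 2:
        raise InsufficientSamplesError("segment has fewer than 2 frames")
    t0 = float(times[0])
    bank = OscillatorBank.harmonic(w)
    states = harmonic_states(bank, times - t0)
    cfg = _resolve_geometry(states, basis)
    D = design_matrix(states, cfg)
    Y, labels = trajectory.channel_matrix(names)
    Y = Y[start:stop]
    lam = default_ridge(D) if ridge is None else float(ridge)
    W = fit_weights(D, Y, ridge=lam)
    model = MotionModel(bank=bank, basis=cfg, W=W, channels=labels, time_origin=t0)
    pred = D @ W.T
    reports = {
        m: accuracy_report(Y[:, 3 * i : 3 * i + 3], pred[:, 3 * i : 3 * i + 3])
        for i, m in enumerate(names)
    }
    return model, reports


def _objective_batch(
    times: np.ndarray,
    Y: np.ndarray,
    omegas: np.ndarray,
    basis: BasisConfig,
    ridge: float | None,
    chunk: int = 32,
) -> np.ndarray:
    """Integral-relative-accuracy objective for many frequency candidates.

    ``omegas`` is (C, n) in rad/s; ``Y`` is the (K, 3*M) channel matrix with
    time already rebased to the segment start.  Returns the (C,) objective:
    the per-marker mean of squared relative axis errors, summed over markers.
    Processes candidates in chunks with batched normal equations; this is
    algebraically the fit done by :func:`fit_at_frequencies` candidate by
    candidate, just vectorized.
    """
    if basis.family != "rbf" or basis.centers is not None:
        # generic but slower path: loop candidates through the scalar fit
        return _objective_loop(times, Y, omegas, basis, ridge)
    K = times.size
    nm = basis.n_satellites
    idx = place_center_indices(K, nm)
    denom = np.sum(Y**2, axis=0)
    if np.any(denom == 0.0):
        bad = int(np.argmin(denom))
        raise DegenerateChannelError(
            f"channel {bad} has zero second moment; relative accuracy undefined"
        )
    n_mark = Y.shape[1] // 3
    C, n = omegas.shape
    out = np.empty(C)
    use_int = basis.use_intercept
    P = nm + (1 if use_int else 0)
    eye = np.eye(P)
    # Separability: with trajectory-placed centers at fixed time indices,
    # |q - qbar|^2 = sum_a (sin(w_a t) - sin(w_a t_idx))^2 splits into
    # per-frequency blocks; precompute them once per unique frequency.
    uniq, inv = np.unique(omegas, return_inverse=True)
    inv = inv.reshape(C, n)
    precompute = uniq.size * K * nm * 8 <= 200e6
    if precompute:
        sin_t = np.sin(times[:, None] * uniq[None, :])  # (K, U)
        d2_blocks = np.empty((uniq.size, K, nm))
        dc_blocks = np.empty((uniq.size, nm, nm))
        for u in range(uniq.size):
            s = sin_t[:, u]
            c = s[idx]
            d2_blocks[u] = (s[:, None] - c[None, :]) ** 2
            dc_blocks[u] = (c[:, None] - c[None, :]) ** 2
    for lo in range(0, C, chunk):
        w = omegas[lo : lo + chunk]  # (B, n)
        B = w.shape[0]
        if precompute:
            ii = inv[lo : lo + chunk]
            d2 = d2_blocks[ii[:, 0]].copy()
            d2c = dc_blocks[ii[:, 0]].copy()
            for a in range(1, n):
                d2 += d2_blocks[ii[:, a]]
                d2c += dc_blocks[ii[:, a]]
        else:
            q = np.sin(times[None, :, None] * w[:, None, :])  # (B, K, n)
            centers = q[:, idx, :]  # (B, nm, n)
            d2 = np.sum(
                (q[:, :, None, :] - centers[:, None, :, :]) ** 2, axis=-1
            )
            d2c = np.sum(
                (centers[:, :, None, :] - centers[:, None, :, :]) ** 2, axis=-1
            )
        if basis.sharpness is None:
            tol2 = 1e-16 * d2c.max(axis=(1, 2))  # near-duplicate threshold
            d2c[d2c <= tol2[:, None, None]] = np.inf  # incl. the diagonal
            nn2 = d2c.min(axis=2)  # (B, nm): nearest *distinct* center
            nn = np.where(np.isfinite(nn2), np.sqrt(nn2), np.nan)
            with np.errstate(all="ignore"):
                med = np.nanmedian(nn, axis=1)
            degenerate = ~np.isfinite(med)
            med[degenerate] = 1.0
            b2 = 1.0 / med**2
        else:
            b2 = np.full(B, float(basis.sharpness) ** 2)
            degenerate = np.zeros(B, dtype=bool)
        Phi = np.empty((B, K, P))
        np.multiply(d2, (-0.5) * b2[:, None, None], out=Phi[:, :, :nm])
        np.exp(Phi[:, :, :nm], out=Phi[:, :, :nm])
        if use_int:
            Phi[:, :, nm] = 1.0
        G = np.matmul(Phi.transpose(0, 2, 1), Phi)  # (B, P, P)
        R = np.matmul(Phi.transpose(0, 2, 1), Y)  # (B, P, 3M)
        if ridge is None:
            lam = 1e-10 * np.einsum("bpp->b", G) / P
        else:
            lam = np.full(B, float(ridge))
        A = G + lam[:, None, None] * eye[None, :, :]
        Wt = np.linalg.solve(A, R)  # (B, P, 3M)
        # rss per channel via the quadratic form (avoids B x K x C residuals)
        rss = (
            denom[None, :]
            - 2.0 * np.einsum("bpc,bpc->bc", Wt, R)
            + np.einsum("bpc,bpc->bc", Wt, np.matmul(G, Wt))
        )
        np.maximum(rss, 0.0, out=rss)
        rel = rss / denom[None, :]
        per_marker = rel.reshape(B, n_mark, 3).mean(axis=2)
        obj = per_marker.sum(axis=1)
        obj[degenerate] = np.inf
        out[lo : lo + B] = obj
    return out


def _objective_loop(times, Y, omegas, basis, ridge):
    """Reference scalar-path objective (any family, fixed centers allowed)."""
    denom = np.sum(Y**2, axis=0)
    if np.any(denom == 0.0):
        raise DegenerateChannelError("zero second moment in a channel")
    n_mark = Y.shape[1] // 3
    out = np.empty(omegas.shape[0])
    for c, w in enumerate(omegas):
        bank = OscillatorBank.harmonic(np.sort(w))
        states = harmonic_states(bank, times)
        try:
            cfg = _resolve_geometry(states, basis)
            D = design_matrix(states, cfg)
        except DegenerateCentersError:
            out[c] = np.inf
            continue
        lam = default_ridge(D) if ridge is None else float(ridge)
        W = fit_weights(D, Y, ridge=lam)
        resid = Y - D @ W.T
        rel = np.sum(resid**2, axis=0) / denom
        out[c] = rel.reshape(n_mark, 3).mean(axis=1).sum()
    return out


def _pick_minimum(omegas_hz: np.ndarray, objective: np.ndarray) -> int:
    """Index of the minimizing candidate; ties (within TIE_TOL) break to the
    lexicographically smallest frequency vector."""
    best = float(np.min(objective))
    ties = np.flatnonzero(objective <= best + TIE_TOL)
    if ties.size == 1:
        return int(ties[0])
    order = np.lexsort(omegas_hz[ties, ::-1].T)
    return int(ties[order[0]])


def _search(
    trajectory, names, n, search, basis, ridge, frames
) -> FitResult:
    start, stop = frames if frames is not None else (0, trajectory.K)
    times = trajectory.times[start:stop] - trajectory.times[start]
    if stop - start < basis.n_satellites:
        raise InsufficientSamplesError(
            f"segment of {stop - start} frames cannot host "
            f"{basis.n_satellites} satellites"
        )
    Y, _ = trajectory.channel_matrix(names)
    Y = Y[start:stop]
    cand_hz = search.candidates(n)
    objective = _objective_batch(times, Y, hz_to_rad(cand_hz), basis, ridge)
    k = _pick_minimum(cand_hz, objective)
    omega = hz_to_rad(np.sort(cand_hz[k]))
    model, reports = fit_at_frequencies(
        trajectory, omega, basis, markers=names, ridge=ridge, frames=frames
    )
    obj = float(
        np.sum([r.integral_rel2 for r in reports.values()])
    )
    return FitResult(
        omega=omega,
        model=model,
        reports=reports,
        objective=obj,
        trace_omegas=hz_to_rad(cand_hz),
        trace_objective=objective,
    )


def search_frequencies(
    trajectory: MarkerTrajectory,
    marker: str,
    n: int,
    search: GridSearch | RandomSearch,
    basis: BasisConfig,
    ridge: float | None = None,
    frames: tuple[int, int] | None = None,
) -> FitResult:
    """Find the frequency vector minimizing one marker's integral relative
    accuracy, refit the weights at the minimizer and report accuracies."""
    if not 1 <= n <= 5:
        raise InvalidParameterError("number of centers n must be in 1..5")
    trajectory.marker_index(marker)
    return _search(trajectory, [marker], n, search, basis, ridge, frames)


def average_marker_search(
    trajectory: MarkerTrajectory,
    n: int,
    search: GridSearch | RandomSearch,
    basis: BasisConfig,
    ridge: float | None = None,
    markers: list[str] | None = None,
    frames: tuple[int, int] | None = None,
) -> FitResult:
    """Frequency search minimizing the sum over markers of the integral
    relative accuracy (slower, but uses all markers' evidence)."""
    if not 1 <= n <= 5:
        raise InvalidParameterError("number of centers n must be in 1..5")
    names = trajectory.markers if markers is None else list(markers)
    return _search(trajectory, names, n, search, basis, ridge, frames)


def transfer_fit(
    omega,
    trajectory: MarkerTrajectory,
    basis: BasisConfig,
    markers: list[str] | None = None,
    ridge: float | None = None,
    frames: tuple[int, int] | None = None,
) -> tuple[MotionModel, dict[str, AccuracyReport]]:
    """Refit only the weights of (all) markers at frequencies learned
    elsewhere.  ``omega`` may be a frequency vector (rad/s) or a FitResult."""
    if isinstance(omega, FitResult):
        omega = omega.omega
    return fit_at_frequencies(
        trajectory, omega, basis, markers=markers, ridge=ridge, frames=frames
    )


# ---------------------------------------------------------------------------
# segmented fits


def fit_segmented(
    trajectory: MarkerTrajectory,
    segmentation: Segmentation,
    n: int,
    search: GridSearch | RandomSearch,
    basis: BasisConfig,
    search_marker: str | None = None,
    ridge: float | None = None,
) -> SegmentedFit:
    """Independent frequency search and weight fit per segment.

    The frequency search runs on ``search_marker`` (default: the first
    marker); weights are then refit for every marker in the segment.  Seam
    jumps report the largest (over markers) Euclidean gap between the
    predictions of consecutive segments at the shared boundary.
    """
    marker = search_marker or trajectory.markers[0]
    slices = segmentation.frame_slices(trajectory.K)
    results = []
    for (start, stop) in slices:
        res = search_frequencies(
            trajectory, marker, n, search, basis, ridge=ridge, frames=(start, stop)
        )
        if len(trajectory.markers) > 1:
            model, reports = transfer_fit(
                res.omega, trajectory, basis, ridge=ridge, frames=(start, stop)
            )
            res = FitResult(
                omega=res.omega,
                model=model,
                reports=reports,
                objective=float(np.sum([r.integral_rel2 for r in reports.values()])),
                trace_omegas=res.trace_omegas,
                trace_objective=res.trace_objective,
            )
        results.append(res)
    jumps = []
    for i in range(len(slices) - 1):
        t_end = trajectory.times[slices[i][1] - 1]
        t_next = trajectory.times[slices[i + 1][0]]
        p_end = predict(results[i].model, [t_end])[0]
        p_next = predict(results[i + 1].model, [t_next])[0]
        gap = (p_next - p_end).reshape(-1, 3)
        jumps.append(float(np.linalg.norm(gap, axis=1).max()))
    return SegmentedFit(
        segmentation=segmentation,
        results=results,
        seam_jumps=np.asarray(jumps),
    )


def predict_segmented(fit: SegmentedFit, trajectory: MarkerTrajectory) -> np.ndarray:
    """Piecewise prediction covering every frame exactly once, (K, C)."""
    slices = fit.segmentation.frame_slices(trajectory.K)
    C = fit.results[0].model.W.shape[0]
    out = np.empty((trajectory.K, C))
    for (start, stop), res in zip(slices, fit.results):
        out[start:stop] = predict(res.model, trajectory.times[start:stop])
    return out


# ---------------------------------------------------------------------------
# model selection


def aicc(rss: float, n_obs: int, k_params: int) -> float:
    """Akaike information criterion corrected for finite samples:

        AICc = n ln(rss/n) + 2k + 2k(k+1)/(n-k-1)

    with n the number of scalar observations and k the number of fitted
    parameters (here: all weight entries plus the searched frequencies).
    """
    if not rss > 0:
        raise InvalidParameterError("rss must be > 0")
    n, k = int(n_obs), int(k_params)
    if n - k - 1 <= 0:
        raise SmallSampleError(
            f"AICc undefined: n_obs={n} must exceed k_params+1={k + 1}"
        )
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass(frozen=True, eq=False)
class ScanResult:
    """AICc model-size scan: one row per (centers, satellites) candidate."""

    table: "object"  # pandas.DataFrame: n, n_satellites, rss, k, aicc, omega_hz
    best_n: int
    best_satellites: int
    fits: dict[tuple[int, int], FitResult]


def model_scan(
    trajectory: MarkerTrajectory,
    center_counts,
    satellite_grid,
    grid: GridSearch | None = None,
    seed: int = 0,
    random_budget: int = 2000,
    basis_family: str = "rbf",
    search_marker: str | None = None,
    ridge: float | None = None,
) -> ScanResult:
    """AICc over the (centers x satellites) lattice.

    Centers n <= 2 use the exhaustive grid; larger n use a seeded random
    search (seed offset by n for independent draws).  The frequency search
    runs on one marker; weights are refit for all markers, and the pooled
    residual over all channels enters the AICc with n_obs = 3*K*M and
    k = (#weights) + n.
    """
    import pandas as pd

    grid = grid or GridSearch()
    center_counts = list(center_counts)
    satellite_grid = list(satellite_grid)
    if not center_counts or not satellite_grid:
        raise ConfigError("empty scan lattice")
    marker = search_marker or trajectory.markers[0]
    rows, fits = [], {}
    for n in center_counts:
        if n <= 2:
            search = grid
        else:
            search = RandomSearch(
                seed=seed + n, budget=random_budget,
                lo_hz=grid.lo_hz, hi_hz=grid.hi_hz,
            )
        for nm in satellite_grid:
            basis = BasisConfig(family=basis_family, n_satellites=nm)
            res = search_frequencies(trajectory, marker, n, search, basis, ridge=ridge)
            model, reports = transfer_fit(res.omega, trajectory, basis, ridge=ridge)
            rss = float(np.sum([r.rss for r in reports.values()]))
            k = model.W.size + n
            n_obs = 3 * trajectory.K * len(trajectory.markers)
            rows.append(
                dict(
                    n=n,
                    n_satellites=nm,
                    rss=rss,
                    k=k,
                    aicc=aicc(rss, n_obs, k),
                    omega_hz=tuple(np.round(rad_to_hz(res.omega), 6)),
                )
            )
            fits[(n, nm)] = FitResult(
                omega=res.omega,
                model=model,
                reports=reports,
                objective=float(np.sum([r.integral_rel2 for r in reports.values()])),
                trace_omegas=res.trace_omegas,
                trace_objective=res.trace_objective,
            )
    table = pd.DataFrame(rows)
    best = table.loc[table["aicc"].idxmin()]
    return ScanResult(
        table=table,
        best_n=int(best["n"]),
        best_satellites=int(best["n_satellites"]),
        fits=fits,
    )
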