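"""Ground-truth generators for testing the whole pipeline without data.

The generator draws a random but reproducible motion model of exactly the
assumed form — a bank of harmonic centers mapped through Gaussian RBF
satellites — evaluates it on a uniform time grid and optionally adds i.i.d.
Gaussian observation noise, scaled per channel as a fraction of that
channel's half peak-to-peak amplitude.  Noise is the minimal observation
model for recovery experiments; motion-capture data themselves are treated
as exact.

Defaults mirror typical mocap practice: 120 Hz sampling and a 10 s clip
(K = 1200).  Segmented motions concatenate independent per-segment models
with distinct frequency vectors on a continuous time axis, the oscillator
phase restarting at each segment start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import BasisConfig, default_sharpness, place_centers
from .errors import InvalidParameterError
from .fitting import MarkerTrajectory, MotionModel, Segmentation, predict
from .oscillators import OscillatorBank, harmonic_states

__all__ = [
    "SynthSpec",
    "SegmentPlan",
    "GroundTruth",
    "generate_model",
    "generate_trajectory",
    "generate_segmented",
]

AXES = ("x", "y", "z")


@dataclass(frozen=True)
class SegmentPlan:
    """One segment of a piecewise motion: duration and frequency vector."""

    duration_s: float
    freqs_hz: tuple

    def __post_init__(self):
        if not self.duration_s > 0:
            raise InvalidParameterError("segment duration must be > 0")
        object.__setattr__(self, "freqs_hz", tuple(float(f) for f in self.freqs_hz))


@dataclass(frozen=True)
class SynthSpec:
    """Specification of a synthetic motion.

    ``freqs_hz=None`` draws ``n_centers`` frequencies uniformly from
    ``freq_range_hz`` (seeded).  ``noise_sd`` is the observation-noise
    standard deviation as a fraction of each channel's half peak-to-peak
    amplitude.  ``segments`` switches to piecewise generation and overrides
    ``duration_s`` and ``freqs_hz``.
    """

    seed: int
    n_centers: int = 2
    freqs_hz: tuple | None = (0.5, 1.3)
    freq_range_hz: tuple = (0.3, 1.6)
    n_satellites: int = 25
    family: str = "rbf"
    n_markers: int = 1
    duration_s: float = 10.0
    rate_hz: float = 120.0
    noise_sd: float = 0.0
    segments: tuple | None = None

    def __post_init__(self):
        if self.n_centers < 1 or self.n_satellites < 1 or self.n_markers < 1:
            raise InvalidParameterError("counts must be >= 1")
        if not (self.rate_hz > 0 and self.duration_s > 0):
            raise InvalidParameterError("rate and duration must be > 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.freqs_hz is not None:
            f = tuple(float(x) for x in self.freqs_hz)
            if len(f) != self.n_centers:
                raise InvalidParameterError(
                    f"{len(f)} frequencies given for n_centers={self.n_centers}"
                )
            if any(x <= 0 for x in f):
                raise InvalidParameterError("frequencies must be > 0")
            object.__setattr__(self, "freqs_hz", f)
        if self.segments is not None:
            segs = tuple(
                s if isinstance(s, SegmentPlan) else SegmentPlan(*s)
                for s in self.segments
            )
            if len(segs) < 2:
                raise InvalidParameterError("a segment plan needs >= 2 segments")
            object.__setattr__(self, "segments", segs)

    def times(self) -> np.ndarray:
        K = int(round(self.duration_s * self.rate_hz))
        return np.arange(K) / self.rate_hz

    def marker_names(self) -> list[str]:
        return [f"m{i + 1:02d}" for i in range(self.n_markers)]


@dataclass(frozen=True, eq=False)
class GroundTruth:
    """What the generator actually used, for recovery scoring."""

    model: MotionModel
    freqs_hz: np.ndarray  # sorted ascending
    noise_sd_per_channel: np.ndarray
    clean: np.ndarray  # (K, C) noiseless channel values
    boundaries: np.ndarray | None = None  # 1-based, for segmented motions
    segment_freqs_hz: tuple | None = None
    segment_models: tuple | None = None


def _draw_model(
    rng: np.random.Generator,
    freqs_hz: np.ndarray,
    n_satellites: int,
    family: str,
    markers: list[str],
    times: np.ndarray,
    time_origin: float = 0.0,
) -> MotionModel:
    bank = OscillatorBank.harmonic_hz(np.sort(freqs_hz))
    states = harmonic_states(bank, times - time_origin)
    if family == "rbf":
        centers = place_centers(states, n_satellites)
        # a lone satellite has no neighbour spacing; unit sharpness matches
        # the unit-amplitude oscillator convention
        b = default_sharpness(centers) if centers.shape[0] > 1 else 1.0
        cfg = BasisConfig(
            family="rbf",
            n_satellites=centers.shape[0],
            sharpness=b,
            centers=centers,
            intercept=True,
        )
    else:
        cfg = BasisConfig(family=family, n_satellites=n_satellites)
    from .basis import design_matrix  # local import to avoid cycle at module load

    D = design_matrix(states, cfg)
    channels = [f"{m}/{a}" for m in markers for a in AXES]
    W = rng.standard_normal((len(channels), D.shape[1]))
    vals = D @ W.T
    amp = 0.5 * (vals.max(axis=0) - vals.min(axis=0))
    amp[amp == 0] = 1.0
    W /= amp[:, None]
    return MotionModel(
        bank=bank, basis=cfg, W=W, channels=channels, time_origin=time_origin
    )


def _resolve_freqs(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.freqs_hz is not None:
        return np.sort(np.asarray(spec.freqs_hz, dtype=float))
    lo, hi = spec.freq_range_hz
    return np.sort(rng.uniform(lo, hi, size=spec.n_centers))


def generate_model(spec: SynthSpec) -> MotionModel:
    """Ground-truth model: seeded weights rescaled to unit channel amplitude,
    RBF centers placed on the actual oscillator trajectory."""
    rng = np.random.default_rng(spec.seed)
    freqs = _resolve_freqs(spec, rng)
    return _draw_model(
        rng, freqs, spec.n_satellites, spec.family, spec.marker_names(), spec.times()
    )


def generate_trajectory(spec: SynthSpec) -> tuple[MarkerTrajectory, GroundTruth]:
    """Sample the model on the spec's grid and add observation noise."""
    if spec.segments is not None:
        traj, seg, truth = generate_segmented(spec)
        return traj, truth
    rng = np.random.default_rng(spec.seed)
    freqs = _resolve_freqs(spec, rng)
    times = spec.times()
    markers = spec.marker_names()
    model = _draw_model(
        rng, freqs, spec.n_satellites, spec.family, markers, times
    )
    clean = predict(model, times)
    amp = 0.5 * (clean.max(axis=0) - clean.min(axis=0))
    amp[amp == 0] = 1.0
    sd = spec.noise_sd * amp
    noisy = clean + rng.standard_normal(clean.shape) * sd[None, :]
    coords = noisy.reshape(times.size, len(markers), 3)
    traj = MarkerTrajectory(
        times=times,
        markers=markers,
        coords=coords,
        sampling_rate=spec.rate_hz,
        units="mm",
    )
    truth = GroundTruth(
        model=model,
        freqs_hz=freqs,
        noise_sd_per_channel=sd,
        clean=clean,
    )
    return traj, truth


def generate_segmented(
    spec: SynthSpec,
) -> tuple[MarkerTrajectory, Segmentation, GroundTruth]:
    """Concatenate independent per-segment models on a continuous time axis.

    Returns the trajectory, the true boundaries (1-based; length = number of
    segments + 1) and the ground truth holding each segment's model."""
    if spec.segments is None:
        raise InvalidParameterError("spec has no segment plan")
    rng = np.random.default_rng(spec.seed)
    markers = spec.marker_names()
    dt = 1.0 / spec.rate_hz
    seg_models, seg_freqs, clean_parts, time_parts = [], [], [], []
    boundaries = [1]
    t_start = 0.0
    for plan in spec.segments:
        K_seg = int(round(plan.duration_s * spec.rate_hz))
        times = t_start + np.arange(K_seg) * dt
        freqs = np.sort(np.asarray(plan.freqs_hz, dtype=float))
        model = _draw_model(
            rng, freqs, spec.n_satellites, spec.family, markers, times,
            time_origin=t_start,
        )
        clean_parts.append(predict(model, times))
        time_parts.append(times)
        seg_models.append(model)
        seg_freqs.append(tuple(freqs))
        boundaries.append(boundaries[-1] + K_seg)
        t_start += K_seg * dt
    clean = np.vstack(clean_parts)
    times = np.concatenate(time_parts)
    amp = 0.5 * (clean.max(axis=0) - clean.min(axis=0))
    amp[amp == 0] = 1.0
    sd = spec.noise_sd * amp
    noisy = clean + rng.standard_normal(clean.shape) * sd[None, :]
    coords = noisy.reshape(times.size, len(markers), 3)
    traj = MarkerTrajectory(
        times=times,
        markers=markers,
        coords=coords,
        sampling_rate=spec.rate_hz,
        units="mm",
    )
    seg = Segmentation(np.asarray(boundaries))
    truth = GroundTruth(
        model=seg_models[0],
        freqs_hz=np.asarray(seg_freqs[0]),
        noise_sd_per_channel=sd,
        clean=clean,
        boundaries=np.asarray(boundaries),
        segment_freqs_hz=tuple(seg_freqs),
        segment_models=tuple(seg_models),
    )
    return traj, seg, truth
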