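"""Reading and writing marker trajectories and model files.

Marker CSV dialect: header ``frame,time_s,<marker>_x,<marker>_y,<marker>_z,
...``; 1-based contiguous frames; time in seconds printed with 12 significant
digits (9 is the guaranteed minimum, but 12 are needed for the uniformity
check below to be meaningful on clips longer than a few seconds at 120 Hz);
coordinates in input units at full precision; UTF-8, comma
separator, ``.`` decimal point, LF line endings.  Readers validate and
reject malformed input rather than repairing it; times are snapped to the
uniform grid implied by the inferred sampling rate (uniformity is checked to
1e-6 relative first).

TRC (the plain-text mocap format, v1.0 header) is supported read-only.

Model files are YAML documents holding the oscillator bank, basis
configuration, weight rows keyed by marker/axis, optional segmentation and
an optional motion library with switch parameters.  All floats round-trip
losslessly.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .basis import BasisConfig
from .errors import DataError, InvalidParameterError, ParseError
from .fitting import MarkerTrajectory, MotionModel, Segmentation
from .oscillators import OscillatorBank, get_nonlinearity
from .switching import MotionEntry, MotionLibrary, SwitchingModule

__all__ = [
    "read_markers_csv",
    "write_markers_csv",
    "read_trc",
    "save_model",
    "load_model",
    "save_segmented_models",
    "load_segmented_models",
    "MODEL_FORMAT_VERSION",
]

MODEL_FORMAT_VERSION = 1
AXES = ("x", "y", "z")


# ---------------------------------------------------------------------------
# marker CSV dialect


def _marker_columns(columns: list[str]) -> list[str]:
    """Marker names from header columns, verifying each has exactly x, y, z."""
    if columns[:2] != ["frame", "time_s"]:
        raise ParseError(
            "first two columns must be 'frame,time_s'; got "
            f"{columns[:2]}"
        )
    seen: dict[str, list[str]] = {}
    order: list[str] = []
    for col in columns[2:]:
        if "_" not in col:
            raise ParseError(f"column {col!r} is not of the form <marker>_<axis>")
        name, axis = col.rsplit("_", 1)
        if axis not in AXES:
            raise ParseError(f"column {col!r} has unknown axis suffix {axis!r}")
        if name not in seen:
            seen[name] = []
            order.append(name)
        seen[name].append(axis)
    for name in order:
        if seen[name] != list(AXES):
            raise ParseError(
                f"marker {name!r} must contribute exactly the columns "
                f"{name}_x,{name}_y,{name}_z in order; got suffixes {seen[name]}"
            )
    if not order:
        raise ParseError("no marker columns found")
    return order


def _validated_trajectory(frame, time_s, blocks, markers, units) -> MarkerTrajectory:
    K = len(time_s)
    if K < 2:
        raise ParseError("need at least 2 frames")
    expected = np.arange(1, K + 1)
    if not np.array_equal(frame, expected):
        bad = int(np.argmax(frame != expected))
        raise ParseError(
            f"frames must be contiguous 1..K; row {bad + 1} has frame {frame[bad]}"
        )
    dt = np.diff(time_s)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0))
        raise ParseError(f"time_s is non-increasing at row {bad + 2}")
    med = float(np.median(dt))
    if np.abs(dt - med).max() > 1e-6 * med:
        bad = int(np.argmax(np.abs(dt - med)))
        raise ParseError(
            f"non-uniform sampling at row {bad + 2}: dt={dt[bad]:.9g} "
            f"vs median {med:.9g} (tolerance 1e-6 relative)"
        )
    rate = 1.0 / med
    times = time_s[0] + np.arange(K) / rate  # snap to the uniform grid
    coords = np.stack(blocks, axis=1)  # (K, M, 3)
    return MarkerTrajectory(
        times=times,
        markers=markers,
        coords=coords,
        sampling_rate=rate,
        units=units,
    )


def read_markers_csv(path, units: str = "mm") -> MarkerTrajectory:
    """Read the marker CSV dialect into a validated trajectory."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=",", encoding="utf-8")
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    markers = _marker_columns(list(df.columns))
    if df.isna().any().any():
        col = df.columns[df.isna().any().to_numpy().argmax()]
        row = int(df[col].isna().to_numpy().argmax())
        raise ParseError(f"missing value at row {row + 2}, column {col!r}")
    frame = df["frame"].to_numpy()
    if not np.issubdtype(frame.dtype, np.number) or np.any(frame != frame.astype(int)):
        raise ParseError("frame column must contain integers")
    blocks = [
        df[[f"{m}_x", f"{m}_y", f"{m}_z"]].to_numpy(dtype=float) for m in markers
    ]
    return _validated_trajectory(
        frame.astype(int), df["time_s"].to_numpy(dtype=float), blocks, markers, units
    )


def write_markers_csv(trajectory: MarkerTrajectory, path) -> None:
    """Write the marker CSV dialect: markers in name-sorted order, then
    x, y, z; time with 9 significant digits, coordinates at full precision."""
    if not trajectory.markers:
        raise DataError("cannot write a trajectory with no markers")
    names = sorted(trajectory.markers)
    header = ["frame", "time_s"]
    for m in names:
        header += [f"{m}_{a}" for a in AXES]
    buf = io.StringIO()
    buf.write(",".join(header) + "\n")
    idx = [trajectory.marker_index(m) for m in names]
    for k in range(trajectory.K):
        row = [str(k + 1), format(trajectory.times[k], ".12g")]
        for mi in idx:
            row += [repr(float(v)) for v in trajectory.coords[k, mi]]
        buf.write(",".join(row) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# TRC (read-only)


def read_trc(path) -> MarkerTrajectory:
    """Read a TRC v1.0 motion-capture file.

    The four header lines (PathFileType, field names, field values, marker
    names) are validated against the data block; units come from the
    ``Units`` header field.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if len(lines) < 6:
        raise ParseError("TRC file too short")
    if not lines[0].startswith("PathFileType"):
        raise ParseError("missing PathFileType header line")
    fields = lines[1].split("\t")
    values = lines[2].split("\t")
    header = dict(zip(fields, values))
    for required in ("DataRate", "NumFrames", "NumMarkers", "Units"):
        if required not in header or not header[required]:
            raise ParseError(f"TRC header missing {required!r}")
    rate = float(header["DataRate"])
    n_frames = int(header["NumFrames"])
    n_markers = int(header["NumMarkers"])
    units = header["Units"]
    name_row = lines[3].split("\t")
    if name_row[0] != "Frame#":
        raise ParseError("fourth line must start with 'Frame#'")
    marker_names = [c for c in name_row[2:] if c.strip()]
    if len(marker_names) != n_markers:
        raise ParseError(
            f"header claims {n_markers} markers but {len(marker_names)} named"
        )
    data_rows = [ln for ln in lines[5:] if ln.strip()]
    if len(data_rows) != n_frames:
        raise ParseError(
            f"header claims {n_frames} frames but {len(data_rows)} data rows"
        )
    frame = np.empty(n_frames, dtype=int)
    time_s = np.empty(n_frames)
    coords = np.empty((n_frames, n_markers, 3))
    for k, ln in enumerate(data_rows):
        cells = ln.split("\t")
        if len(cells) < 2 + 3 * n_markers:
            raise ParseError(f"data row {k + 1} has too few columns")
        frame[k] = int(float(cells[0]))
        time_s[k] = float(cells[1])
        try:
            vals = [float(c) for c in cells[2 : 2 + 3 * n_markers]]
        except ValueError as exc:
            raise ParseError(f"non-numeric cell in data row {k + 1}") from exc
        coords[k] = np.asarray(vals).reshape(n_markers, 3)
    if np.any(~np.isfinite(coords)):
        raise ParseError("TRC data contain non-finite values")
    blocks = [coords[:, i, :] for i in range(n_markers)]
    traj = _validated_trajectory(frame, time_s, blocks, marker_names, units)
    if abs(traj.sampling_rate - rate) > 1e-3 * rate:
        raise ParseError(
            f"DataRate header {rate} disagrees with data spacing "
            f"({traj.sampling_rate:.6g} Hz)"
        )
    return traj


# ---------------------------------------------------------------------------
# model files (YAML)


def _floats(arr) -> list:
    return np.asarray(arr, dtype=float).tolist()


def _bank_to_doc(bank: OscillatorBank) -> dict:
    doc = {"kind": bank.kind}
    if bank.kind == "harmonic":
        doc["omega_rad"] = _floats(bank.omega)
    else:
        doc["z_c"] = _floats(bank.z_c)
        doc["nonlinearity"] = {
            "name": bank.nonlinearity.name,
            "params": {k: v for k, v in bank.nonlinearity.params},
        }
    doc["p0"] = None if bank.p0 is None else _floats(bank.p0)
    return doc


def _bank_from_doc(doc: dict) -> OscillatorBank:
    kind = doc["kind"]
    p0 = None if doc.get("p0") is None else np.asarray(doc["p0"], dtype=float)
    if kind == "harmonic":
        return OscillatorBank.harmonic(np.asarray(doc["omega_rad"]), p0=p0)
    nl = doc["nonlinearity"]
    return OscillatorBank.nonlinear(
        np.asarray(doc["z_c"]),
        get_nonlinearity(nl["name"], **nl.get("params", {})),
        p0=1.0 if p0 is None else p0,
    )


def _basis_to_doc(cfg: BasisConfig) -> dict:
    return {
        "family": cfg.family,
        "n_satellites": cfg.n_satellites,
        "sharpness": None if cfg.sharpness is None else float(cfg.sharpness),
        "centers": None if cfg.centers is None else [_floats(c) for c in cfg.centers],
        "x0": float(cfg.x0),
        "projection": None if cfg.projection is None else _floats(cfg.projection),
        "intercept": cfg.intercept,
    }


def _basis_from_doc(doc: dict) -> BasisConfig:
    return BasisConfig(
        family=doc["family"],
        n_satellites=int(doc["n_satellites"]),
        sharpness=doc.get("sharpness"),
        centers=None if doc.get("centers") is None else np.asarray(doc["centers"]),
        x0=float(doc.get("x0", 1.0)),
        projection=(
            None if doc.get("projection") is None else np.asarray(doc["projection"])
        ),
        intercept=doc.get("intercept"),
    )


def _model_to_doc(model: MotionModel) -> dict:
    return {
        "bank": _bank_to_doc(model.bank),
        "basis": _basis_to_doc(model.basis),
        "time_origin": float(model.time_origin),
        "weights": {ch: _floats(row) for ch, row in zip(model.channels, model.W)},
        "channel_order": list(model.channels),
    }


def _model_from_doc(doc: dict) -> MotionModel:
    channels = doc["channel_order"]
    W = np.array([doc["weights"][ch] for ch in channels], dtype=float)
    return MotionModel(
        bank=_bank_from_doc(doc["bank"]),
        basis=_basis_from_doc(doc["basis"]),
        W=W,
        channels=channels,
        time_origin=float(doc.get("time_origin", 0.0)),
    )


def _switch_to_doc(module: SwitchingModule) -> dict:
    return {
        "a": _floats(module.a),
        "b": _floats(module.b),
        "h_sat": _floats(module.h_sat),
        "h": float(module.h),
        "kappa": float(module.kappa),
        "lam": float(module.lam),
        "xi": float(module.xi),
        "sigmoid_kind": module.sigmoid_kind,
    }


def _switch_from_doc(doc: dict) -> SwitchingModule:
    return SwitchingModule(
        a=np.asarray(doc["a"]),
        b=np.asarray(doc["b"]),
        h_sat=np.asarray(doc["h_sat"]),
        h=float(doc["h"]),
        kappa=float(doc["kappa"]),
        lam=float(doc["lam"]),
        xi=float(doc["xi"]),
        sigmoid_kind=doc.get("sigmoid_kind", "logistic"),
    )


def save_model(
    model: MotionModel,
    path,
    segmentation: Segmentation | None = None,
    library: MotionLibrary | None = None,
    switch: SwitchingModule | None = None,
) -> None:
    """Write a model file (YAML).  Floats round-trip losslessly."""
    doc = {"format_version": MODEL_FORMAT_VERSION, "model": _model_to_doc(model)}
    if segmentation is not None:
        doc["segmentation"] = [int(b) for b in segmentation.boundaries]
    if library is not None:
        doc["library"] = [
            {"z_anchor": float(e.z_anchor), "model": _model_to_doc(e.model)}
            for e in library.entries
        ]
    if switch is not None:
        doc["switch"] = _switch_to_doc(switch)
    Path(path).write_text(
        yaml.safe_dump(doc, sort_keys=False, default_flow_style=None),
        encoding="utf-8",
    )


def load_model(path):
    """Read a model file; returns (model, segmentation, library, switch)."""
    doc = _load_doc(path)
    model = _model_from_doc(doc["model"])
    seg = (
        Segmentation(np.asarray(doc["segmentation"]))
        if doc.get("segmentation")
        else None
    )
    library = None
    if doc.get("library"):
        library = MotionLibrary(
            entries=[
                MotionEntry(
                    z_anchor=float(e["z_anchor"]), model=_model_from_doc(e["model"])
                )
                for e in doc["library"]
            ]
        )
    switch = _switch_from_doc(doc["switch"]) if doc.get("switch") else None
    return model, seg, library, switch


def save_segmented_models(
    models: list[MotionModel], segmentation: Segmentation, path
) -> None:
    """Write one model per segment plus the shared segmentation."""
    if len(models) != segmentation.n_segments:
        raise InvalidParameterError(
            f"{len(models)} models for {segmentation.n_segments} segments"
        )
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "segmentation": [int(b) for b in segmentation.boundaries],
        "segments": [_model_to_doc(m) for m in models],
    }
    Path(path).write_text(
        yaml.safe_dump(doc, sort_keys=False, default_flow_style=None),
        encoding="utf-8",
    )


def load_segmented_models(path):
    """Read a segmented model file; returns (models, segmentation)."""
    doc = _load_doc(path)
    if "segments" not in doc:
        raise ParseError("not a segmented model file (no 'segments' key)")
    models = [_model_from_doc(d) for d in doc["segments"]]
    seg = Segmentation(np.asarray(doc["segmentation"]))
    return models, seg


def is_segmented_model_file(path) -> bool:
    return "segments" in _load_doc(path)


def _load_doc(path) -> dict:
    try:
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ParseError(f"cannot parse model file {path}: {exc}") from exc
    if not isinstance(doc, dict) or "format_version" not in doc:
        raise ParseError(f"{path} is not a model file")
    if int(doc["format_version"]) > MODEL_FORMAT_VERSION:
        raise ParseError(
            f"model file version {doc['format_version']} is newer than "
            f"supported version {MODEL_FORMAT_VERSION}"
        )
    return doc
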