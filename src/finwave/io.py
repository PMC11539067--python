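"""File I/O: CSV serialisation of bending fields, midlines and
trajectories; WAV traces; TIFF stacks; JSON ground truth; run manifests.

CSV dialect: comma-separated, UTF-8, '.' decimal, header row mandatory.
Times are seconds; lengths are mm unless the sidecar says 'px'. Tables
carry a sidecar metadata block (fps, units, scale) as a JSON file next
to the CSV so round trips are lossless.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.io import wavfile

from .synthetic import EphysTrace, Trajectory
from .wave_model import BendingField, Midline, MidlineSequence

__all__ = [
    "write_bending_field", "read_bending_field",
    "write_midline_sequence", "read_midline_sequence",
    "write_trajectory", "read_trajectory",
    "write_trace_wav", "read_trace_wav",
    "write_stack", "read_stack",
    "write_json", "read_json", "write_manifest",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_bending_field(field: BendingField, path: str | Path) -> None:
    """Long-format CSV: frame, time_s, s_frac, theta_rad."""
    path = Path(path)
    n_t, n_s = field.theta.shape
    frame = np.repeat(np.arange(n_t), n_s)
    df = pd.DataFrame({
        "frame": frame,
        "time_s": np.repeat(field.times_s, n_s),
        "s_frac": np.tile(field.s_frac, n_t),
        "theta_rad": field.theta.ravel(),
    })
    df.to_csv(path, index=False)
    _sidecar(path).write_text(json.dumps({"fps": field.fps, "kind": "bending_field"}))


def read_bending_field(path: str | Path) -> BendingField:
    df = pd.read_csv(path)
    times = df.drop_duplicates("frame").sort_values("frame")["time_s"].to_numpy()
    s = np.sort(df["s_frac"].unique())
    theta = (df.pivot(index="frame", columns="s_frac", values="theta_rad")
             .sort_index().to_numpy())
    return BendingField(theta=theta, times_s=times, s_frac=s)


def write_midline_sequence(seq: MidlineSequence, path: str | Path) -> None:
    """Long-format CSV: frame, point_idx, x, y (+ sidecar fps/units/scale)."""
    path = Path(path)
    pts = seq.points_array()
    n_f, n_p, _ = pts.shape
    df = pd.DataFrame({
        "frame": np.repeat(np.arange(n_f), n_p),
        "point_idx": np.tile(np.arange(n_p), n_f),
        "x": pts[:, :, 0].ravel(),
        "y": pts[:, :, 1].ravel(),
    })
    df.to_csv(path, index=False)
    meta = {"fps": seq.fps, "units": seq.units,
            "scale_px_per_mm": seq.scale_px_per_mm, "kind": "midline_sequence"}
    _sidecar(path).write_text(json.dumps(meta))


def read_midline_sequence(path: str | Path) -> MidlineSequence:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    mids = []
    for _, g in df.sort_values(["frame", "point_idx"]).groupby("frame"):
        mids.append(Midline(g[["x", "y"]].to_numpy()))
    return MidlineSequence(mids, fps=meta["fps"], units=meta["units"],
                           scale_px_per_mm=meta.get("scale_px_per_mm"))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    pd.DataFrame({"time_s": traj.times_s, "x_mm": traj.x_mm,
                  "y_mm": traj.y_mm}).to_csv(path, index=False)
    _sidecar(Path(path)).write_text(json.dumps({"fps": traj.fps, "kind": "trajectory"}))


def read_trajectory(path: str | Path) -> Trajectory:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    return Trajectory(times_s=df["time_s"].to_numpy(), x_mm=df["x_mm"].to_numpy(),
                      y_mm=df["y_mm"].to_numpy(), fps=meta["fps"])


def write_trace_wav(trace: EphysTrace, path: str | Path) -> None:
    """Float32 WAV; the stimulus time travels in the sidecar."""
    wavfile.write(str(path), int(trace.fs), trace.samples.astype(np.float32))
    _sidecar(Path(path)).write_text(json.dumps({"stim_time_s": trace.stim_time_s}))


def read_trace_wav(path: str | Path) -> EphysTrace:
    path = Path(path)
    fs, samples = wavfile.read(str(path))
    stim = 0.0
    if _sidecar(path).exists():
        stim = json.loads(_sidecar(path).read_text()).get("stim_time_s", 0.0)
    return EphysTrace(samples=np.asarray(samples, dtype=float), fs=float(fs),
                      stim_time_s=stim)


def write_stack(frames: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), frames)


def read_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(out_dir: str | Path, command: str, seed: int,
                   config_hash: str, inputs: list[str | Path] = (),
                   outputs: list[str | Path] = ()) -> Path:
    """Run manifest: command, seed, config hash, versions, file hashes."""
    import finwave

    out_dir = Path(out_dir)
    manifest = {
        "command": command,
        "seed": seed,
        "config_hash": config_hash,
        "versions": {
            "finwave": finwave.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
        "inputs": {str(p): file_sha256(p) for p in inputs},
        "outputs": {str(p): file_sha256(p) for p in outputs},
    }
    path = out_dir / "manifest.json"
    write_json(manifest, path)
    return path
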