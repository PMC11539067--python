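"""Synthetic-data generators with ground truth for every pipeline stage.

No raw recordings ship with this package, so each consumer (tracker,
feature extraction, spike analysis, morphometry) is exercised against
generated inputs that mimic the real acquisition setup:

* top-view grayscale video of a single swimming fish (30 s cruising at
  200 fps; 5 s escape clips at 936 fps);
* counter-current arena trajectories at three stream-speed settings;
* Mauthner-cell field potentials: two spike-amplitude classes on top of
  50 Hz mains hum and broadband noise, with a stimulus timestamp;
* spinal-cord cross-section images with a known number of bright axon
  profiles of known diameters.

Every generator is deterministic for a seed and returns the ground truth
needed to score the downstream analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon

from .wave_model import Midline, MidlineSequence

__all__ = [
    "ArenaSpec",
    "Trajectory",
    "EphysTrace",
    "render_frames",
    "default_body_width_profile",
    "simulate_arena_track",
    "simulate_field_potential",
    "simulate_axon_image",
    "simulate_escape_sequence",
    "OutOfFrameError",
    "PackingError",
    "STREAM_FLOW_ML_S",
]

#: nominal pump flows (ml/s) behind the categorical stream-speed labels
STREAM_FLOW_ML_S = {"slow": 172.0, "medium": 240.0, "fast": 277.0}


class OutOfFrameError(ValueError):
    """Rendered fish would leave the frame bounds."""

    def __init__(self, frames):
        self.frames = list(frames)
        super().__init__(f"fish exceeds frame bounds in frames {self.frames[:10]}"
                         + ("..." if len(self.frames) > 10 else ""))


class PackingError(RuntimeError):
    """Could not place all axons without overlap."""


@dataclass(frozen=True)
class ArenaSpec:
    """Counter-current swim arena geometry (the real one is 17.2 x 4.4 cm)."""

    width_mm: float = 172.0
    height_mm: float = 44.0
    stream_speed_label: str = "medium"
    centre_band_frac: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ValueError("arena dimensions must be > 0")
        if self.stream_speed_label not in STREAM_FLOW_ML_S:
            raise ValueError(f"unknown stream label {self.stream_speed_label!r}")
        if not 0 < self.centre_band_frac <= 1:
            raise ValueError("centre_band_frac must be in (0, 1]")

    @property
    def flow_ml_s(self) -> float:
        return STREAM_FLOW_ML_S[self.stream_speed_label]


@dataclass
class Trajectory:
    """Centroid positions (mm) over time in arena coordinates."""

    times_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        if not (self.times_s.size == self.x_mm.size == self.y_mm.size):
            raise ValueError("times, x and y must have equal length")
        if self.times_s.size >= 2 and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times_s.size


@dataclass
class EphysTrace:
    """Sampled field potential with stimulus reference."""

    samples: np.ndarray
    fs: float
    stim_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 2 * 500.0:
            raise ValueError("sampling rate must exceed twice the 500 Hz passband top")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


def default_body_width_profile(s: np.ndarray, body_length_mm: float = 30.0) -> np.ndarray:
    """Half-width (mm) of the fish at arc-length fraction ``s``.

    A rostro-caudally tapering fusiform profile: widest just behind the
    head (~7% of body length half-width), tapering to a fine tail.
    """
    s = np.asarray(s, dtype=float)
    # smooth rise to a maximum near s=0.22, then taper toward the tail
    w = s**0.5 * (1.0 - s) ** 1.6
    w = w / np.max(w + 1e-300)
    return 0.07 * body_length_mm * w + 0.01 * body_length_mm


def _silhouette_polygon(points_mm: np.ndarray, half_width_mm: np.ndarray) -> np.ndarray:
    """Closed outline polygon: midline offset by the width profile on
    both sides along the local normal."""
    d = np.gradient(points_mm, axis=0)
    norm = np.linalg.norm(d, axis=1, keepdims=True)
    tang = d / np.where(norm > 0, norm, 1.0)
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    left = points_mm + normal * half_width_mm[:, None]
    right = points_mm - normal * half_width_mm[:, None]
    return np.vstack([left, right[::-1]])


def render_frames(
    seq: MidlineSequence,
    px_per_mm: float = 6.0,
    frame_shape: tuple[int, int] | None = None,
    body_width_profile=default_body_width_profile,
    bg_noise_sd: float = 4.0,
    fish_intensity: int = 40,
    bg_intensity: int = 200,
    origin_mm: tuple[float, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a midline sequence as an 8-bit grayscale frame stack.

    The fish is drawn as a dark filled silhouette (midline swept by the
    tapering width profile) on a bright background, with zero-mean
    Gaussian pixel noise added and the result clipped to [0, 255].
    Returns ``(frames, masks)`` where ``masks`` is the boolean
    ground-truth silhouette per frame.

    Raises :class:`OutOfFrameError` if the silhouette leaves the frame in
    any frame.
    """
    if px_per_mm <= 0:
        raise ValueError("px_per_mm must be > 0")
    rng = np.random.default_rng(seed)
    seq = seq.to_mm()
    pts_all = seq.points_array()
    n_pts = pts_all.shape[1]
    s = np.linspace(0, 1, n_pts)
    bl = float(np.median([m.arc_length for m in seq.midlines]))
    hw = body_width_profile(s, bl)

    if origin_mm is None:
        margin = hw.max() + 2.0 / px_per_mm
        origin_mm = (pts_all[..., 0].min() - margin, pts_all[..., 1].min() - margin)
    if frame_shape is None:
        margin = hw.max() + 2.0 / px_per_mm
        w = int(np.ceil((pts_all[..., 0].max() - origin_mm[0] + margin) * px_per_mm)) + 1
        h = int(np.ceil((pts_all[..., 1].max() - origin_mm[1] + margin) * px_per_mm)) + 1
        frame_shape = (h, w)

    h_px, w_px = frame_shape
    frames = np.empty((len(seq), h_px, w_px), dtype=np.uint8)
    masks = np.zeros((len(seq), h_px, w_px), dtype=bool)
    bad_frames = []
    for i, pts in enumerate(pts_all):
        poly = _silhouette_polygon(pts, hw)
        col = (poly[:, 0] - origin_mm[0]) * px_per_mm
        row = (poly[:, 1] - origin_mm[1]) * px_per_mm
        if col.min() < 0 or row.min() < 0 or col.max() > w_px - 1 or row.max() > h_px - 1:
            bad_frames.append(i)
            continue
        rr, cc = draw_polygon(row, col, shape=frame_shape)
        mask = np.zeros(frame_shape, dtype=bool)
        mask[rr, cc] = True
        masks[i] = mask
        img = np.full(frame_shape, float(bg_intensity))
        img[mask] = float(fish_intensity)
        if bg_noise_sd > 0:
            img += rng.normal(0.0, bg_noise_sd, frame_shape)
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)
    if bad_frames:
        raise OutOfFrameError(bad_frames)
    return frames, masks


def simulate_arena_track(
    spec: ArenaSpec,
    preset: str = "wildtype",
    duration_s: float = 30.0,
    fps: float = 200.0,
    seed: int | np.random.Generator = 0,
    centre_pull_per_s: float = 2.0,
    step_sd_mm: dict[str, float] | None = None,
) -> tuple[Trajectory, dict]:
    """Reflected biased random walk of a fish holding station in a stream.

    The ``wildtype`` preset feels a mean-reverting (Ornstein-Uhlenbeck
    style) pull toward the arena's longitudinal centre line; the
    ``mutant`` preset has zero pull and larger step dispersion, so it
    drifts and disperses across the channel. Positions reflect at the
    walls. Returns the trajectory and a ground-truth dict.
    """
    n = int(round(duration_s * fps))
    if n < 100:
        raise ValueError("need duration_s * fps >= 100 samples")
    if preset not in ("wildtype", "mutant"):
        raise ValueError("preset must be 'wildtype' or 'mutant'")
    rng = np.random.default_rng(seed)
    step_sd_mm = step_sd_mm or {"wildtype": 0.35, "mutant": 0.7}
    sd = step_sd_mm[preset] / np.sqrt(fps) * np.sqrt(200.0)  # per-step, fps-scaled
    pull = centre_pull_per_s if preset == "wildtype" else 0.0
    dt = 1.0 / fps
    cx, cy = spec.width_mm / 2, spec.height_mm / 2
    x = np.empty(n)
    y = np.empty(n)
    x[0], y[0] = cx, cy
    noise = rng.normal(0.0, sd, size=(n - 1, 2))
    for i in range(1, n):
        # pull acts on the lateral (y) coordinate toward the centre line,
        # and weakly on x toward mid-channel where the current is steady
        dy = -pull * (y[i - 1] - cy) * dt + noise[i - 1, 1]
        dx = -0.3 * pull * (x[i - 1] - cx) * dt + noise[i - 1, 0]
        x[i] = x[i - 1] + dx
        y[i] = y[i - 1] + dy
        # reflect at walls
        x[i] = np.clip(np.abs(x[i]), 0, None)
        if x[i] > spec.width_mm:
            x[i] = 2 * spec.width_mm - x[i]
        y[i] = np.abs(y[i])
        if y[i] > spec.height_mm:
            y[i] = 2 * spec.height_mm - y[i]
        x[i] = np.clip(x[i], 0, spec.width_mm)
        y[i] = np.clip(y[i], 0, spec.height_mm)
    traj = Trajectory(times_s=np.arange(n) * dt, x_mm=x, y_mm=y, fps=fps)
    truth = {
        "preset": preset,
        "centre_pull_per_s": pull,
        "step_sd_mm": step_sd_mm[preset],
        "arena": {"width_mm": spec.width_mm, "height_mm": spec.height_mm,
                  "stream": spec.stream_speed_label},
    }
    return traj, truth


def spike_template(fs: float, width_ms: float = 2.5) -> np.ndarray:
    """Biphasic extracellular spike template, peak amplitude 1.

    A Gaussian-derivative wavelet whose two lobes are ~0.9 ms apart (a
    ~1 ms biphasic transient with short tails), putting its spectral
    energy inside the 300-500 Hz recording passband.
    """
    n = max(int(round(width_ms * 1e-3 * fs)), 5)
    t = np.linspace(-1.0, 1.0, n)
    w = -t * np.exp(-4 * t**2)  # odd, biphasic
    return w / np.max(np.abs(w))


def simulate_field_potential(
    large_times: np.ndarray,
    small_times: np.ndarray,
    fs: float = 25_000.0,
    duration_s: float = 5.0,
    amp_large: float = 10.0,
    amp_small: float = 3.0,
    hum_amp: float = 1.0,
    noise_sd: float = 1.0,
    stim_time_s: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[EphysTrace, dict]:
    """Synthesize a raw (pre-filter) Mauthner-cell field-potential trace.

    Biphasic ~1 ms spike templates are inserted at the given times with
    two amplitude classes, on top of 50 Hz mains hum and white noise —
    the signal the 300-500 Hz band-pass plus 50 Hz hum filter of the
    real rig are designed for. Spike times are relative to trace start;
    ``stim_time_s`` marks the stimulus for downstream alignment.
    """
    large_times = np.sort(np.asarray(large_times, dtype=float))
    small_times = np.sort(np.asarray(small_times, dtype=float))
    if amp_large <= amp_small or amp_small <= 0:
        raise ValueError("need amp_large > amp_small > 0")
    n = int(round(duration_s * fs))
    for t_arr in (large_times, small_times):
        if t_arr.size and (t_arr.min() < 0 or t_arr.max() >= duration_s):
            raise ValueError("spike times must lie within the trace duration")
    rng = np.random.default_rng(seed)
    tmpl = spike_template(fs)
    half = tmpl.size // 2
    sig = np.zeros(n)
    all_t = np.concatenate([large_times, small_times])
    if all_t.size >= 2:
        gaps = np.diff(np.sort(all_t))
        if np.any(gaps < tmpl.size / fs):
            warnings.warn(
                "spikes closer than the template width overlap; superposition kept",
                RuntimeWarning,
            )
    for times, amp in ((large_times, amp_large), (small_times, amp_small)):
        for t0 in times:
            i = int(round(t0 * fs))
            lo, hi = max(0, i - half), min(n, i - half + tmpl.size)
            sig[lo:hi] += amp * tmpl[lo - (i - half): hi - (i - half)]
    t = np.arange(n) / fs
    sig += hum_amp * np.sin(2 * np.pi * 50.0 * t)
    if noise_sd > 0:
        sig += rng.normal(0.0, noise_sd, n)
    trace = EphysTrace(samples=sig, fs=fs, stim_time_s=stim_time_s)
    truth = {
        "large_times_s": large_times.tolist(),
        "small_times_s": small_times.tolist(),
        "amp_large": amp_large,
        "amp_small": amp_small,
        "hum_amp": hum_amp,
        "noise_sd": noise_sd,
        "stim_time_s": stim_time_s,
    }
    return trace, truth


def simulate_axon_image(
    n_axons: int,
    diameter_mean_px: float = 12.0,
    diameter_sd_px: float = 2.0,
    roi_polygon: np.ndarray | None = None,
    image_shape: tuple[int, int] = (512, 512),
    blur_sigma: float = 1.0,
    noise_sd: float = 5.0,
    seed: int | np.random.Generator = 0,
    max_tries: int = 20_000,
) -> tuple[np.ndarray, dict]:
    """Cross-section micrograph stand-in: bright non-overlapping axon
    disks inside a ROI on a dark background, mildly blurred and noised.

    ``roi_polygon`` is an (k, 2) array of (row, col) vertices; default is
    a triangular ROI reminiscent of the ventral spinal-cord quantification
    area. Returns the uint8 image and ground truth (centres, diameters).

    Raises :class:`PackingError` when the disks cannot be placed without
    overlap within ``max_tries`` rejection-sampling attempts.
    """
    if n_axons < 0:
        raise ValueError("n_axons must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = image_shape
    if roi_polygon is None:
        roi_polygon = np.array([[h * 0.1, w * 0.5], [h * 0.9, w * 0.08],
                                [h * 0.9, w * 0.92]])
    roi_polygon = np.asarray(roi_polygon, dtype=float)
    rr, cc = draw_polygon(roi_polygon[:, 0], roi_polygon[:, 1], shape=image_shape)
    roi_mask = np.zeros(image_shape, dtype=bool)
    roi_mask[rr, cc] = True

    centres: list[tuple[float, float]] = []
    diams: list[float] = []
    tries = 0
    while len(centres) < n_axons:
        if tries >= max_tries:
            raise PackingError(
                f"placed only {len(centres)}/{n_axons} axons in {max_tries} tries"
            )
        tries += 1
        d = diameter_mean_px if diameter_sd_px == 0 else max(
            rng.normal(diameter_mean_px, diameter_sd_px), 2.0)
        r = d / 2
        row = rng.uniform(r, h - r)
        col = rng.uniform(r, w - r)
        ri, ci = int(round(row)), int(round(col))
        if not roi_mask[ri, ci]:
            continue
        ok = all((row - r0) ** 2 + (col - c0) ** 2 >= (r + d0 / 2 + 2.0) ** 2
                 for (r0, c0), d0 in zip(centres, diams))
        if ok:
            centres.append((row, col))
            diams.append(d)

    img = np.zeros(image_shape, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    for (row, col), d in zip(centres, diams):
        disk = (yy - row) ** 2 + (xx - col) ** 2 <= (d / 2) ** 2
        img[disk] = 200.0
    if blur_sigma > 0:
        img = gaussian_filter(img, blur_sigma)
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, image_shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    truth = {
        "centres_rc": [list(c) for c in centres],
        "diameters_px": diams,
        "roi_polygon": roi_polygon.tolist(),
    }
    return img, truth


def simulate_escape_sequence(
    duration_s: float = 5.0,
    fps: float = 936.0,
    stim_time_s: float = 1.0,
    peak_tortuosity: float = 0.6,
    bend_latency_s: float = 0.01,
    bend_duration_s: float = 0.05,
    n_points: int = 51,
    body_length_mm: float = 30.0,
    responds: bool = True,
) -> tuple[MidlineSequence, dict]:
    """Midline sequence of a C-start escape: straight swimming, then a
    transient C-bend shortly after the stimulus (if ``responds``).

    The C-bend is modelled as a uniform-curvature arc whose total turning
    angle rises and falls with a raised-cosine time course, scaled so the
    peak tortuosity matches ``peak_tortuosity``. Deterministic.
    """
    n = int(round(duration_s * fps))
    if not 0 <= stim_time_s < duration_s:
        raise ValueError("stim_time_s must lie within the record")
    t = np.arange(n) / fps
    # map target tortuosity -> arc total turning angle Theta via
    # chord/arc relation: tort = 1 - (2/Theta) sin(Theta/2)
    from scipy.optimize import brentq

    def tort_of(theta):
        return 1.0 - (2.0 / theta) * np.sin(theta / 2.0) if theta > 0 else 0.0

    theta_peak = brentq(lambda th: tort_of(th) - peak_tortuosity, 1e-6, 2 * np.pi - 1e-9)
    env = np.zeros(n)
    if responds:
        t0 = stim_time_s + bend_latency_s
        in_bend = (t >= t0) & (t <= t0 + bend_duration_s)
        u = (t[in_bend] - t0) / bend_duration_s
        env[in_bend] = 0.5 * (1 - np.cos(2 * np.pi * u))  # rise and fall
    s = np.linspace(0, 1, n_points)
    mids = []
    for e in env:
        theta = theta_peak * e
        if theta < 1e-9:
            pts = np.column_stack([s * body_length_mm, np.zeros(n_points)])
        else:
            R = body_length_mm / theta
            ang = theta * s
            pts = np.column_stack([R * np.sin(ang), R * (1 - np.cos(ang))])
        mids.append(Midline(pts))
    seq = MidlineSequence(mids, fps=fps, units="mm")
    truth = {
        "stim_time_s": stim_time_s,
        "peak_tortuosity": peak_tortuosity if responds else 0.0,
        "peak_time_s": stim_time_s + bend_latency_s + bend_duration_s / 2 if responds else None,
        "responds": responds,
    }
    return seq, truth
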