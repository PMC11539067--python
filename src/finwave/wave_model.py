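"""Kinematic model of zebrafish body undulation.

The body's local bending is modelled as the superposition of two
components that together produce the familiar sinus-like swimming motion:

* a **standing wave** concentrated over the pectoral region — a Gaussian
  envelope in arc length, oscillating in place with no spatial phase
  propagation;
* a **travelling wave** propagating rostro-caudally, with an amplitude
  envelope that grows toward the tail as a power of arc-length fraction.

A stiffness factor ``stiffness_gamma`` scales the travelling wave caudal
to ``stiffness_onset``, emulating a caudally stiffened body (the
"stiff" condition); ``stiffness_gamma = 1`` is full flexibility.

The inverse direction is also provided: fitting a single-frequency
complex amplitude profile to an observed bending field and splitting it
into standing and travelling parts via the spatial analytic signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "WaveParams",
    "BendingField",
    "Midline",
    "MidlineSequence",
    "generate_bending_field",
    "midlines_from_bending",
    "fit_single_frequency",
    "decompose_standing_travelling",
    "pectoral_peak_position",
    "SingleFrequencyFit",
    "WaveDecomposition",
    "InsufficientDataError",
    "UndefinedPeakError",
]

#: width (in body-length fraction) of the half-cosine ramp smoothing the
#: stiffness step, so reconstructed midlines have no curvature jump
STIFFNESS_RAMP_BL = 0.05


class InsufficientDataError(ValueError):
    """Record too short for the requested analysis."""


class UndefinedPeakError(ValueError):
    """No peak can be located (e.g. all-zero envelope)."""


@dataclass(frozen=True)
class WaveParams:
    """Full parameter set of the undulation model.

    All amplitudes are local bending angles in radians; all positions are
    arc-length fractions of body length (0 = snout, 1 = tail tip).
    """

    body_length_mm: float = 30.0
    n_segments: int = 50
    freq_hz: float = 2.5
    wavelength_bl: float = 1.0
    standing_amp_rad: float = 0.03
    standing_peak_pos: float = 0.25
    standing_width: float = 0.10
    travelling_amp_rad: float = 0.08
    caudal_growth_exp: float = 2.0
    stiffness_gamma: float = 1.0
    stiffness_onset: float = 0.5

    def __post_init__(self) -> None:
        numeric = {
            "body_length_mm": self.body_length_mm,
            "freq_hz": self.freq_hz,
            "wavelength_bl": self.wavelength_bl,
            "standing_amp_rad": self.standing_amp_rad,
            "standing_peak_pos": self.standing_peak_pos,
            "standing_width": self.standing_width,
            "travelling_amp_rad": self.travelling_amp_rad,
            "caudal_growth_exp": self.caudal_growth_exp,
            "stiffness_gamma": self.stiffness_gamma,
            "stiffness_onset": self.stiffness_onset,
        }
        for name, value in numeric.items():
            if not np.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
        if self.body_length_mm <= 0:
            raise ValueError("body_length_mm must be > 0")
        if self.n_segments < 10:
            raise ValueError("n_segments must be >= 10")
        if self.freq_hz <= 0:
            raise ValueError("freq_hz must be > 0")
        if self.wavelength_bl <= 0:
            raise ValueError("wavelength_bl must be > 0")
        if self.standing_amp_rad < 0 or self.travelling_amp_rad < 0:
            raise ValueError("amplitudes must be >= 0")
        if not 0.0 <= self.standing_peak_pos <= 1.0:
            raise ValueError("standing_peak_pos must be in [0, 1]")
        if self.standing_width <= 0:
            raise ValueError("standing_width must be > 0")
        if self.caudal_growth_exp < 0:
            raise ValueError("caudal_growth_exp must be >= 0")
        if not 0.0 <= self.stiffness_gamma <= 1.0:
            raise ValueError("stiffness_gamma must be in [0, 1]")
        if not 0.0 <= self.stiffness_onset <= 1.0:
            raise ValueError("stiffness_onset must be in [0, 1]")

    def with_(self, **kwargs) -> "WaveParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class BendingField:
    """Local bending angles indexed ``[time, segment]``.

    ``theta[i, j]`` is the bending (radians, positive counter-clockwise)
    of segment ``j`` at time ``times_s[i]``; ``s_frac[j]`` is the
    arc-length fraction of the segment midpoint.
    """

    theta: np.ndarray
    times_s: np.ndarray
    s_frac: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.s_frac = np.asarray(self.s_frac, dtype=float)
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("theta must be finite everywhere")
        if self.theta.shape != (self.times_s.size, self.s_frac.size):
            raise ValueError("theta shape inconsistent with times/s_frac")
        if np.any(np.diff(self.s_frac) <= 0):
            raise ValueError("s_frac must be strictly increasing")

    @property
    def fps(self) -> float:
        if self.times_s.size < 2:
            return 1.0  # single frame: rate is undefined, 1 Hz nominal
        return 1.0 / float(np.median(np.diff(self.times_s)))


@dataclass
class Midline:
    """Ordered 2D body curve, head first."""

    points: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("consecutive midline points must be distinct")

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def arc_length(self) -> float:
        return float(self.segment_lengths.sum())

    @property
    def head(self) -> np.ndarray:
        return self.points[0]

    @property
    def tail(self) -> np.ndarray:
        return self.points[-1]

    def resample(self, n_points: int, tol: float = 1e-7,
                 max_iter: int = 25) -> "Midline":
        """Resample to ``n_points`` points with equal spacing.

        Linear interpolation at uniform arc positions is repeated until
        consecutive point distances agree to ``tol`` (relative): a
        single pass spaces points uniformly along the old polyline, but
        their chord distances still vary where the polyline bends.
        """
        pts = self.points
        for _ in range(max_iter):
            seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            cum = np.concatenate([[0.0], np.cumsum(seg)])
            target = np.linspace(0.0, cum[-1], n_points)
            x = np.interp(target, cum, pts[:, 0])
            y = np.interp(target, cum, pts[:, 1])
            pts = np.column_stack([x, y])
            d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            if np.max(np.abs(d - d.mean())) <= tol * d.mean():
                break
        return Midline(pts)


@dataclass
class MidlineSequence:
    """Midline per video frame, with frame rate and units."""

    midlines: list
    fps: float
    units: str = "mm"
    scale_px_per_mm: float | None = None

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.units not in ("mm", "px"):
            raise ValueError("units must be 'mm' or 'px'")
        counts = {m.points.shape[0] for m in self.midlines}
        if len(counts) > 1:
            raise ValueError("all frames must have the same point count")

    def __len__(self) -> int:
        return len(self.midlines)

    @property
    def n_points(self) -> int:
        return self.midlines[0].points.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.midlines)) / self.fps

    def points_array(self) -> np.ndarray:
        """Stack all midlines into a (frames, points, 2) array."""
        return np.stack([m.points for m in self.midlines])

    def to_mm(self) -> "MidlineSequence":
        if self.units == "mm":
            return self
        if self.scale_px_per_mm is None:
            raise ValueError("scale_px_per_mm required to convert px -> mm")
        pts = self.points_array() / self.scale_px_per_mm
        return MidlineSequence([Midline(p) for p in pts], fps=self.fps, units="mm")


def _gaussian_envelope(s: np.ndarray, peak: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((s - peak) / width) ** 2)


def stiffness_profile(s: np.ndarray, params: WaveParams) -> np.ndarray:
    """Travelling-wave scaling gamma(s): 1 rostrally, ``stiffness_gamma``
    caudal to ``stiffness_onset``, joined by a half-cosine ramp of width
    ``STIFFNESS_RAMP_BL`` centred on the onset."""
    s = np.asarray(s, dtype=float)
    g0, g1 = 1.0, params.stiffness_gamma
    half = STIFFNESS_RAMP_BL / 2.0
    lo, hi = params.stiffness_onset - half, params.stiffness_onset + half
    out = np.where(s < lo, g0, g1)
    in_ramp = (s >= lo) & (s <= hi)
    if np.any(in_ramp):
        u = (s[in_ramp] - lo) / (hi - lo)
        out = out.astype(float)
        out[in_ramp] = g0 + (g1 - g0) * 0.5 * (1 - np.cos(np.pi * u))
    return out


def generate_bending_field(
    params: WaveParams, duration_s: float, fps: float
) -> BendingField:
    """Sample the model bending field over ``duration_s`` at ``fps``.

    theta(s, t) = A_st G(s) cos(2 pi f t)
                + gamma(s) A_tr s^q cos(2 pi f t - 2 pi s / lambda)

    with G a Gaussian envelope (max 1 at ``standing_peak_pos``) and
    gamma(s) the smoothed stiffness profile. Deterministic.
    """
    if duration_s <= 0 or fps <= 0:
        raise ValueError("duration_s and fps must be > 0")
    if fps < 2 * params.freq_hz:
        warnings.warn(
            f"fps={fps} below Nyquist for freq_hz={params.freq_hz}: "
            "bending field will be aliased",
            RuntimeWarning,
        )
    n_frames = int(round(duration_s * fps))
    t = np.arange(n_frames) / fps
    # segment midpoints in arc-length fraction
    s = (np.arange(params.n_segments) + 0.5) / params.n_segments
    G = _gaussian_envelope(s, params.standing_peak_pos, params.standing_width)
    gamma = stiffness_profile(s, params)
    omega_t = 2 * np.pi * params.freq_hz * t[:, None]
    standing = params.standing_amp_rad * G[None, :] * np.cos(omega_t)
    phase = 2 * np.pi * s[None, :] / params.wavelength_bl
    travelling = (
        gamma[None, :]
        * params.travelling_amp_rad
        * s[None, :] ** params.caudal_growth_exp
        * np.cos(omega_t - phase)
    )
    return BendingField(theta=standing + travelling, times_s=t, s_frac=s)


def midlines_from_bending(field: BendingField, params: WaveParams) -> MidlineSequence:
    """Reconstruct the inextensible body curve from bending angles.

    Per frame, heading is accumulated over segments and unit tangents are
    integrated with uniform segment length ``body_length_mm/n_segments``;
    the head sits at the origin with initial heading along +x, so total
    arc length equals body length by construction.
    """
    if field.s_frac.size != params.n_segments:
        raise ValueError("field segment count inconsistent with params.n_segments")
    ds = params.body_length_mm / params.n_segments
    heading = np.cumsum(field.theta, axis=1)  # (T, n_segments)
    tx = np.cos(heading) * ds
    ty = np.sin(heading) * ds
    x = np.concatenate([np.zeros((field.theta.shape[0], 1)), np.cumsum(tx, axis=1)], axis=1)
    y = np.concatenate([np.zeros((field.theta.shape[0], 1)), np.cumsum(ty, axis=1)], axis=1)
    fps = field.fps
    mids = [Midline(np.column_stack([xi, yi])) for xi, yi in zip(x, y)]
    return MidlineSequence(mids, fps=fps, units="mm")


@dataclass
class SingleFrequencyFit:
    """Complex amplitude profile at the dominant oscillation frequency."""

    freq_hz: float
    z: np.ndarray  # complex, per segment
    s_frac: np.ndarray
    low_power: bool = False

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.z)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.z)


def fit_single_frequency(field: BendingField, low_power_rel: float = 0.05) -> SingleFrequencyFit:
    """Fit ``theta(s, t) ~ C(s) cos(2 pi f t) + S(s) sin(2 pi f t)``.

    The dominant frequency is the argmax of the mean power spectrum of
    mean-subtracted bending over mid-body segments; per segment a
    least-squares fit then yields Z(s) = C(s) - i S(s).

    Raises
    ------
    InsufficientDataError
        if the record is shorter than two oscillation periods of the
        dominant frequency.
    """
    theta = field.theta - field.theta.mean(axis=0, keepdims=True)
    n_t = theta.shape[0]
    fps = field.fps
    # mid-body segments carry the most power and least noise
    n_seg = theta.shape[1]
    mid = slice(n_seg // 4, 3 * n_seg // 4)
    spec = np.abs(np.fft.rfft(theta[:, mid], axis=0)) ** 2
    freqs = np.fft.rfftfreq(n_t, d=1.0 / fps)
    mean_power = spec.mean(axis=1)
    mean_power[0] = 0.0  # exclude DC
    k = int(np.argmax(mean_power))
    f = float(freqs[k])
    if f <= 0 or (n_t / fps) < 2.0 / f:
        raise InsufficientDataError(
            "record must contain at least 2 full periods of the dominant frequency"
        )
    t = field.times_s
    design = np.column_stack([np.cos(2 * np.pi * f * t), np.sin(2 * np.pi * f * t)])
    coef, *_ = np.linalg.lstsq(design, theta, rcond=None)
    z = coef[0] - 1j * coef[1]
    resid = theta - design @ coef
    total = float(np.sum(theta**2))
    explained = total - float(np.sum(resid**2))
    low_power = total == 0 or explained / max(total, 1e-300) < low_power_rel
    if low_power:
        warnings.warn(
            "single-frequency fit explains little variance (low-power field)",
            RuntimeWarning,
        )
    return SingleFrequencyFit(freq_hz=f, z=z, s_frac=field.s_frac, low_power=low_power)


@dataclass
class WaveDecomposition:
    """Standing/travelling split of a complex amplitude profile."""

    standing: np.ndarray
    travelling: np.ndarray
    travelling_index: np.ndarray
    s_frac: np.ndarray


def _spatial_halves(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a complex profile into positive / negative spatial-frequency
    parts (the two counter-propagating components). DC and Nyquist are
    shared half-and-half."""
    n = z.size
    Z = np.fft.fft(z)
    pos = np.zeros_like(Z)
    neg = np.zeros_like(Z)
    pos[0] = neg[0] = Z[0] / 2
    half = n // 2
    if n % 2 == 0:
        pos[half] = neg[half] = Z[half] / 2
        pos[1:half] = Z[1:half]
        neg[half + 1 :] = Z[half + 1 :]
    else:
        pos[1 : half + 1] = Z[1 : half + 1]
        neg[half + 1 :] = Z[half + 1 :]
    return np.fft.ifft(pos), np.fft.ifft(neg)


def decompose_standing_travelling(
    fit: SingleFrequencyFit | np.ndarray, s_frac: np.ndarray | None = None
) -> WaveDecomposition:
    """Split a complex amplitude profile into standing and travelling parts.

    The profile is separated into counter-propagating components
    ``Z = Z+ + Z-`` via its spatial analytic signal; then per segment

    * standing amplitude  = 2 min(|Z+|, |Z-|)
    * travelling amplitude = | |Z+| - |Z-| |
    * travelling_index = travelling / (travelling + standing), with the
      0/0 case defined as 0.
    """
    if isinstance(fit, SingleFrequencyFit):
        z, s = fit.z, fit.s_frac
    else:
        z = np.asarray(fit, dtype=complex)
        s = np.asarray(s_frac) if s_frac is not None else np.linspace(0, 1, z.size)
    if z.size < 10:
        raise ValueError("profile must span at least 10 segments")
    zp, zn = _spatial_halves(z)
    ap, an = np.abs(zp), np.abs(zn)
    standing = 2 * np.minimum(ap, an)
    travelling = np.abs(ap - an)
    denom = standing + travelling
    with np.errstate(invalid="ignore", divide="ignore"):
        ti = np.where(denom > 0, travelling / np.where(denom > 0, denom, 1.0), 0.0)
    return WaveDecomposition(standing=standing, travelling=travelling,
                             travelling_index=ti, s_frac=s)


def pectoral_peak_position(
    envelope: np.ndarray,
    s_frac: np.ndarray,
    rostral_window: tuple[float, float] = (0.0, 0.5),
) -> float:
    """Arc-length fraction of the envelope maximum in the rostral window.

    Ties break to the most rostral maximum; the argmax is refined to
    sub-segment resolution by parabolic interpolation over its neighbours.
    This is the model-side analogue of the "pectoral bending peak
    position (normalised to body length)" reported for tracked fish.
    """
    envelope = np.asarray(envelope, dtype=float)
    s_frac = np.asarray(s_frac, dtype=float)
    if np.any(envelope < 0):
        raise ValueError("envelope must be non-negative")
    lo, hi = rostral_window
    mask = (s_frac >= lo) & (s_frac <= hi)
    if not np.any(mask) or np.all(envelope[mask] == 0):
        raise UndefinedPeakError("envelope is all-zero within the rostral window")
    idx = np.flatnonzero(mask)
    sub = envelope[idx]
    k = idx[int(np.argmax(sub))]  # np.argmax returns first (most rostral) max
    if 0 < k < envelope.size - 1 and envelope[k - 1] != envelope[k + 1]:
        y0, y1, y2 = envelope[k - 1], envelope[k], envelope[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:  # genuine local max: refine
            delta = 0.5 * (y0 - y2) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            ds = s_frac[min(k + 1, s_frac.size - 1)] - s_frac[k] if k + 1 < s_frac.size else s_frac[k] - s_frac[k - 1]
            return float(np.clip(s_frac[k] + delta * ds, 0.0, 1.0))
    return float(s_frac[k])
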