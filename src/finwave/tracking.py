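"""Midline tracker for single-fish grayscale video.

Per frame: threshold (Otsu or fixed), keep the largest blob, fill holes,
skeletonize, prune the skeleton to its longest path, smooth and resample
to equidistant points. Head/tail orientation is resolved from the
centroid velocity with a temporal-consistency window, falling back to
the wider body end when the fish is near-stationary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_fill_holes, uniform_filter1d
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import skeletonize

from .synthetic import Trajectory
from .wave_model import Midline, MidlineSequence

__all__ = [
    "TrackConfig",
    "segment_fish",
    "extract_midline",
    "orient_head",
    "track_stack",
    "NoFishError",
    "DegenerateShapeError",
    "TrackingAbort",
]


class NoFishError(ValueError):
    """No sufficiently large blob found in the frame."""


class DegenerateShapeError(ValueError):
    """Mask skeleton too short to define a midline."""


class TrackingAbort(RuntimeError):
    """Too many frames failed quality control."""


@dataclass(frozen=True)
class TrackConfig:
    threshold_method: str = "automatic"      # automatic (Otsu) | fixed
    fixed_threshold: float = 128.0
    polarity: str = "dark-fish"              # dark-fish | bright-fish
    min_blob_px: int = 50
    n_midline_points: int = 51
    smoothing_window: int = 7
    speed_threshold_px_per_frame: float = 0.2
    orientation_window: int = 31

    def __post_init__(self) -> None:
        if self.threshold_method not in ("automatic", "fixed"):
            raise ValueError("threshold_method must be 'automatic' or 'fixed'")
        if self.polarity not in ("dark-fish", "bright-fish"):
            raise ValueError("polarity must be 'dark-fish' or 'bright-fish'")
        if self.n_midline_points < 11 or self.n_midline_points % 2 == 0:
            raise ValueError("n_midline_points must be >= 11 and odd")


def segment_fish(frame: np.ndarray, cfg: TrackConfig = TrackConfig()) -> np.ndarray:
    """Binary fish mask: threshold, keep largest blob, fill holes."""
    img = np.asarray(frame, dtype=float)
    thr = threshold_otsu(img) if cfg.threshold_method == "automatic" else cfg.fixed_threshold
    fg = img < thr if cfg.polarity == "dark-fish" else img > thr
    lab = label(fg)
    if lab.max() == 0:
        raise NoFishError("no foreground component in frame")
    sizes = np.bincount(lab.ravel())[1:]
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < cfg.min_blob_px:
        raise NoFishError(
            f"largest component ({sizes[best - 1]} px) below min_blob_px={cfg.min_blob_px}"
        )
    return binary_fill_holes(lab == best)


_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _longest_path(skel: np.ndarray) -> np.ndarray:
    """Longest path (graph diameter) over 8-connected skeleton pixels,
    via double breadth-first search. Returns (n, 2) array of (row, col)."""
    pix = np.argwhere(skel)
    index = {tuple(p): i for i, p in enumerate(map(tuple, pix))}
    adj: list[list[int]] = [[] for _ in range(len(pix))]
    for (r, c), i in index.items():
        for dr, dc in _NBRS:
            j = index.get((r + dr, c + dc))
            if j is not None:
                adj[i].append(j)

    def bfs(start: int) -> tuple[np.ndarray, np.ndarray]:
        dist = np.full(len(pix), -1, dtype=int)
        parent = np.full(len(pix), -1, dtype=int)
        dist[start] = 0
        queue = [start]
        while queue:
            nxt = []
            for u in queue:
                for v in adj[u]:
                    if dist[v] < 0:
                        dist[v] = dist[u] + 1
                        parent[v] = u
                        nxt.append(v)
            queue = nxt
        return dist, parent

    d0, _ = bfs(0)
    a = int(np.argmax(d0))
    d1, par = bfs(a)
    b = int(np.argmax(d1))
    path = [b]
    while par[path[-1]] >= 0:
        path.append(int(par[path[-1]]))
    return pix[path[::-1]]


def _extend_to_boundary(xy: np.ndarray, mask: np.ndarray, fit_pts: int = 14,
                        step: float = 0.5, max_steps: int = 200) -> np.ndarray:
    """Extrapolate both path ends to the mask boundary, so the midline
    reaches the snout and tail tips instead of stopping where the
    skeleton erodes.

    Each end is continued by a quadratic fit (in arc length) to its last
    ``fit_pts`` points, which preserves local curvature; a straight
    tangent would kink whenever the body end is bent, imprinting a
    spurious oscillation on the bending field at the junction.
    """
    h, w = mask.shape

    def inside(p):
        c, r = int(round(p[0])), int(round(p[1]))
        return 0 <= r < h and 0 <= c < w and mask[r, c]

    out = [xy]
    for end in (0, -1):
        k = min(fit_pts, xy.shape[0])
        pts = xy[:k] if end == 0 else xy[-k:]
        # arc-length distance from the end point, increasing inward
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        t_par = np.cumsum(np.concatenate([[0.0], seg]))
        dist = t_par if end == 0 else t_par[-1] - t_par
        if np.allclose(dist.max(), 0):
            continue
        cx = np.polyfit(dist, pts[:, 0], 2)
        cy = np.polyfit(dist, pts[:, 1], 2)
        ext = []
        for i in range(1, max_steps + 1):
            d = -i * step  # negative distance: beyond the end
            q = np.array([np.polyval(cx, d), np.polyval(cy, d)])
            if not inside(q):
                break
            ext.append(q)
        if ext:
            if end == 0:
                out.insert(0, np.array(ext[::-1]))
            else:
                out.append(np.array(ext))
    return np.vstack(out)


def _refine_to_chord_midpoints(xy: np.ndarray, mask: np.ndarray,
                               n_iter: int = 2, step: float = 0.25,
                               reach_px: float = 40.0) -> np.ndarray:
    """Snap midline points to the midpoints of the mask cross-sections.

    For a bilaterally symmetric body the midline is, by construction,
    the locus of midpoints of chords perpendicular to it. The raw
    skeleton path deviates from that locus where the body is wide (the
    medial axis branches toward boundary corners); sampling the mask
    along each point's normal and re-centring on the inside-mask chord
    removes this bias at sub-pixel resolution.
    """
    from scipy.ndimage import map_coordinates

    maskf = mask.astype(float)
    offs = np.arange(-reach_px, reach_px + step / 2, step)  # (K,)
    for _ in range(n_iter):
        d = np.gradient(xy, axis=0)
        nrm = np.linalg.norm(d, axis=1, keepdims=True)
        tang = d / np.where(nrm > 0, nrm, 1.0)
        normal = np.column_stack([-tang[:, 1], tang[:, 0]])  # (N, 2)
        # sample the mask along each normal: coords (N, K)
        px = xy[:, 0:1] + normal[:, 0:1] * offs[None, :]
        py = xy[:, 1:2] + normal[:, 1:2] * offs[None, :]
        vals = map_coordinates(maskf, [py.ravel(), px.ravel()], order=1,
                               mode="constant").reshape(px.shape)
        inside = vals > 0.5
        k0 = offs.size // 2  # index of the current point (offset 0)
        new = xy.copy()
        for i in range(xy.shape[0]):
            row = inside[i]
            if not row[k0]:
                continue  # point off the mask: leave it for smoothing
            lo = k0
            while lo > 0 and row[lo - 1]:
                lo -= 1
            hi = k0
            while hi < offs.size - 1 and row[hi + 1]:
                hi += 1
            centre = 0.5 * (offs[lo] + offs[hi])
            new[i] = xy[i] + normal[i] * centre
        xy = new
    return xy


def extract_midline(mask: np.ndarray, cfg: TrackConfig = TrackConfig()) -> Midline:
    """Skeleton-based midline: longest skeleton path, extended to the
    mask boundary along its end tangents, smoothed and resampled to
    ``n_midline_points`` equidistant points (x, y in px)."""
    skel = skeletonize(mask)
    if skel.sum() == 0:
        raise DegenerateShapeError("empty skeleton")
    path_rc = _longest_path(skel)
    if path_rc.shape[0] < 5:
        raise DegenerateShapeError("skeleton path shorter than 5 px")
    xy = np.column_stack([path_rc[:, 1], path_rc[:, 0]]).astype(float)
    win = min(cfg.smoothing_window, max(3, (xy.shape[0] // 2) * 2 - 1))
    if win >= 3:
        xy = np.column_stack([uniform_filter1d(xy[:, 0], win, mode="nearest"),
                              uniform_filter1d(xy[:, 1], win, mode="nearest")])
    # tangent directions at the eroded ends point toward the true tips
    xy = _extend_to_boundary(xy, mask)
    # drop accidental duplicate points after smoothing
    keep = np.ones(len(xy), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(xy, axis=0), axis=1) > 1e-12
    mid = Midline(xy[keep]).resample(cfg.n_midline_points)
    # re-centre on the body: chord-midpoint refinement kills the medial
    # axis' bias toward boundary corners in the wide head region
    refined = _refine_to_chord_midpoints(mid.points, mask)
    win = cfg.smoothing_window
    if win >= 3:
        refined = np.column_stack([
            uniform_filter1d(refined[:, 0], win, mode="nearest"),
            uniform_filter1d(refined[:, 1], win, mode="nearest"),
        ])
    keep = np.ones(len(refined), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(refined, axis=0), axis=1) > 1e-12
    return Midline(refined[keep]).resample(cfg.n_midline_points)


def _widths_at_ends(mask: np.ndarray, midline: Midline) -> tuple[float, float]:
    """Approximate body width near each midline end via the distance
    transform of the mask."""
    from scipy.ndimage import distance_transform_edt

    dt = distance_transform_edt(mask)
    h, w = mask.shape

    def width_at(pt_xy: np.ndarray) -> float:
        c = int(np.clip(round(pt_xy[0]), 0, w - 1))
        r = int(np.clip(round(pt_xy[1]), 0, h - 1))
        return float(dt[r, c])

    n = midline.points.shape[0]
    # sample interior bands (10-25% from each end): the extreme points
    # sit on the mask boundary where the distance transform vanishes
    i0, i1 = max(1, n // 10), max(2, n // 4)
    first = float(np.mean([width_at(p) for p in midline.points[i0:i1]]))
    last = float(np.mean([width_at(p) for p in midline.points[n - i1:n - i0]]))
    return first, last


def orient_head(
    midlines: list[Midline],
    trajectory: Trajectory,
    cfg: TrackConfig = TrackConfig(),
    end_widths: list[tuple[float, float]] | None = None,
    fps: float | None = None,
    units: str = "px",
) -> tuple[MidlineSequence, np.ndarray]:
    """Orient each midline head-first.

    The head is the endpoint whose local tangent best aligns with the
    centroid velocity, voted over a sliding window so single frames
    cannot flip the orientation. When centroid speed is below threshold
    the decision falls back to the wider body end (if widths are given)
    or carries the previous orientation forward; such frames are flagged.
    Returns the oriented sequence and a boolean array of flagged frames.
    """
    n = len(midlines)
    if n < 3:
        raise ValueError("need at least 3 frames to orient")
    fps = fps if fps is not None else trajectory.fps

    # the raw skeleton path order is arbitrary per frame: make it
    # temporally consistent first by aligning each frame to its
    # predecessor (whichever order matches point-for-point better),
    # flipping the end-width pairs along with the points
    midlines = list(midlines)
    end_widths = list(end_widths) if end_widths is not None else None
    for i in range(1, n):
        prev = midlines[i - 1].points
        cur = midlines[i].points
        direct = float(np.sum((cur - prev) ** 2))
        flipped = float(np.sum((cur[::-1] - prev) ** 2))
        if flipped < direct:
            midlines[i] = Midline(cur[::-1])
            if end_widths is not None:
                end_widths[i] = end_widths[i][::-1]
    # smooth positions over the consistency window first, so lateral
    # centroid oscillation from the tail beat cancels and only net
    # displacement votes on the heading
    win_s = min(cfg.orientation_window, n)
    sx = uniform_filter1d(trajectory.x_mm, win_s, mode="nearest")
    sy = uniform_filter1d(trajectory.y_mm, win_s, mode="nearest")
    vx = np.gradient(sx)
    vy = np.gradient(sy)
    speed = np.hypot(vx, vy)

    # per-frame evidence that the current point order is head-first:
    # velocity vote (head leads, so velocity opposes the head->tail chord)
    # weighted by how decisively the fish is moving, plus a width vote
    # (the head end of the body is wider than the tail end)
    score = np.zeros(n)
    for i, m in enumerate(midlines):
        chord = m.tail - m.head
        nrm = np.linalg.norm(chord)
        if nrm > 0 and speed[i] >= cfg.speed_threshold_px_per_frame:
            align = -(chord[0] * vx[i] + chord[1] * vy[i]) / (nrm * max(speed[i], 1e-12))
            weight = min(speed[i] / cfg.speed_threshold_px_per_frame, 5.0)
            score[i] = align * weight
        if end_widths is not None:
            first, last = end_widths[i]
            if first + last > 0:
                score[i] += 0.5 * (first - last) / (first + last)
    win = cfg.orientation_window
    votes = uniform_filter1d(score, size=min(win, n), mode="nearest")

    # hysteresis: only a decisive opposite vote flips the orientation,
    # so borderline frames carry the previous decision forward
    flagged = np.abs(votes) < 0.05
    oriented: list[Midline] = []
    prev_keep = votes[np.argmax(np.abs(votes))] > 0 if n else True
    for i, m in enumerate(midlines):
        keep = votes[i] > 0 if not flagged[i] else prev_keep
        prev_keep = keep
        oriented.append(m if keep else Midline(m.points[::-1]))
    return MidlineSequence(oriented, fps=fps, units=units), flagged


def track_stack(
    frames: np.ndarray,
    cfg: TrackConfig = TrackConfig(),
    fps: float = 200.0,
    scale_px_per_mm: float | None = None,
    max_failed_frac: float = 0.2,
) -> tuple[MidlineSequence, Trajectory, pd.DataFrame]:
    """Track a frame stack: per-frame segmentation + midline extraction,
    centroid trajectory, head orientation and a QC table.

    Failed frames (no fish / degenerate shape) are flagged in QC and
    interpolated from neighbours in the output sequence; if more than
    ``max_failed_frac`` of frames fail, the run aborts with a QC report
    attached to the exception.
    """
    n = len(frames)
    raw_mids: list[Midline | None] = []
    cents = np.full((n, 2), np.nan)
    widths: list[tuple[float, float]] = []
    qc_rows = []
    for i, frame in enumerate(frames):
        status = "ok"
        try:
            mask = segment_fish(frame, cfg)
            mid = extract_midline(mask, cfg)
            props = regionprops(mask.astype(int))[0]
            cents[i] = props.centroid[::-1]  # (x, y)
            widths.append(_widths_at_ends(mask, mid))
            raw_mids.append(mid)
        except (NoFishError, DegenerateShapeError) as exc:
            status = type(exc).__name__
            raw_mids.append(None)
            widths.append((0.0, 0.0))
        qc_rows.append({"frame": i, "status": status})
    qc = pd.DataFrame(qc_rows)
    failed = qc["status"] != "ok"
    if failed.mean() > max_failed_frac:
        raise TrackingAbort(
            f"{int(failed.sum())}/{n} frames failed QC "
            f"({failed.mean():.0%} > {max_failed_frac:.0%}); statuses: "
            f"{qc['status'].value_counts().to_dict()}"
        )
    # fill failed frames from nearest tracked neighbour so the sequence
    # stays rectangular; QC marks them for downstream masking
    last_good = None
    for i in range(n):
        if raw_mids[i] is None:
            raw_mids[i] = last_good
        else:
            last_good = raw_mids[i]
    first_good = next(m for m in raw_mids if m is not None)
    raw_mids = [m if m is not None else first_good for m in raw_mids]
    for i in range(n):
        if not np.isfinite(cents[i]).all():
            cents[i] = cents[i - 1] if i > 0 else np.nanmean(cents, axis=0)

    traj = Trajectory(times_s=np.arange(n) / fps, x_mm=cents[:, 0],
                      y_mm=cents[:, 1], fps=fps)
    seq, flagged = orient_head(raw_mids, traj, cfg, end_widths=widths, fps=fps)
    qc["orientation_flagged"] = flagged
    if scale_px_per_mm is not None:
        seq = MidlineSequence(seq.midlines, fps=fps, units="px",
                              scale_px_per_mm=scale_px_per_mm).to_mm()
        traj = Trajectory(times_s=traj.times_s, x_mm=traj.x_mm / scale_px_per_mm,
                          y_mm=traj.y_mm / scale_px_per_mm, fps=fps)
    return seq, traj, qc
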