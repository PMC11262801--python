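"""Turn raw tracks into fixed-shape, normalized posture windows.

A posture window is a short (default 2 s) slice of a larva's midline series,
resampled to ``L`` uniform time samples and ``S`` arc-length-uniform spine
points, then normalized so that learning is invariant to where the animal is,
which way it faces and how large it is:

* translation — the window centroid is moved to the origin;
* scale — coordinates are divided by the mean body length over the window;
* rotation — the head->tail axis of the first time sample is aligned with +x.

Each window may carry an extended context slab covering ``context_windows``
window-lengths of past and future postures, normalized with the *same*
transform as the centre slab; the autoencoder reconstructs this extended
sequence from the centre window alone.

Normalization is per-window, not per-track, so a tagger needs no track-level
statistics at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trackdata_io import Track

__all__ = [
    "WindowingConfig",
    "PostureWindow",
    "resample_spine",
    "normalize_window",
    "extract_windows",
    "extract_windows_indexed",
]


@dataclass(frozen=True)
class WindowingConfig:
    """Shape and timing parameters of posture-window extraction.

    window_seconds : temporal extent of the centre window (s).
    samples_per_window : L, number of uniform time samples per window.
    spine_points : S, number of arc-length-uniform midline points.
    context_windows : window-lengths of past and of future context to attach.
    stride_seconds : minimum time between consecutive window centres; None
        places one window at every timestep.
    pad_boundaries : replicate the first/last frame so that every timestep
        gets a window; if False, windows overlapping the track ends are
        dropped.
    max_gap_fraction : a window is invalidated when the raw sampling gap
        inside its span exceeds this fraction of ``window_seconds``.
    """

    window_seconds: float = 2.0
    samples_per_window: int = 20
    spine_points: int = 5
    context_windows: int = 1
    stride_seconds: float | None = None
    pad_boundaries: bool = True
    max_gap_fraction: float = 0.5

    def __post_init__(self):
        if self.window_seconds <= 0 or self.samples_per_window < 2 or self.spine_points < 3:
            raise ValueError("window_seconds > 0, L >= 2 and S >= 3 required")
        if self.context_windows < 0:
            raise ValueError("context_windows must be >= 0")

    @property
    def extended_samples(self) -> int:
        return (1 + 2 * self.context_windows) * self.samples_per_window


@dataclass
class PostureWindow:
    """A normalized, fixed-shape posture sequence X_t centred at ``t_center``.

    ``x`` has shape (L, S, 2); ``context`` (when present) has shape
    ((1 + 2*context_windows) * L, S, 2) and contains ``x`` as its centre slab.
    ``frame_index`` is the timestep of the source track the window maps back to.
    """

    larva_id: int
    t_center: float
    x: np.ndarray
    context: np.ndarray | None = None
    frame_index: int = field(default=-1)


def resample_spine(points: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a piecewise-linear midline to points uniform in arc length.

    Endpoints are preserved exactly. Requires >= 2 input points with distinct
    consecutive coordinates.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2 or points.shape[1] != 2:
        raise ValueError(f"expected (K>=2, 2) array, got {points.shape}")
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if np.any(seg == 0):
        raise ValueError("consecutive midline points must be distinct")
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    target = np.linspace(0.0, arc[-1], n_points)
    out = np.column_stack([np.interp(target, arc, points[:, d]) for d in range(2)])
    out[0], out[-1] = points[0], points[-1]
    return out


def _window_transform(center: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Translation/scale/rotation parameters computed from a centre slab."""
    centroid = center.reshape(-1, 2).mean(axis=0)
    seg = np.diff(center - centroid, axis=1)
    mean_length = np.linalg.norm(seg, axis=2).sum(axis=1).mean()
    if mean_length <= 0:
        raise ValueError("zero body length in window")
    first = (center[0] - centroid) / mean_length
    axis = first[-1] - first[0]  # head -> tail
    angle = float(np.arctan2(axis[1], axis[0]))
    return centroid, float(mean_length), angle


def _apply_transform(raw: np.ndarray, centroid, scale, angle) -> np.ndarray:
    out = (raw - centroid) / scale
    c, s = np.cos(-angle), np.sin(-angle)
    rot = np.array([[c, -s], [s, c]])
    return out @ rot.T


def normalize_window(raw: np.ndarray) -> np.ndarray:
    """Normalize an (L, S, 2) slab: centroid to origin, mean body length to 1,
    first-sample head->tail axis along +x. Idempotent."""
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("non-finite coordinates in window")
    centroid, scale, angle = _window_transform(raw)
    return _apply_transform(raw, centroid, scale, angle)


def _interp_slab(t_grid: np.ndarray, t: np.ndarray, spine: np.ndarray) -> np.ndarray:
    """Linear interpolation of an (T, S, 2) series onto ``t_grid``; the grid is
    clamped to the track's time range, which replicates the boundary frames."""
    T, S, _ = spine.shape
    grid = np.clip(t_grid, t[0], t[-1])
    out = np.empty((len(grid), S, 2))
    for j in range(S):
        for d in range(2):
            out[:, j, d] = np.interp(grid, t, spine[:, j, d])
    return out


def extract_windows_indexed(
    track: Track, cfg: WindowingConfig
) -> list[PostureWindow]:
    """Extract one normalized window per (strided) timestep of ``track``.

    Returns windows carrying ``frame_index`` so that predictions can be mapped
    back onto timesteps; timesteps whose window is invalidated (large sampling
    gap, or boundary overlap with padding disabled) are simply absent.
    """
    if track.n_frames < 2 or track.duration() < cfg.window_seconds:
        return []
    if not np.all(np.isfinite(track.spine)):
        raise ValueError("non-finite coordinates; clean the track at I/O level first")

    t = track.t
    spine = np.stack([resample_spine(track.spine[k], cfg.spine_points)
                      for k in range(track.n_frames)])
    half = cfg.window_seconds / 2.0
    chalf = (cfg.context_windows + 0.5) * cfg.window_seconds
    L, C = cfg.samples_per_window, cfg.context_windows
    diffs = np.diff(t)
    max_gap = cfg.max_gap_fraction * cfg.window_seconds

    windows: list[PostureWindow] = []
    last_center = -np.inf
    for k in range(track.n_frames):
        tc = t[k]
        if cfg.stride_seconds is not None and tc - last_center < cfg.stride_seconds - 1e-12:
            continue
        if not cfg.pad_boundaries and (tc - half < t[0] or tc + half > t[-1]):
            continue
        # a raw sampling gap overlapping the centre span invalidates the
        # window (its content would be interpolated across the hole)
        overlapping = (t[1:] > tc - half) & (t[:-1] < tc + half)
        if np.any(diffs[overlapping] > max_gap):
            continue
        grid = np.linspace(tc - chalf, tc + chalf, cfg.extended_samples)
        slab = _interp_slab(grid, t, spine)
        center = slab[C * L:(C + 1) * L]
        centroid, scale, angle = _window_transform(center)
        slab = _apply_transform(slab, centroid, scale, angle)
        windows.append(PostureWindow(
            larva_id=track.larva_id, t_center=float(tc),
            x=slab[C * L:(C + 1) * L], context=slab, frame_index=k,
        ))
        last_center = tc
    return windows


def extract_windows(track: Track, cfg: WindowingConfig) -> list[PostureWindow]:
    """Public alias of :func:`extract_windows_indexed` (same contract)."""
    return extract_windows_indexed(track, cfg)
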