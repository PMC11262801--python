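"""Synthetic dorsal-view larval midline trajectories with ground-truth labels.

The simulator is a kinematic cartoon, not a biomechanical model: its job is to
provide the learning and statistics modules with distinguishable, labelled
action classes under controllable difficulty (coordinate noise, slow/fast
phenotype multiplier). Six archetypal actions are generated in midline terms:

* ``crawl`` — travelling longitudinal compression wave (tail -> head) plus net
  head-first displacement; body length oscillates at the peristaltic frequency.
* ``back`` — the same wave reversed, with net tail-first displacement.
* ``bend`` — the head segments rotate about the neck with growing/oscillating
  angle while the centroid barely moves (head cast).
* ``hunch`` — rapid uniform body-length contraction; the retraction rate is
  faster than the crawl wave's contraction rate *by construction*, and both
  scale with the phenotype multiplier so the ratio is speed-invariant.
* ``roll`` — approximated in 2-D midline terms as alternating-sign body
  curvature with lateral centroid oscillation; dorsal-view rolling has no
  faithful midline signature, making this deliberately the weakest class.
* ``stop`` — a static posture plus Gaussian jitter only.

Additive Gaussian coordinate noise (tracking noise) is applied last.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .trackdata_io import AssayMetadata, LabelSet, LabelSpec, Track

__all__ = [
    "ACTIONS",
    "DEFAULT_DICTIONARY",
    "ActionParams",
    "SimScript",
    "simulate_track",
    "simulate_assay",
    "make_labelled_windows",
]

#: The six simulated actions. The default label dictionary appends the
#: catch-all ``small_action`` class used for weak/undecided movements.
ACTIONS = ("crawl", "bend", "back", "hunch", "roll", "stop")

DEFAULT_DICTIONARY = [
    LabelSpec("crawl", "#1f77b4"),
    LabelSpec("bend", "#ff7f0e"),
    LabelSpec("back", "#2ca02c"),
    LabelSpec("hunch", "#d62728"),
    LabelSpec("roll", "#9467bd"),
    LabelSpec("stop", "#8c564b"),
    LabelSpec("small_action", "#7f7f7f"),
]


@dataclass(frozen=True)
class ActionParams:
    """Kinematic parameters of the simulated actions.

    Units: lengths in mm, rates in Hz, speeds in mm/s, angles in rad.
    ``speed_multiplier`` emulates slow/fast genetic phenotypes by scaling all
    rates and speeds jointly (so ratios between movements are preserved).
    ``stop_jitter`` multiplies the global ``noise_sd`` during stops.
    """

    body_length: float = 4.0
    frame_rate: float = 10.0
    noise_sd: float = 0.1
    speed_multiplier: float = 1.0

    crawl_freq: float = 1.5           # peristaltic cycles per second
    crawl_stride: float = 0.15        # body lengths advanced per cycle
    crawl_wave_amp: float = 0.06      # relative segment-length modulation

    bend_amp: float = 1.0             # peak head-cast angle
    bend_period: float = 4.0          # seconds per full cast cycle

    hunch_contraction: float = 0.25   # fraction of body length retracted
    hunch_speed: float = 5.0          # head-retraction speed, mm/s

    back_speed: float = 0.6           # tail-first speed, mm/s

    roll_freq: float = 0.8            # curvature alternation rate
    roll_curvature: float = 0.5       # peak curvature, 1/body_length units
    roll_lateral: float = 0.15        # lateral oscillation, body lengths

    stop_jitter: float = 1.0          # multiplier of noise_sd during stops

    spine_points: int = 5

    def __post_init__(self):
        positive = (
            self.body_length, self.frame_rate, self.speed_multiplier,
            self.crawl_freq, self.crawl_stride, self.bend_amp, self.bend_period,
            self.hunch_speed, self.back_speed, self.roll_freq,
        )
        if any(v <= 0 for v in positive):
            raise ValueError("rates, durations, speeds and lengths must be > 0")
        if not 0 < self.hunch_contraction < 1:
            raise ValueError("hunch_contraction must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.spine_points < 3:
            raise ValueError("spine_points >= 3 required")


@dataclass
class SimScript:
    """An ordered list of (action, duration-in-seconds) steps for one larva."""

    steps: list[tuple[str, float]]
    params: ActionParams = field(default_factory=ActionParams)
    seed: int = 0
    larva_id: int = 0

    def validate(self) -> None:
        for action, duration in self.steps:
            if action not in ACTIONS:
                raise ValueError(f"unknown action {action!r}; valid: {ACTIONS}")
            if duration <= 0:
                raise ValueError("step durations must be > 0")


def _segment_frames(action: str, tau: np.ndarray, p: ActionParams,
                    rng: np.random.Generator) -> np.ndarray:
    """Body-frame spine frames for one action segment.

    The body axis is +x with the head at positive x (head-first convention);
    returns an (len(tau), S, 2) array relative to the segment's start pose.
    """
    S = p.spine_points
    mult = p.speed_multiplier
    BL = p.body_length
    s = np.linspace(0.0, 1.0, S)               # head (0) -> tail (1)
    base = (0.5 - s) * BL                      # straight axial positions
    n_t = len(tau)
    out = np.zeros((n_t, S, 2))
    phase = rng.uniform(0, 2 * math.pi)

    if action in ("crawl", "back"):
        f = p.crawl_freq * mult
        if action == "crawl":
            v = p.crawl_stride * BL * f
            wave = np.sin(2 * math.pi * f * tau[:, None] - 2 * math.pi * s[None, :] + phase)
        else:
            v = -p.back_speed * mult
            wave = np.sin(2 * math.pi * f * tau[:, None] + 2 * math.pi * s[None, :] + phase)
        out[:, :, 0] = base[None, :] * (1 + p.crawl_wave_amp * wave) + v * tau[:, None]
    elif action == "bend":
        angle = p.bend_amp * np.sin(2 * math.pi * mult * tau / p.bend_period + phase)
        out[:, :, 0] = base[None, :]
        neck = base[S // 2]
        head = s < 0.5
        dx = base[head] - neck
        out[:, head, 0] = neck + dx[None, :] * np.cos(angle)[:, None]
        out[:, head, 1] = dx[None, :] * np.sin(angle)[:, None]
    elif action == "hunch":
        # cyclic hunching: retract at hunch_speed, hold, re-extend at half
        # speed, pause, repeat — every 2-s window contains retraction dynamics
        t_contract = p.hunch_contraction * BL / (p.hunch_speed * mult)
        t_hold, t_release, t_rest = 0.6 / mult, 2 * t_contract, 0.4 / mult
        period = t_contract + t_hold + t_release + t_rest
        phase_t = np.mod(tau, period)
        r = np.where(
            phase_t < t_contract, phase_t / t_contract,
            np.where(
                phase_t < t_contract + t_hold, 1.0,
                np.where(
                    phase_t < t_contract + t_hold + t_release,
                    1.0 - (phase_t - t_contract - t_hold) / t_release,
                    0.0,
                ),
            ),
        )
        out[:, :, 0] = base[None, :] * (1 - p.hunch_contraction * r[:, None])
    elif action == "roll":
        f = p.roll_freq * mult
        kappa = (p.roll_curvature / BL) * np.sin(2 * math.pi * f * tau + phase)
        ell = base  # arc-length position along the bent body
        for i in range(n_t):
            k = kappa[i]
            if abs(k) < 1e-9:
                out[i, :, 0] = ell
            else:
                out[i, :, 0] = np.sin(k * ell) / k
                out[i, :, 1] = (1 - np.cos(k * ell)) / k
        out[:, :, 1] += (p.roll_lateral * BL
                         * np.sin(2 * math.pi * f * tau + phase))[:, None]
    elif action == "stop":
        out[:, :, 0] = base[None, :]
        sd = p.stop_jitter * p.noise_sd
        if sd > 0:
            out += rng.normal(0.0, sd, out.shape)
    else:  # pragma: no cover - guarded by SimScript.validate
        raise ValueError(f"unknown action {action!r}")
    return out


def simulate_track(script: SimScript) -> tuple[Track, LabelSet]:
    """Simulate one larva following ``script``; returns the track and its
    ground-truth per-timestep labels (boundary frames belong to the later
    action)."""
    script.validate()
    p = script.params
    rng = np.random.default_rng(script.seed)
    dt = 1.0 / p.frame_rate
    total = sum(d for _, d in script.steps)
    n_frames = int(round(total * p.frame_rate))
    t = np.arange(n_frames) * dt

    pos = np.zeros(2)
    heading = rng.uniform(0, 2 * math.pi)
    c, sn = math.cos(heading), math.sin(heading)
    rot = np.array([[c, -sn], [sn, c]])

    spine = np.zeros((n_frames, p.spine_points, 2))
    label_names: list[str] = []
    start = 0.0
    for action, duration in script.steps:
        end = start + duration
        mask = (t >= start - 1e-9) & (t < end - 1e-9)
        tau = t[mask] - start
        body = _segment_frames(action, tau, p, rng)
        spine[mask] = body @ rot.T + pos
        # carry the net centroid displacement of the segment forward
        if action in ("crawl", "back"):
            if action == "crawl":
                v = p.crawl_stride * p.body_length * p.crawl_freq * p.speed_multiplier
            else:
                v = -p.back_speed * p.speed_multiplier
            pos = pos + rot @ np.array([v * duration, 0.0])
        label_names.extend([action] * int(mask.sum()))
        start = end

    if p.noise_sd > 0:
        spine += rng.normal(0.0, p.noise_sd, spine.shape)

    track = Track(larva_id=script.larva_id, t=t, spine=spine)
    track.validate()
    index = {spec.name: i for i, spec in enumerate(DEFAULT_DICTIONARY)}
    labels = LabelSet(
        dictionary=list(DEFAULT_DICTIONARY),
        assignments={script.larva_id: [[index[name]] for name in label_names]},
        provenance={script.larva_id: "manual"},
        times={script.larva_id: t},
    )
    labels.validate([track])
    return track, labels


def _check_mixture(mixture: dict[str, float]) -> None:
    vals = list(mixture.values())
    if any(v < 0 for v in vals) or abs(sum(vals) - 1.0) > 1e-6:
        raise ValueError(f"invalid mixture (must be non-negative, sum to 1): {mixture}")
    unknown = set(mixture) - set(ACTIONS)
    if unknown:
        raise ValueError(f"mixture references unknown actions: {sorted(unknown)}")


def _draw(rng: np.random.Generator, mixture: dict[str, float]) -> str:
    names = sorted(mixture)
    probs = np.array([mixture[n] for n in names])
    return names[rng.choice(len(names), p=probs / probs.sum())]


def simulate_assay(
    n_larvae: int,
    pre_mixture: dict[str, float],
    post_mixture: dict[str, float],
    seed: int = 0,
    stimulus_onset: float = 45.0,
    stimulus_duration: float = 38.0,
    post_seconds: float = 10.0,
    params: ActionParams | None = None,
    assay_id: str = "assay",
) -> tuple[list[Track], LabelSet, AssayMetadata]:
    """Simulate a stimulus assay: each larva draws actions from ``pre_mixture``
    until the stimulus onset, then from ``post_mixture``.

    The first post-onset segment starts exactly at the onset and lasts at
    least 1.5 s, so the action observed in a 1-s post-onset analysis window is
    a single draw from ``post_mixture`` — population action frequencies in
    that window converge to the mixture as ``n_larvae`` grows.
    """
    _check_mixture(pre_mixture)
    _check_mixture(post_mixture)
    if params is None:
        params = ActionParams()
    meta = AssayMetadata(
        assay_id=assay_id,
        stimulus_onset=stimulus_onset,
        stimulus_duration=stimulus_duration,
        frame_rate_hint=params.frame_rate,
    )
    meta.validate()
    root = np.random.default_rng(seed)
    tracks: list[Track] = []
    merged = LabelSet(dictionary=list(DEFAULT_DICTIONARY))
    for larva_id in range(n_larvae):
        rng = np.random.default_rng(root.integers(0, 2**31 - 1))
        steps: list[tuple[str, float]] = []
        elapsed = 0.0
        while elapsed < stimulus_onset - 1e-9:
            duration = min(float(rng.uniform(2.0, 3.0)), stimulus_onset - elapsed)
            steps.append((_draw(rng, pre_mixture), duration))
            elapsed += duration
        while elapsed < stimulus_onset + post_seconds - 1e-9:
            duration = min(float(rng.uniform(1.5, 2.5)),
                           stimulus_onset + post_seconds - elapsed)
            # keep the first post-onset segment >= 1.5 s for a clean 1-s window
            if duration < 1.5 and steps and elapsed == stimulus_onset:
                duration = 1.5
            steps.append((_draw(rng, post_mixture), duration))
            elapsed += duration
        script = SimScript(steps=steps, params=params,
                           seed=int(rng.integers(0, 2**31 - 1)), larva_id=larva_id)
        track, labels = simulate_track(script)
        track.assay = meta
        tracks.append(track)
        merged.assignments[larva_id] = labels.assignments[larva_id]
        merged.provenance[larva_id] = "manual"
        merged.times[larva_id] = labels.times[larva_id]
    merged.validate(tracks)
    return tracks, merged, meta


def make_labelled_windows(
    cfg,
    n_per_class: int,
    seed: int = 0,
    actions: tuple[str, ...] = ACTIONS,
    params: ActionParams | None = None,
    track_seconds: float = 5.0,
    windows_per_track: int = 12,
    vary_phenotype: bool = True,
):
    """Generate (PostureWindow, class-name) pairs, ``n_per_class`` per action.

    Each source track runs a single action and contributes a spread of at most
    ``windows_per_track`` windows so classes are built from many independent
    larvae. With ``vary_phenotype`` each track draws a speed multiplier in
    [0.7, 1.4], emulating slow/fast genetic lines.
    """
    from .preprocess import extract_windows_indexed

    if params is None:
        params = ActionParams()
    rng = np.random.default_rng(seed)
    windows, labels = [], []
    for action in actions:
        collected = 0
        while collected < n_per_class:
            par = params
            if vary_phenotype:
                par = replace(params, speed_multiplier=float(rng.uniform(0.7, 1.4)))
            script = SimScript(steps=[(action, track_seconds)], params=par,
                               seed=int(rng.integers(0, 2**31 - 1)))
            track, _ = simulate_track(script)
            ws = extract_windows_indexed(track, cfg)
            if not ws:
                continue
            take = min(windows_per_track, n_per_class - collected, len(ws))
            picks = rng.choice(len(ws), size=take, replace=False)
            for i in sorted(picks):
                windows.append(ws[i])
                labels.append(action)
            collected += take
    return windows, labels
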