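"""Reading and writing larval tracking data and label annotations.

Supported formats:

* Choreography-style spine/outline text files (Multi-Worm Tracker toolchain).
  Dialect: whitespace-separated, one frame per line, ``larva_id t x1 y1 ... xS yS``.
  The number of spine points ``S`` is free but must be constant within a larva.
  An optional outline file shares the ``id t`` columns followed by closed-contour
  coordinate pairs.
* FIMTrack-style ``table.csv``: semicolon-separated, one column per larva
  (``larva(<id>)``), rows indexed by feature name with the frame number in
  parentheses, e.g. ``spinepoint_x_2(14)``. An optional ``time(<frame>)`` row
  carries timestamps; otherwise a frame rate must be supplied.
* A WCON-like JSON label file holding the label dictionary (names + colours)
  and per-larva, per-timestep label lists.

Coordinates are carried opaquely (no mm/px conversion); normalization further
down the pipeline removes scale. Timestamps are authoritative — frame indices
are never assumed equispaced, because trackers drop frames. Unparseable frames
are dropped (never interpolated) at this level; gap handling belongs to the
preprocessor.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AssayMetadata",
    "Track",
    "LabelSpec",
    "LabelSet",
    "LabelSchemaError",
    "read_choreography",
    "write_choreography",
    "read_fimtrack_csv",
    "write_fimtrack_csv",
    "read_labels_json",
    "write_labels_json",
]


class LabelSchemaError(ValueError):
    """Raised when a label JSON document violates the expected schema."""


@dataclass
class AssayMetadata:
    """Assay-level protocol metadata attached to every track of a recording."""

    assay_id: str = ""
    stimulus_onset: float | None = None
    stimulus_duration: float | None = None
    frame_rate_hint: float | None = None
    extra: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if self.stimulus_onset is not None and self.stimulus_duration is not None:
            if self.stimulus_onset < 0:
                raise ValueError("stimulus_onset must be >= 0")
            if self.stimulus_duration <= 0:
                raise ValueError("stimulus_duration must be > 0")


@dataclass
class Track:
    """One larva's timestamped midline (and optional contour) series.

    Attributes
    ----------
    larva_id : int
    t : (T,) float array, strictly increasing, seconds.
    spine : (T, S, 2) float array of planar coordinates, head -> tail.
    outline : optional (T, C, 2) closed-contour coordinates.
    assay : AssayMetadata
    """

    larva_id: int
    t: np.ndarray
    spine: np.ndarray
    outline: np.ndarray | None = None
    assay: AssayMetadata = field(default_factory=AssayMetadata)

    @property
    def n_frames(self) -> int:
        return len(self.t)

    @property
    def n_spine_points(self) -> int:
        return self.spine.shape[1]

    def body_length(self) -> np.ndarray:
        """Per-frame body length: sum of midline segment lengths."""
        seg = np.diff(self.spine, axis=1)
        return np.linalg.norm(seg, axis=2).sum(axis=1)

    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    def validate(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1:
            raise ValueError("t must be a 1-D vector")
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError(f"larva {self.larva_id}: t must be strictly increasing")
        if self.spine.ndim != 3 or self.spine.shape[0] != len(t) or self.spine.shape[2] != 2:
            raise ValueError(
                f"larva {self.larva_id}: spine must have shape (T, S, 2), got {self.spine.shape}"
            )
        if not np.all(np.isfinite(self.spine)):
            raise ValueError(f"larva {self.larva_id}: non-finite spine coordinates")
        if len(t) and np.any(self.body_length() <= 0):
            raise ValueError(f"larva {self.larva_id}: zero body length at some frame")
        if self.outline is not None:
            if self.outline.shape[0] != len(t) or self.outline.shape[2] != 2:
                raise ValueError(f"larva {self.larva_id}: outline/t shape mismatch")
        self.assay.validate()


@dataclass(frozen=True)
class LabelSpec:
    name: str
    color: str = "#808080"


@dataclass
class LabelSet:
    """Per-track, per-timestep action labels plus the label dictionary.

    ``assignments`` maps larva_id to a list (one entry per timestep) of lists
    of label indices into ``dictionary``; an empty inner list means untagged.
    ``times`` optionally carries the timestep vector per larva so a LabelSet
    is self-contained when detached from its tracks.
    """

    dictionary: list[LabelSpec] = field(default_factory=list)
    assignments: dict[int, list[list[int]]] = field(default_factory=dict)
    provenance: dict[int, str] = field(default_factory=dict)
    times: dict[int, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)  # passthrough for unknown JSON keys

    @property
    def names(self) -> list[str]:
        return [spec.name for spec in self.dictionary]

    def label_index(self, name: str) -> int:
        return self.names.index(name)

    def validate(self, tracks: list[Track] | None = None) -> None:
        names = self.names
        if len(set(names)) != len(names):
            raise ValueError("label dictionary names must be unique")
        n = len(names)
        for larva_id, vec in self.assignments.items():
            for step, labels in enumerate(vec):
                for idx in labels:
                    if not 0 <= idx < n:
                        raise ValueError(
                            f"larva {larva_id}, timestep {step}: label index {idx} "
                            f"outside dictionary of size {n}"
                        )
            if larva_id in self.times and len(self.times[larva_id]) != len(vec):
                raise ValueError(f"larva {larva_id}: times/assignments length mismatch")
        if tracks is not None:
            by_id = {tr.larva_id: tr for tr in tracks}
            for larva_id, vec in self.assignments.items():
                if larva_id in by_id and len(vec) != by_id[larva_id].n_frames:
                    raise ValueError(
                        f"larva {larva_id}: {len(vec)} label entries for "
                        f"{by_id[larva_id].n_frames} frames"
                    )


# ---------------------------------------------------------------------------
# Choreography-style spine/outline text files
# ---------------------------------------------------------------------------


def _parse_frame_lines(path: Path) -> dict[int, list[tuple[float, np.ndarray]]]:
    """Parse ``id t x1 y1 ...`` lines, grouped by larva id.

    Frames whose coordinate count differs from the larva's first frame, or
    that contain unparseable/non-finite numbers, are dropped with a warning.
    """
    frames: dict[int, list[tuple[float, np.ndarray]]] = {}
    n_coords: dict[int, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            try:
                larva_id = int(parts[0])
                t = float(parts[1])
                coords = np.array([float(v) for v in parts[2:]], dtype=float)
            except (ValueError, IndexError):
                logger.warning("%s:%d: unparseable frame dropped", path, lineno)
                continue
            if len(coords) < 4 or len(coords) % 2 or not np.all(np.isfinite(coords)):
                logger.warning("%s:%d: invalid coordinates, frame dropped", path, lineno)
                continue
            expected = n_coords.setdefault(larva_id, len(coords))
            if len(coords) != expected:
                logger.warning(
                    "%s:%d: larva %d has %d coordinates, expected %d; frame dropped",
                    path, lineno, larva_id, len(coords), expected,
                )
                continue
            frames.setdefault(larva_id, []).append((t, coords.reshape(-1, 2)))
    return frames


def _assemble(frames: list[tuple[float, np.ndarray]], larva_id: int):
    frames.sort(key=lambda item: item[0])
    t, kept = [], []
    for time, coords in frames:
        if t and time <= t[-1]:
            logger.warning("larva %d: duplicate/non-monotone t=%g, keeping first", larva_id, time)
            continue
        t.append(time)
        kept.append(coords)
    return np.array(t, dtype=float), np.stack(kept)


def read_choreography(
    spine_path: str | Path,
    outline_path: str | Path | None = None,
    assay: AssayMetadata | None = None,
) -> list[Track]:
    """Read a Choreography-style spine file (and optional outline file)."""
    spine_frames = _parse_frame_lines(Path(spine_path))
    outline_frames = _parse_frame_lines(Path(outline_path)) if outline_path else {}
    tracks = []
    for larva_id in sorted(spine_frames):
        t, spine = _assemble(spine_frames[larva_id], larva_id)
        outline = None
        if larva_id in outline_frames:
            t_out, contour = _assemble(outline_frames[larva_id], larva_id)
            if len(t_out) == len(t) and np.allclose(t_out, t):
                outline = contour
            else:
                logger.warning("larva %d: outline timestamps mismatch spine; outline dropped", larva_id)
        track = Track(
            larva_id=larva_id, t=t, spine=spine, outline=outline,
            assay=assay if assay is not None else AssayMetadata(),
        )
        track.validate()
        tracks.append(track)
    return tracks


def _format_frame(larva_id: int, t: float, coords: np.ndarray) -> str:
    flat = " ".join(f"{v:.6f}" for v in coords.reshape(-1))
    return f"{larva_id} {t:.6f} {flat}\n"


def write_choreography(
    tracks: list[Track],
    spine_path: str | Path,
    outline_path: str | Path | None = None,
) -> None:
    with open(spine_path, "w") as fh:
        for track in tracks:
            for k in range(track.n_frames):
                fh.write(_format_frame(track.larva_id, track.t[k], track.spine[k]))
    if outline_path is not None:
        with open(outline_path, "w") as fh:
            for track in tracks:
                if track.outline is None:
                    continue
                for k in range(track.n_frames):
                    fh.write(_format_frame(track.larva_id, track.t[k], track.outline[k]))


# ---------------------------------------------------------------------------
# FIMTrack-style table.csv
# ---------------------------------------------------------------------------


def read_fimtrack_csv(path: str | Path, frame_rate: float | None = None) -> list[Track]:
    """Read a FIMTrack-style semicolon-separated feature table.

    Rows are indexed ``<feature>(<frame>)``; columns are ``larva(<id>)``.
    Spine coordinates live in rows ``spinepoint_x_<j>`` / ``spinepoint_y_<j>``
    (j = 1..S, head first). Timestamps come from ``time(<frame>)`` rows when
    present, else from ``frame / frame_rate``.
    """
    table = pd.read_csv(path, sep=";", index_col=0)
    feature_frame = []
    for row_name in table.index:
        name, _, frame_part = str(row_name).partition("(")
        feature_frame.append((name, int(frame_part.rstrip(")"))))
    features = pd.DataFrame(feature_frame, columns=["feature", "frame"], index=table.index)

    spine_feats = sorted(
        {f for f in features["feature"] if f.startswith("spinepoint_x_")},
        key=lambda f: int(f.rsplit("_", 1)[1]),
    )
    has_time = (features["feature"] == "time").any()
    if not has_time and frame_rate is None:
        raise ValueError(f"{path}: no time(<frame>) rows and no frame_rate given")

    tracks = []
    for col in table.columns:
        name, _, id_part = str(col).partition("(")
        larva_id = int(id_part.rstrip(")"))
        if not spine_feats:
            raise ValueError(f"{path}: no spinepoint_x/y rows for larva group {col!r}")
        frames = sorted(features.loc[features["feature"] == spine_feats[0], "frame"])
        t_list, spine_list = [], []
        for frame in frames:
            coords = []
            ok = True
            for feat in spine_feats:
                j = feat.rsplit("_", 1)[1]
                try:
                    x = table.at[f"spinepoint_x_{j}({frame})", col]
                    y = table.at[f"spinepoint_y_{j}({frame})", col]
                except KeyError as exc:
                    raise ValueError(
                        f"{path}: missing spine row for larva group {col!r}: {exc}"
                    ) from exc
                if pd.isna(x) or pd.isna(y):
                    ok = False
                    break
                coords.append((float(x), float(y)))
            if not ok:
                continue
            if has_time:
                tval = table.at[f"time({frame})", col]
                if pd.isna(tval):
                    continue
                t_list.append(float(tval))
            else:
                t_list.append(frame / frame_rate)
            spine_list.append(np.array(coords))
        if not t_list:
            continue
        track = Track(larva_id=larva_id, t=np.array(t_list), spine=np.stack(spine_list))
        track.validate()
        tracks.append(track)
    return tracks


def write_fimtrack_csv(tracks: list[Track], path: str | Path, include_time: bool = True) -> None:
    """Write tracks as a FIMTrack-style semicolon-separated feature table."""
    columns = {}
    rows: list[str] = []
    seen = set()
    for track in tracks:
        S = track.n_spine_points
        col = {}
        for k in range(track.n_frames):
            frame = k
            if include_time:
                col[f"time({frame})"] = f"{track.t[k]:.6f}"
            for j in range(S):
                col[f"spinepoint_x_{j + 1}({frame})"] = f"{track.spine[k, j, 0]:.6f}"
                col[f"spinepoint_y_{j + 1}({frame})"] = f"{track.spine[k, j, 1]:.6f}"
        columns[f"larva({track.larva_id})"] = col
        for key in col:
            if key not in seen:
                seen.add(key)
                rows.append(key)
    frame = pd.DataFrame(columns, index=rows)
    frame.index.name = "feature"
    frame.to_csv(path, sep=";")


# ---------------------------------------------------------------------------
# WCON-like label JSON
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {"units", "metadata", "labels", "data"}


def _require(doc: dict, key: str, path: str) -> object:
    if key not in doc:
        raise LabelSchemaError(f"missing required key at {path}/{key}")
    return doc[key]


def read_labels_json(path: str | Path) -> LabelSet:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict):
        raise LabelSchemaError("top-level document must be a JSON object at $")
    _require(doc, "units", "$")
    labels_block = _require(doc, "labels", "$")
    names = _require(labels_block, "names", "$/labels")
    colors = labels_block.get("colors", ["#808080"] * len(names))
    if len(colors) != len(names):
        raise LabelSchemaError("$/labels: names and colors must have equal length")
    data = _require(doc, "data", "$")

    dictionary = [LabelSpec(str(n), str(c)) for n, c in zip(names, colors)]
    index = {n: i for i, n in enumerate(names)}
    labelset = LabelSet(dictionary=dictionary, metadata=doc.get("metadata", {}))
    unknown = set()
    for entry_no, entry in enumerate(data):
        larva_id = int(_require(entry, "id", f"$/data/{entry_no}"))
        t = np.asarray(_require(entry, "t", f"$/data/{entry_no}"), dtype=float)
        per_step = _require(entry, "labels", f"$/data/{entry_no}")
        if len(per_step) != len(t):
            raise LabelSchemaError(f"$/data/{entry_no}: t and labels length mismatch")
        vec = []
        for step in per_step:
            idxs = []
            for name in step:
                if name not in index:
                    unknown.add(str(name))
                else:
                    idxs.append(index[name])
            vec.append(idxs)
        labelset.assignments[larva_id] = vec
        labelset.times[larva_id] = t
        if "provenance" in entry:
            labelset.provenance[larva_id] = str(entry["provenance"])
    if unknown:
        raise LabelSchemaError(
            "labels reference undefined names: " + ", ".join(sorted(unknown))
        )
    labelset.extra = {k: v for k, v in doc.items() if k not in _KNOWN_KEYS}
    labelset.validate()
    return labelset


def write_labels_json(labels: LabelSet, path: str | Path) -> None:
    labels.validate()
    names = labels.names
    data = []
    for larva_id in sorted(labels.assignments):
        vec = labels.assignments[larva_id]
        t = labels.times.get(larva_id)
        if t is None:
            t = np.arange(len(vec), dtype=float)
        entry = {
            "id": int(larva_id),
            "t": [float(v) for v in t],
            "labels": [[names[i] for i in step] for step in vec],
        }
        if larva_id in labels.provenance:
            entry["provenance"] = labels.provenance[larva_id]
        data.append(entry)
    doc = {
        "units": {"t": "s"},
        "metadata": labels.metadata,
        "labels": {
            "names": names,
            "colors": [spec.color for spec in labels.dictionary],
        },
        "data": data,
    }
    doc.update(labels.extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, sort_keys=True, indent=1, ensure_ascii=False)
        fh.write("\n")
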