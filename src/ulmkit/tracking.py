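"""Centroid pairing across frames, track filtering, velocity and tortuosity.

Frame-to-frame pairing is a gated linear-assignment problem: per consecutive
frame pair, the one-to-one assignment minimizing summed Euclidean distance
subject to a maximum-displacement gate (max_speed / frame_rate). Unmatched
detections start new tracks; tracks unmatched for longer than the gap-close
window terminate. Tortuosity is the sum-of-angles metric (SOAM): the
accumulated unsigned turning angle along the trajectory divided by its path
length, in degrees/mm; the companion distance metric is path length over
end-to-end distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .localization import FrameLocalizations

logger = logging.getLogger(__name__)


@dataclass
class Track:
    """One microbubble trajectory: ordered (frame, z µm, x µm) samples."""

    track_id: int
    frames: np.ndarray  # (n,) int, strictly increasing
    positions: np.ndarray  # (n, 2) µm

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int).reshape(-1)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        if len(self.frames) != len(self.positions):
            raise ValueError("frames and positions must have equal length")
        if len(self.frames) > 1 and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def path_length(self) -> float:
        """Total traversed path, µm."""
        d = np.diff(self.positions, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    @property
    def end_to_end(self) -> float:
        """Straight-line distance between first and last sample, µm."""
        d = self.positions[-1] - self.positions[0]
        return float(np.hypot(d[0], d[1]))

    @property
    def direction_sign(self) -> int:
        """Sign of net axial displacement (+1 away from the transducer)."""
        dz = self.positions[-1, 0] - self.positions[0, 0]
        return int(np.sign(dz)) if dz != 0 else 0


@dataclass
class TrackSet:
    """A collection of tracks plus the linking parameters that produced it."""

    tracks: list[Track] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)


def link_frames(localizations: list[FrameLocalizations], max_speed: float = 50.0,
                gap_close: int = 0, frame_rate: float = 1000.0) -> TrackSet:
    """Pair centroids across frames by gated minimum-cost assignment.

    Parameters
    ----------
    localizations : list of FrameLocalizations
        Per-frame detections, ordered by frame index.
    max_speed : float
        Gate in mm/s: a link is admissible only if the centroid displacement
        per frame step does not exceed max_speed / frame_rate.
    gap_close : int
        Number of missed frames a track may survive (0 = strict
        frame-to-frame pairing).
    frame_rate : float
        Frames per second, used to convert the gate to µm/frame.

    Ties in assignment are broken deterministically by (frame, detection
    index) order via the assignment solver's row-major scan.
    """
    if max_speed <= 0:
        raise ValueError("max_speed must be > 0")
    frames = sorted(localizations, key=lambda fl: fl.frame)
    gate_um_per_frame = max_speed * 1000.0 / frame_rate

    next_id = 0
    open_tracks: list[dict] = []  # {"id", "frames": [...], "pos": [...], "last_frame"}
    done: list[Track] = []

    for fl in frames:
        pts = fl.positions
        # retire tracks that fell outside the gap-close window
        still_open = []
        for tr in open_tracks:
            if fl.frame - tr["last_frame"] > gap_close + 1:
                done.append(Track(tr["id"], tr["frames"], tr["pos"]))
            else:
                still_open.append(tr)
        open_tracks = still_open

        n_t, n_d = len(open_tracks), len(pts)
        assigned_d = np.zeros(n_d, dtype=bool)
        if n_t and n_d:
            last = np.array([tr["pos"][-1] for tr in open_tracks])
            gaps = np.array([fl.frame - tr["last_frame"] for tr in open_tracks])
            dist = np.hypot(last[:, None, 0] - pts[None, :, 0],
                            last[:, None, 1] - pts[None, :, 1])
            allowed = dist <= gate_um_per_frame * gaps[:, None]
            big = 1e12
            cost = np.where(allowed, dist, big)
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if allowed[r, c]:
                    tr = open_tracks[r]
                    tr["frames"].append(fl.frame)
                    tr["pos"].append(pts[c])
                    tr["last_frame"] = fl.frame
                    assigned_d[c] = True
        for c in np.flatnonzero(~assigned_d):
            open_tracks.append({"id": next_id, "frames": [fl.frame],
                                "pos": [pts[c]], "last_frame": fl.frame})
            next_id += 1

    for tr in open_tracks:
        done.append(Track(tr["id"], tr["frames"], tr["pos"]))
    done.sort(key=lambda t: t.track_id)
    return TrackSet(tracks=done, provenance={
        "max_speed_mm_s": max_speed, "gap_close": gap_close, "frame_rate": frame_rate})


def filter_tracks(trackset: TrackSet, min_length: int = 20) -> TrackSet:
    """Drop tracks shorter than ``min_length`` frames (default 20, i.e. 20 ms
    at 1000 Hz); ordering of the survivors is preserved."""
    kept = [t for t in trackset.tracks if len(t) >= min_length]
    prov = dict(trackset.provenance)
    prov["min_length"] = min_length
    return TrackSet(tracks=kept, provenance=prov)


def track_velocity(track: Track, frame_rate: float = 1000.0) -> tuple[np.ndarray, float]:
    """Per-step and mean speed of a track, in mm/s.

    Step speed is the Euclidean frame-to-frame displacement divided by the
    step's time interval; the mean is the arithmetic mean of step speeds.
    """
    if len(track) < 2:
        raise ValueError("velocity needs a track with at least 2 points")
    d = np.diff(track.positions, axis=0)
    steps_um = np.hypot(d[:, 0], d[:, 1])
    dt_frames = np.diff(track.frames)
    speeds = steps_um * frame_rate / dt_frames / 1000.0  # µm/s -> mm/s
    return speeds, float(speeds.mean())


def track_soam(track: Track) -> tuple[float, float]:
    """Sum-of-angles tortuosity of a track.

    Returns ``(soam, distance_metric)`` where soam is the summed unsigned
    turning angle between consecutive segments divided by the path length,
    in degrees/mm, and distance_metric is path length / end-to-end distance.
    Zero-length segments are dropped before angle computation. Tracks with
    fewer than 3 points are undefined and raise ``ValueError`` (callers
    should skip them; a log entry is emitted).
    """
    if len(track) < 3:
        logger.info("track %d has < 3 points: SOAM undefined, skipped", track.track_id)
        raise ValueError("SOAM needs at least 3 points")
    v = np.diff(track.positions, axis=0)
    lengths = np.hypot(v[:, 0], v[:, 1])
    v, lengths = v[lengths > 0], lengths[lengths > 0]
    path_mm = lengths.sum() / 1000.0
    if len(v) < 2 or path_mm == 0:
        ete = track.end_to_end
        return 0.0, (lengths.sum() / ete if ete > 0 else 1.0)
    # atan2(|cross|, dot) is exact for collinear segments, unlike arccos
    dot = np.sum(v[:-1] * v[1:], axis=1)
    cross = v[:-1, 0] * v[1:, 1] - v[:-1, 1] * v[1:, 0]
    angles = np.degrees(np.arctan2(np.abs(cross), dot))
    soam = float(angles.sum() / path_mm)
    ete = track.end_to_end
    dm = float(lengths.sum() / ete) if ete > 0 else float("inf")
    return soam, dm


def angle_sum(track: Track) -> float:
    """Raw summed turning angle of a track, degrees (unnormalized SOAM)."""
    v = np.diff(track.positions, axis=0)
    lengths = np.hypot(v[:, 0], v[:, 1])
    v, lengths = v[lengths > 0], lengths[lengths > 0]
    if len(v) < 2:
        return 0.0
    dot = np.sum(v[:-1] * v[1:], axis=1)
    cross = v[:-1, 0] * v[1:, 1] - v[:-1, 1] * v[1:, 0]
    return float(np.degrees(np.arctan2(np.abs(cross), dot)).sum())


def track_summary(trackset: TrackSet, frame_rate: float = 1000.0) -> list[dict]:
    """Per-track summary rows (id, n points, mean speed, path, SOAM, ...)."""
    rows = []
    for t in trackset:
        if len(t) < 2:
            continue
        _, mean_speed = track_velocity(t, frame_rate)
        if len(t) >= 3:
            soam, dm = track_soam(t)
        else:
            soam, dm = float("nan"), float("nan")
        rows.append({
            "track_id": t.track_id, "n_points": len(t),
            "mean_speed_mm_s": mean_speed, "path_len_um": t.path_length,
            "end_to_end_um": t.end_to_end, "soam_deg_mm": soam,
            "distance_metric": dm, "direction_sign": t.direction_sign,
        })
    return rows
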