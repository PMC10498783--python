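"""Centroid tracking and cell-velocity estimation.

A deliberately simple frame-to-frame tracker for well-separated cells:
greedy nearest-neighbour linking with a maximum displacement gate, followed
by per-track speed computation.  Cell velocity is defined as total path
length divided by elapsed time (the quantity usually reported as "average
cell velocity" in migration assays); the net-displacement variant is also
exposed.  Note that positional jitter inflates path-length speed: with
per-step jitter below ~20% of the per-step displacement the upward bias
stays under 10%.

Centroid *detection* from images is out of scope; detections come from the
simulator's truth channel or an external detector as per-frame (x, y) lists
in micrometres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Track",
    "link_tracks",
    "track_speed",
    "track_net_speed",
    "average_velocity",
]


@dataclass(frozen=True)
class Track:
    """One cell's trajectory: strictly increasing times (h), positions (um)."""

    cell_id: str
    times_h: np.ndarray  # (n,)
    xy_um: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        xy = np.asarray(self.xy_um, dtype=float)
        if t.ndim != 1 or xy.ndim != 2 or xy.shape != (t.size, 2):
            raise ValueError("times_h must be (n,), xy_um must be (n, 2)")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times_h must be strictly increasing")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "xy_um", xy)

    def __len__(self) -> int:
        return self.times_h.size

    @property
    def samples(self) -> list[tuple[float, float, float]]:
        """Ordered (time_h, x_um, y_um) triples."""
        return [
            (float(t), float(x), float(y))
            for t, (x, y) in zip(self.times_h, self.xy_um)
        ]

    def path_length_um(self) -> float:
        steps = np.diff(self.xy_um, axis=0)
        return float(np.hypot(steps[:, 0], steps[:, 1]).sum())

    def net_displacement_um(self) -> float:
        d = self.xy_um[-1] - self.xy_um[0]
        return float(np.hypot(d[0], d[1]))

    def elapsed_h(self) -> float:
        return float(self.times_h[-1] - self.times_h[0])


def link_tracks(
    detections: Sequence[np.ndarray],
    times_h: Sequence[float],
    max_disp_um: float,
) -> list[Track]:
    """Greedy nearest-neighbour linking of per-frame centroid lists.

    For each consecutive frame pair, candidate (track, detection) pairs are
    taken in order of increasing distance; each active track and each
    detection is assigned at most once, and pairs farther than
    ``max_disp_um`` are never linked.  A track that finds no match ends; an
    unmatched detection starts a new track.

    Parameters
    ----------
    detections:
        One ``(n_i, 2)`` array of (x, y) positions in um per frame.
    times_h:
        Acquisition time of each frame, strictly increasing.
    max_disp_um:
        Maximum allowed frame-to-frame displacement.
    """
    if len(detections) < 2:
        raise ValueError("need at least 2 frames of detections")
    if len(detections) != len(times_h):
        raise ValueError("detections and times_h must have equal length")
    times = np.asarray(times_h, dtype=float)
    if not np.all(np.diff(times) > 0):
        raise ValueError("times_h must be strictly increasing")
    if max_disp_um <= 0:
        raise ValueError("max_disp_um must be > 0")

    frames = [np.asarray(d, dtype=float).reshape(-1, 2) for d in detections]
    next_id = 0
    finished: list[Track] = []
    # active: list of (cell_id, [times], [positions])
    active: list[tuple[str, list[float], list[np.ndarray]]] = []
    for p in frames[0]:
        active.append((f"cell{next_id:03d}", [float(times[0])], [p]))
        next_id += 1

    for fi in range(1, len(frames)):
        dets = frames[fi]
        t = float(times[fi])
        assigned_track = np.zeros(len(active), dtype=bool)
        assigned_det = np.zeros(len(dets), dtype=bool)
        if len(active) and len(dets):
            last = np.stack([tr[2][-1] for tr in active])
            dist = np.hypot(
                last[:, 0:1] - dets[None, :, 0], last[:, 1:2] - dets[None, :, 1]
            )
            order = np.argsort(dist, axis=None, kind="stable")
            for flat in order:
                i, j = divmod(int(flat), len(dets))
                if dist[i, j] > max_disp_um:
                    break  # all remaining pairs are farther still
                if assigned_track[i] or assigned_det[j]:
                    continue
                assigned_track[i] = True
                assigned_det[j] = True
                active[i][1].append(t)
                active[i][2].append(dets[j])
        # close unmatched tracks, start new ones from unmatched detections
        still_active = []
        for i, tr in enumerate(active):
            if assigned_track[i]:
                still_active.append(tr)
            else:
                finished.append(_to_track(tr))
        for j in np.flatnonzero(~assigned_det):
            still_active.append((f"cell{next_id:03d}", [t], [dets[j]]))
            next_id += 1
        active = still_active

    finished.extend(_to_track(tr) for tr in active)
    finished.sort(key=lambda tr: tr.cell_id)
    return finished


def _to_track(raw: tuple[str, list[float], list[np.ndarray]]) -> Track:
    cell_id, ts, ps = raw
    return Track(cell_id, np.asarray(ts), np.stack(ps))


def track_speed(track: Track) -> float:
    """Path-length speed in um/h: sum of step lengths / elapsed time."""
    if len(track) < 2:
        raise ValueError(f"track {track.cell_id} has fewer than 2 samples")
    return track.path_length_um() / track.elapsed_h()


def track_net_speed(track: Track) -> float:
    """Net-displacement speed in um/h (start-to-end distance / elapsed)."""
    if len(track) < 2:
        raise ValueError(f"track {track.cell_id} has fewer than 2 samples")
    return track.net_displacement_um() / track.elapsed_h()


def average_velocity(
    tracks: Sequence[Track], definition: str = "path"
) -> tuple[float, float]:
    """Mean and sample SD of per-track speed (um/h) over a set of tracks.

    Tracks with fewer than 2 samples are skipped with a warning.  With a
    single usable track the SD is reported as 0.
    """
    if definition not in ("path", "net"):
        raise ValueError("definition must be 'path' or 'net'")
    speed_fn = track_speed if definition == "path" else track_net_speed
    speeds = []
    for tr in tracks:
        if len(tr) < 2:
            warnings.warn(
                f"track {tr.cell_id} has fewer than 2 samples; skipped", stacklevel=2
            )
            continue
        speeds.append(speed_fn(tr))
    if not speeds:
        raise ValueError("no track with >= 2 samples")
    arr = np.asarray(speeds)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd
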