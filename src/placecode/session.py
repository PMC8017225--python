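"""Core containers for linear-track sessions and calcium event rasters.

A session holds the per-frame behavioural state of a mouse shuttling on a
linear track (position in cm, running direction, traversal index); an event
raster holds the deconvolved calcium event counts of every recorded neuron
at the same frame rate.  Both are thin, validated wrappers around NumPy
arrays, with plain-text readers/writers so sessions round-trip through
delimited files.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: direction codes used throughout: +1 = left-to-right, -1 = right-to-left,
#: 0 = not inside a traversal (dwell at the track ends).
LR, RL, NONE = 1, -1, 0

_DIR_TO_STR = {LR: "LR", RL: "RL", NONE: "none"}
_STR_TO_DIR = {v: k for k, v in _DIR_TO_STR.items()}


def direction_code(direction: str | int) -> int:
    """Normalise a direction given as 'LR'/'RL' or +1/-1 to the int code."""
    if isinstance(direction, str):
        try:
            code = _STR_TO_DIR[direction]
        except KeyError:
            raise ValueError(f"unknown direction label {direction!r}") from None
    else:
        code = int(direction)
    if code not in (LR, RL):
        raise ValueError(f"direction must be LR or RL, got {direction!r}")
    return code


@dataclass
class TrackSession:
    """Per-frame behavioural record of one linear-track session.

    Parameters
    ----------
    x_cm
        Head position along the track, one value per frame.
    fps
        Acquisition frame rate (frames/s).
    track_length_cm
        Physical track length.
    direction
        Per-frame direction code (+1 LR, -1 RL, 0 outside traversals).
    trial_index
        Per-frame traversal index (0-based, -1 outside traversals).
        Traversals are numbered in temporal order within each direction.
    """

    x_cm: np.ndarray
    fps: float
    track_length_cm: float
    direction: np.ndarray
    trial_index: np.ndarray
    time_s: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.x_cm = np.asarray(self.x_cm, dtype=float)
        self.direction = np.asarray(self.direction, dtype=np.int8)
        self.trial_index = np.asarray(self.trial_index, dtype=np.int32)
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.track_length_cm <= 0:
            raise ValueError("track_length_cm must be positive")
        n = self.x_cm.size
        if self.direction.size != n or self.trial_index.size != n:
            raise ValueError("direction/trial_index must match x_cm length")
        if np.any(self.x_cm < -1e-9) or np.any(self.x_cm > self.track_length_cm + 1e-9):
            raise ValueError("positions fall outside [0, track_length_cm]")
        if self.time_s is None:
            self.time_s = np.arange(n) / self.fps
        else:
            self.time_s = np.asarray(self.time_s, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.x_cm.size

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def n_traversals(self, direction: str | int) -> int:
        code = direction_code(direction)
        sel = self.trial_index[self.direction == code]
        return 0 if sel.size == 0 else int(sel.max()) + 1


@dataclass
class EventRaster:
    """Neurons x frames matrix of non-negative calcium event counts."""

    counts: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be 2-D (neurons x frames)")
        if np.any(counts < 0):
            raise ValueError("event counts must be non-negative")
        self.counts = counts.astype(np.int32, copy=False)
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def n_frames(self) -> int:
        return self.counts.shape[1]

    def mean_rate_hz(self, neurons: np.ndarray | None = None) -> float:
        """Population mean event rate (events/s), optionally over a subset."""
        c = self.counts if neurons is None else self.counts[neurons]
        if c.size == 0:
            return 0.0
        return float(c.sum() / c.shape[0] / (c.shape[1] / self.fps))

    def detected_mask(self) -> np.ndarray:
        """Neurons with at least one event (proxy for 'detected' cells)."""
        return self.counts.sum(axis=1) > 0


# ---------------------------------------------------------------------------
# plain-text IO


def write_positions(session: TrackSession, path) -> None:
    df = pd.DataFrame(
        {
            "frame_index": np.arange(session.n_frames),
            "time_s": session.time_s,
            "x_cm": session.x_cm,
            "direction": [_DIR_TO_STR[int(d)] for d in session.direction],
            "trial_index": session.trial_index,
        }
    )
    with open(path, "w") as fh:
        fh.write(
            f"# fps={session.fps} track_length_cm={session.track_length_cm}\n"
        )
        df.to_csv(fh, sep="\t", index=False)


def read_positions(path) -> TrackSession:
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(tok.split("=") for tok in header.lstrip("# ").split())
        df = pd.read_csv(fh, sep="\t")
    return TrackSession(
        x_cm=df["x_cm"].to_numpy(),
        fps=float(meta["fps"]),
        track_length_cm=float(meta["track_length_cm"]),
        direction=np.array([_STR_TO_DIR[d] for d in df["direction"]]),
        trial_index=df["trial_index"].to_numpy(),
        time_s=df["time_s"].to_numpy(),
    )


def write_events(raster: EventRaster, path) -> None:
    """Sparse triplet text format: neuron_id, frame_index, count."""
    n, f = np.nonzero(raster.counts)
    with open(path, "w") as fh:
        fh.write(
            f"# n_neurons={raster.n_neurons} n_frames={raster.n_frames} "
            f"fps={raster.fps}\n"
        )
        fh.write("neuron_id\tframe_index\tcount\n")
        for ni, fi in zip(n, f):
            fh.write(f"{ni}\t{fi}\t{raster.counts[ni, fi]}\n")


def read_events(path) -> EventRaster:
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(tok.split("=") for tok in header.lstrip("# ").split())
        df = pd.read_csv(fh, sep="\t")
    counts = np.zeros(
        (int(meta["n_neurons"]), int(meta["n_frames"])), dtype=np.int32
    )
    np.add.at(
        counts,
        (df["neuron_id"].to_numpy(), df["frame_index"].to_numpy()),
        df["count"].to_numpy(),
    )
    return EventRaster(counts=counts, fps=float(meta["fps"]))


def config_hash(obj) -> str:
    """Stable short hash of a configuration object's repr (for manifests)."""
    return hashlib.sha1(repr(obj).encode()).hexdigest()[:12]


def write_manifest(path, entries: dict) -> None:
    with open(path, "w") as fh:
        for k, v in entries.items():
            fh.write(f"{k}\t{v}\n")


def read_manifest(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            k, _, v = line.rstrip("\n").partition("\t")
            out[k] = v
    return out
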