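"""Place-field maps: binning, speed filtering, occupancy, and smoothing.

The mapping convention: the track is divided into 2 cm bins, the bin at each
end is discarded (reward/dwell zones), frames are kept only while the animal
runs in the requested direction at 8-25 cm/s, the per-bin event counts and
occupancy are each smoothed with a truncated Gaussian kernel (sigma = 1.5
bins, 5 taps), and the event-rate map is the ratio of the two smoothed
vectors.  The bin of the map maximum is the place field's position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import EventRaster, TrackSession, direction_code

#: sentinel returned by `bin_index` for positions in discarded end bins
OUTSIDE = -1


@dataclass(frozen=True)
class BinningSpec:
    """Spatial binning and frame-filtering parameters."""

    bin_width_cm: float = 2.0
    n_end_bins_discarded_per_side: int = 1
    speed_min_cms: float = 8.0
    speed_max_cms: float = 25.0
    smooth_sigma_bins: float = 1.5
    smooth_size_bins: int = 5

    def __post_init__(self) -> None:
        if self.bin_width_cm <= 0:
            raise ValueError("bin_width_cm must be positive")
        if self.speed_min_cms >= self.speed_max_cms:
            raise ValueError("speed_min must be below speed_max")
        if self.smooth_size_bins < 1 or self.smooth_size_bins % 2 == 0:
            raise ValueError("smooth_size_bins must be odd and >= 1")

    def n_raw_bins(self, track_length_cm: float) -> int:
        return int(np.ceil(track_length_cm / self.bin_width_cm - 1e-9))

    def n_kept_bins(self, track_length_cm: float) -> int:
        k = self.n_raw_bins(track_length_cm) - 2 * self.n_end_bins_discarded_per_side
        if k <= 0:
            raise ValueError("no bins remain after discarding end bins")
        return k

    def kept_bin_centres_cm(self, track_length_cm: float) -> np.ndarray:
        k = self.n_kept_bins(track_length_cm)
        off = self.n_end_bins_discarded_per_side
        return (np.arange(k) + off + 0.5) * self.bin_width_cm


@dataclass
class PlaceFieldMap:
    """Per-neuron event-rate map over the kept bins of one direction.

    `rate` is in events/s; `occupancy_s` is the time spent per bin (s) on
    valid frames; `occupancy_frac` sums to 1 over visited bins and is the
    P_i of the spatial-information formula and the decoder prior.
    """

    rate: np.ndarray            # neurons x K, events/s (smoothed)
    counts: np.ndarray          # neurons x K, raw event counts
    occupancy_s: np.ndarray     # K, raw seconds per bin
    occupancy_frac: np.ndarray  # K, fraction of valid time per bin
    field_bin: np.ndarray       # neurons, argmax bin (ties -> lowest)
    visited: np.ndarray         # K, bool: smoothed occupancy > 0
    direction: int
    spec: BinningSpec
    track_length_cm: float
    fps: float

    @property
    def n_neurons(self) -> int:
        return self.rate.shape[0]

    @property
    def n_bins(self) -> int:
        return self.rate.shape[1]

    def bin_centres_cm(self) -> np.ndarray:
        return self.spec.kept_bin_centres_cm(self.track_length_cm)

    def display_map(self) -> np.ndarray:
        """Rate map normalised per neuron to peak 1 (all-zero rows stay 0)."""
        peak = self.rate.max(axis=1, keepdims=True)
        safe = np.where(peak > 0, peak, 1.0)
        return self.rate / safe


def compute_speed(session: TrackSession) -> np.ndarray:
    """Per-frame running speed (cm/s).

    Central finite difference of position scaled by the frame rate, smoothed
    with a 5-frame boxcar; the first and last frame use one-sided
    differences.  The result is an unsigned speed.
    """
    x = session.x_cm
    if x.size < 3:
        raise ValueError("need at least 3 frames to compute speed")
    v = np.empty_like(x)
    v[1:-1] = (x[2:] - x[:-2]) / 2.0
    v[0] = x[1] - x[0]
    v[-1] = x[-1] - x[-2]
    v *= session.fps
    speed = np.abs(v)
    # 5-frame boxcar; edges truncate-renormalise via convolution of ones
    kernel = np.ones(5)
    norm = np.convolve(np.ones_like(speed), kernel, mode="same")
    return np.convolve(speed, kernel, mode="same") / norm


def smoothed_velocity(session: TrackSession, window: int = 5) -> np.ndarray:
    """Signed velocity (cm/s), boxcar-smoothed; used to infer direction."""
    x = session.x_cm
    v = np.empty_like(x)
    v[1:-1] = (x[2:] - x[:-2]) / 2.0
    v[0] = x[1] - x[0]
    v[-1] = x[-1] - x[-2]
    v *= session.fps
    kernel = np.ones(window)
    norm = np.convolve(np.ones_like(v), kernel, mode="same")
    return np.convolve(v, kernel, mode="same") / norm


def bin_index(
    x_cm: np.ndarray | float, spec: BinningSpec, track_length_cm: float
):
    """Kept-bin index of position(s); OUTSIDE (-1) for discarded end bins.

    Bins are half-open [k*w, (k+1)*w); x == track_length maps into the last
    raw bin.  The returned index is relative to the kept bins, i.e. the
    first kept bin (after the discarded ones) is 0.
    """
    x = np.asarray(x_cm, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if np.any(x < -1e-9) or np.any(x > track_length_cm + 1e-9):
        raise ValueError("position outside the track")
    n_raw = spec.n_raw_bins(track_length_cm)
    raw = np.minimum((x / spec.bin_width_cm).astype(int), n_raw - 1)
    off = spec.n_end_bins_discarded_per_side
    kept = raw - off
    kept[(raw < off) | (raw >= n_raw - off)] = OUTSIDE
    return int(kept[0]) if scalar else kept


def valid_frame_mask(
    session: TrackSession,
    spec: BinningSpec,
    direction: str | int,
    speed: np.ndarray | None = None,
) -> np.ndarray:
    """Frames kept for mapping: right direction, speed in range, kept bin."""
    code = direction_code(direction)
    if speed is None:
        speed = compute_speed(session)
    kept = bin_index(session.x_cm, spec, session.track_length_cm) != OUTSIDE
    return (
        (session.direction == code)
        & (speed >= spec.speed_min_cms)
        & (speed <= spec.speed_max_cms)
        & kept
    )


def occupancy_and_counts(
    session: TrackSession,
    raster: EventRaster,
    spec: BinningSpec,
    direction: str | int,
    speed: np.ndarray | None = None,
    mask: np.ndarray | None = None,
):
    """Raw per-bin occupancy (seconds) and per-neuron event counts.

    Conservation holds exactly: occupancy sums to n_valid_frames/fps and the
    counts sum to the raster total over valid frames.
    """
    if mask is None:
        mask = valid_frame_mask(session, spec, direction, speed=speed)
    if not mask.any():
        raise ValueError("no valid frames for this direction/speed range")
    k = spec.n_kept_bins(session.track_length_cm)
    bins = bin_index(session.x_cm[mask], spec, session.track_length_cm)
    occupancy_s = np.bincount(bins, minlength=k).astype(float) / session.fps
    sub = raster.counts[:, mask]
    counts = np.zeros((raster.n_neurons, k))
    np.add.at(counts.T, bins, sub.T.astype(float))
    return occupancy_s, counts


def gaussian_kernel(spec: BinningSpec) -> np.ndarray:
    """Discrete Gaussian taps, normalised to sum 1."""
    half = spec.smooth_size_bins // 2
    k = np.arange(-half, half + 1, dtype=float)
    if spec.smooth_sigma_bins <= 0:
        w = (k == 0).astype(float)
    else:
        w = np.exp(-(k**2) / (2.0 * spec.smooth_sigma_bins**2))
    return w / w.sum()


def smoothing_matrix(n_bins: int, spec: BinningSpec) -> np.ndarray:
    """K x K matrix applying the truncated-renormalised Gaussian smoother.

    Row i holds the kernel centred at bin i, clipped to the vector support
    and renormalised, so edge bins are smoothed only over existing
    neighbours (no padding values are invented).
    """
    if spec.smooth_size_bins > n_bins:
        raise ValueError("smoothing kernel larger than the vector")
    kern = gaussian_kernel(spec)
    half = spec.smooth_size_bins // 2
    s = np.zeros((n_bins, n_bins))
    for i in range(n_bins):
        lo = max(0, i - half)
        hi = min(n_bins, i + half + 1)
        taps = kern[lo - i + half : hi - i + half]
        s[i, lo:hi] = taps / taps.sum()
    return s


def gaussian_smooth(vector: np.ndarray, spec: BinningSpec) -> np.ndarray:
    """Smooth a 1-D (or row-stacked 2-D) vector with the map kernel."""
    v = np.asarray(vector, dtype=float)
    s = smoothing_matrix(v.shape[-1], spec)
    return v @ s.T


def place_field_map(
    session: TrackSession,
    raster: EventRaster,
    spec: BinningSpec,
    direction: str | int,
    speed: np.ndarray | None = None,
) -> PlaceFieldMap:
    """Build the per-neuron rate map for one running direction."""
    occupancy_s, counts = occupancy_and_counts(
        session, raster, spec, direction, speed=speed
    )
    s = smoothing_matrix(occupancy_s.size, spec)
    occ_smooth = occupancy_s @ s.T
    cnt_smooth = counts @ s.T
    visited = occ_smooth > 0
    rate = np.zeros_like(cnt_smooth)
    rate[:, visited] = cnt_smooth[:, visited] / occ_smooth[visited]
    total = occupancy_s.sum()
    occupancy_frac = occupancy_s / total if total > 0 else occupancy_s
    field_bin = rate.argmax(axis=1)  # argmax ties -> lowest index
    return PlaceFieldMap(
        rate=rate,
        counts=counts,
        occupancy_s=occupancy_s,
        occupancy_frac=occupancy_frac,
        field_bin=field_bin,
        visited=visited,
        direction=direction_code(direction),
        spec=spec,
        track_length_cm=session.track_length_cm,
        fps=session.fps,
    )


def write_map(pfm: PlaceFieldMap, path) -> None:
    """Delimited-text map: metadata header, occupancy row, then one
    neurons-row per line."""
    with open(path, "w") as fh:
        fh.write(
            f"# direction={pfm.direction} bin_width_cm={pfm.spec.bin_width_cm} "
            f"kept_bin_offset={pfm.spec.n_end_bins_discarded_per_side} "
            f"n_bins={pfm.n_bins}\n"
        )
        fh.write("occupancy_s\t" + "\t".join(f"{v:.6g}" for v in pfm.occupancy_s) + "\n")
        for n in range(pfm.n_neurons):
            fh.write(
                f"neuron_{n}\t" + "\t".join(f"{v:.6g}" for v in pfm.rate[n]) + "\n"
            )
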