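"""Spatial information content (SIC) and the shuffle-based place-cell test.

SIC is the Skaggs information rate per event,

    I = sum_i P_i (lam_i / lam_bar) log2(lam_i / lam_bar),
    lam_bar = sum_i P_i lam_i,

with P_i the occupancy fraction of bin i and lam_i the smoothed event rate.
Significance is assessed against a null built by circularly shifting each
neuron's event train relative to the (fixed) trajectory by a random offset
of at least 15 s, recomputing the map and SIC each time; this preserves the
event train's autocorrelation and the occupancy map while destroying the
position locking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .maps import BinningSpec, PlaceFieldMap, bin_index, smoothing_matrix, valid_frame_mask
from .session import EventRaster, TrackSession


@dataclass
class SICResult:
    """Per-neuron spatial information and place-cell classification."""

    sic_bits: np.ndarray
    p_value: np.ndarray
    is_place_cell: np.ndarray
    mean_rate_hz: np.ndarray
    n_shuffles: int
    direction: int | None = None


def sic(pfm_or_p, rates=None) -> np.ndarray:
    """Spatial information (bits/event) per neuron.

    Accepts either a :class:`~placecode.maps.PlaceFieldMap` or an explicit
    pair ``(occupancy_fractions, rate_rows)``.  Bins with zero rate
    contribute zero (the x log x -> 0 limit); neurons with zero mean rate
    get SIC 0.
    """
    if isinstance(pfm_or_p, PlaceFieldMap):
        p = pfm_or_p.occupancy_frac
        lam = pfm_or_p.rate
    else:
        p = np.asarray(pfm_or_p, dtype=float)
        lam = np.asarray(rates, dtype=float)
    lam = np.atleast_2d(lam)
    if np.any(lam < 0):
        raise ValueError("rates must be non-negative")
    lam_bar = lam @ p
    out = np.zeros(lam.shape[0])
    ok = lam_bar > 0
    if ok.any():
        ratio = lam[ok] / lam_bar[ok, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(ratio > 0, ratio * np.log2(ratio), 0.0)
        out[ok] = term @ p
    return out


def shuffle_null(
    session: TrackSession,
    raster: EventRaster,
    spec: BinningSpec,
    direction,
    n_shuffles: int = 1000,
    seed=None,
    min_shift_s: float = 15.0,
    method: str = "permute_frames",
    speed=None,
) -> np.ndarray:
    """Null SIC samples, shape (n_neurons, n_shuffles).

    ``method='permute_frames'`` (default) permutes the valid frames' bin
    assignment, the exact null for frame-independent event trains.
    ``method='circular'`` circularly shifts every neuron's event train by a
    per-shuffle random offset drawn uniformly from [15 s, duration - 15 s];
    it preserves the event train's autocorrelation, but on tightly
    stereotyped shuttle behaviour the trajectory's quasi-periodicity leaks
    position information through the shift, which inflates the null and
    destabilises the place-cell count (see the methods note), so it is an
    option rather than the default here.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    n_frames = session.n_frames
    min_shift = int(round(min_shift_s * session.fps))
    if method == "circular" and n_frames <= 2 * min_shift:
        raise ValueError("session shorter than twice the minimum shift")

    mask = valid_frame_mask(session, spec, direction, speed=speed)
    if not mask.any():
        raise ValueError("no valid frames")
    k = spec.n_kept_bins(session.track_length_cm)
    # per-frame kept-bin id, -2 where the frame is invalid for this direction
    frame_bin = np.full(n_frames, -2, dtype=np.int64)
    frame_bin[mask] = bin_index(
        session.x_cm[mask], spec, session.track_length_cm
    )
    occupancy_s = (
        np.bincount(frame_bin[mask], minlength=k).astype(float) / session.fps
    )
    smat = smoothing_matrix(k, spec)
    occ_smooth = occupancy_s @ smat.T
    total = occupancy_s.sum()
    p_occ = occupancy_s / total

    # sparse event list shared by all shuffles
    neuron_id, ev_frame = np.nonzero(raster.counts)
    ev_count = raster.counts[neuron_id, ev_frame].astype(float)
    n_neurons = raster.n_neurons

    if method == "circular":
        offsets = rng.integers(min_shift, n_frames - min_shift, size=n_shuffles)
    elif method == "permute_frames":
        offsets = None
    else:
        raise ValueError(f"unknown shuffle method {method!r}")

    inv_occ = np.where(occ_smooth > 0, 1.0 / occ_smooth, 0.0)
    null = np.empty((n_neurons, n_shuffles))
    flat_dim = n_neurons * (k + 1)
    for s in range(n_shuffles):
        if method == "circular":
            bins = frame_bin[(ev_frame + offsets[s]) % n_frames]
        else:
            perm = np.empty(n_frames, dtype=np.int64)
            perm[:] = frame_bin
            idx = np.nonzero(mask)[0]
            perm[idx] = frame_bin[rng.permutation(idx)]
            bins = perm[ev_frame]
        keep = bins >= 0
        flat = neuron_id[keep] * (k + 1) + bins[keep]
        counts = np.bincount(
            flat, weights=ev_count[keep], minlength=flat_dim
        ).reshape(n_neurons, k + 1)[:, :k]
        rate = (counts @ smat.T) * inv_occ
        null[:, s] = sic(p_occ, rate)
    return null


def classify_place_cells(
    sic_values: np.ndarray,
    null_samples: np.ndarray,
    alpha: float = 0.05,
    mean_rate_hz: np.ndarray | None = None,
    direction=None,
) -> SICResult:
    """Permutation p-values and the place-cell call.

    p = (1 + #{null >= observed}) / (1 + n_shuffles); a neuron is a place
    cell iff p < alpha.  Silent neurons (zero mean rate) are never place
    cells.
    """
    sic_values = np.asarray(sic_values, dtype=float)
    null_samples = np.atleast_2d(null_samples)
    n_shuffles = null_samples.shape[1]
    ge = (null_samples >= sic_values[:, None]).sum(axis=1)
    p = (1.0 + ge) / (1.0 + n_shuffles)
    is_pc = p < alpha
    if mean_rate_hz is None:
        mean_rate_hz = np.full(sic_values.shape, np.nan)
    else:
        mean_rate_hz = np.asarray(mean_rate_hz, dtype=float)
        is_pc = is_pc & (mean_rate_hz > 0)
    return SICResult(
        sic_bits=sic_values,
        p_value=p,
        is_place_cell=is_pc,
        mean_rate_hz=mean_rate_hz,
        n_shuffles=n_shuffles,
        direction=direction,
    )


def high_sic_count(sic_values, threshold_bits: float = 2.0) -> int:
    """Number of neurons with SIC strictly above the threshold."""
    v = np.asarray(sic_values, dtype=float)
    return int((v > threshold_bits).sum())


def score_direction(
    session: TrackSession,
    raster: EventRaster,
    spec: BinningSpec,
    direction,
    n_shuffles: int = 1000,
    alpha: float = 0.05,
    seed=None,
    speed=None,
    method: str = "permute_frames",
) -> SICResult:
    """Convenience: map -> SIC -> shuffle null -> classification."""
    from .maps import place_field_map

    pfm = place_field_map(session, raster, spec, direction, speed=speed)
    obs = sic(pfm)
    null = shuffle_null(
        session, raster, spec, direction,
        n_shuffles=n_shuffles, seed=seed, speed=speed, method=method,
    )
    mean_rate = pfm.rate @ pfm.occupancy_frac
    return classify_place_cells(
        obs, null, alpha=alpha, mean_rate_hz=mean_rate, direction=pfm.direction
    )


def write_results(result: SICResult, path, direction_label: str = "") -> None:
    with open(path, "w") as fh:
        fh.write("neuron_id\tdirection\tsic_bits\tp_value\tis_place_cell\tmean_rate_hz\n")
        for i in range(result.sic_bits.size):
            fh.write(
                f"{i}\t{direction_label}\t{result.sic_bits[i]:.6g}\t"
                f"{result.p_value[i]:.6g}\t{int(result.is_place_cell[i])}\t"
                f"{result.mean_rate_hz[i]:.6g}\n"
            )
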