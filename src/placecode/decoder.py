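"""Memoryless naive Bayesian position decoding from population event counts.

For a window of length tau holding event counts n = (n_1 .. n_N), the
posterior over position bins is

    P(x | n)  propto  P(x) * prod_i f_i(x)^{n_i} * exp(-tau * sum_i f_i(x))

with f_i(x) the neuron's place-field rate map and P(x) the occupancy prior.
The estimate is the centre of the maximum-posterior bin and the decoding
error is the mean |true - estimated| distance per decoded frame (cm/frame).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .maps import BinningSpec, place_field_map, valid_frame_mask
from .session import EventRaster, TrackSession, direction_code

#: log-probability assigned to f_i(x) = 0 when n_i > 0 (posterior ~ 0 there)
_LOG_ZERO = -1e12


@dataclass
class DecoderModel:
    """Trained decoder: rate maps, occupancy prior and window length."""

    f: np.ndarray               # neurons x K rate maps (events/s)
    prior: np.ndarray           # K occupancy prior, sums to 1
    tau_s: float
    neuron_ids: np.ndarray
    bin_centres_cm: np.ndarray
    direction: int
    fps: float

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise ValueError("tau must be positive")
        if np.any(self.f < 0):
            raise ValueError("rate maps must be non-negative")
        if abs(self.prior.sum() - 1.0) > 1e-9:
            raise ValueError("prior must sum to 1")

    @property
    def n_bins(self) -> int:
        return self.f.shape[1]


def train(
    session: TrackSession,
    raster: EventRaster,
    spec: BinningSpec,
    direction,
    tau_s: float = 0.5,
    place_cells_only: bool = True,
    place_cell_mask: np.ndarray | None = None,
    speed=None,
    n_shuffles: int = 1000,
    seed=None,
    rate_floor_hz: float = 0.01,
) -> DecoderModel:
    """Fit rate maps and the occupancy prior for one direction.

    With ``place_cells_only`` the model keeps only neurons passing the
    shuffle test; pass ``place_cell_mask`` to reuse an existing
    classification instead of re-running the (costly) shuffles.

    ``rate_floor_hz`` clips the trained maps away from exact zero.  Maps
    estimated from a dozen traversals are sparse, and an exact zero acts as
    a veto: one stray out-of-field event from a neuron whose estimated rate
    at the true bin is zero annihilates that bin's posterior.  A small
    floor turns the veto into a finite penalty; set it to 0 to decode with
    the raw maps.
    """
    pfm = place_field_map(session, raster, spec, direction, speed=speed)
    if place_cells_only:
        if place_cell_mask is None:
            from .info import score_direction

            place_cell_mask = score_direction(
                session, raster, spec, direction,
                n_shuffles=n_shuffles, seed=seed, speed=speed,
            ).is_place_cell
        ids = np.nonzero(np.asarray(place_cell_mask))[0]
    else:
        ids = np.arange(raster.n_neurons)
    if ids.size == 0:
        raise ValueError("no neurons available to train the decoder")
    return DecoderModel(
        f=np.maximum(pfm.rate[ids], rate_floor_hz),
        prior=pfm.occupancy_frac.copy(),
        tau_s=tau_s,
        neuron_ids=ids,
        bin_centres_cm=pfm.bin_centres_cm(),
        direction=pfm.direction,
        fps=session.fps,
    )


def posterior(
    model: DecoderModel, window_counts: np.ndarray, tau_s: float | None = None
) -> np.ndarray:
    """Normalised posterior over bins for one window of counts.

    Computed in log space.  Bins where some active neuron (n_i > 0) has
    f_i(x) = 0 get probability 0; if every bin is excluded this way the
    posterior falls back to the prior.
    """
    n = np.asarray(window_counts, dtype=float)
    if n.shape != (model.f.shape[0],):
        raise ValueError("window counts must match the model's neuron count")
    if np.any(n < 0):
        raise ValueError("counts must be non-negative")
    tau = model.tau_s if tau_s is None else tau_s
    logp = _log_posterior(model.f, model.prior, n[None, :], tau)[0]
    return _normalise(logp, model.prior)


def _log_posterior(f, prior, counts, tau) -> np.ndarray:
    """Unnormalised log posterior for rows of counts; shape (n_win, K)."""
    with np.errstate(divide="ignore"):
        logf = np.log(f)
    logf = np.where(np.isfinite(logf), logf, _LOG_ZERO)
    with np.errstate(divide="ignore"):
        logprior = np.where(prior > 0, np.log(prior), _LOG_ZERO)
    return logprior[None, :] + counts @ logf - tau * f.sum(axis=0)[None, :]


def _normalise(logp: np.ndarray, prior: np.ndarray) -> np.ndarray:
    if logp.max() < _LOG_ZERO / 2:  # every bin excluded -> prior fallback
        return prior.copy()
    p = np.exp(logp - logp.max())
    return p / p.sum()


def decode_session(
    model: DecoderModel,
    session: TrackSession,
    raster: EventRaster,
    direction=None,
    spec: BinningSpec | None = None,
    speed=None,
):
    """Per-frame MAP position estimates on the valid frames.

    A window of length tau is centred on each valid frame (stepped one frame
    at a time); truncated boundary windows rescale tau to the actual window
    duration.  Returns ``(frame_indices, est_x_cm, true_x_cm)``.
    """
    if direction is None:
        direction = model.direction
    if spec is None:
        spec = BinningSpec()
    code = direction_code(direction)
    mask = valid_frame_mask(session, spec, code, speed=speed)
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return idx, np.empty(0), np.empty(0)

    counts = raster.counts[model.neuron_ids].astype(float)  # N x F
    n_frames = counts.shape[1]
    half = int(round(model.tau_s * session.fps / 2))
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n_frames)
    csum = np.concatenate(
        [np.zeros((counts.shape[0], 1)), np.cumsum(counts, axis=1)], axis=1
    )
    win = (csum[:, hi] - csum[:, lo]).T                     # n_valid x N
    tau_eff = (hi - lo) / session.fps

    with np.errstate(divide="ignore"):
        logf = np.log(model.f)
    logf = np.where(np.isfinite(logf), logf, _LOG_ZERO)
    with np.errstate(divide="ignore"):
        logprior = np.where(model.prior > 0, np.log(model.prior), _LOG_ZERO)
    logp = (
        logprior[None, :]
        + win @ logf
        - tau_eff[:, None] * model.f.sum(axis=0)[None, :]
    )
    best = logp.argmax(axis=1)
    # all-excluded windows fall back to the prior's mode
    dead = logp.max(axis=1) < _LOG_ZERO / 2
    if dead.any():
        best[dead] = int(np.argmax(model.prior))
    est = model.bin_centres_cm[best]
    return idx, est, session.x_cm[idx]


def decoding_error(est_x_cm: np.ndarray, true_x_cm: np.ndarray) -> float:
    """Mean absolute distance between estimate and truth (cm/frame)."""
    est_x_cm = np.asarray(est_x_cm, dtype=float)
    true_x_cm = np.asarray(true_x_cm, dtype=float)
    if est_x_cm.size == 0:
        raise ValueError("no decoded frames")
    return float(np.abs(est_x_cm - true_x_cm).mean())


def write_decoded(path, frame_idx, true_x, est_x) -> None:
    with open(path, "w") as fh:
        fh.write("frame_index\ttrue_x_cm\test_x_cm\tabs_error_cm\n")
        for i, t, e in zip(frame_idx, true_x, est_x):
            fh.write(f"{i}\t{t:.4f}\t{e:.4f}\t{abs(t - e):.4f}\n")
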