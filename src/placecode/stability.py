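"""Ensemble stability: odd/even-trial population vector overlap (PVO).

Same-direction traversals are split by parity of their temporal order; a
place-field map is built independently from each half.  PVO(x, y) is the
cosine similarity between the population rate vector at bin x of the
odd-trial map and bin y of the even-trial map; a PVO matrix concentrated on
its diagonal means the ensemble fires in the same places in both halves.
The diagonal index DI = 1 / sum((PVO - I)^2) summarises that concentration:
larger DI, more stable spatial coding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .maps import BinningSpec, PlaceFieldMap, place_field_map
from .session import EventRaster, TrackSession, direction_code


@dataclass
class PVOMatrix:
    """Bins x bins overlap matrix with its diagonal index."""

    matrix: np.ndarray
    n_neurons: int
    direction: int | None
    zero_odd_bins: np.ndarray    # bins whose odd-half population vector is 0
    zero_even_bins: np.ndarray

    @property
    def diagonal_index(self) -> float:
        return diagonal_index(self)


def odd_even_maps(
    session: TrackSession,
    raster: EventRaster,
    spec: BinningSpec,
    direction,
    speed=None,
) -> tuple[PlaceFieldMap, PlaceFieldMap]:
    """Maps built from odd-indexed and even-indexed traversals.

    Traversals are numbered 1..T in temporal order (so "odd" starts with the
    first traversal); both halves must be non-empty.
    """
    code = direction_code(direction)
    n_trials = session.n_traversals(code)
    if n_trials < 2:
        raise ValueError("need at least 2 traversals for an odd/even split")
    # trial_index is 0-based; temporal order 1..T makes odd = even 0-based
    parity = session.trial_index % 2
    halves = []
    for want in (0, 1):  # 0-based even == 1-based odd
        sub = TrackSession(
            x_cm=session.x_cm,
            fps=session.fps,
            track_length_cm=session.track_length_cm,
            direction=np.where(
                (session.direction == code) & (parity == want), code, 0
            ).astype(np.int8),
            trial_index=session.trial_index,
            time_s=session.time_s,
        )
        halves.append(place_field_map(sub, raster, spec, code, speed=speed))
    return halves[0], halves[1]


def pvo(
    map_odd: PlaceFieldMap,
    map_even: PlaceFieldMap,
    neurons_subset: np.ndarray | None = None,
) -> PVOMatrix:
    """Cosine population-vector overlap between two map estimates."""
    if map_odd.rate.shape != map_even.rate.shape:
        raise ValueError("odd/even maps must share neurons and bins")
    a = map_odd.rate
    b = map_even.rate
    if neurons_subset is not None:
        neurons_subset = np.asarray(neurons_subset)
        a = a[neurons_subset]
        b = b[neurons_subset]
    num = a.T @ b                         # K x K
    norm_a = np.linalg.norm(a, axis=0)    # per-bin population-vector norms
    norm_b = np.linalg.norm(b, axis=0)
    denom = np.outer(norm_a, norm_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return PVOMatrix(
        matrix=m,
        n_neurons=a.shape[0],
        direction=map_odd.direction,
        zero_odd_bins=norm_a == 0,
        zero_even_bins=norm_b == 0,
    )


def diagonal_index(pvo_matrix) -> float:
    """DI = 1 / sum((PVO - I)^2); +inf (flagged by value) for a perfect
    identity matrix."""
    m = pvo_matrix.matrix if isinstance(pvo_matrix, PVOMatrix) else np.asarray(pvo_matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("PVO matrix must be square")
    dev = float(((m - np.eye(m.shape[0])) ** 2).sum())
    return np.inf if dev == 0 else 1.0 / dev


def odd_even_stability(
    session: TrackSession,
    raster: EventRaster,
    spec: BinningSpec,
    direction,
    neurons_subset=None,
    speed=None,
) -> PVOMatrix:
    """Convenience: odd/even maps -> PVO on the given neuron subset."""
    m_odd, m_even = odd_even_maps(session, raster, spec, direction, speed=speed)
    return pvo(m_odd, m_even, neurons_subset)


def write_pvo(p: PVOMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# n_neurons={p.n_neurons} direction={p.direction} "
            f"diagonal_index={p.diagonal_index:.6g}\n"
        )
        for row in p.matrix:
            fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")
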