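"""Synthetic linear-track sessions with calcium-event rasters.

Stands in for unreleased miniscope recordings: a head-fixed-free mouse
shuttles on a 1.6 m track (12 traversals per direction at ~15 cm/s, 30
frames/s) while ~640 neurons emit Poisson calcium events.  55% of neurons
are place cells with Gaussian spatial tuning (SD 8 cm, in-field peak
1 event/s); the out-of-field rate is solved so the population mean event
rate hits the target 0.077 Hz.  A drug effect (modelled on systemic
scopolamine) scales rates to ~83%, drops ~15% of cells below detection,
jitters field centres trial-to-trial, remaps a fraction of fields and adds
diffuse off-field drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .session import LR, NONE, RL, EventRaster, TrackSession


@dataclass(frozen=True)
class SpeedProfile:
    """Running-speed statistics of the simulated mouse."""

    mean_cms: float = 15.0
    sd_cms: float = 2.0            # frame-to-frame speed noise
    trial_sd_cms: float = 4.0      # traversal-to-traversal mean-speed spread
    dwell_s: float = 2.0           # mean pause at each end between traversals
    dwell_jitter_s: float = 1.5    # half-range of the uniform dwell spread
    ramp_cm: float = 4.0           # accel/decel zone at each end of a traversal


@dataclass(frozen=True)
class SessionConfig:
    """Study-condition parameters of one synthetic session."""

    track_length_cm: float = 160.0
    fps: float = 30.0
    n_trials: int = 12
    n_neurons: int = 640
    place_cell_fraction: float = 0.55
    field_width_cm: float = 8.0
    peak_rate_hz: float = 1.0
    baseline_rate_hz: float | None = None   # None -> solved from target
    target_mean_rate_hz: float = 0.077
    direction_selective_fraction: float = 0.5
    tuning_irregularity_sd: float = 1.0   # log-sd of the stable rate texture
    irregularity_grid_cm: float = 2.0     # spatial grain of the texture
    speed_profile: SpeedProfile = field(default_factory=SpeedProfile)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.track_length_cm <= 0 or self.fps <= 0:
            raise ValueError("track_length_cm and fps must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0 <= self.place_cell_fraction <= 1:
            raise ValueError("place_cell_fraction must be in [0, 1]")
        for r in (self.peak_rate_hz, self.target_mean_rate_hz):
            if r < 0:
                raise ValueError("rates must be non-negative")
        if self.baseline_rate_hz is not None and self.baseline_rate_hz < 0:
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class DrugEffect:
    """Multiplicative/structural perturbation applied to a tuning set."""

    rate_scale: float = 0.834
    detect_scale: float = 0.847
    field_jitter_cm: float = 0.0
    offfield_rate_hz: float = 0.0
    remap_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.detect_scale <= 1:
            raise ValueError("detect_scale must be in [0, 1]")
        if self.rate_scale < 0 or self.offfield_rate_hz < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.remap_fraction <= 1:
            raise ValueError("remap_fraction must be in [0, 1]")

    @classmethod
    def identity(cls) -> "DrugEffect":
        """Saline control: nothing changes."""
        return cls(rate_scale=1.0, detect_scale=1.0)

    @classmethod
    def scopolamine(cls) -> "DrugEffect":
        """Calibrated muscarinic-blockade effect.

        rate and detection scales follow the reported population changes;
        the field destabilisation (per-trial centre jitter, partial
        remapping, diffuse off-field drive) is calibrated so the full
        analysis pipeline reproduces the reported directional changes
        (place cells and map stability down, decoding error up ~2.7x).
        """
        return cls(
            rate_scale=0.82,
            detect_scale=0.847,
            field_jitter_cm=24.0,
            offfield_rate_hz=0.005,
            remap_fraction=0.3,
        )


@dataclass
class TuningSet:
    """Per-neuron, per-direction inhomogeneous-Poisson rate model.

    Direction axis 0 is LR, axis 1 is RL.  Direction-selective place cells
    carry peak 0 in their untuned direction; undetected neurons emit no
    events regardless of tuning.
    """

    field_centre_cm: np.ndarray    # n x 2
    field_width_cm: np.ndarray     # n x 2
    peak_rate_hz: np.ndarray       # n x 2
    baseline_rate_hz: np.ndarray   # n
    is_place_cell: np.ndarray      # n bool
    detected: np.ndarray           # n bool
    track_length_cm: float
    field_jitter_cm: float = 0.0
    #: stable per-cell multiplicative rate texture (n x 2 x grid points),
    #: mean 1; rides with the field under jitter.  Real place fields are
    #: irregular but reliable at the ~bin scale, which is what makes the
    #: odd/even population-vector overlap diagonal-dominated; a pure smooth
    #: Gaussian bump cannot reproduce that.
    texture: np.ndarray | None = None
    texture_grid_cm: float = 2.0

    def __post_init__(self) -> None:
        if np.any(self.field_width_cm <= 0):
            raise ValueError("field widths must be positive")
        if np.any(self.field_centre_cm < 0) or np.any(
            self.field_centre_cm > self.track_length_cm
        ):
            raise ValueError("field centres must lie on the track")

    @property
    def n_neurons(self) -> int:
        return self.baseline_rate_hz.size


@dataclass
class SessionBundle:
    """One recorded condition: behaviour, events, and the generating model."""

    session: TrackSession
    raster: EventRaster
    tuning: TuningSet


_DIR_COL = {LR: 0, RL: 1}


def simulate_trajectory(
    config: SessionConfig, rng: np.random.Generator | None = None
) -> TrackSession:
    """Alternating end-to-end traversals with a smoothed bang-bang speed.

    Each traversal runs at Gaussian-noise speed around a per-traversal mean
    (itself jittered trial to trial, as real mice do) with short
    acceleration/deceleration ramps at the ends; the mouse dwells for a
    variable time (direction 'none') at each end between traversals.  The
    trial-to-trial duration variability matters: it is what decorrelates
    the circular-shift shuffle null from the quasi-periodic trajectory.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sp = config.speed_profile
    fps, length = config.fps, config.track_length_cm

    xs: list[float] = []
    dirs: list[int] = []
    trials: list[int] = []
    trial_count = {LR: 0, RL: 0}
    x = 0.0
    for traversal in range(2 * config.n_trials):
        d = LR if traversal % 2 == 0 else RL
        sign = 1.0 if d == LR else -1.0
        mean_t = max(
            sp.mean_cms * 0.6,
            sp.mean_cms + sp.trial_sd_cms * rng.standard_normal(),
        )
        t_idx = trial_count[d]
        trial_count[d] += 1
        xs.append(x)
        dirs.append(d)
        trials.append(t_idx)
        while True:
            edge = min(x, length - x)
            ramp = min(1.0, (edge + 0.5) / sp.ramp_cm) if sp.ramp_cm > 0 else 1.0
            ramp = max(ramp, 0.3)
            v = max(2.0, mean_t + sp.sd_cms * rng.standard_normal()) * ramp
            x_new = x + sign * v / fps
            if (d == LR and x_new >= length) or (d == RL and x_new <= 0.0):
                x = length if d == LR else 0.0
                xs.append(x)
                dirs.append(d)
                trials.append(t_idx)
                break
            x = x_new
            xs.append(x)
            dirs.append(d)
            trials.append(t_idx)
        if sp.dwell_s > 0 and traversal < 2 * config.n_trials - 1:
            dwell = max(
                0.0,
                sp.dwell_s + rng.uniform(-sp.dwell_jitter_s, sp.dwell_jitter_s),
            )
            dwell_frames = int(round(dwell * fps))
            xs.extend([x] * dwell_frames)
            dirs.extend([NONE] * dwell_frames)
            trials.extend([-1] * dwell_frames)
    return TrackSession(
        x_cm=np.array(xs),
        fps=fps,
        track_length_cm=length,
        direction=np.array(dirs),
        trial_index=np.array(trials),
    )


def _field_mass_fraction(width_cm: float, track_length_cm: float) -> float:
    """E over uniform centres of the track-average of the Gaussian bump."""
    x = np.linspace(0, track_length_cm, 401)
    c = np.linspace(0, track_length_cm, 101)
    bump = np.exp(-((x[None, :] - c[:, None]) ** 2) / (2 * width_cm**2))
    return float(bump.mean())


def solve_baseline_rate(config: SessionConfig, run_fraction: float = 0.85) -> float:
    """Out-of-field rate making the population mean hit the target.

    mean = b + run_fraction * pc_frac * (1 - sel_frac/2) * peak * G with G
    the average in-field mass fraction; clipped at 0 if the fields alone
    already exceed the target.
    """
    g = _field_mass_fraction(config.field_width_cm, config.track_length_cm)
    tuned = (
        run_fraction
        * config.place_cell_fraction
        * (1.0 - config.direction_selective_fraction / 2.0)
        * config.peak_rate_hz
        * g
    )
    return max(0.0, config.target_mean_rate_hz - tuned)


def simulate_tuning(
    config: SessionConfig, rng: np.random.Generator | None = None
) -> TuningSet:
    """Draw the population's tuning curves.

    round(place_cell_fraction * n) neurons get Gaussian fields with centres
    uniform along the track; a configurable fraction of them are tuned in
    one direction only (peak 0 in the other); the rest of the population is
    untuned at the solved constant rate.  Each tuned cell also carries a
    stable lognormal rate texture (mean 1) at ~bin resolution, giving the
    irregular-but-reliable within-field rate landscape of real place cells.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_neurons
    n_pc = int(round(config.place_cell_fraction * n))
    is_pc = np.zeros(n, dtype=bool)
    is_pc[rng.choice(n, size=n_pc, replace=False)] = True

    b = (
        config.baseline_rate_hz
        if config.baseline_rate_hz is not None
        else solve_baseline_rate(config)
    )
    centre = rng.uniform(0, config.track_length_cm, size=(n, 2))
    width = np.full((n, 2), config.field_width_cm)
    peak = np.zeros((n, 2))
    peak[is_pc] = config.peak_rate_hz

    pc_idx = np.nonzero(is_pc)[0]
    n_sel = int(round(config.direction_selective_fraction * n_pc))
    sel = rng.choice(pc_idx, size=n_sel, replace=False) if n_sel else np.array([], int)
    # selective cells keep one direction (random); the others share a centre
    drop_dir = rng.integers(0, 2, size=n_sel)
    peak[sel, drop_dir] = 0.0
    nonsel = np.setdiff1d(pc_idx, sel)
    centre[nonsel, 1] = centre[nonsel, 0]

    n_grid = int(np.ceil(config.track_length_cm / config.irregularity_grid_cm)) + 2
    sd = config.tuning_irregularity_sd
    texture = (
        np.exp(rng.normal(-sd**2 / 2.0, sd, size=(n, 2, n_grid)))
        if sd > 0
        else np.ones((n, 2, n_grid))
    )

    return TuningSet(
        field_centre_cm=centre,
        field_width_cm=width,
        peak_rate_hz=peak,
        baseline_rate_hz=np.full(n, b),
        is_place_cell=is_pc,
        detected=np.ones(n, dtype=bool),
        track_length_cm=config.track_length_cm,
        texture=texture,
        texture_grid_cm=config.irregularity_grid_cm,
    )


def rate_matrix(
    session: TrackSession,
    tuning: TuningSet,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-neuron, per-frame expected event rate (events/s).

    During traversals the rate is baseline + the direction's Gaussian bump
    evaluated at the current position (with the per-trial centre jitter, if
    any); during end dwell only the baseline applies.  Undetected neurons
    have rate 0.
    """
    if session.track_length_cm != tuning.track_length_cm:
        raise ValueError("session and tuning geometry differ")
    if rng is None:
        rng = np.random.default_rng()
    n = tuning.n_neurons
    rates = np.tile(tuning.baseline_rate_hz[:, None], (1, session.n_frames))
    for d, col in _DIR_COL.items():
        sel = session.direction == d
        if not sel.any():
            continue
        x = session.x_cm[sel]
        trial = session.trial_index[sel]
        n_trials = int(trial.max()) + 1
        jitter = (
            rng.normal(0.0, tuning.field_jitter_cm, size=(n, n_trials))
            if tuning.field_jitter_cm > 0
            else np.zeros((n, n_trials))
        )
        centre = tuning.field_centre_cm[:, col][:, None] + jitter[:, trial]
        bump = np.exp(
            -((x[None, :] - centre) ** 2)
            / (2 * tuning.field_width_cm[:, col][:, None] ** 2)
        )
        if tuning.texture is not None:
            # texture rides with the (jittered) field, so trial-to-trial
            # jitter displaces the whole rate landscape coherently
            xrel = x[None, :] - jitter[:, trial]
            gi = np.clip(
                (xrel / tuning.texture_grid_cm).astype(int),
                0,
                tuning.texture.shape[2] - 1,
            )
            bump = bump * np.take_along_axis(tuning.texture[:, col, :], gi, axis=1)
        rates[:, sel] += tuning.peak_rate_hz[:, col][:, None] * bump
    rates[~tuning.detected] = 0.0
    return rates


def simulate_events(
    session: TrackSession,
    tuning: TuningSet,
    rng: np.random.Generator | None = None,
) -> EventRaster:
    """Independent Poisson counts per frame with mean rate/fps."""
    if rng is None:
        rng = np.random.default_rng()
    rates = rate_matrix(session, tuning, rng=rng)
    counts = rng.poisson(rates / session.fps)
    return EventRaster(counts=counts.astype(np.int32), fps=session.fps)


def apply_drug_effect(
    tuning: TuningSet,
    effect: DrugEffect,
    rng: np.random.Generator | None = None,
) -> TuningSet:
    """Perturbed copy of a tuning set with preserved neuron identity.

    Rates are scaled, a detect_scale fraction of currently detected neurons
    stays detected (the rest are marked undetected, not deleted), a
    remap_fraction of place cells gets fresh uniform centres, and the
    per-trial jitter / off-field rate are installed for event simulation.
    """
    if rng is None:
        rng = np.random.default_rng()
    det = tuning.detected.copy()
    det_idx = np.nonzero(det)[0]
    n_keep = int(round(effect.detect_scale * det_idx.size))
    keep = rng.choice(det_idx, size=n_keep, replace=False)
    det[:] = False
    det[keep] = True

    centre = tuning.field_centre_cm.copy()
    pc_idx = np.nonzero(tuning.is_place_cell)[0]
    n_remap = int(round(effect.remap_fraction * pc_idx.size))
    if n_remap:
        remap = rng.choice(pc_idx, size=n_remap, replace=False)
        centre[remap] = rng.uniform(
            0, tuning.track_length_cm, size=(n_remap, 2)
        )

    return TuningSet(
        field_centre_cm=centre,
        field_width_cm=tuning.field_width_cm.copy(),
        peak_rate_hz=tuning.peak_rate_hz * effect.rate_scale,
        baseline_rate_hz=tuning.baseline_rate_hz * effect.rate_scale
        + effect.offfield_rate_hz,
        is_place_cell=tuning.is_place_cell.copy(),
        detected=det,
        track_length_cm=tuning.track_length_cm,
        field_jitter_cm=effect.field_jitter_cm,
        texture=None if tuning.texture is None else tuning.texture.copy(),
        texture_grid_cm=tuning.texture_grid_cm,
    )


def generate_paired_experiment(
    config: SessionConfig, effect: DrugEffect, seed: int | None = None
) -> tuple[SessionBundle, SessionBundle]:
    """Baseline and post-injection bundles with shared neuron identities.

    Fully reproducible given the seed: the same seed yields bit-identical
    trajectories and rasters.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    tuning = simulate_tuning(config, rng=rng)
    sess_base = simulate_trajectory(config, rng=rng)
    raster_base = simulate_events(sess_base, tuning, rng=rng)
    tuning_post = apply_drug_effect(tuning, effect, rng=rng)
    sess_post = simulate_trajectory(config, rng=rng)
    raster_post = simulate_events(sess_post, tuning_post, rng=rng)
    return (
        SessionBundle(sess_base, raster_base, tuning),
        SessionBundle(sess_post, raster_post, tuning_post),
    )


__all__ = [
    "SpeedProfile",
    "SessionConfig",
    "DrugEffect",
    "TuningSet",
    "SessionBundle",
    "simulate_trajectory",
    "simulate_tuning",
    "simulate_events",
    "rate_matrix",
    "apply_drug_effect",
    "generate_paired_experiment",
    "solve_baseline_rate",
]
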