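"""Session-level metrics and paired post/baseline reports.

Mirrors the reporting convention of pharmacology experiments on paired
recordings: every metric (detected cells, mean event rate, place cells,
spatial information, diagonal index, decoding error, running speed) is
computed per condition and per running direction, then expressed as a
percentage of its baseline value.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import decoder as bd
from . import info as si
from . import stability as st
from .maps import BinningSpec, compute_speed, place_field_map, bin_index, OUTSIDE
from .session import EventRaster, TrackSession
from .synthetic import DrugEffect, SessionConfig, SpeedProfile, generate_paired_experiment

log = logging.getLogger("placecode")

DIRECTIONS = ("LR", "RL")


@dataclass
class DirectionMetrics:
    n_place_cells: int
    pct_place_cells: float
    mean_sic_bits: float          # over all detected neurons
    mean_sic_place_cells: float
    n_high_sic: int
    diagonal_index: float
    decoding_error_cm_per_frame: float


@dataclass
class ConditionMetrics:
    n_detected_neurons: int
    mean_rate_hz: float
    mean_speed_cms: float
    per_direction: dict[str, DirectionMetrics] = field(default_factory=dict)


@dataclass
class SessionReport:
    """Per-condition metrics plus post/baseline percentage ratios."""

    baseline: ConditionMetrics
    post: ConditionMetrics
    ratios_pct: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "baseline": asdict(self.baseline),
            "post": asdict(self.post),
            "ratios_pct": self.ratios_pct,
        }


def mean_speed(
    session: TrackSession, spec: BinningSpec, speed: np.ndarray | None = None
) -> float:
    """Average running speed over frames in kept bins, both directions.

    No speed-range filter is applied here (the 8-25 cm/s filter is a
    mapping choice); only the discarded end bins are excluded.
    """
    if speed is None:
        speed = compute_speed(session)
    kept = bin_index(session.x_cm, spec, session.track_length_cm) != OUTSIDE
    kept &= session.direction != 0
    if not kept.any():
        raise ValueError("no frames outside the discarded end bins")
    return float(speed[kept].mean())


def condition_metrics(
    session: TrackSession,
    raster: EventRaster,
    spec: BinningSpec,
    n_shuffles: int = 1000,
    alpha: float = 0.05,
    tau_s: float = 0.5,
    seed=None,
    sic_threshold_bits: float = 2.0,
) -> ConditionMetrics:
    """Full single-condition analysis: maps, SIC shuffle test, PVO/DI,
    decoding, speed.  Mean rate and percentages are over detected neurons
    (those with at least one event)."""
    speed = compute_speed(session)
    detected = raster.detected_mask()
    n_det = int(detected.sum())
    out = ConditionMetrics(
        n_detected_neurons=n_det,
        mean_rate_hz=raster.mean_rate_hz(detected) if n_det else 0.0,
        mean_speed_cms=mean_speed(session, spec, speed=speed),
    )
    rng = np.random.default_rng(seed)
    for d in DIRECTIONS:
        res = si.score_direction(
            session, raster, spec, d,
            n_shuffles=n_shuffles, alpha=alpha,
            seed=int(rng.integers(2**31)), speed=speed,
        )
        pc = res.is_place_cell & detected
        pvo = st.odd_even_stability(
            session, raster, spec, d,
            neurons_subset=np.nonzero(pc)[0] if pc.any() else None,
            speed=speed,
        )
        if pc.any():
            model = bd.train(
                session, raster, spec, d, tau_s=tau_s,
                place_cell_mask=pc, speed=speed,
            )
            _, est, true = bd.decode_session(model, session, raster, speed=speed)
            err = bd.decoding_error(est, true)
        else:
            err = np.nan
        sic_det = res.sic_bits[detected]
        out.per_direction[d] = DirectionMetrics(
            n_place_cells=int(pc.sum()),
            pct_place_cells=float(pc.sum() / n_det * 100) if n_det else 0.0,
            mean_sic_bits=float(sic_det.mean()) if n_det else 0.0,
            mean_sic_place_cells=float(res.sic_bits[pc].mean()) if pc.any() else 0.0,
            n_high_sic=si.high_sic_count(sic_det, sic_threshold_bits),
            diagonal_index=pvo.diagonal_index,
            decoding_error_cm_per_frame=err,
        )
    return out


def _ratio(post, base) -> float:
    return float(post / base * 100.0) if base else np.nan


def paired_report(base: ConditionMetrics, post: ConditionMetrics) -> SessionReport:
    """Percentage-of-baseline ratios on matched quantities."""
    ratios = {
        "n_detected_neurons": _ratio(post.n_detected_neurons, base.n_detected_neurons),
        "mean_rate_hz": _ratio(post.mean_rate_hz, base.mean_rate_hz),
        "mean_speed_cms": _ratio(post.mean_speed_cms, base.mean_speed_cms),
    }
    for d in DIRECTIONS:
        b, p = base.per_direction[d], post.per_direction[d]
        ratios[f"n_place_cells_{d}"] = _ratio(p.n_place_cells, b.n_place_cells)
        ratios[f"mean_sic_bits_{d}"] = _ratio(p.mean_sic_bits, b.mean_sic_bits)
        ratios[f"n_high_sic_{d}"] = _ratio(p.n_high_sic, b.n_high_sic)
        ratios[f"diagonal_index_{d}"] = _ratio(p.diagonal_index, b.diagonal_index)
        ratios[f"decoding_error_{d}"] = _ratio(
            p.decoding_error_cm_per_frame, b.decoding_error_cm_per_frame
        )
    return SessionReport(baseline=base, post=post, ratios_pct=ratios)


def analyze_paired_experiment(
    config: SessionConfig,
    effect: DrugEffect,
    seed: int,
    spec: BinningSpec | None = None,
    n_shuffles: int = 1000,
    tau_s: float = 0.5,
) -> SessionReport:
    """Generate a paired synthetic experiment and report it."""
    if spec is None:
        spec = BinningSpec()
    bundle_base, bundle_post = generate_paired_experiment(config, effect, seed=seed)
    base = condition_metrics(
        bundle_base.session, bundle_base.raster, spec,
        n_shuffles=n_shuffles, tau_s=tau_s, seed=seed,
    )
    post = condition_metrics(
        bundle_post.session, bundle_post.raster, spec,
        n_shuffles=n_shuffles, tau_s=tau_s, seed=seed + 1,
    )
    return paired_report(base, post)


# ---------------------------------------------------------------------------
# config-driven pipeline


def _effect_from_config(d: dict) -> DrugEffect:
    if isinstance(d, str):
        return {"identity": DrugEffect.identity,
                "saline": DrugEffect.identity,
                "scopolamine": DrugEffect.scopolamine}[d]()
    return DrugEffect(**d)


def run_pipeline(config_path, seed: int | None = None, out_dir=None) -> SessionReport:
    """Execute simulate -> maps -> SIC -> PVO -> decode from a YAML config.

    The config may override any SessionConfig / DrugEffect / BinningSpec
    field; artefacts (report JSON) are written under ``out_dir``.
    """
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if seed is None:
        seed = int(cfg.get("seed", 0))
    sp = SpeedProfile(**cfg.get("speed_profile", {}))
    session_cfg = SessionConfig(speed_profile=sp, **cfg.get("session", {}))
    effect = _effect_from_config(cfg.get("effect", "identity"))
    spec = BinningSpec(**cfg.get("binning", {}))
    log.info("pipeline: seed=%d effect=%s", seed, effect)
    report = analyze_paired_experiment(
        session_cfg, effect, seed,
        spec=spec,
        n_shuffles=int(cfg.get("n_shuffles", 1000)),
        tau_s=float(cfg.get("tau_s", 0.5)),
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        log.info("report written to %s", out_dir / "report.json")
    return report
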