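"""Simplified conductance-based CA1 microcircuit with M-current modulation.

The circuit follows the classic CA1 microcircuit cartoon: 130 pyramidal
cells (PYR) plus 19 interneurons -- 8 basket (BC), 2 axo-axonic (AAC), 2
bistratified (BIS), 2 oriens-lacunosum-moleculare (OLM), 1 VIP+/CCK+ and 4
VIP+/calretinin+ cells.  Afferents are CA3-like place-tuned Poisson inputs,
built by passing grid-like (multi-period, phase-shifted) spatial inputs
through a rectifying spatial filter, plus an 8 Hz septal (SEP) inhibitory
theta drive onto the interneurons; the entorhinal-to-CA1 pathway is
disabled (retrieval mode).  All cells are single-compartment
Hodgkin-Huxley-type neurons (fast Na, delayed-rectifier K, leak) carrying a
slow non-inactivating Kv7/M-type potassium current

    I_M = g_M * w * (V - E_K),   w' = (w_inf(V) - w)/tau_w(V),

with half-activation near -35 mV and a time constant of order 100 ms.
SST+ (OLM, BIS) and PV+ (BC, AAC) interneurons carry an M-conductance of
2 pS/um^2 (0.2 mS/cm^2); the muscarinic-blockade experiment scales the
pyramidal M-conductance by x5..x20 (and the interneuron one by a fitted
factor reproducing the observed population-rate reduction), then feeds the
pyramidal spike trains, binned at 30 Hz, to the same place-field /
information / stability pipeline as the imaging data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .session import LR, EventRaster, TrackSession

CLASSES = ("PYR", "BC", "AAC", "BIS", "OLM", "VIPCCK", "VIPCR")
POPULATION_SIZES = {"PYR": 130, "BC": 8, "AAC": 2, "BIS": 2, "OLM": 2, "VIPCCK": 1, "VIPCR": 4}
SST_CLASSES = ("OLM", "BIS")
PV_CLASSES = ("BC", "AAC")

#: class-level synaptic edges of the microcircuit schematic (source, target)
SCHEMATIC_EDGES = frozenset(
    [("CA3", "PYR"), ("CA3", "BC"), ("CA3", "AAC")]
    + [("PYR", c) for c in CLASSES if c != "PYR"]
    + [("BC", "PYR"), ("AAC", "PYR"), ("BIS", "PYR"), ("OLM", "PYR")]
    + [("VIPCR", "OLM"), ("VIPCR", "BIS"), ("VIPCCK", "BC")]
    + [("SEP", c) for c in CLASSES if c != "PYR"]
)

#: interneuron M-conductance multiplier fitted so the x5 pyramidal
#: condition reproduces the ~17% population-rate reduction observed
#: experimentally; applied in the treatment groups only
FITTED_INTERNEURON_SCALE = 3.0

E_K = -90.0
E_NA = 55.0
E_EXC = 0.0
E_INH = -75.0


@dataclass(frozen=True)
class InputSpec:
    """Afferent drive: grid inputs -> CA3 spatial filter, plus SEP theta."""

    n_grid: int = 50
    grid_periods_cm: tuple = (40.0, 60.0, 90.0)
    n_ca3: int = 130
    ca3_peak_hz: float = 45.0
    ca3_sigma_cm: float = 1.5
    ca3_bg_hz: float = 0.05
    sep_theta_hz: float = 8.0
    sep_g_ms_cm2: float = 0.02
    ec_to_ca1_enabled: bool = False   # retrieval mode: EC->CA1 deleted


@dataclass(frozen=True)
class NetworkSpec:
    """Population sizes, wiring strengths, conductances and the M-current
    scaling experiment's knobs.  Conductance densities in mS/cm^2 (1 mS/cm^2
    = 10 pS/um^2); synaptic weights are the conductance increment one
    presynaptic spike adds to the target, likewise as densities."""

    m_scale_pyr: float = 1.0
    m_scale_interneuron: float = 1.0
    g_m_pyr: float = 0.5              # baseline PYR M-conductance
    g_m_sst: float = 0.2              # 2 pS/um^2 on OLM/BIS
    g_m_pv: float = 0.2               # 2 pS/um^2 on BC/AAC
    # CA3 -> PYR topographic drive
    n_ca3_per_pyr: int = 4
    w_ca3_pyr: float = 0.30
    ca3_weight_cv: float = 1.0
    pyr_flat_fraction: float = 0.06   # PYR with spatially diffuse CA3 input
    # other afferent weights
    w_ca3_perisomatic: float = 0.8    # summed over the afferent population
    w_bg_pyr: float = 0.25            # sparse, strong non-spatial events
    bg_rate_hz: float = 0.15          # per-PYR background event rate
    # recurrent weights (class level)
    w_pyr_in: float = 0.02
    p_pyr_in: float = 0.5
    w_bc_pyr: float = 0.2
    w_aac_pyr: float = 0.2
    w_bis_pyr: float = 0.03
    w_olm_pyr: float = 0.03
    w_vip_in: float = 0.05
    p_in_pyr: float = 0.7
    # slow per-cell excitability fluctuation (OU current, uA/cm^2): models
    # state/neuromodulatory drift; near threshold it converts into
    # trial-to-trial place-field variability
    slow_noise_sd: float = 0.35
    slow_noise_tau_ms: float = 6000.0
    # membrane/integration
    dt_ms: float = 0.1
    tau_exc_ms: float = 3.0
    tau_inh_ms: float = 8.0
    inputs: InputSpec = field(default_factory=InputSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ValueError("dt must be positive")
        for name in ("g_m_pyr", "g_m_sst", "g_m_pv", "m_scale_pyr", "m_scale_interneuron"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# single-cell machinery (Wang-Buzsaki-style kinetics + Kv7/M current)


def m_current(V, w, g_M) -> float | np.ndarray:
    """M-current density (uA/cm^2): outward for V > E_K."""
    return g_M * w * (np.asarray(V) - E_K)


#: M-gate half-activation (mV) and slope (mV); the steep slope keeps resting
#: activation small so the current acts mainly as depolarisation-driven
#: adaptation rather than a tonic leak
M_HALF_MV = -35.0
M_SLOPE_MV = 7.0


def m_gate_steady_state(V):
    """w_inf: sigmoidal activation around -35 mV."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(V) - M_HALF_MV) / M_SLOPE_MV))


def m_gate_tau_ms(V):
    """tau_w: voltage-independent 100 ms (slow Kv7 gating)."""
    return np.full_like(np.asarray(V, dtype=float), 100.0)


def _rate_tables(phi: float, dt_ms: float, v_grid: np.ndarray):
    """Steady states and exponential-Euler update factors on a V grid."""
    v = v_grid
    am = 0.1 * (v + 35.0) / (1.0 - np.exp(-(v + 35.0) / 10.0))
    bm = 4.0 * np.exp(-(v + 60.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 58.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 28.0) / 10.0))
    an = 0.01 * (v + 34.0) / (1.0 - np.exp(-(v + 34.0) / 10.0))
    bn = 0.125 * np.exp(-(v + 44.0) / 80.0)
    m_inf = am / (am + bm)
    h_inf = ah / (ah + bh)
    n_inf = an / (an + bn)
    tau_h = 1.0 / (phi * (ah + bh))
    tau_n = 1.0 / (phi * (an + bn))
    w_inf = m_gate_steady_state(v)
    tau_w = m_gate_tau_ms(v)
    return (
        m_inf,
        h_inf,
        1.0 - np.exp(-dt_ms / tau_h),
        n_inf,
        1.0 - np.exp(-dt_ms / tau_n),
        w_inf,
        1.0 - np.exp(-dt_ms / tau_w),
    )


_V_LO, _V_HI, _V_STEP = -100.0, 50.0, 0.05
_V_GRID = np.arange(_V_LO, _V_HI + _V_STEP, _V_STEP)

#: per-class spike-rate scaling of the gating kinetics (fast-spiking PV+
#: classes fastest, pyramidal slowest)
CLASS_PHI = {"PYR": 1.0, "BC": 5.0, "AAC": 5.0, "BIS": 5.0, "OLM": 2.0, "VIPCCK": 3.0, "VIPCR": 3.0}
CLASS_G_NA = {c: 35.0 for c in CLASSES}
CLASS_G_K = {c: 9.0 for c in CLASSES}
CLASS_G_L = {c: 0.1 for c in CLASSES}
CLASS_E_L = {"PYR": -67.0, "BC": -65.0, "AAC": -65.0, "BIS": -65.0, "OLM": -60.0, "VIPCCK": -65.0, "VIPCR": -65.0}


@dataclass
class Network:
    """Wired network: cell parameter arrays plus weight matrices."""

    spec: NetworkSpec
    class_of_cell: np.ndarray          # int index into CLASSES
    g_m: np.ndarray                    # per-cell, scaling applied
    g_na: np.ndarray
    g_k: np.ndarray
    g_l: np.ndarray
    e_l: np.ndarray
    phi_class: np.ndarray
    w_exc: np.ndarray                  # n x n recurrent excitation
    w_inh: np.ndarray                  # n x n recurrent inhibition
    w_ca3: np.ndarray                  # n_ca3 x n afferent weights
    ca3_rate_table: np.ndarray         # n_ca3 x n_pos_bins (Hz)
    pyr_flat: np.ndarray               # bool per PYR: diffuse input
    sep_mask: np.ndarray               # cells receiving SEP theta drive

    @property
    def n_cells(self) -> int:
        return self.class_of_cell.size

    @property
    def pyr_ids(self) -> np.ndarray:
        return np.nonzero(self.class_of_cell == 0)[0]

    def edge_set(self) -> set:
        """Realised class-level edges (for checking against the schematic)."""
        edges = set()
        for mat, _ in ((self.w_exc, "exc"), (self.w_inh, "inh")):
            src, tgt = np.nonzero(mat.T)  # w[post, pre] convention below
            for s, t in zip(src, tgt):
                edges.add((CLASSES[self.class_of_cell[s]], CLASSES[self.class_of_cell[t]]))
        if np.any(self.w_ca3 > 0):
            for t in np.nonzero(self.w_ca3.sum(axis=0) > 0)[0]:
                edges.add(("CA3", CLASSES[self.class_of_cell[t]]))
        for t in np.nonzero(self.sep_mask)[0]:
            edges.add(("SEP", CLASSES[self.class_of_cell[t]]))
        return edges


def grid_rate_maps(inputs: InputSpec, track_length_cm: float, rng) -> np.ndarray:
    """Grid-like inputs: rectified cosines of 3 spatial periods, random
    phases; rows normalised to peak 1.  Shape (n_grid, n_pos_bins at 1 cm)."""
    x = np.arange(int(track_length_cm) + 1, dtype=float)
    periods = np.asarray(inputs.grid_periods_cm)
    per = periods[np.arange(inputs.n_grid) % periods.size]
    phase = rng.uniform(0, 2 * np.pi, size=inputs.n_grid)
    g = np.cos(2 * np.pi * x[None, :] / per[:, None] + phase[:, None])
    return np.maximum(g, 0.0)


def ca3_rate_maps(inputs: InputSpec, track_length_cm: float, rng) -> np.ndarray:
    """CA3-like place-tuned afferents from a rectifying spatial filter.

    Each CA3 cell's weights onto the grid population are the positive part
    of the grid cells' match to a Gaussian template at the CA3 cell's
    (tiled) preferred position; the weighted sum is threshold-rectified and
    rescaled to the requested peak rate.
    """
    grids = grid_rate_maps(inputs, track_length_cm, rng)
    x = np.arange(grids.shape[1], dtype=float)
    centres = (np.arange(inputs.n_ca3) + 0.5) * track_length_cm / inputs.n_ca3
    rates = np.empty((inputs.n_ca3, x.size))
    gm = grids - grids.mean(axis=1, keepdims=True)
    for j, c in enumerate(centres):
        template = np.exp(-((x - c) ** 2) / (2 * inputs.ca3_sigma_cm**2))
        w = np.maximum(gm @ (template - template.mean()), 0.0)
        prof = w @ grids
        prof -= np.percentile(prof, 60)
        prof = np.maximum(prof, 0.0)
        # the filter's output window: suppress distal secondary bumps the
        # grid interference pattern would otherwise leave
        prof *= np.exp(-((x - c) ** 2) / (2 * (3.0 * inputs.ca3_sigma_cm) ** 2))
        if prof.max() > 0:
            prof /= prof.max()
        rates[j] = inputs.ca3_peak_hz * prof + inputs.ca3_bg_hz
    return rates


def build_network(spec: NetworkSpec) -> Network:
    """Deterministic wiring under the spec's seed; class-level edges match
    the microcircuit schematic exactly."""
    rng = np.random.default_rng(spec.seed)
    sizes = [POPULATION_SIZES[c] for c in CLASSES]
    class_of_cell = np.repeat(np.arange(len(CLASSES)), sizes)
    n = class_of_cell.size
    idx_of = {c: np.nonzero(class_of_cell == i)[0] for i, c in enumerate(CLASSES)}

    g_m = np.zeros(n)
    g_m[idx_of["PYR"]] = spec.g_m_pyr * spec.m_scale_pyr
    for c in SST_CLASSES:
        g_m[idx_of[c]] = spec.g_m_sst * spec.m_scale_interneuron
    for c in PV_CLASSES:
        g_m[idx_of[c]] = spec.g_m_pv * spec.m_scale_interneuron

    g_na = np.array([CLASS_G_NA[CLASSES[k]] for k in class_of_cell])
    g_k = np.array([CLASS_G_K[CLASSES[k]] for k in class_of_cell])
    g_l = np.array([CLASS_G_L[CLASSES[k]] for k in class_of_cell])
    e_l = np.array([CLASS_E_L[CLASSES[k]] for k in class_of_cell])
    phi_class = np.array([CLASS_PHI[c] for c in CLASSES])

    w_exc = np.zeros((n, n))   # [post, pre]
    w_inh = np.zeros((n, n))
    pyr = idx_of["PYR"]
    interneurons = np.concatenate([idx_of[c] for c in CLASSES if c != "PYR"])
    # PYR -> every interneuron class
    for j in interneurons:
        mask = rng.random(pyr.size) < spec.p_pyr_in
        w_exc[j, pyr[mask]] = spec.w_pyr_in
    # perisomatic and dendritic inhibition onto PYR
    for cls, w in (("BC", spec.w_bc_pyr), ("AAC", spec.w_aac_pyr),
                   ("BIS", spec.w_bis_pyr), ("OLM", spec.w_olm_pyr)):
        for j in idx_of[cls]:
            mask = rng.random(pyr.size) < spec.p_in_pyr
            w_inh[pyr[mask], j] = w
    # VIP disinhibition
    for j in idx_of["VIPCR"]:
        for tgt in np.concatenate([idx_of["OLM"], idx_of["BIS"]]):
            w_inh[tgt, j] = spec.w_vip_in
    for j in idx_of["VIPCCK"]:
        for tgt in idx_of["BC"]:
            w_inh[tgt, j] = spec.w_vip_in

    # CA3 afferents: topographic onto PYR, diffuse onto perisomatic cells
    inputs = spec.inputs
    ca3_table = ca3_rate_maps(inputs, 160.0, rng)
    w_ca3 = np.zeros((inputs.n_ca3, n))
    n_flat = int(round(spec.pyr_flat_fraction * pyr.size))
    flat = np.zeros(pyr.size, dtype=bool)
    flat[rng.choice(pyr.size, size=n_flat, replace=False)] = True
    s2 = np.log(1 + spec.ca3_weight_cv**2)
    gain = rng.lognormal(-0.5 * s2, np.sqrt(s2), size=pyr.size)
    for i, p in enumerate(pyr):
        if flat[i]:
            # spatially diffuse input: same total weight spread over the
            # whole afferent population
            w_ca3[:, p] = spec.w_ca3_pyr * gain[i] / inputs.n_ca3
        else:
            c0 = int(round(i * inputs.n_ca3 / pyr.size))
            src = (c0 + np.arange(spec.n_ca3_per_pyr) - spec.n_ca3_per_pyr // 2) % inputs.n_ca3
            w_ca3[src, p] = spec.w_ca3_pyr * gain[i] / spec.n_ca3_per_pyr
    for cls in ("BC", "AAC"):
        for j in idx_of[cls]:
            # uniform diffuse CA3 drive onto perisomatic interneurons
            w_ca3[:, j] = spec.w_ca3_perisomatic / inputs.n_ca3
    sep_mask = np.zeros(n, dtype=bool)
    sep_mask[interneurons] = True
    return Network(
        spec=spec,
        class_of_cell=class_of_cell,
        g_m=g_m,
        g_na=g_na,
        g_k=g_k,
        g_l=g_l,
        e_l=e_l,
        phi_class=phi_class,
        w_exc=w_exc,
        w_inh=w_inh,
        w_ca3=w_ca3,
        ca3_rate_table=ca3_table,
        pyr_flat=flat,
        sep_mask=sep_mask,
    )


@njit(cache=True)
def _simulate_kernel(
    pos_bin,            # int32 per step: position index into ca3 table
    frame_of_step,      # int32 per step: 30 Hz raster frame
    class_of_cell,
    g_m, g_na, g_k, g_l, e_l,
    m_inf_t, h_inf_t, fh_t, n_inf_t, fn_t, w_inf_t, fw_t,   # (n_class, nv)
    w_exc, w_inh, w_ca3, ca3_p,        # ca3_p: spike prob per step per cell
    bg_p_pyr, w_bg, n_pyr,
    sep_mask, sep_g, sep_omega,
    slow_sd, slow_tau, n_slow_sub,
    dt, dec_e, dec_i,
    raster,             # (n_cells, n_frames) int32 output
    seed,
):
    np.random.seed(seed)
    n = class_of_cell.size
    n_steps = pos_bin.size
    V = np.full(n, -65.0) + 5.0 * np.random.random(n)
    h = np.full(n, 0.78)
    ng = np.full(n, 0.09)
    w = np.full(n, 0.05)
    ge = np.zeros(n)
    gi = np.zeros(n)
    slow = np.zeros(n)
    if slow_sd > 0.0:
        for j in range(n):
            slow[j] = slow_sd * np.random.normal()
    sub_dt = dt * n_slow_sub
    slow_a = 1.0 - sub_dt / slow_tau
    slow_b = slow_sd * np.sqrt(2.0 * sub_dt / slow_tau)
    last_spike = np.full(n, -1000.0)
    inv_step = 1.0 / _V_STEP
    for t in range(n_steps):
        # afferent CA3 spikes
        pb = pos_bin[t]
        for a in range(ca3_p.shape[0]):
            if np.random.random() < ca3_p[a, pb]:
                for j in range(n):
                    if w_ca3[a, j] > 0.0:
                        ge[j] += w_ca3[a, j]
        # background noise onto PYR
        for j in range(n_pyr):
            if np.random.random() < bg_p_pyr:
                ge[j] += w_bg
        if slow_sd > 0.0 and t % n_slow_sub == 0:
            for j in range(n):
                slow[j] = slow_a * slow[j] + slow_b * np.random.normal()
        sep = sep_g * 0.5 * (1.0 + np.sin(sep_omega * t))
        tms = t * dt
        for j in range(n):
            vi = (V[j] - _V_LO) * inv_step
            iv = int(vi)
            if iv < 0:
                iv = 0
            elif iv > m_inf_t.shape[1] - 2:
                iv = m_inf_t.shape[1] - 2
            k = class_of_cell[j]
            m = m_inf_t[k, iv]
            h[j] += (h_inf_t[k, iv] - h[j]) * fh_t[k, iv]
            ng[j] += (n_inf_t[k, iv] - ng[j]) * fn_t[k, iv]
            w[j] += (w_inf_t[k, iv] - w[j]) * fw_t[k, iv]
            gna = g_na[j] * m * m * m * h[j]
            gk = g_k[j] * ng[j] ** 4
            gm = g_m[j] * w[j]
            g_i_tot = gi[j] + (sep if sep_mask[j] else 0.0)
            gtot = g_l[j] + gna + gk + gm + ge[j] + g_i_tot
            vinf = (
                g_l[j] * e_l[j]
                + gna * E_NA
                + gk * E_K
                + gm * E_K
                + ge[j] * E_EXC
                + g_i_tot * E_INH
                + slow[j]
            ) / gtot
            vold = V[j]
            V[j] = vinf + (vold - vinf) * np.exp(-dt * gtot)
            if vold < 0.0 <= V[j] and tms - last_spike[j] > 2.0:
                last_spike[j] = tms
                raster[j, frame_of_step[t]] += 1
                # recurrent propagation (next-step effect)
                for p in range(n):
                    if w_exc[p, j] > 0.0:
                        ge[p] += w_exc[p, j]
                    if w_inh[p, j] > 0.0:
                        gi[p] += w_inh[p, j]
            ge[j] *= dec_e
            gi[j] *= dec_i
    return raster


def network_trajectory(
    n_trials: int = 12,
    speed_mean_cms: float = 18.0,
    speed_trial_sd_cms: float = 2.0,
    fps: float = 30.0,
    track_length_cm: float = 160.0,
    seed=0,
) -> TrackSession:
    """Repeated one-way traversals for the model experiment.

    The virtual animal sweeps the track left-to-right n_trials times
    (instantaneous return); the afferents depend only on position, so the
    analysed direction's statistics match a physical shuttle at half the
    simulation cost.
    """
    rng = np.random.default_rng(seed)
    xs, dirs, trials = [], [], []
    for trial in range(n_trials):
        v = max(10.0, speed_mean_cms + speed_trial_sd_cms * rng.standard_normal())
        n_frames = int(round(track_length_cm / v * fps))
        xs.append(np.linspace(0, track_length_cm, n_frames, endpoint=False))
        dirs.append(np.full(n_frames, LR, dtype=np.int8))
        trials.append(np.full(n_frames, trial, dtype=np.int32))
    return TrackSession(
        x_cm=np.concatenate(xs),
        fps=fps,
        track_length_cm=track_length_cm,
        direction=np.concatenate(dirs),
        trial_index=np.concatenate(trials),
    )


def simulate(network: Network, trajectory: TrackSession, seed=None) -> EventRaster:
    """Integrate the network along the trajectory; returns the PYR+IN spike
    raster binned at the trajectory's frame rate (use ``pyr_raster`` for
    the analysis-ready pyramidal rows)."""
    spec = network.spec
    if seed is None:
        seed = spec.seed
    dt = spec.dt_ms
    fps = trajectory.fps
    steps_per_frame = 1000.0 / fps / dt
    n_steps = int(round(trajectory.n_frames * steps_per_frame))
    step_idx = np.arange(n_steps)
    frame_of_step = np.minimum(
        (step_idx / steps_per_frame).astype(np.int32), trajectory.n_frames - 1
    )
    pos = trajectory.x_cm[frame_of_step]
    pos_bin = np.clip(pos.astype(np.int32), 0, network.ca3_rate_table.shape[1] - 1)

    tables = [
        np.stack(arrs)
        for arrs in zip(*[_rate_tables(phi, dt, _V_GRID) for phi in network.phi_class])
    ]
    m_inf_t, h_inf_t, fh_t, n_inf_t, fn_t, w_inf_t, fw_t = tables

    ca3_p = network.ca3_rate_table * dt / 1000.0
    inputs = spec.inputs
    raster = np.zeros((network.n_cells, trajectory.n_frames), dtype=np.int32)
    _simulate_kernel(
        pos_bin,
        frame_of_step,
        network.class_of_cell.astype(np.int64),
        network.g_m, network.g_na, network.g_k, network.g_l, network.e_l,
        m_inf_t, h_inf_t, fh_t, n_inf_t, fn_t, w_inf_t, fw_t,
        network.w_exc, network.w_inh, network.w_ca3, ca3_p,
        spec.bg_rate_hz * dt / 1000.0, spec.w_bg_pyr, POPULATION_SIZES["PYR"],
        network.sep_mask, inputs.sep_g_ms_cm2,
        2 * np.pi * inputs.sep_theta_hz * dt / 1000.0,
        spec.slow_noise_sd, spec.slow_noise_tau_ms, 10,
        dt, np.exp(-dt / spec.tau_exc_ms), np.exp(-dt / spec.tau_inh_ms),
        raster,
        int(seed) % (2**31),
    )
    if not np.all(np.isfinite(raster)):
        raise FloatingPointError("network integration diverged")
    return EventRaster(counts=raster, fps=fps)


def pyr_raster(network: Network, raster: EventRaster) -> EventRaster:
    return EventRaster(counts=raster.counts[network.pyr_ids], fps=raster.fps)


def simulate_condition(
    spec: NetworkSpec,
    seed: int,
    n_trials: int = 12,
) -> tuple[TrackSession, EventRaster]:
    """Wire, drive and integrate one condition; PYR raster returned."""
    wired = build_network(replace(spec, seed=seed))
    traj = network_trajectory(n_trials=n_trials, seed=seed + 10_000)
    raster = simulate(wired, traj, seed=seed + 20_000)
    return traj, pyr_raster(wired, raster)


def analyse_condition(
    session: TrackSession,
    raster: EventRaster,
    n_shuffles: int = 1000,
    seed: int = 0,
):
    """Place-cell %, mean place-cell SIC, DI and mean rate of one run."""
    from .info import score_direction
    from .maps import BinningSpec, compute_speed
    from .stability import odd_even_stability

    spec = BinningSpec()
    speed = compute_speed(session)
    res = score_direction(
        session, raster, spec, LR, n_shuffles=n_shuffles, seed=seed, speed=speed
    )
    pc = res.is_place_cell
    pvo = odd_even_stability(
        session, raster, spec, LR,
        neurons_subset=np.nonzero(pc)[0] if pc.any() else None,
        speed=speed,
    )
    return {
        "pct_place_cells": 100.0 * pc.mean(),
        "mean_sic_place_cells": float(res.sic_bits[pc].mean()) if pc.any() else 0.0,
        "diagonal_index": pvo.diagonal_index,
        "mean_rate_hz": raster.mean_rate_hz(),
    }


def run_mcurrent_experiment(
    base_spec: NetworkSpec | None = None,
    scales=(1, 5, 10, 15, 20),
    n_replicates: int = 5,
    seed: int = 0,
    n_trials: int = 12,
    n_shuffles: int = 1000,
):
    """The M-conductance scaling experiment: per-condition replicate
    metrics plus group means and SEM.

    Returns a pandas DataFrame with one row per (scale, replicate) and the
    four metrics; the non-control conditions also apply the fitted
    interneuron scale.
    """
    import pandas as pd

    if base_spec is None:
        base_spec = NetworkSpec()
    rows = []
    for scale in scales:
        ins = (
            base_spec.m_scale_interneuron
            if base_spec.m_scale_interneuron != 1.0
            else FITTED_INTERNEURON_SCALE
        )
        spec = replace(
            base_spec,
            m_scale_pyr=float(scale),
            m_scale_interneuron=ins if scale != 1 else 1.0,
        )
        for rep in range(n_replicates):
            run_seed = seed + 1000 * rep + int(scale)
            session, raster = simulate_condition(spec, run_seed, n_trials=n_trials)
            metrics = analyse_condition(
                session, raster, n_shuffles=n_shuffles, seed=run_seed
            )
            rows.append({"m_scale_pyr": scale, "replicate": rep, **metrics})
    return pd.DataFrame(rows)


def summarise_experiment(df) -> "pd.DataFrame":  # noqa: F821
    """Group means +/- SEM per condition, in scale order."""
    g = df.groupby("m_scale_pyr")[
        ["pct_place_cells", "mean_sic_place_cells", "diagonal_index", "mean_rate_hz"]
    ]
    out = g.mean()
    sem = g.sem()
    sem.columns = [f"{c}_sem" for c in sem.columns]
    return out.join(sem)
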