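"""Three-layer spiking decoder with local plasticity and self-backpropagation.

Architecture and training regime: 100 threshold-coded input neurons, 200
leaky integrate-and-fire hidden neurons (excitatory:inhibitory 1:1, Dale
sign constraint on their outgoing weights), and 1 (binary) or 4
(four-class) excitatory LIF output neurons.  Input->hidden and
hidden->output weights are initialised from a small-world rule over the
471-node spatial grid (local connections within a radius, 80 % positive,
plus sparse long-range links).  Training runs in batches: forward LIF
simulation with Tsodyks-Markram short-term plasticity, teacher-driven
STDP at the output synapses (potentiation paired with the teaching spike
train, depression with the realised output spikes), self-backpropagation
(SBP) mirroring the potentiating and depressing parts of those
adjustments onto the active hidden-layer synapses with separate
proportions, and homeostatic threshold adjustment.  The loss is
C = 1/2 * sum_k (u_k - o_k)^2 where u_k is the realised output rate
normalised by the teaching rate and o_k the expected output.

A rate-based two-layer reference network trained by exact gradient
descent on the same loss (the "RBM reference") is provided for gradient
checking and as the pure-backpropagation comparison point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from sbpsnn.encode import (NodeGrid, SpikeTensor, allocate_input_streams,
                           build_node_grid, project_spikes)
from sbpsnn.montage import Montage, standard_montage_62

# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LIFParams:
    tau_m: float = 0.02         # membrane time constant, s
    v_rest: float = 0.0
    v_reset: float = 0.0
    v_th: float = 1.0
    t_ref: float = 0.002        # refractory period, s
    r_m: float = 1.0            # membrane resistance

    def __post_init__(self) -> None:
        if self.v_th <= self.v_rest:
            raise ValueError("v_th must exceed v_rest")
        if self.tau_m <= 0 or self.t_ref < 0:
            raise ValueError("time constants must be positive")


@dataclass(frozen=True)
class STPParams:
    # facilitation-dominant regime: with small U the steady-state drive
    # stays nearly linear in presynaptic rate, preserving the rate code
    # the decoder reads out (depression-dominant settings normalise the
    # drive and erase rate differences between classes)
    U: float = 0.05             # utilisation increment per spike
    tau_f: float = 0.2          # facilitation decay, s
    tau_d: float = 0.3          # depression recovery, s

    def __post_init__(self) -> None:
        if not 0 < self.U <= 1:
            raise ValueError("U must lie in (0, 1]")
        if self.tau_f <= 0 or self.tau_d <= 0:
            raise ValueError("time constants must be positive")


@dataclass(frozen=True)
class STDPParams:
    a_plus: float = 0.01
    a_minus: float = 0.01
    tau_plus: float = 0.02      # s
    tau_minus: float = 0.02

    def __post_init__(self) -> None:
        if self.a_plus < 0 or self.a_minus < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("time constants must be positive")


@dataclass(frozen=True)
class SBPParams:
    rho_ltp: float = 0.9        # proportion of potentiation mirrored upstream
    rho_ltd: float = 0.6        # proportion of depression mirrored upstream

    def __post_init__(self) -> None:
        if not (0 <= self.rho_ltp <= 1 and 0 <= self.rho_ltd <= 1):
            raise ValueError("SBP proportions must lie in [0, 1]")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 20
    teaching_rate: float = 100.0    # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.teaching_rate <= 0:
            raise ValueError("training configuration values must be positive")


# ---------------------------------------------------------------------------
# elementary operations (unit-testable building blocks)
# ---------------------------------------------------------------------------


@dataclass
class LIFState:
    v: float = 0.0
    refrac: float = 0.0         # remaining refractory time, s


def lif_step(state: LIFState, input_current: float, p: LIFParams,
             dt: float) -> tuple[LIFState, bool]:
    """One forward-Euler step of dv/dt = (-(v - v_rest) + r_m I) / tau_m."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > p.tau_m / 10:
        warnings.warn("dt exceeds tau_m/10; integration will be coarse")
    if state.refrac > 0:
        return LIFState(state.v, max(0.0, state.refrac - dt)), False
    v = state.v + dt * (-(state.v - p.v_rest) + p.r_m * input_current) / p.tau_m
    if v >= p.v_th:
        return LIFState(p.v_reset, p.t_ref), True
    return LIFState(v, 0.0), False


@dataclass
class STPState:
    u: float = 0.0
    R: float = 1.0


def stp_update(state: STPState, pre_spike: bool, p: STPParams, dt: float,
               w: float = 1.0) -> tuple[STPState, float]:
    """Tsodyks-Markram short-term plasticity; returns (state, efficacy).

    Between spikes u decays to 0 (tau_f) and R recovers to 1 (tau_d); on a
    presynaptic spike u <- u + U(1-u), the efficacy u*R*w is released and
    R <- R(1-u).  Without a spike the efficacy is 0.
    """
    if not (0 <= state.u <= 1 and 0 <= state.R <= 1):
        raise ValueError("invalid STP state")
    u = state.u * np.exp(-dt / p.tau_f)
    R = 1.0 - (1.0 - state.R) * np.exp(-dt / p.tau_d)
    if not pre_spike:
        return STPState(u, R), 0.0
    u = u + p.U * (1.0 - u)
    efficacy = u * R * w
    R = R * (1.0 - u)
    return STPState(u, R), efficacy


def stdp_delta(delta_t: float, p: STDPParams) -> float:
    """Antisymmetric exponential STDP window; delta_t = t_post - t_pre (s)."""
    if not np.isfinite(delta_t):
        raise ValueError("delta_t must be finite")
    if delta_t > 0:
        return p.a_plus * float(np.exp(-delta_t / p.tau_plus))
    if delta_t < 0:
        return -p.a_minus * float(np.exp(delta_t / p.tau_minus))
    return 0.0


@dataclass
class HomeostasisState:
    v_th: float
    v_th_init: float


def homeostatic_adjust(state: HomeostasisState, observed_rate: float,
                       target_rate: float, gamma: float = 0.1) -> HomeostasisState:
    """Multiplicative threshold adjustment toward a target firing rate.

    v_th scales by (1 + gamma * (rate - target)/target), bounded to
    [0.5, 2] times the initial threshold.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    factor = 1.0 + gamma * (observed_rate - target_rate) / target_rate
    v_th = state.v_th * factor
    v_th = float(np.clip(v_th, 0.5 * state.v_th_init, 2.0 * state.v_th_init))
    return HomeostasisState(v_th, state.v_th_init)


def loss_mse(u, o) -> float:
    """C = 1/2 sum_k (u_k - o_k)^2."""
    u = np.asarray(u, dtype=float)
    o = np.asarray(o, dtype=float)
    if u.shape != o.shape:
        raise ValueError("realised and expected outputs must have equal length")
    return 0.5 * float(np.sum((u - o) ** 2))


def sbp_backpropagate(output_deltas: np.ndarray, active: np.ndarray,
                      p: SBPParams) -> np.ndarray:
    """Mirror output-synapse adjustments onto active hidden-layer synapses.

    ``output_deltas`` is the (n_hidden, n_out) batch adjustment of the
    hidden->output weights; ``active`` is a boolean (n_in, n_hidden) mask
    of synapses whose presynaptic input neuron spiked within the STDP
    window this batch.  For each hidden neuron the potentiating part of
    its outgoing deltas is mirrored with proportion rho_ltp, the
    depressing part with rho_ltd.
    """
    output_deltas = np.asarray(output_deltas, dtype=float)
    active = np.asarray(active)
    if output_deltas.ndim != 2 or active.ndim != 2 or \
            active.shape[1] != output_deltas.shape[0]:
        raise ValueError("shape mismatch between output deltas and active mask")
    pot = np.clip(output_deltas, 0.0, None).sum(axis=1)
    dep = np.clip(output_deltas, None, 0.0).sum(axis=1)
    mirrored = p.rho_ltp * pot + p.rho_ltd * dep
    return active.astype(float) * mirrored[None, :]


# ---------------------------------------------------------------------------
# RBM reference network (pure backpropagation)
# ---------------------------------------------------------------------------


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def rbm_forward(weights, x):
    """Two-layer rate network: h = sigma(x W1), u = sigma(h W2)."""
    w1, w2 = weights
    h = _sigmoid(x @ w1)
    u = _sigmoid(h @ w2)
    return h, u


def rbm_loss(weights, x, o) -> float:
    _, u = rbm_forward(weights, x)
    return 0.5 * float(np.sum((u - o) ** 2))


def rbm_bp_update(weights, batch, eta: float):
    """Exact-gradient weight deltas, -eta * dC/dW, via the chain rule."""
    x, o = batch
    w1, w2 = weights
    h, u = rbm_forward(weights, x)
    d_out = (u - o) * u * (1.0 - u)              # dC/d(pre-activation of u)
    d_hid = (d_out @ w2.T) * h * (1.0 - h)
    g2 = h.T @ d_out
    g1 = x.T @ d_hid
    return [-eta * g1, -eta * g2]


# ---------------------------------------------------------------------------
# small-world initialisation
# ---------------------------------------------------------------------------


def small_world_weights(pos_pre: np.ndarray, pos_post: np.ndarray, radius: float,
                        p_long: float, rng: np.random.Generator,
                        scale: float = 0.5, frac_positive: float = 0.8):
    """Distance-dependent random weights between two neuron populations.

    Pairs within ``radius`` are always connected with magnitude
    Uniform(0, scale] and sign positive with probability
    ``frac_positive``; pairs beyond the radius connect with probability
    ``p_long`` at half magnitude and balanced sign.  Returns
    (weights, mask, local_mask).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    d = np.linalg.norm(pos_pre[:, None, :] - pos_post[None, :, :], axis=2)
    local = d <= radius
    longr = (~local) & (rng.random(d.shape) < p_long)
    mask = local | longr
    if not mask.any():
        raise ValueError("radius and p_long yield zero connections")
    mag = scale * rng.random(d.shape)
    sign_local = np.where(rng.random(d.shape) < frac_positive, 1.0, -1.0)
    sign_long = np.where(rng.random(d.shape) < 0.5, 1.0, -1.0)
    w = np.zeros_like(d)
    w[local] = (mag * sign_local)[local]
    w[longr] = (0.5 * mag * sign_long)[longr]
    return w, mask, local


def init_small_world(grid: NodeGrid, radius: float = 30.0, p_long: float = 0.02,
                     n_inputs: int = 100, n_hidden: int = 200, n_out: int = 1,
                     input_streams=None, seed: int = 0):
    """Initial decoder weights from the spatial grid.

    Input neurons sit at their electrode's assigned node, hidden neurons
    at random grid nodes; input->hidden connectivity follows the
    small-world rule (local links within ``radius`` mm, 80 % positive,
    long-range links with probability ``p_long``).  Hidden->output
    weights are dense, small, and Dale-signed.  Returns
    (w_in, in_mask, local_mask, w_out, hidden_sign, hidden_pos).
    """
    rng = np.random.default_rng(seed)
    hid_idx = rng.integers(0, len(grid.nodes), size=n_hidden)
    hidden_pos = grid.nodes[hid_idx]
    if input_streams is None:
        pos_in = grid.nodes[rng.integers(0, len(grid.nodes), size=n_inputs)]
    else:
        pos_in = np.array([grid.nodes[grid.electrode_assignment[e]]
                           for e, _pol in input_streams])
    w_in, mask, local = small_world_weights(pos_in, hidden_pos, radius, p_long, rng)
    hidden_sign = np.ones(n_hidden)
    hidden_sign[n_hidden // 2:] = -1.0       # excitatory:inhibitory 1:1
    # readout weights start small so the learned structure, not the random
    # initialisation, dominates the trained readout
    w_out = 0.05 * rng.random((n_hidden, n_out)) * hidden_sign[:, None]
    return w_in, mask, local, w_out, hidden_sign, hidden_pos


# ---------------------------------------------------------------------------
# the decoder model (fit -> results)
# ---------------------------------------------------------------------------


@dataclass
class _NetParams:
    lif_hidden: LIFParams
    lif_out: LIFParams
    stp: STPParams
    stdp: STDPParams
    sbp: SBPParams
    eta: float
    w_decay: float
    homeo_target: float
    homeo_gamma: float
    w_clip: float
    syn_gain: float


class EmotionDecoder:
    """Spiking emotion decoder: model object built from spike data.

    Parameters
    ----------
    spike_tensors : list of SpikeTensor
        One tensor per trial.  When the tensors carry electrode ON/OFF
        streams and ``electrodes`` is given, the 100-neuron input layer
        is allocated round-robin over those electrode streams; tensors
        whose row count already equals ``n_inputs`` are used directly.
    labels : sequence
        Per-trial class labels.
    electrodes : optional sequence of electrode names used for input
        allocation and spatial initialisation.
    sbp_enabled : bool
        Disable to ablate self-backpropagation (pure local learning at
        the output synapses only).
    """

    def __init__(self, spike_tensors, labels, electrodes=None,
                 montage: Montage | None = None, grid: NodeGrid | None = None,
                 n_inputs: int = 100, n_hidden: int = 200,
                 lif: LIFParams = LIFParams(), lif_out: LIFParams | None = None,
                 stp: STPParams = STPParams(), stdp: STDPParams = STDPParams(),
                 sbp: SBPParams = SBPParams(), eta: float = 0.2,
                 radius: float = 30.0, p_long: float = 0.02,
                 homeo_target: float = 20.0, homeo_gamma: float = 0.05,
                 w_clip: float = 1.0, syn_gain: float | None = None,
                 w_decay: float = 0.02, sbp_eta_scale: float = 0.05,
                 sbp_gating: str = "error", sbp_enabled: bool = True):
        if len(spike_tensors) != len(labels):
            raise ValueError("one label per spike tensor required")
        if len(spike_tensors) == 0:
            raise ValueError("empty dataset")
        self.classes = tuple(sorted(set(labels)))
        if len(self.classes) < 2:
            raise ValueError("training requires at least two classes")
        if len(self.classes) == 2 and "neutral" in self.classes:
            # binary emotion-vs-neutral: the emotion is the positive class
            # (the teaching signal drives the class carrying the effect)
            other = next(c for c in self.classes if c != "neutral")
            self.classes = ("neutral", other)
        dts = {st.dt for st in spike_tensors}
        if len(dts) != 1:
            raise ValueError("spike tensors must share dt")
        self.dt = dts.pop()
        self.labels = list(labels)
        self.n_inputs = n_inputs
        self.n_hidden = n_hidden
        self.n_out = 1 if len(self.classes) == 2 else len(self.classes)
        self.sbp_enabled = sbp_enabled
        self.electrodes = tuple(electrodes) if electrodes is not None else None

        if self.electrodes is not None:
            self.input_streams = allocate_input_streams(self.electrodes, n_inputs)
            self.inputs = [project_spikes(st, self.input_streams) for st in spike_tensors]
        else:
            if spike_tensors[0].n_neurons != n_inputs:
                raise ValueError("raw spike tensors must already have n_inputs rows")
            self.input_streams = spike_tensors[0].neuron_map
            self.inputs = [st.spikes for st in spike_tensors]

        if montage is None:
            montage = standard_montage_62()
        self.montage = montage
        if grid is None:
            grid = build_node_grid(montage)
        self.grid = grid
        # synaptic gain normalises the first-spike STP efficacy (U*w) back
        # to a membrane kick of w, keeping weights and kicks on one scale
        if syn_gain is None:
            syn_gain = 1.0 / stp.U
        self.params = _NetParams(lif, lif_out or lif, stp, stdp, sbp, eta, w_decay,
                                 homeo_target, homeo_gamma, w_clip, syn_gain)
        self.sbp_eta_scale = sbp_eta_scale
        if sbp_gating not in ("error", "boolean"):
            raise ValueError("sbp_gating must be 'error' or 'boolean'")
        self.sbp_gating = sbp_gating
        self._radius = radius
        self._p_long = p_long

    # -- initialisation ----------------------------------------------------

    def _init_weights(self, seed: int):
        streams = self.input_streams if self.electrodes is not None else None
        return init_small_world(self.grid, self._radius, self._p_long,
                                self.n_inputs, self.n_hidden, self.n_out,
                                input_streams=streams, seed=seed)

    def _calibrate(self, spk_sample: np.ndarray, w_in: np.ndarray,
                   hidden_sign: np.ndarray, drive_target: float = 1.3,
                   out_drive_target: float = 1.5, w_mid: float = 0.05):
        """Activity-normalised calibration of synaptic scales.

        Encoded spike density varies widely between sampling rates and
        datasets, so fixed weight scales leave hidden neurons either
        silent or saturated.  Two quantities are calibrated on a data
        sample before training: (i) a per-hidden-neuron scale on the
        incoming weights that sets the steady-state membrane level under
        the sampled input statistics to ``drive_target`` times threshold
        (input-driven but unsaturated firing), and (ii) the output
        synaptic gain, set so that mid-range readout weights (``w_mid``)
        place the output neuron's steady-state level at
        ``out_drive_target`` times threshold — the learnable weight range
        then spans silence to strong firing.  Returns
        (per-neuron input scale, output gain).
        """
        p = self.params
        B, n_in, T = spk_sample.shape
        fdec = np.exp(-self.dt / p.stp.tau_f)
        ddec = np.exp(-self.dt / p.stp.tau_d)
        # pass 1: mean excitatory drive per hidden neuron
        u = np.zeros((B, n_in)); R = np.ones((B, n_in))
        w_pos = np.clip(w_in, 0.0, None)
        kick_sum = np.zeros(w_in.shape[1])
        for t in range(T):
            spk = spk_sample[:, :, t] > 0
            u *= fdec
            R = 1.0 - (1.0 - R) * ddec
            u = np.where(spk, u + p.stp.U * (1.0 - u), u)
            eff = np.where(spk, u * R, 0.0)
            R = np.where(spk, R * (1.0 - u), R)
            kick_sum += (p.syn_gain * (eff @ w_pos)).mean(axis=0)
        mean_kick = kick_sum / T
        decay_h = np.exp(-self.dt / p.lif_hidden.tau_m)
        target = drive_target * (p.lif_hidden.v_th - p.lif_hidden.v_rest) * (1.0 - decay_h)
        floor = max(1e-12, 1e-4 * mean_kick.max()) if mean_kick.max() > 0 else 1.0
        scale = target / np.maximum(mean_kick, floor)
        # pass 2: hidden firing under scaled weights -> output gain
        w_scaled = w_in * scale
        u = np.zeros((B, n_in)); R = np.ones((B, n_in))
        u_h = np.zeros((B, self.n_hidden)); R_h = np.ones((B, self.n_hidden))
        v_h = np.full((B, self.n_hidden), p.lif_hidden.v_rest)
        eff_mass = 0.0
        for t in range(T):
            spk = spk_sample[:, :, t] > 0
            u *= fdec
            R = 1.0 - (1.0 - R) * ddec
            u = np.where(spk, u + p.stp.U * (1.0 - u), u)
            eff = np.where(spk, u * R, 0.0)
            R = np.where(spk, R * (1.0 - u), R)
            v_h = p.lif_hidden.v_rest + (v_h - p.lif_hidden.v_rest) * decay_h \
                + p.syn_gain * (eff @ w_scaled)
            s_h = v_h >= p.lif_hidden.v_th
            v_h = np.where(s_h, p.lif_hidden.v_reset, v_h)
            u_h *= fdec
            R_h = 1.0 - (1.0 - R_h) * ddec
            u_h = np.where(s_h, u_h + p.stp.U * (1.0 - u_h), u_h)
            eff_h = np.where(s_h, u_h * R_h, 0.0)
            R_h = np.where(s_h, R_h * (1.0 - u_h), R_h)
            eff_mass += eff_h[:, hidden_sign > 0].sum(axis=1).mean()
        mean_eff_exc = eff_mass / T
        decay_o = np.exp(-self.dt / p.lif_out.tau_m)
        out_target = out_drive_target * (p.lif_out.v_th - p.lif_out.v_rest) * (1.0 - decay_o)
        if mean_eff_exc <= 1e-12:
            syn_gain_out = p.syn_gain
        else:
            syn_gain_out = float(out_target / (mean_eff_exc * w_mid))
        return scale, syn_gain_out

    # -- forward simulation ------------------------------------------------

    def _teacher_trains(self, label_idx: np.ndarray, n_steps: int,
                        teaching_rate: float) -> np.ndarray:
        """Regular teaching spike trains for the true class, silence elsewhere."""
        period = max(1, int(round(1.0 / (teaching_rate * self.dt))))
        teach = np.zeros((len(label_idx), self.n_out, n_steps), dtype=np.uint8)
        ticks = np.arange(period - 1, n_steps, period)
        for b, li in enumerate(label_idx):
            k = li if self.n_out > 1 else 0
            if self.n_out > 1 or li == 1:
                teach[b, k, ticks] = 1
        return teach

    def _simulate_batch(self, spk_in: np.ndarray, w_in: np.ndarray,
                        w_out: np.ndarray, v_th_hidden: np.ndarray,
                        teach: np.ndarray | None):
        """Clocked forward pass; returns spike counts and STDP accumulators.

        ``spk_in``: (B, n_in, T) binary.  Synapses act as instantaneous
        voltage kicks weighted by the STP efficacy.
        """
        p = self.params
        B, n_in, T = spk_in.shape
        dt = self.dt
        decay_h = np.exp(-dt / p.lif_hidden.tau_m)
        decay_o = np.exp(-dt / p.lif_out.tau_m)
        ref_steps_h = int(round(p.lif_hidden.t_ref / dt))
        ref_steps_o = int(round(p.lif_out.t_ref / dt))
        fdec = np.exp(-dt / p.stp.tau_f)
        ddec = np.exp(-dt / p.stp.tau_d)
        tdec_p = np.exp(-dt / p.stdp.tau_plus)
        tdec_m = np.exp(-dt / p.stdp.tau_minus)

        # input-synapse STP states (per presynaptic neuron)
        u_i = np.zeros((B, n_in)); R_i = np.ones((B, n_in))
        u_h = np.zeros((B, self.n_hidden)); R_h = np.ones((B, self.n_hidden))
        v_h = np.full((B, self.n_hidden), p.lif_hidden.v_rest)
        v_o = np.full((B, self.n_out), p.lif_out.v_rest)
        ref_h = np.zeros((B, self.n_hidden), dtype=int)
        ref_o = np.zeros((B, self.n_out), dtype=int)
        trace_p = np.zeros((B, self.n_hidden))
        trace_m = np.zeros((B, self.n_hidden))
        trace_mass_p = np.zeros((B, self.n_hidden))
        trace_mass_m = np.zeros((B, self.n_hidden))

        hid_counts = np.zeros((B, self.n_hidden))
        out_counts = np.zeros((B, self.n_out))
        in_any = np.zeros((B, n_in), dtype=bool)
        in_trace = np.zeros((B, n_in))
        in_trace_mass = np.zeros((B, n_in))
        dW_out = np.zeros((self.n_hidden, self.n_out))

        for t in range(T):
            s_in = spk_in[:, :, t].astype(float)
            in_any |= s_in > 0
            in_trace = in_trace * tdec_p + s_in
            # input STP
            u_i *= fdec
            R_i = 1.0 - (1.0 - R_i) * ddec
            spk = s_in > 0
            u_i = np.where(spk, u_i + p.stp.U * (1.0 - u_i), u_i)
            eff_in = np.where(spk, u_i * R_i, 0.0)
            R_i = np.where(spk, R_i * (1.0 - u_i), R_i)
            # hidden LIF
            kick_h = p.syn_gain * (eff_in @ w_in)
            v_h = p.lif_hidden.v_rest + (v_h - p.lif_hidden.v_rest) * decay_h
            ok = ref_h <= 0
            v_h = np.where(ok, v_h + kick_h, v_h)
            s_h = ok & (v_h >= v_th_hidden)
            v_h = np.where(s_h, p.lif_hidden.v_reset, v_h)
            ref_h = np.where(s_h, ref_steps_h, np.maximum(ref_h - 1, 0))
            hid_counts += s_h
            in_trace_mass += in_trace
            # hidden STP + output LIF
            u_h *= fdec
            R_h = 1.0 - (1.0 - R_h) * ddec
            u_h = np.where(s_h, u_h + p.stp.U * (1.0 - u_h), u_h)
            eff_h = np.where(s_h, u_h * R_h, 0.0)
            R_h = np.where(s_h, R_h * (1.0 - u_h), R_h)
            kick_o = getattr(self, "_syn_gain_out", p.syn_gain) * (eff_h @ w_out)
            v_o = p.lif_out.v_rest + (v_o - p.lif_out.v_rest) * decay_o
            ok_o = ref_o <= 0
            v_o = np.where(ok_o, v_o + kick_o, v_o)
            s_o = ok_o & (v_o >= p.lif_out.v_th)
            v_o = np.where(s_o, p.lif_out.v_reset, v_o)
            ref_o = np.where(s_o, ref_steps_o, np.maximum(ref_o - 1, 0))
            out_counts += s_o
            # STDP traces of hidden (presynaptic to output) spikes
            trace_p = trace_p * tdec_p + s_h
            trace_m = trace_m * tdec_m + s_h
            trace_mass_p += trace_p
            trace_mass_m += trace_m
        if teach is not None:
            # teacher-driven plasticity accumulated over the batch: the
            # potentiating part pairs the presynaptic trace mass with the
            # teaching spike count, the depressing part with the realised
            # output spike count (rate-coded STDP; the signed count error
            # is the per-trial teaching signal)
            err = teach.sum(axis=2).astype(float) - out_counts
            pot = p.stdp.a_plus * np.clip(err, 0.0, None)
            dep = p.stdp.a_minus * np.clip(err, None, 0.0)
            dW_out = ((trace_mass_p / T).T @ pot + (trace_mass_m / T).T @ dep) / B
        return hid_counts, out_counts, in_any, dW_out, in_trace_mass / T

    # -- training ----------------------------------------------------------

    def fit(self, cfg: TrainConfig | None = None, progress: bool = False) -> "DecoderFit":
        cfg = cfg or TrainConfig()
        p = self.params
        w_in, in_mask, local_mask, w_out, hidden_sign, hidden_pos = \
            self._init_weights(cfg.seed)
        v_th_hidden = np.full(self.n_hidden, p.lif_hidden.v_th)
        n_cal = min(8, len(self.inputs))
        T_all = max(arr.shape[1] for arr in self.inputs)
        cal = np.zeros((n_cal, self.n_inputs, T_all), dtype=np.uint8)
        for i in range(n_cal):
            cal[i, :, :self.inputs[i].shape[1]] = self.inputs[i]
        scale, syn_gain_out = self._calibrate(cal, w_in, hidden_sign)
        self._syn_gain_out = syn_gain_out
        w_in = w_in * scale
        # fan-out normalisation: every input neuron starts with the same
        # total outgoing weight mass, so any later divergence in electrode
        # weight mass is learned, not inherited from the random wiring
        row_mass = np.abs(w_in).sum(axis=1)
        ok_rows = row_mass > 0
        w_in[ok_rows] *= (row_mass[ok_rows].mean() / row_mass[ok_rows])[:, None]
        w_in_clip = max(p.w_clip, float(np.abs(w_in).max()))
        rng = np.random.default_rng(cfg.seed + 1)
        n = len(self.inputs)
        label_idx = np.array([self.classes.index(lbl) for lbl in self.labels])
        T = max(arr.shape[1] for arr in self.inputs)
        spk_all = np.zeros((n, self.n_inputs, T), dtype=np.uint8)
        for i, arr in enumerate(self.inputs):
            spk_all[i, :, :arr.shape[1]] = arr
        duration = T * self.dt

        history = []
        # tail-averaged (Polyak) weights over the final third of epochs
        # smooth out the residual equilibrium oscillation of the online rule
        avg_start = int(cfg.epochs * 2 / 3)
        avg = {"w_in": 0.0, "w_out": 0.0, "v_th": 0.0, "n": 0}
        for _epoch in range(cfg.epochs):
            # class-interleaved batch order keeps batch composition balanced
            by_class = [rng.permutation(np.flatnonzero(label_idx == c))
                        for c in range(len(self.classes))]
            order = []
            for i in range(max(len(b) for b in by_class)):
                for b in by_class:
                    if i < len(b):
                        order.append(b[i])
            perm = np.array(order)
            # annealed rates: large early steps find the readout direction,
            # small late steps let the equilibrium settle instead of cycling
            anneal = 1.0 / (1.0 + _epoch / max(10.0, cfg.epochs / 3.0))
            eta_e = p.eta * anneal
            gamma_e = p.homeo_gamma * anneal
            epoch_loss = 0.0
            correct = 0
            for start in range(0, n, cfg.batch_size):
                sel = perm[start:start + cfg.batch_size]
                spk = spk_all[sel]
                teach = self._teacher_trains(label_idx[sel], T, cfg.teaching_rate)
                hid_counts, out_counts, in_any, dW_out, in_mean = \
                    self._simulate_batch(spk, w_in, w_out, v_th_hidden, teach)
                # loss on realised vs expected normalised output rates
                u = np.clip(out_counts / (cfg.teaching_rate * duration), 0.0, None)
                o = np.zeros((len(sel), self.n_out))
                for b, li in enumerate(label_idx[sel]):
                    if self.n_out > 1:
                        o[b, li] = 1.0
                    else:
                        o[b, 0] = float(li == 1)
                epoch_loss += sum(loss_mse(u[b], o[b]) for b in range(len(sel)))
                correct += int((self._decide(out_counts, cfg.teaching_rate, duration)
                                == label_idx[sel]).sum())
                # output-synapse update
                # weight decay regularises the readout (p >> n regime)
                w_out = w_out + eta_e * (dW_out - p.w_decay * w_out)
                # self-backpropagation to the input synapses
                if self.sbp_enabled:
                    if self.sbp_gating == "boolean":
                        # active synapses: presynaptic neuron spiked within
                        # the STDP window this batch
                        active = (in_mask & in_any.any(axis=0)[:, None]).astype(float)
                    else:
                        # error-gated salience: per-trial pre/post pairing
                        # weighted by the teaching error, centred within
                        # each hidden neuron's afferents.  Centring removes
                        # the common gain component (which homeostatic
                        # threshold scaling would cancel anyway) and keeps
                        # the selectivity-reshaping part.
                        err_b = (teach.sum(axis=2) - out_counts).sum(axis=1)
                        denom = np.abs(err_b).mean() + 1e-12
                        hid_rate = hid_counts / max(spk.shape[2], 1)
                        sal = np.einsum("b,bi,bj->ij", err_b / denom,
                                        in_mean, hid_rate) / len(sel)
                        sal = sal * in_mask
                        col_n = np.maximum(in_mask.sum(axis=0), 1)
                        sal = sal - (sal.sum(axis=0) / col_n)[None, :]
                        active = sal * in_mask
                    dW_in = sbp_backpropagate(dW_out, active, p.sbp)
                    # normalise the mirrored step to a fixed fraction of the
                    # input-weight scale so SBP refines rather than rewrites
                    # the calibrated wiring
                    step_rms = np.sqrt((dW_in[in_mask] ** 2).mean())
                    w_rms = np.sqrt((w_in[in_mask] ** 2).mean())
                    if step_rms > 0:
                        dW_in = dW_in * (w_rms / step_rms)
                    w_in = np.clip(w_in + anneal * self.sbp_eta_scale * dW_in,
                                   -w_in_clip, w_in_clip)
                    w_in[~in_mask] = 0.0
                # Dale sign constraint and clipping after every update
                w_out = np.clip(w_out, -p.w_clip, p.w_clip)
                w_out[hidden_sign > 0] = np.clip(w_out[hidden_sign > 0], 0.0, None)
                w_out[hidden_sign < 0] = np.clip(w_out[hidden_sign < 0], None, 0.0)
                # homeostatic threshold adjustment
                rates = hid_counts.mean(axis=0) / duration
                factor = 1.0 + gamma_e * (rates - p.homeo_target) / p.homeo_target
                v_th_hidden = np.clip(v_th_hidden * factor,
                                      0.5 * p.lif_hidden.v_th, 2.0 * p.lif_hidden.v_th)
            if _epoch >= avg_start:
                avg["w_in"] = avg["w_in"] + w_in
                avg["w_out"] = avg["w_out"] + w_out
                avg["v_th"] = avg["v_th"] + v_th_hidden
                avg["n"] += 1
            history.append(epoch_loss / n)
            if progress:
                print(f"epoch {_epoch + 1}/{cfg.epochs}  C={history[-1]:.4f}")
        if avg["n"] > 0:
            w_in = avg["w_in"] / avg["n"]
            w_out = avg["w_out"] / avg["n"]
            v_th_hidden = avg["v_th"] / avg["n"]
        # calibrate the binary decision threshold on the realised training
        # counts (midpoint of class-mean counts); the nominal rule
        # 0.5 * teaching_rate * duration is the uncalibrated fallback
        threshold = 0.5 * cfg.teaching_rate * duration
        final_counts = np.zeros((n, self.n_out))
        for start in range(0, n, cfg.batch_size):
            sel = np.arange(start, min(start + cfg.batch_size, n))
            _, oc, _, _, _ = self._simulate_batch(spk_all[sel], w_in, w_out,
                                                  v_th_hidden, None)
            final_counts[sel] = oc
        if self.n_out == 1:
            pos = final_counts[label_idx == 1, 0]
            neg = final_counts[label_idx == 0, 0]
            if len(pos) and len(neg):
                threshold = 0.5 * (pos.mean() + neg.mean())
        preds = self._decide(final_counts, cfg.teaching_rate, duration, threshold)
        train_acc = float((preds == label_idx).mean() * 100.0)
        return DecoderFit(self, cfg, w_in, w_out, hidden_sign, v_th_hidden,
                          in_mask, local_mask, np.array(history), train_acc,
                          threshold)

    def _decide(self, out_counts: np.ndarray, teaching_rate: float,
                duration: float, threshold: float | None = None) -> np.ndarray:
        if self.n_out > 1:
            return np.argmax(out_counts, axis=1)
        if threshold is None:
            threshold = 0.5 * teaching_rate * duration
        return (out_counts[:, 0] >= threshold).astype(int)


class DecoderFit:
    """Trained decoder: weights, loss history and prediction interface."""

    def __init__(self, model: EmotionDecoder, cfg: TrainConfig, w_in, w_out,
                 hidden_sign, v_th_hidden, in_mask, local_mask,
                 loss_history, train_accuracy, decision_threshold=None):
        self.model = model
        self.cfg = cfg
        self.w_in = w_in
        self.w_out = w_out
        self.hidden_sign = hidden_sign
        self.v_th_hidden = v_th_hidden
        self.in_mask = in_mask
        self.local_mask = local_mask
        self.loss_history = loss_history
        self.train_accuracy = train_accuracy
        self.decision_threshold = decision_threshold

    def predict(self, spike_tensors) -> list:
        """Predicted class labels (arg-max output spike count; documented
        tie-break toward the lowest class index)."""
        m = self.model
        if m.electrodes is not None:
            arrs = [project_spikes(st, m.input_streams) for st in spike_tensors]
        else:
            arrs = [st.spikes for st in spike_tensors]
        T = max(a.shape[1] for a in arrs)
        spk = np.zeros((len(arrs), m.n_inputs, T), dtype=np.uint8)
        for i, a in enumerate(arrs):
            spk[i, :, :a.shape[1]] = a
        _, out_counts, _, _, _ = m._simulate_batch(spk, self.w_in, self.w_out,
                                                   self.v_th_hidden, None)
        idx = m._decide(out_counts, self.cfg.teaching_rate, T * m.dt,
                        self.decision_threshold)
        return [m.classes[i] for i in idx]

    def electrode_weight_mass(self) -> dict[str, float]:
        """Sum of |w_in| per electrode over its input neurons (unnormalised)."""
        mass: dict[str, float] = {}
        for i, (elec, _pol) in enumerate(self.model.input_streams):
            mass[elec] = mass.get(elec, 0.0) + float(np.abs(self.w_in[i]).sum())
        return mass

    def summary(self) -> str:
        m = self.model
        lines = [
            "Spiking emotion decoder (self-backpropagation SNN)",
            "=" * 52,
            f"classes:        {', '.join(m.classes)}",
            f"architecture:   {m.n_inputs} input / {m.n_hidden} hidden / {m.n_out} output",
            f"E:I hidden:     1:1 (Dale sign constraint on outgoing weights)",
            f"SBP:            {'on' if m.sbp_enabled else 'off'} "
            f"(rho_ltp={m.params.sbp.rho_ltp}, rho_ltd={m.params.sbp.rho_ltd})",
            f"epochs/batch:   {self.cfg.epochs} / {self.cfg.batch_size}",
            f"teaching rate:  {self.cfg.teaching_rate:.0f} Hz",
            f"final loss C:   {self.loss_history[-1]:.4f}",
            f"train accuracy: {self.train_accuracy:.2f} %",
        ]
        return "\n".join(lines)


def train(spike_tensors, labels, cfg: TrainConfig | None = None,
          **model_kwargs) -> tuple[DecoderFit, np.ndarray]:
    """Functional wrapper: build an :class:`EmotionDecoder` and fit it.

    Returns (fit, loss_history).
    """
    model = EmotionDecoder(spike_tensors, labels, **model_kwargs)
    fit = model.fit(cfg)
    return fit, fit.loss_history


def predict(fit: DecoderFit, spike_tensors) -> list:
    """Functional wrapper for :meth:`DecoderFit.predict`."""
    return fit.predict(spike_tensors)
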