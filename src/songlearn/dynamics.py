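"""Leaky-integrator circuit dynamics for one song rendition.

Three populations of equal size (Area X, LMAN, RA) are simulated as rate
units driven by the HVC clock:

.. math::

    \\tau \\dot{x}_t &= -x_t + M h_t + w_{XL} l_t \\\\
    l_t &= w_{LX} x_t + \\xi_t, \\qquad \\xi_t \\sim \\mathcal{N}(0, \\sigma_{LMAN}) \\\\
    \\tau \\dot{r}_t &= -r_t + W h_t + w_{LR} l_t \\\\
    \\hat{m}_t &= A r_t

``M`` (HVC -> Area X) and ``W`` (HVC -> RA) are the two trainable weight
matrices; ``A`` is a fixed linear readout onto the two motor channels
(amplitude, pitch).  LMAN injects Gaussian exploration noise and relays
Area X activity to RA through the thalamus, closing the loop that makes
weight transfer possible.

Integration is explicit Euler with step ``dt`` (default one song time
step).  Within a step, the LMAN state ``l_t`` is computed from the
*previous* Area X state plus fresh noise, then used in the Euler updates
of both ``x`` and ``r`` — a one-step synaptic delay in the X<->LMAN loop
that keeps the update explicit.  Because every equation is linear, each
population is a first-order linear recurrence and is integrated with
``scipy.signal.lfilter``; this is arithmetic-identical to the explicit
loop but runs the whole trial in a handful of vector operations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import lfilter

from .stimuli import HVCCode

__all__ = [
    "NetworkParams",
    "NetworkState",
    "TrialRecord",
    "DivergenceError",
    "init_state",
    "simulate_trial",
    "effective_code",
    "evaluate_song",
]


class DivergenceError(RuntimeError):
    """Raised when an activity variable becomes non-finite during a trial."""

    def __init__(self, population: str, step: int):
        self.population = population
        self.step = step
        super().__init__(
            f"non-finite {population} activity at time step {step}; "
            "the simulation has diverged (check weights / dt)"
        )


@dataclass(frozen=True)
class NetworkParams:
    """All scalar parameters of the circuit and its learning rules.

    Defaults are the values used for the square-pulse song experiments:
    160 HVC neurons, 200 neurons in each of RA/LMAN/Area X, an 80-step
    song, tau = 10 time steps, LMAN<->Area X loop gains w_XL = 0.3 and
    w_LX = 1, exploration noise of variance 0.01 (sigma_lman here is the
    standard deviation, 0.1), learning rates eta_RL = 1e-3 and
    eta_STDP = 1e-4, and weight-decay constants tau_M = 1e6, tau_W = 1e5
    iterations.  LMAN output synapses share one gain: the LMAN -> RA
    coupling w_LR defaults to the same 0.3 as the LMAN -> Area X limb,
    which is what makes consolidation complete on the 20,000-iteration
    protocol (see docs/methods.md).
    """

    n_hvc: int = 160
    n_ra: int = 200  # neurons per nucleus (RA, LMAN and Area X are equal-sized)
    n_steps: int = 80
    tau: float = 10.0
    w_xl: float = 0.3
    w_lx: float = 1.0
    w_lr: float = 0.3  # LMAN -> RA coupling; LMAN output synapses share one gain
    sigma_lman: float = 0.1
    eta_rl: float = 1e-3
    eta_stdp: float = 1e-4
    tau_m_decay: float = 1e6
    tau_w_decay: float = 1e5
    dt: float = 1.0
    hvc_decay_const: float = 20.0
    weight_init_scale: float = 1e-3
    baseline_alpha: float = 0.1
    reward_normalized: bool = False
    stdp_post: str = "x"        # postsynaptic term of the transfer rule: "x" or "ra"
    kernel_pre: str = "effective"  # solve the kernel on the "effective" or raw "code" clock
    eligibility_form: str = "noise"  # RL eligibility from the "noise" alone or full "lman" activity

    def __post_init__(self) -> None:
        if min(self.n_hvc, self.n_ra, self.n_steps) <= 0:
            raise ValueError("population sizes and n_steps must be positive")
        if not (self.tau > 0 and self.dt > 0):
            raise ValueError("tau and dt must be positive")
        if self.dt > self.tau:
            raise ValueError("explicit Euler needs dt <= tau for stability")
        if self.sigma_lman < 0 or self.eta_rl < 0 or self.eta_stdp < 0:
            raise ValueError("noise level and learning rates must be non-negative")
        if self.tau_m_decay <= 0 or self.tau_w_decay <= 0:
            raise ValueError("weight decay constants must be positive")
        for name in ("tau", "w_xl", "w_lx", "w_lr", "sigma_lman", "eta_rl",
                     "eta_stdp", "tau_m_decay", "tau_w_decay", "dt"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.stdp_post not in ("x", "ra"):
            raise ValueError("stdp_post must be 'x' or 'ra'")
        if self.kernel_pre not in ("effective", "code"):
            raise ValueError("kernel_pre must be 'effective' or 'code'")
        if self.eligibility_form not in ("noise", "lman"):
            raise ValueError("eligibility_form must be 'noise' or 'lman'")


@dataclass
class NetworkState:
    """Trainable weights plus the fixed readout and the running reward baseline."""

    m_weights: np.ndarray  # (n_ra, n_hvc)  HVC -> Area X
    w_weights: np.ndarray  # (n_ra, n_hvc)  HVC -> RA
    a_readout: np.ndarray  # (2, n_ra)      fixed RA -> motor readout
    reward_baseline: Optional[float] = None  # None until the first trial

    def copy(self) -> "NetworkState":
        return NetworkState(
            m_weights=self.m_weights.copy(),
            w_weights=self.w_weights.copy(),
            a_readout=self.a_readout.copy(),
            reward_baseline=self.reward_baseline,
        )


@dataclass
class TrialRecord:
    """Everything recorded during one rollout (one rendition of the song)."""

    x_activity: np.ndarray   # (n_ra, T) Area X
    l_activity: np.ndarray   # (n_ra, T) LMAN (feedback + noise, as realized)
    ra_activity: np.ndarray  # (n_ra, T) RA
    motor_out: np.ndarray    # (2, T)
    eligibility: np.ndarray  # (n_ra, n_hvc), sum over t of l_t h_t^T
    noise_eligibility: np.ndarray | None = None  # sum over t of xi_t h_t^T
    reward: Optional[float] = None


def init_state(params: NetworkParams, seed: int) -> NetworkState:
    """Random initial state.

    ``M`` and ``W`` start as small i.i.d. Gaussians (scale
    ``weight_init_scale``) so the initial song is near-silent; the readout
    ``A`` has i.i.d. N(0, 1/sqrt(n_ra)) entries, drawn once from a
    dedicated child seed and never modified afterwards.
    """
    ss = np.random.SeedSequence(seed)
    ss_a, ss_w = ss.spawn(2)
    rng_a = np.random.default_rng(ss_a)
    rng_w = np.random.default_rng(ss_w)
    a = rng_a.normal(0.0, 1.0 / np.sqrt(params.n_ra), size=(2, params.n_ra))
    m = rng_w.normal(0.0, params.weight_init_scale, size=(params.n_ra, params.n_hvc))
    w = rng_w.normal(0.0, params.weight_init_scale, size=(params.n_ra, params.n_hvc))
    return NetworkState(m_weights=m, w_weights=w, a_readout=a)


def _check_finite(name: str, arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        bad = np.where(~np.isfinite(arr).all(axis=0))[0]
        raise DivergenceError(name, int(bad[0]))


def simulate_trial(
    state: NetworkState,
    code: HVCCode,
    params: NetworkParams,
    noise_seed: int | np.random.Generator | None = None,
    lman_to_ra: bool = True,
    lman_noise: bool = True,
    x_to_lman: bool = True,
) -> TrialRecord:
    """Simulate one rendition of the song and return the full trial record.

    Parameters
    ----------
    noise_seed
        Seed (or Generator) for the LMAN exploration noise; trials with
        equal seeds and arguments are bit-identical.
    lman_to_ra
        If False, the LMAN term is dropped from the RA update (the
        configuration used to evaluate the crystallized song).
    lman_noise
        If False, no noise is injected (xi = 0).
    x_to_lman
        If False, the Area X -> thalamus -> LMAN limb is severed, so LMAN
        carries only its own noise.
    """
    H = code.matrix
    n_ra, T = params.n_ra, code.n_steps
    if H.shape[0] != params.n_hvc:
        raise ValueError(f"HVC code has {H.shape[0]} neurons, params expect {params.n_hvc}")
    if state.m_weights.shape != (n_ra, params.n_hvc) or state.w_weights.shape != (n_ra, params.n_hvc):
        raise ValueError("weight matrices inconsistent with params")
    if state.a_readout.shape != (2, n_ra):
        raise ValueError("readout matrix must be 2 x n_ra")

    a = params.dt / params.tau
    w_lx_eff = params.w_lx if x_to_lman else 0.0

    if lman_noise and params.sigma_lman > 0:
        rng = noise_seed if isinstance(noise_seed, np.random.Generator) \
            else np.random.default_rng(noise_seed)
        xi = rng.normal(0.0, params.sigma_lman, size=(n_ra, T))
    else:
        xi = np.zeros((n_ra, T))

    drive_x = state.m_weights @ H  # (n_ra, T)

    # x_t = pole_x * x_{t-1} + a*(M h_t + w_xl * xi_t); the feedback term
    # w_xl * w_lx * x_{t-1} is folded into the pole.
    pole_x = 1.0 - a + a * params.w_xl * w_lx_eff
    u_x = a * (drive_x + params.w_xl * xi)
    x = lfilter([1.0], [1.0, -pole_x], u_x, axis=1)
    _check_finite("Area X", x)

    x_prev = np.concatenate([np.zeros((n_ra, 1)), x[:, :-1]], axis=1)
    l = w_lx_eff * x_prev + xi
    _check_finite("LMAN", l)

    drive_r = state.w_weights @ H
    u_r = a * (drive_r + (params.w_lr * l if lman_to_ra else 0.0))
    r = lfilter([1.0], [1.0, -(1.0 - a)], u_r, axis=1)
    _check_finite("RA", r)

    motor = state.a_readout @ r
    eligibility = l @ H.T
    return TrialRecord(
        x_activity=x,
        l_activity=l,
        ra_activity=r,
        motor_out=motor,
        eligibility=eligibility,
        noise_eligibility=xi @ H.T,
    )


def effective_code(code: HVCCode, params: NetworkParams) -> HVCCode:
    """The HVC code as seen through the synaptic filter.

    Area X is a leaky integrator driven by ``M h_t`` and by its own
    activity returning through the LMAN loop, so its deterministic part
    is exactly ``M (H G)`` where ``G`` is the causal first-order lowpass
    of the Euler recurrence with gain ``dt/tau`` and pole
    ``1 - (dt/tau)(1 - w_xl w_lx)``.  ``H G`` is the *effective*
    presynaptic trace behind the Area X activity, and solving the
    transfer kernel on it (instead of on the raw clock) makes the
    consolidation update an exact copy of ``M`` even though the dynamics
    smear the clock in time.
    """
    a = params.dt / params.tau
    pole = 1.0 - a * (1.0 - params.w_xl * params.w_lx)
    filtered = lfilter([a], [1.0, -pole], code.matrix, axis=1)
    return HVCCode(
        matrix=filtered,
        onsets=code.onsets,
        decay_const=code.decay_const,
        form=code.form,
    )


def evaluate_song(state: NetworkState, code: HVCCode, params: NetworkParams) -> np.ndarray:
    """Produce the crystallized song: LMAN-to-RA input and noise removed.

    Returns the deterministic 2 x T motor trace driven purely by the
    HVC -> RA pathway (W).
    """
    trial = simulate_trial(
        state, code, params, noise_seed=0,
        lman_to_ra=False, lman_noise=False, x_to_lman=True,
    )
    return trial.motor_out
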