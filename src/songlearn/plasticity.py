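"""Reward, reinforcement learning, and STDP weight transfer.

Two learning rules act on the two HVC projections:

* **Node-perturbation RL** on the HVC -> Area X weights ``M``.  The
  eligibility trace ``e = sum_t l_t h_t^T`` pairs the (noisy) LMAN state
  with the presynaptic HVC state; multiplying it by the reward-prediction
  error ``R - Rbar`` yields an unbiased estimate of the policy gradient,

  .. math:: \\Delta M = \\eta_{RL} \\; e \\, (R - \\bar{R}) - \\tau_M^{-1} M .

* **STDP-kernel consolidation** of ``M`` into the HVC -> RA weights ``W``.
  A fixed temporal mixing kernel ``K`` (T x T) is chosen so that
  ``H K H^T`` is the identity (or, when HVC has more neurons than time
  steps, the orthogonal projector onto the column space of ``H``), which
  makes the unsupervised Hebbian update proportional to ``M`` itself:

  .. math:: \\Delta W = \\eta_{STDP} \\; (\\text{post} \\cdot K \\cdot H^T)
            - \\tau_W^{-1} W ,

  with ``post`` the postsynaptic activity matrix (RA by default; Area X
  for the idealized derivation in which
  ``post K H^T = M H K H^T = M``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .dynamics import NetworkParams, NetworkState, TrialRecord
from .stimuli import HVCCode, TemplateSong

__all__ = [
    "TransferKernel",
    "KernelMismatchError",
    "compute_reward",
    "rl_update",
    "compute_kernel",
    "identity_kernel",
    "stdp_update",
    "weight_correlation",
]

#: relative singular-value cutoff for the pseudoinverse in compute_kernel
PINV_RCOND = 1e-10


class KernelMismatchError(ValueError):
    """The kernel was computed from a different HVC code than the trial used."""


@dataclass
class TransferKernel:
    """The T x T temporal mixing kernel ``K`` for weight transfer.

    ``projector_residual`` is the Frobenius distance of ``H K H^T`` from
    the orthogonal projector onto the column space of ``H`` — zero up to
    round-off whenever ``H`` has full rank in time.
    """

    k_matrix: np.ndarray
    source_code_hash: str
    projector_residual: float
    _kht_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def kht(self, code: HVCCode) -> np.ndarray:
        """``K @ H^T`` for the source code, cached (it is reused every iteration)."""
        if self.source_code_hash != code.digest:
            raise KernelMismatchError(
                "transfer kernel was computed from a different HVC code"
            )
        if self._kht_cache is None:
            self._kht_cache = self.k_matrix @ code.matrix.T
        return self._kht_cache


def compute_reward(
    motor_out: np.ndarray,
    template: TemplateSong | np.ndarray,
    normalized: bool = False,
) -> float:
    """Reward of one rendition: ``R = 1 - sum |m - mhat|``.

    The error term sums the absolute difference over both channels and
    all time steps, so ``R = 1`` exactly when the output reproduces the
    template and decreases as the song deviates.  The default raw sum is
    the form the learning rates are calibrated against; pass
    ``normalized=True`` to divide the sum by ``2 T`` (the number of trace
    entries), which bounds the reward in ``[1 - max|error|, 1]``
    independent of song length and is the convenient scale for comparing
    songs of different durations.
    """
    target = template.traces if isinstance(template, TemplateSong) else np.asarray(template)
    motor_out = np.asarray(motor_out)
    if motor_out.shape != target.shape:
        raise ValueError(
            f"motor output shape {motor_out.shape} != template shape {target.shape}"
        )
    err = np.abs(target - motor_out).sum()
    if normalized:
        err /= target.size
    return float(1.0 - err)


def rl_update(
    state: NetworkState,
    trial: TrialRecord,
    params: NetworkParams,
    weights: Literal["m", "w"] = "m",
) -> NetworkState:
    """Apply the node-perturbation RL rule in place and return the state.

    Updates the HVC -> Area X weights with
    ``M += eta_RL * e * (R - Rbar) - M / tau_M`` and then advances the
    reward baseline as an exponential moving average
    ``Rbar <- (1 - alpha) Rbar + alpha R`` (initialized to the first
    trial's reward, so the very first update carries no gradient term).

    ``weights="w"`` applies the same rule to the HVC -> RA weights (with
    decay constant tau_W) — the single-pathway configuration of the
    classical direct-RL models used as the ablation baseline.
    """
    if trial.reward is None:
        raise ValueError("trial.reward must be set before the RL update")
    target = state.m_weights if weights == "m" else state.w_weights
    if params.eligibility_form == "noise" and trial.noise_eligibility is not None:
        eligibility = trial.noise_eligibility
    else:
        eligibility = trial.eligibility
    if eligibility.shape != target.shape:
        raise ValueError("eligibility trace shape does not match the weight matrix")
    tau_decay = params.tau_m_decay if weights == "m" else params.tau_w_decay
    baseline = trial.reward if state.reward_baseline is None else state.reward_baseline
    target += params.eta_rl * eligibility * (trial.reward - baseline)
    target -= target / tau_decay
    alpha = params.baseline_alpha
    state.reward_baseline = (1.0 - alpha) * baseline + alpha * trial.reward
    return state


def compute_kernel(code: HVCCode) -> TransferKernel:
    """Solve ``H K H^T = I`` (in the least-squares sense) for the kernel.

    ``K = H^+ (H^T)^+`` with Moore-Penrose pseudoinverses, so
    ``H K H^T = (H H^+) (H H^+)^T`` is the orthogonal projector onto the
    column space of ``H``: exactly the identity when ``H`` has full row
    rank with ``N <= T``, and a rank-``min(N, T)`` projector otherwise.
    The projector leaves ``W h_t = M h_t`` for every realizable HVC
    state, which is the functionally relevant equality.  A rank-deficient
    code triggers a warning and is reported through
    ``projector_residual``, not a hard failure.
    """
    H = code.matrix
    u, s, vt = np.linalg.svd(H, full_matrices=False)
    cutoff = PINV_RCOND * s.max() if s.size else 0.0
    rank = int(np.sum(s > cutoff))
    if rank < min(H.shape):
        warnings.warn(
            f"HVC code is rank deficient ({rank} < {min(H.shape)}); "
            "the transfer projector will not cover the full temporal space",
            RuntimeWarning,
            stacklevel=2,
        )
    inv_s = np.where(s > cutoff, 1.0 / np.where(s > cutoff, s, 1.0), 0.0)
    h_pinv = (vt.T * inv_s) @ u.T          # H^+  (T x N)
    k = h_pinv @ h_pinv.T                  # H^+ (H^T)^+ = H^+ (H^+)^T
    k = 0.5 * (k + k.T)                    # enforce exact symmetry
    projector = u[:, :rank] @ u[:, :rank].T
    residual = float(np.linalg.norm(H @ k @ H.T - projector))
    return TransferKernel(
        k_matrix=k, source_code_hash=code.digest, projector_residual=residual
    )


def identity_kernel(code: HVCCode) -> TransferKernel:
    """A do-nothing kernel (K = I) for the kernel-removal ablation."""
    H = code.matrix
    k = np.eye(code.n_steps)
    u, s, _ = np.linalg.svd(H, full_matrices=False)
    rank = int(np.sum(s > PINV_RCOND * s.max()))
    projector = u[:, :rank] @ u[:, :rank].T
    residual = float(np.linalg.norm(H @ k @ H.T - projector))
    return TransferKernel(
        k_matrix=k, source_code_hash=code.digest, projector_residual=residual
    )


def stdp_update(
    state: NetworkState,
    trial: TrialRecord,
    kernel: TransferKernel,
    code: HVCCode,
    params: NetworkParams,
    post: Literal["ra", "x"] = "ra",
) -> NetworkState:
    """Apply the reward-gated Hebbian consolidation rule in place.

    ``W += eta_STDP * (post @ K @ H^T) - W / tau_W`` where ``post`` is
    the postsynaptic activity of the trial: RA activity by default (the
    biological pathway, which receives the Area X signal through LMAN),
    or Area X activity for the idealized derivation in which the update
    collapses to a multiple of ``M``.  The rule is unsupervised — no
    reward term — which is what makes the consolidation pathway a pure
    Hebbian copy of whatever the RL pathway currently plays.
    """
    post_activity = trial.ra_activity if post == "ra" else trial.x_activity
    kht = kernel.kht(code)  # raises KernelMismatchError on a stale kernel
    state.w_weights += params.eta_stdp * (post_activity @ kht)
    state.w_weights -= state.w_weights / params.tau_w_decay
    return state


def weight_correlation(w_weights: np.ndarray, m_weights: np.ndarray) -> float:
    """Pearson correlation of the two flattened weight matrices.

    Tracks how completely the song stored in the HVC -> Area X weights has
    been transferred into the HVC -> RA weights (1 = perfect transfer up
    to a positive scale).
    """
    w = np.asarray(w_weights, dtype=float).ravel()
    m = np.asarray(m_weights, dtype=float).ravel()
    if w.shape != m.shape:
        raise ValueError("weight matrices must have the same shape")
    if np.ptp(w) == 0 or np.ptp(m) == 0:
        raise ValueError("correlation undefined for a constant weight matrix")
    return float(np.corrcoef(w, m)[0, 1])
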