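"""Training protocol: rollout -> reward -> RL update -> STDP transfer.

One *iteration* is one rendition of the song with exploration noise on,
followed by the two plasticity updates.  The transfer kernel is computed
once per run (the HVC code never changes).  The history records, per
iteration, the noisy-trial reward and the Pearson correlation between the
two trainable weight matrices; the *final song* is evaluated separately
with LMAN input to RA and noise removed, which is the quantity the
trained bird actually sings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Optional, Protocol, Sequence

import numpy as np

from .dynamics import (
    NetworkParams,
    NetworkState,
    effective_code,
    evaluate_song,
    init_state,
    simulate_trial,
)
from .plasticity import (
    compute_kernel,
    compute_reward,
    identity_kernel,
    rl_update,
    stdp_update,
    weight_correlation,
)
from .stimuli import HVCCode, TemplateSong

__all__ = ["TrainingHistory", "train", "replicate_runs"]


class ScheduleLike(Protocol):
    """Anything with a variant name and a cutoff iteration (see ablations)."""

    variant: str
    cutoff_iter: int
    no_kernel_mode: str


@dataclass
class TrainingHistory:
    """Per-iteration records plus the final (crystallized) state and song."""

    reward_per_iter: np.ndarray
    weight_corr_per_iter: np.ndarray
    final_state: NetworkState
    final_song: np.ndarray  # (2, T), noise-free evaluation
    final_reward: float     # reward of final_song against the template
    config_digest: str
    eval_iters: np.ndarray | None = None    # iterations at which the song was
    eval_rewards: np.ndarray | None = None  # evaluated noise-free mid-training

    @property
    def n_iters(self) -> int:
        return len(self.reward_per_iter)


def _config_digest(params: NetworkParams, n_iters: int, run_seed: int,
                   variant: str, cutoff_iter: int) -> str:
    payload = json.dumps(
        {
            "params": {k: getattr(params, k) for k in params.__dataclass_fields__},
            "n_iters": n_iters,
            "run_seed": run_seed,
            "variant": variant,
            "cutoff_iter": cutoff_iter,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def train(
    params: NetworkParams,
    code: HVCCode,
    template: TemplateSong,
    n_iters: int,
    run_seed: int,
    schedule: Optional[ScheduleLike] = None,
    state: Optional[NetworkState] = None,
    eval_every: int = 0,
) -> TrainingHistory:
    """Run the full two-pathway learning protocol.

    Deterministic in all arguments: the trial-noise stream for iteration
    ``i`` is seeded from ``(run_seed, i)``, and the initial weights and
    readout from ``run_seed`` alone.  ``schedule`` selects an ablation
    variant (see :mod:`songlearn.ablations`); ``None`` runs the full
    model.  ``eval_every > 0`` additionally evaluates the crystallized
    (noise-free) song every that many iterations — the learning curve of
    the song the bird would actually produce.
    """
    if n_iters <= 0:
        raise ValueError("n_iters must be positive")
    variant = schedule.variant if schedule is not None else "full"
    cutoff = int(getattr(schedule, "cutoff_iter", 0) or 0)
    no_kernel_mode = getattr(schedule, "no_kernel_mode", "identity")

    sim_params = params
    lman_to_ra = True
    if variant == "lman_silenced":
        # LMAN is silent: no noise and no output to either target.  Cutting
        # the X -> LMAN limb (w_lx = 0) with zero noise makes l identically 0.
        sim_params = NetworkParams(**{
            **{k: getattr(params, k) for k in params.__dataclass_fields__},
            "sigma_lman": 0.0, "w_lx": 0.0,
        })
        lman_to_ra = False

    # The kernel is solved once per run on the presynaptic trace the
    # consolidation synapses actually see: the raw clock H, or H passed
    # through the synaptic filter of the Area X integrator ("effective").
    kernel_code = (
        effective_code(code, sim_params) if params.kernel_pre == "effective" else code
    )
    if variant == "no_kernel":
        kernel = identity_kernel(kernel_code) if no_kernel_mode == "identity" else None
    else:
        kernel = compute_kernel(kernel_code)

    if state is None:
        state = init_state(params, run_seed)
    else:
        state = state.copy()

    rewards = np.empty(n_iters)
    corrs = np.empty(n_iters)
    eval_iters: list[int] = []
    eval_rewards: list[float] = []
    for i in range(n_iters):
        rng = np.random.default_rng([run_seed, i])
        rl_on = True
        x_to_lman = True
        if variant == "no_rl_in_x":
            rl_on = False
        elif variant == "rl_first_k_then_cut_x" and i >= cutoff:
            rl_on = False
            x_to_lman = False

        trial = simulate_trial(
            state, code, sim_params, noise_seed=rng,
            lman_to_ra=lman_to_ra, lman_noise=True, x_to_lman=x_to_lman,
        )
        trial.reward = compute_reward(
            trial.motor_out, template, normalized=params.reward_normalized
        )

        if variant == "baseline_direct_rl":
            # Single-pathway model: node-perturbation RL acts directly on the
            # HVC -> RA weights; no Area X learning, no kernel transfer.
            rl_update(state, trial, sim_params, weights="w")
        else:
            if rl_on:
                rl_update(state, trial, sim_params, weights="m")
            else:
                state.m_weights -= state.m_weights / params.tau_m_decay
                # the reward baseline keeps tracking even without RL
                alpha = params.baseline_alpha
                base = trial.reward if state.reward_baseline is None else state.reward_baseline
                state.reward_baseline = (1 - alpha) * base + alpha * trial.reward
            if kernel is not None:
                stdp_update(state, trial, kernel, kernel_code, sim_params,
                            post=params.stdp_post)
            else:  # no_kernel in "skip" mode: consolidation is absent entirely
                state.w_weights -= state.w_weights / params.tau_w_decay

        rewards[i] = trial.reward
        corrs[i] = weight_correlation(state.w_weights, state.m_weights)
        if eval_every and (i + 1) % eval_every == 0:
            song = evaluate_song(state, code, params)
            eval_iters.append(i + 1)
            eval_rewards.append(
                compute_reward(song, template, normalized=params.reward_normalized)
            )

    final_song = evaluate_song(state, code, params)
    final_reward = compute_reward(final_song, template, normalized=params.reward_normalized)
    return TrainingHistory(
        reward_per_iter=rewards,
        weight_corr_per_iter=corrs,
        final_state=state,
        final_song=final_song,
        final_reward=final_reward,
        config_digest=_config_digest(params, n_iters, run_seed, variant, cutoff),
        eval_iters=np.array(eval_iters) if eval_iters else None,
        eval_rewards=np.array(eval_rewards) if eval_rewards else None,
    )


def seeds_for_runs(base_seed: int, n_runs: int) -> list[int]:
    """Deterministic list of independent run seeds derived from one base seed."""
    return [int(s) for s in
            np.random.SeedSequence(base_seed).generate_state(n_runs) % (2**31)]


def replicate_runs(
    params: NetworkParams,
    code: HVCCode,
    template: TemplateSong,
    n_iters: int,
    seeds: Sequence[int] | int,
    n_runs: Optional[int] = None,
    schedule: Optional[ScheduleLike] = None,
) -> tuple[list[TrainingHistory], np.ndarray, np.ndarray]:
    """Train several replicates differing only in their run seed.

    ``seeds`` may be an explicit seed list or a single base seed together
    with ``n_runs``.  Returns the per-run histories plus the across-run
    mean reward and mean weight-correlation curves.
    """
    if isinstance(seeds, (int, np.integer)):
        if n_runs is None or n_runs < 1:
            raise ValueError("n_runs must be >= 1 when a single base seed is given")
        seeds = seeds_for_runs(int(seeds), n_runs)
    seeds = list(seeds)
    if not seeds:
        raise ValueError("need at least one run seed")
    histories = [
        train(params, code, template, n_iters, run_seed=s, schedule=schedule)
        for s in seeds
    ]
    mean_reward = np.mean([h.reward_per_iter for h in histories], axis=0)
    mean_corr = np.mean([h.weight_corr_per_iter for h in histories], axis=0)
    return histories, mean_reward, mean_corr
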