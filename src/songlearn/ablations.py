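"""Ablation battery: which pieces of the two-pathway model are necessary.

Each variant modifies one element of the architecture or protocol and is
trained over the same list of seeds as every other variant, so
cross-variant differences in the final (noise-free) reward reflect the
manipulation and not seed luck:

``full``
    The complete two-pathway model.
``baseline_direct_rl``
    The classical single-pathway model (Doya & Sejnowski; Fiete et al.):
    node-perturbation RL acts directly on the HVC -> RA weights, with no
    Area X learning and no kernel transfer.
``no_rl_in_x``
    RL in Area X disabled from the start (juvenile Area X inactivation).
``rl_first_k_then_cut_x``
    RL runs only for the first ``cutoff_iter`` iterations, after which the
    Area X -> thalamus -> LMAN connection is severed (crystallization):
    consolidation via STDP continues.
``no_kernel``
    The transfer kernel is replaced by the identity (or the STDP update is
    skipped entirely with ``no_kernel_mode="skip"``).
``lman_silenced``
    LMAN output is silenced throughout: no exploration noise and no relay
    of Area X activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
import numpy as np

from .dynamics import NetworkParams
from .stimuli import HVCCode, TemplateSong
from .training import TrainingHistory, train

__all__ = ["VARIANTS", "AblationSchedule", "AblationResult", "run_variant", "ablation_report"]

VARIANTS = (
    "full",
    "baseline_direct_rl",
    "no_rl_in_x",
    "rl_first_k_then_cut_x",
    "no_kernel",
    "lman_silenced",
)


@dataclass(frozen=True)
class AblationSchedule:
    """Which variant to run, and when RL is cut for the crystallization variant."""

    variant: str = "full"
    cutoff_iter: int = 0
    no_kernel_mode: str = "identity"  # or "skip"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.cutoff_iter < 0:
            raise ValueError("cutoff_iter must be non-negative")
        if self.no_kernel_mode not in ("identity", "skip"):
            raise ValueError("no_kernel_mode must be 'identity' or 'skip'")


@dataclass
class AblationResult:
    """Final noise-free rewards of one variant across seeds."""

    variant: str
    final_rewards: np.ndarray  # one entry per seed
    histories: Optional[list[TrainingHistory]] = field(default=None, repr=False)

    @property
    def mean_reward(self) -> float:
        return float(np.mean(self.final_rewards))

    @property
    def sem_reward(self) -> float:
        n = len(self.final_rewards)
        if n < 2:
            return 0.0
        return float(np.std(self.final_rewards, ddof=1) / np.sqrt(n))


def run_variant(
    schedule: AblationSchedule,
    params: NetworkParams,
    code: HVCCode,
    template: TemplateSong,
    n_iters: int,
    seeds: Sequence[int],
    keep_histories: bool = False,
) -> AblationResult:
    """Train one variant over a list of seeds and collect final rewards.

    The schedule's ``cutoff_iter`` must fall inside the run when the
    variant uses it.
    """
    if schedule.variant == "rl_first_k_then_cut_x" and not (0 < schedule.cutoff_iter < n_iters):
        raise ValueError(
            f"cutoff_iter must lie in (0, n_iters) for {schedule.variant}, "
            f"got {schedule.cutoff_iter} of {n_iters}"
        )
    histories = [
        train(params, code, template, n_iters, run_seed=s, schedule=schedule)
        for s in seeds
    ]
    return AblationResult(
        variant=schedule.variant,
        final_rewards=np.array([h.final_reward for h in histories]),
        histories=histories if keep_histories else None,
    )


def ablation_report(results: Sequence[AblationResult]) -> pd.DataFrame:
    """Summary table of an ablation battery, sorted by mean reward descending."""
    if not results:
        raise ValueError("need at least one ablation result")
    rows = [
        {
            "variant": r.variant,
            "n_seeds": len(r.final_rewards),
            "mean_reward": r.mean_reward,
            "sem_reward": r.sem_reward,
            "per_seed_rewards": ";".join(f"{x:.6g}" for x in r.final_rewards),
        }
        for r in results
    ]
    df = pd.DataFrame(rows).sort_values(
        ["mean_reward", "variant"], ascending=[False, True]
    )
    return df.reset_index(drop=True)
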