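"""Persistence of runs: config snapshots, history CSVs and array archives.

A run archive is a directory containing

``config.json``
    The exact :class:`~songlearn.config.RunConfig` used (re-runnable).
``history.csv``
    Columns ``iteration, reward, weight_corr``.  Runs longer than 5,000
    iterations are downsampled to every 10th iteration beyond that point
    to keep files small; the stored rows always include the first and
    last iteration.
``arrays.npz``
    ``m_weights``, ``w_weights``, ``kernel``, ``final_song``,
    ``a_readout`` and the ``template`` traces, keyed by name.
``log.txt``
    Plain-text milestones and final metrics.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .dynamics import effective_code
from .plasticity import compute_kernel, identity_kernel
from .stimuli import TemplateSong
from .training import TrainingHistory

__all__ = ["history_frame", "write_run", "read_run"]

#: above this many iterations, history rows thin out to every 10th iteration
DOWNSAMPLE_AFTER = 5000


def history_frame(history: TrainingHistory, downsample: bool = True) -> pd.DataFrame:
    """Per-iteration history as a DataFrame, optionally downsampled for disk."""
    n = history.n_iters
    idx = np.arange(n)
    if downsample and n > DOWNSAMPLE_AFTER:
        keep = (idx < DOWNSAMPLE_AFTER) | (idx % 10 == 0) | (idx == n - 1)
        idx = idx[keep]
    return pd.DataFrame(
        {
            "iteration": idx,
            "reward": history.reward_per_iter[idx],
            "weight_corr": history.weight_corr_per_iter[idx],
        }
    )


def write_run(
    out_dir: str | Path,
    config: RunConfig,
    history: TrainingHistory,
    template: TemplateSong,
) -> Path:
    """Write a self-describing run archive; returns the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    history_frame(history).to_csv(out / "history.csv", index=False)

    params = config.params()
    code = config.hvc_code()
    kernel_code = effective_code(code, params) if params.kernel_pre == "effective" else code
    kernel = (
        identity_kernel(kernel_code)
        if config.variant == "no_kernel" and config.no_kernel_mode == "identity"
        else compute_kernel(kernel_code)
    )
    np.savez_compressed(
        out / "arrays.npz",
        m_weights=history.final_state.m_weights,
        w_weights=history.final_state.w_weights,
        a_readout=history.final_state.a_readout,
        kernel=kernel.k_matrix,
        final_song=history.final_song,
        template=template.traces,
    )

    n = history.n_iters
    milestones = [0, n // 4, n // 2, 3 * n // 4, n - 1]
    lines = [
        f"run archive for config digest {history.config_digest}",
        f"iterations: {n}",
    ]
    for i in sorted(set(milestones)):
        lines.append(
            f"iter {i:>8d}: reward={history.reward_per_iter[i]:+.6f} "
            f"weight_corr={history.weight_corr_per_iter[i]:+.6f}"
        )
    lines.append(f"final noise-free reward: {history.final_reward:+.6f}")
    lines.append(f"final weight correlation: {history.weight_corr_per_iter[-1]:+.6f}")
    (out / "log.txt").write_text("\n".join(lines) + "\n")
    return out


def read_run(run_dir: str | Path) -> tuple[RunConfig, pd.DataFrame, dict[str, np.ndarray]]:
    """Load a run archive back: (config, history frame, named arrays)."""
    run = Path(run_dir)
    config = RunConfig.from_json(run / "config.json")
    hist = pd.read_csv(run / "history.csv")
    with np.load(run / "arrays.npz") as npz:
        arrays = {k: npz[k] for k in npz.files}
    return config, hist, arrays
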