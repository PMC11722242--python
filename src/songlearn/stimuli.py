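"""HVC timing code and template songs.

HVC acts as the clock of the song system: each premotor neuron fires a
transient burst at a fixed time in the motif, so the population activity
over one rendition is an ``N x T`` matrix ``H`` whose column ``t`` is the
HVC state at time step ``t``.  Every experiment in this package is driven
by such a code together with a two-channel (amplitude, pitch) template
song that the network is rewarded for reproducing.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

__all__ = [
    "HVCCode",
    "TemplateSong",
    "make_hvc_code",
    "make_template_song",
    "load_template_csv",
    "save_template_csv",
]

HvcForm = Literal["transient", "as-printed"]

#: default e-folding time (in time steps) of the burst of a single HVC neuron
DEFAULT_DECAY_CONST = 20.0


@dataclass(frozen=True)
class HVCCode:
    """The premotor timing code ``H``.

    Attributes
    ----------
    matrix
        ``(n_neurons, n_steps)`` array; entry ``(i, j)`` is the rate of
        neuron ``i`` at time step ``j``.  Entries lie in ``[0, 1]``.
    onsets
        Onset time step of each neuron (the column at which its row first
        becomes non-zero).  Non-decreasing, and covering every time step.
    decay_const
        e-folding constant of the within-burst decay, in time steps.
    form
        ``"transient"`` (each neuron peaks at its onset and decays in
        time) or ``"as-printed"`` (each neuron holds a constant plateau
        whose amplitude decays with neuron index).
    """

    matrix: np.ndarray
    onsets: np.ndarray
    decay_const: float
    form: str = "transient"

    @property
    def n_neurons(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_steps(self) -> int:
        return self.matrix.shape[1]

    def onset_of(self, neuron: int) -> int:
        return int(self.onsets[neuron])

    @property
    def digest(self) -> str:
        """SHA-256 digest of shape and contents; used to pin kernels to codes."""
        h = hashlib.sha256()
        h.update(repr(self.matrix.shape).encode())
        h.update(np.ascontiguousarray(self.matrix).tobytes())
        return h.hexdigest()


@dataclass(frozen=True)
class TemplateSong:
    """A 2-channel target motor trace (channel 0 amplitude, channel 1 pitch)."""

    traces: np.ndarray  # (2, n_steps)
    kind: str = "square_pulse"

    @property
    def n_steps(self) -> int:
        return self.traces.shape[1]

    def __post_init__(self) -> None:
        t = np.asarray(self.traces, dtype=float)
        if t.ndim != 2 or t.shape[0] != 2:
            raise ValueError(f"template traces must be 2 x T, got shape {t.shape}")
        if not np.all(np.isfinite(t)):
            raise ValueError("template traces must be finite")
        object.__setattr__(self, "traces", t)


def _assign_onsets(n_neurons: int, n_steps: int) -> np.ndarray:
    # i * T // N spreads N onsets evenly over T steps: each step receives
    # either floor(N/T) or ceil(N/T) neurons and onsets are sorted.
    return np.arange(n_neurons) * n_steps // n_neurons


def make_hvc_code(
    n_neurons: int,
    n_steps: int,
    decay_const: float = DEFAULT_DECAY_CONST,
    form: HvcForm = "transient",
) -> HVCCode:
    """Build the HVC timing-code matrix.

    In the default ``"transient"`` form neuron ``i`` is silent before its
    onset step and then decays exponentially,

    .. math:: h_{ij} = e^{-(j - o_i)/\\tau_h} \\quad (j \\ge o_i),

    with onsets :math:`o_i` assigned evenly so that every time step is the
    onset of either ``floor(N/T)`` or ``ceil(N/T)`` neurons.  The
    ``"as-printed"`` form instead gives neuron ``i`` a constant plateau of
    amplitude :math:`e^{-i/\\tau_h}` from its onset onward.

    Parameters
    ----------
    n_neurons
        Number of HVC neurons ``N``; must be at least ``n_steps``.
    n_steps
        Number of time steps ``T`` in the song.
    decay_const
        Burst decay constant in time steps (default 20).
    form
        Which functional form to use for each neuron's burst.
    """
    if n_neurons <= 0 or n_steps <= 0:
        raise ValueError("n_neurons and n_steps must be positive")
    if n_neurons < n_steps:
        raise ValueError(
            f"need n_neurons >= n_steps so onsets can cover every step "
            f"(got N={n_neurons}, T={n_steps})"
        )
    if decay_const <= 0:
        raise ValueError("decay_const must be positive")
    if form not in ("transient", "as-printed"):
        raise ValueError(f"unknown HVC form {form!r}")

    onsets = _assign_onsets(n_neurons, n_steps)
    j = np.arange(n_steps)[None, :]
    o = onsets[:, None]
    active = j >= o
    if form == "transient":
        matrix = np.where(active, np.exp(-(j - o) / decay_const), 0.0)
    else:
        amp = np.exp(-np.arange(n_neurons) / decay_const)[:, None]
        matrix = np.where(active, amp, 0.0)
    return HVCCode(matrix=matrix, onsets=onsets, decay_const=float(decay_const), form=form)


def make_template_song(
    n_steps: int,
    kind: str = "square_pulse",
    rng_seed: int = 0,
) -> TemplateSong:
    """Draw a square-pulse template song.

    Each of the two channels is piecewise constant with 2-4 segments and
    levels drawn uniformly in [0.2, 0.8] (kept away from 0 and 1 so the
    reward is neither trivially high nor saturating).  Deterministic for a
    fixed seed.
    """
    if n_steps < 4:
        raise ValueError("n_steps must be at least 4")
    if kind != "square_pulse":
        raise ValueError(
            f"kind must be 'square_pulse' (custom songs load via load_template_csv), got {kind!r}"
        )
    rng = np.random.default_rng(rng_seed)
    traces = np.empty((2, n_steps))
    for ch in range(2):
        n_seg = int(rng.integers(2, 5))
        cuts = np.sort(rng.choice(np.arange(1, n_steps), size=n_seg - 1, replace=False))
        levels = rng.uniform(0.2, 0.8, size=n_seg)
        bounds = np.concatenate(([0], cuts, [n_steps]))
        for s in range(n_seg):
            traces[ch, bounds[s] : bounds[s + 1]] = levels[s]
    return TemplateSong(traces=traces, kind="square_pulse")


def load_template_csv(path: str | Path, normalize: bool = True) -> TemplateSong:
    """Load a custom 2 x T template from CSV (2 rows, comma-separated, no header).

    With ``normalize`` each channel is rescaled to span [0, 1]; channels
    with zero range are left unchanged.
    """
    arr = np.atleast_2d(np.loadtxt(path, delimiter=",", dtype=float))
    if arr.shape[0] != 2:
        raise ValueError(
            f"custom template CSV must have exactly 2 rows (amplitude, pitch), got {arr.shape[0]}"
        )
    if normalize:
        arr = arr.copy()
        for ch in range(2):
            lo, hi = arr[ch].min(), arr[ch].max()
            if hi > lo:
                arr[ch] = (arr[ch] - lo) / (hi - lo)
    return TemplateSong(traces=arr, kind="custom")


def save_template_csv(song: TemplateSong, path: str | Path) -> None:
    """Write a template song as a 2-row CSV (decimal point, comma separator)."""
    np.savetxt(path, song.traces, delimiter=",", fmt="%.17g")
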