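"""Run configuration: a flat, losslessly serializable record of one experiment.

A :class:`RunConfig` pins down everything needed to reproduce a run —
network sizes, circuit constants, learning rates, the song, the ablation
variant and the seed — and builds the concrete objects (params, HVC code,
template, schedule) the training loop consumes.  Named presets encode the
two reference protocols plus small analogues that finish in seconds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .ablations import AblationSchedule
from .dynamics import NetworkParams
from .stimuli import HVCCode, TemplateSong, load_template_csv, make_hvc_code, make_template_song

__all__ = ["RunConfig", "PRESETS", "preset"]


@dataclass(frozen=True)
class RunConfig:
    """Flat key-value description of one training or ablation run."""

    # circuit / learning-rule parameters (see NetworkParams)
    n_hvc: int = 160
    n_ra: int = 200
    n_steps: int = 80
    tau: float = 10.0
    w_xl: float = 0.3
    w_lx: float = 1.0
    w_lr: float = 0.3
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
    stdp_post: str = "x"
    kernel_pre: str = "effective"
    eligibility_form: str = "noise"
    # protocol
    n_iters: int = 20000
    run_seed: int = 0
    # stimuli
    hvc_form: str = "transient"
    song_kind: str = "square_pulse"
    song_csv: Optional[str] = None
    song_seed: int = 0
    normalize_song: bool = True
    # ablation
    variant: str = "full"
    cutoff_iter: int = 0
    no_kernel_mode: str = "identity"

    _PARAM_KEYS = (
        "n_hvc", "n_ra", "n_steps", "tau", "w_xl", "w_lx", "w_lr", "sigma_lman",
        "eta_rl", "eta_stdp", "tau_m_decay", "tau_w_decay", "dt",
        "hvc_decay_const", "weight_init_scale", "baseline_alpha",
        "reward_normalized", "stdp_post", "kernel_pre", "eligibility_form",
    )

    # -- construction of the concrete run objects ------------------------
    def params(self) -> NetworkParams:
        return NetworkParams(**{k: getattr(self, k) for k in self._PARAM_KEYS})

    def hvc_code(self) -> HVCCode:
        return make_hvc_code(
            self.n_hvc, self.n_steps, self.hvc_decay_const, form=self.hvc_form
        )

    def template(self) -> TemplateSong:
        if self.song_kind == "custom":
            if not self.song_csv:
                raise ValueError("song_kind='custom' requires song_csv")
            song = load_template_csv(self.song_csv, normalize=self.normalize_song)
            if song.n_steps != self.n_steps:
                raise ValueError(
                    f"custom song has {song.n_steps} steps, config expects {self.n_steps}"
                )
            return song
        return make_template_song(self.n_steps, self.song_kind, rng_seed=self.song_seed)

    def schedule(self) -> AblationSchedule:
        return AblationSchedule(
            variant=self.variant,
            cutoff_iter=self.cutoff_iter,
            no_kernel_mode=self.no_kernel_mode,
        )

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def replace(self, **changes) -> "RunConfig":
        return dataclasses.replace(self, **changes)


def _base() -> RunConfig:
    return RunConfig()  # the defaults are the 160/200/80 square-pulse protocol


#: named parameter sets: the two reference protocols and fast small analogues
PRESETS: dict[str, RunConfig] = {
    "square-song": _base(),
    "control-traces": _base().replace(
        n_hvc=2200, n_ra=300, n_steps=1100, eta_stdp=1e-3,
    ),
    # The small analogues shorten the protocol 4x; eta_STDP scales up by the
    # same factor so the consolidation time constant (~ w_lr / eta_STDP
    # iterations, independent of network size) keeps its ratio to the
    # protocol length.
    "square-song-small": _base().replace(
        n_hvc=40, n_ra=50, n_steps=20, n_iters=5000, eta_stdp=4e-4,
    ),
    "ablation-small": _base().replace(
        n_hvc=40, n_ra=50, n_steps=20, n_iters=5000, eta_stdp=4e-4,
        cutoff_iter=1250,
    ),
    "smoke": _base().replace(
        n_hvc=20, n_ra=20, n_steps=10, n_iters=200,
    ),
}


def preset(name: str) -> RunConfig:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
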