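# songlearn

A rate-network model of birdsong acquisition in which a song is first
**learned by reinforcement** in the basal-ganglia pathway and then
**consolidated by Hebbian plasticity** into the motor pathway.

Juvenile songbirds learn their song by trial and error: premotor nucleus
HVC provides a stereotyped clock, LMAN injects exploration noise, and
dopaminergic reward signals reach Area X, the song system's basal
ganglia. Yet the adult song is produced by the direct HVC→RA projection,
which raises the question this model answers mechanistically: *how does
a song acquired in the learning pathway end up stored in the production
pathway?*

The package is for computational neuroscientists studying sensorimotor
learning and memory consolidation: it simulates the full circuit,
trains it, runs the lesion/ablation battery, and exposes every piece
(clock, dynamics, plasticity rules, kernel) as a library.

## Model

Four populations (HVC clock `H ∈ R^{N×T}`; Area X, LMAN, RA of equal
size `M`) with leaky-integrator dynamics, time constant τ = 10 steps:

    τ ẋ_t = −x_t + M h_t + w_XL l_t          (Area X)
      l_t = w_LX x_t + ξ_t,  ξ ~ N(0, σ²)    (LMAN)
    τ ṙ_t = −r_t + W h_t + w_LR l_t          (RA)
      m̂_t = A r_t                            (motor: amplitude, pitch)

Each rendition is scored against a 2×T template, `R = 1 − Σ|m − m̂|`,
and two plasticity rules run side by side:

* **node-perturbation RL** on the HVC→Area X weights
  `ΔM = η_RL · (Σ_t ξ_t h_tᵀ) · (R − R̄) − M/τ_M`, and
* **unsupervised STDP-kernel consolidation** of the HVC→RA weights
  `ΔW = η_STDP · X · K · H_eᵀ − W/τ_W`, where the fixed temporal kernel
  `K` solves `H_e K H_eᵀ = I` on the synaptically filtered clock `H_e`,
  making the update an exact copy of `M` — the weight-transfer
  mechanism at the heart of the model.

After training, the song is evaluated **noise-free with LMAN input to
RA removed**: what remains is only what was consolidated into `W`.
See `docs/methods.md` for parameter conventions, the consolidation
timescale, and design decisions.

## Worked example

```python
from songlearn import preset, train, compute_reward, weight_correlation

cfg = preset("square-song-small")          # 40 HVC, 50 per nucleus, T=20, 5000 iters
history = train(cfg.params(), cfg.hvc_code(), cfg.template(),
                cfg.n_iters, run_seed=0)

reward = compute_reward(history.final_song, cfg.template(), normalized=True)
corr = weight_correlation(history.final_state.w_weights,
                          history.final_state.m_weights)
print(f"trial reward, first 100 iters: {history.reward_per_iter[:100].mean():+.2f}")
print(f"trial reward, last 100 iters:  {history.reward_per_iter[-100:].mean():+.2f}")
print(f"final noise-free reward (max 1): {reward:.3f}")
print(f"final W-M weight correlation:    {corr:.3f}")
```

prints (a few seconds on one core):

```
trial reward, first 100 iters: -18.72
trial reward, last 100 iters:  -11.46
final noise-free reward (max 1): 0.710
final W-M weight correlation:    0.934
```

The raw trial reward (`1 − Σ|m − m̂|`, the scale the learning rates are
calibrated against) climbs as the noisy song approaches the template;
the noise-free reward is reported on the normalized max-1 scale
(1 = perfect imitation); and the W–M correlation of 0.93 shows the song
has been largely copied from the learning pathway into the production
pathway. At the full reference scale (`square-song`: 160 HVC neurons,
200 per nucleus, T = 80, 20,000 iterations) both the final noise-free
reward and the correlation reach ≈ 0.92.

## Command line

```sh
songlearn train --preset square-song --seed 0 --out runs/square-seed0/
songlearn ablate --preset ablation-small \
    --variants full,baseline_direct_rl,no_rl_in_x,rl_first_k_then_cut_x,no_kernel,lman_silenced \
    --seeds 10 --out runs/ablation/
songlearn evaluate --run runs/square-seed0/
songlearn report --run runs/square-seed0/
```

`train` writes a self-describing archive (config snapshot, history CSV,
final weights/kernel/song as `.npz`, plain-text log); re-running from
the stored `config.json` reproduces the history byte-for-byte. Custom
2×T template songs load from CSV via `--song-csv` (two rows, comma
separated; `--no-normalize` to keep raw units).

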