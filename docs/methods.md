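# Methods

`songlearn` simulates a two-pathway model of how juvenile songbirds
acquire and then crystallize a song. The song system is modelled as four
rate populations: HVC provides a stereotyped clock; Area X (basal
ganglia) is the site of reinforcement learning; LMAN injects exploration
noise and relays Area X activity to the motor pathway through the
thalamus; RA drives the motor output. Learning proceeds in two coupled
processes that run simultaneously on every rendition of the song: a
node-perturbation policy gradient shapes the HVC→Area X weights `M`, and
an unsupervised Hebbian rule with a fixed temporal kernel copies `M`
into the HVC→RA weights `W`, where the song is ultimately stored.

## Model

### HVC clock

HVC activity is an `N × T` matrix `H`; neuron `i` is silent until its
onset step `o_i` and then decays,

    h_ij = exp(-(j - o_i) / τ_h),   j ≥ o_i,     τ_h = 20 steps.

Onsets are assigned evenly (`o_i = ⌊iT/N⌋`), so every time step is the
onset of `⌊N/T⌋` or `⌈N/T⌉` neurons; at the default scale (N = 160,
T = 80) exactly two neurons onset per step. An alternative form
(`form="as-printed"`) gives each neuron a constant plateau with
amplitude `exp(-i/τ_h)` instead; the two forms share the same support
pattern and either can drive learning, but the transient form realizes
the "one burst per neuron per song" picture of HVC and is the default.

### Circuit dynamics

All three downstream populations are leaky integrators with time
constant τ = 10 steps, integrated by explicit Euler with `dt = 1` song
time step (the discrete "time steps" of the protocol):

    τ ẋ = -x + M h_t + w_XL l_t          (Area X)
    l_t = w_LX x_{t-1} + ξ_t             (LMAN; ξ_t i.i.d. N(0, σ²))
    τ ṙ = -r + W h_t + w_LR l_t          (RA)
    m̂_t = A r_t                          (motor readout, 2 channels)

with `w_XL = 0.3`, `w_LX = 1`. LMAN is computed from the *previous*
Area X state plus fresh noise — a one-step synaptic delay that keeps the
update explicit and breaks the algebraic loop. All activities start at
zero. Because the system is linear, each population is a first-order
scalar recurrence per neuron and is integrated exactly as written with
`scipy.signal.lfilter`; this is arithmetic-identical to the explicit
Python loop and roughly an order of magnitude faster.

Two parameter conventions deserve a note:

* **Noise scale.** The LMAN noise is specified as N(0, σ_LMAN) with
  σ_LMAN = 0.01 in the convention where the second argument is the
  *variance*; `NetworkParams.sigma_lman` stores the standard deviation,
  0.1. With the s.d. read as 0.01 instead, the policy-gradient signal is
  two orders of magnitude weaker and the stated learning rates produce
  no visible learning within the 20,000-iteration protocol.
* **LMAN output gain.** LMAN projects to two targets, Area X and RA. The
  model gives LMAN output synapses a single shared gain: `w_LR = w_XL =
  0.3`. This choice is forced by the consolidation timescale: the
  handoff of the song from the learning pathway to `W` has time constant
  ≈ `w_LR / η_STDP` iterations (see below), so a unit LMAN→RA coupling
  would give τ ≈ 17,000 iterations — incompatible with both saturation
  by 20,000 iterations and with the observation that cutting the
  learning pathway at iteration 5,000 leaves the song intact. With
  `w_LR = 0.3`, τ ≈ 3,000 iterations and both results hold. The literal
  unit coupling remains available (`w_lr=1.0`).

The fixed readout `A` has i.i.d. `N(0, 1/√n_RA)` entries drawn once per
run from a dedicated seed stream. Trainable weights initialize as
i.i.d. `N(0, 10⁻³)`, so the naive song is near-silent.

### Reward

Each rendition is scored against a 2×T template (amplitude and pitch):

    R = 1 - Σ_{c,t} |m_ct - m̂_ct|.

The raw sum (not a per-entry mean) is the scale against which
η_RL = 10⁻³ is calibrated; `compute_reward(..., normalized=True)`
divides the sum by `2T`, giving the length-independent max-1 scale used
for reporting. Absolute differences are used: a signed sum would let
errors cancel and would unbound the reward. The default template is
piecewise constant (2–4 segments per channel, levels drawn in
[0.2, 0.8] so the reward is neither trivially high nor saturated);
arbitrary 2×T traces can be supplied by CSV.

### Reinforcement learning (HVC → Area X)

Node perturbation: correlate the injected noise with reward surprise,

    ΔM = η_RL · e · (R - R̄) - M/τ_M,    e = Σ_t ξ_t h_tᵀ,

with η_RL = 10⁻³ and τ_M = 10⁶. The eligibility trace uses the noise
`ξ_t` (the perturbation), which is the classical node-perturbation
estimator. Using the full LMAN activity `l_t = w_LX x + ξ` instead
(`eligibility_form="lman"`) adds a term proportional to `x hᵀ` whose
product with the reward fluctuation acts as multiplicative noise on `M`;
at the full network scale this destabilizes training (the magnitude of
the destabilizing term grows with ‖H‖², i.e. with network size), so the
noise-only estimator is the default. The baseline `R̄` is an exponential
moving average with α = 0.1, initialized to the first trial's reward so
the first update carries no gradient term.

### Weight transfer (HVC → RA)

The consolidation rule is unsupervised and reward-free:

    ΔW = η_STDP · post · K · H_eᵀ - W/τ_W,

with η_STDP = 10⁻⁴, τ_W = 10⁵, and `post` the postsynaptic activity
matrix. The kernel `K` (T×T) is chosen so the update copies `M`:
`K = H_e⁺ (H_e⁺)ᵀ`, which makes `H_e K H_eᵀ` the orthogonal projector
onto the column space of `H_e` — exactly the identity when the code has
full row rank with `N ≤ T`. When `N > T` (the default geometry) the
full identity is unreachable; the projector leaves `W h_t = M h_t` for
every realizable clock state, which is the functionally relevant
equality. The residual from the true projector is recorded on the
kernel (`projector_residual`, < 10⁻⁶ for full-rank-in-time codes).
Singular values below `10⁻¹⁰ σ_max` are treated as zero.

Two choices make the copy exact in the presence of the circuit's
temporal filtering:

* **Presynaptic trace** (`kernel_pre="effective"`, default): the kernel
  is solved on `H_e = H G`, the clock as seen through the synaptic
  filter `G` of the Area X integrator (first-order lowpass with gain
  `dt/τ` and pole `1 - (dt/τ)(1 - w_XL w_LX)`). Area X activity is
  exactly `M H_e` (plus noise), so `post · K · H_eᵀ = M P + noise` with
  `P` the row-space projector. Solving on the raw clock
  (`kernel_pre="code"`) leaves the copy smeared by the filter — the
  measured transfer operator then correlates with the identity at only
  ≈ 0.3 — and is retained as an option.
* **Postsynaptic term** (`stdp_post="x"`, default): Area X activity, as
  in the derivation chain post·K·Hᵀ ∝ X·K·Hᵀ ≈ M·H·K·Hᵀ. Using RA
  activity (`stdp_post="ra"`) inserts the doubly-filtered relay and a
  `W`-self-amplification term with growth rate η_STDP > 1/τ_W, which
  degrades or destabilizes the transfer; it is kept as the
  biologically-literal option.

### Consolidation timescale

During training the song reaches the motor output along two routes: the
direct `W` route and the LMAN relay (`M` → X → LMAN → RA, gain ∝ w_LR).
RL holds the *total* at the template while the Hebbian rule keeps
adding copies of `M` to `W`; the relay's share of the output therefore
decays with time constant ≈ `w_LR / η_STDP` ≈ 3,000 iterations. The
noise-free ("crystallized") song — evaluated with LMAN input to RA
removed — converges to the template on this timescale, which also
explains why cutting Area X output after 5,000 iterations leaves the
song intact: consolidation is already ≈ 80% complete.

## Training protocol

One iteration = one noisy rendition → reward → RL update → STDP update,
with weights updated once per iteration after the full rollout. The
kernel is computed once per run (the clock never changes). Histories
record the noisy-trial reward and the Pearson correlation of the
flattened `W` and `M` every iteration; the final song is always the
noise-free evaluation. Everything is a pure function of the run seed:
per-iteration noise streams are seeded from `(run_seed, iteration)`,
initialization from the run seed alone.

At the full scale (160 HVC / 200 per nucleus / T = 80 / 20,000
iterations), the final noise-free reward reaches ≈ 0.92 on the max-1
scale and the W–M correlation ≈ 0.92, consistently across seeds. One
run takes well under a minute on one CPU core.

## Ablation battery

Six variants, every variant trained over the same seed list so
differences are not seed artifacts:

| variant | manipulation |
|---|---|
| `full` | complete model |
| `baseline_direct_rl` | classical single-pathway model: node-perturbation RL directly on `W`; no Area X learning, no kernel |
| `no_rl_in_x` | RL disabled from iteration 0 (juvenile Area X lesion) |
| `rl_first_k_then_cut_x` | RL only for the first `cutoff` iterations, then the X→thalamus→LMAN limb is severed (crystallization) |
| `no_kernel` | `K` replaced by the identity (or the update skipped, `no_kernel_mode="skip"`) |
| `lman_silenced` | LMAN output silenced entirely: no noise, no relay (implemented as σ = 0, `w_LX = 0`, no LMAN→RA term) |

Expected ordering, which the scaled-down battery reproduces: the two
learning models far exceed `no_rl_in_x` and `lman_silenced` (which never
learn at all); `no_kernel` falls below `full`; the crystallization
variant is statistically indistinguishable from `full`; and the
single-pathway baseline slightly exceeds the two-pathway model — the
price of separating learning from production, as reported for the
original circuit models.

## Scaled-down presets

The `square-song-small` / `ablation-small` presets (40 HVC, 50 per
nucleus, T = 20, 5,000 iterations) are protocol analogues for fast
iteration and CI. Because the consolidation time constant
`w_LR / η_STDP` is independent of network size and protocol length,
shortening the protocol 4× requires scaling η_STDP up by the same
factor (to 4×10⁻⁴) to preserve the crystallization-to-protocol timing;
everything else is unchanged. The `smoke` preset (20/20/10, 200
iterations) exercises the machinery only.

## What the synthetic data does and does not capture

All inputs are generated internally: the HVC code is an idealized,
perfectly stereotyped, jitter-free clock, and the template song is a
piecewise-constant two-channel trace. Real HVC sequences have trial-to-
trial timing jitter, non-uniform burst density and plasticity of their
own; real song targets are smooth, structured, and evaluated through a
nonlinear syrinx rather than compared entry-wise. Passing tests
therefore demonstrate the learning-and-consolidation mechanism under
the model's own idealized conditions, not performance on acoustic data.
Synthesis of audible song from the two control traces is out of scope.

## Numerical choices and degenerate inputs

* Explicit Euler, `dt = 1` (validated against the matrix-exponential
  solution on a small instance; `dt ≤ τ` enforced for stability).
* Non-finite activities abort the trial with the offending population
  and step index (`DivergenceError`); the CLI maps this to exit code 3.
* Rank-deficient clocks produce a warning and a recorded projector
  residual, not a failure.
* Pearson correlation of a constant weight matrix is undefined and
  raises.
* Custom songs with a constant channel are left unnormalized for that
  channel.
* Histories persist to CSV with every iteration up to 5,000 and every
  10th beyond, always including the final iteration.

## Known limitations

* The stability of the RL loop is sensitive to the product of noise
  s.d. and readout scale; the defaults sit comfortably inside the
  stable region, but raising σ or the readout gain a few-fold at full
  scale destabilizes training (the model inherits REINFORCE's
  step-size fragility).
* The W–M correlation peaks near saturation and then erodes slowly on
  very long runs as `W` integrates gradient jitter; at the standard
  20,000-iteration protocol this effect is small (corr ≈ 0.92).
* `n_neurons ≥ n_steps` is required of the clock so onsets can cover
  every step; longer songs need proportionally more HVC neurons.
* The realistic-song protocol (2,200 HVC neurons, T = 1,100,
  η_STDP = 10⁻³) is encoded as the `control-traces` preset and runs, but
  the acceptance battery exercises the square-pulse protocol only.
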