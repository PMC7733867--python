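# Methods

## Model

A linear birth–death process starts with one individual at age `t_or`
(time measured before present, increasing into the past) with per-capita
birth rate λ > 0 and death rate μ ≥ 0. Three sampling schemes are
superimposed: ψ-sampling (rate ψ, sample placed in the reconstructed tree
`T`), ω-sampling (rate ω, only the time is recorded in the occurrence
record `O`), and ρ-sampling (each individual alive at present is included
in `T` with probability ρ). A ψ- or ω-sample removes its bearer with
probability `r`; removal labels may also be missing ("unknown"), in which
case every update uses the sum of the removed and non-removed branches.
The total count `I_t` is therefore a birth–death process with birth rate
λ and death rate μ + (ψ+ω)r per capita.

Two one-lineage probabilities underlie all closed forms: `u(t, z)`, the
probability that a lineage alive at age t leaves no sample at all by the
present (with `z` the per-individual probability of escaping ρ-sampling),
and `p(t, z)`, the probability that it yields exactly one sample, at
present. Writing γ = λ+μ+ψ+ω, Δ = sqrt(γ²−4λμ) and `x1 ≤ x2` for the
roots of λx²−γx+μ:

    u(t,z) = [x1(x2−z) − x2(x1−z)e^{−Δt}] / [(x2−z) − (x1−z)e^{−Δt}]
    p(t,z) = (1−z)(Δ/λ)² e^{−Δt} / [(x2−z) − (x1−z)e^{−Δt}]²

The critical boundary Δ = 0 (λ = μ with ψ = ω = 0) is rejected at
parameter construction: every formula above assumes Δ > 0, and callers can
perturb rates by ~1e-12 if they genuinely need the boundary. Both
functions are evaluated from the closed forms only; adaptive ODE
integration of their defining equations exists solely as a test oracle.

## Data reduction: the event schedule

The likelihood recursions depend on the data only through the
time-ordered list of punctual events — present-day tips, ancient leaves
(removed / non-removed / unknown), sampled ancestors, branchings,
occurrences — and the lineage count `k` on each *epoch* (maximal
event-free time slice). `build_schedule` pools tree events, occurrences
and requested evaluation times, then computes `k` by one backward sweep
(leaves increment, branchings decrement; the sweep must end at k = 1 on
the epoch adjoining the origin, and `x = w + y + u + k0 − 1` branchings
are enforced at parse time).

Conventions, chosen once and used everywhere:

* Epochs are half-open `(t_{h−1}, t_h]`; event factors apply exactly at
  the event time, with explicit above/below sides.
* A grid time may coincide with a data event; evaluation is then on the
  **present side (t⁻)** of the event: the backward sweep records L before
  applying the event update, the forward sweep records M after it, and at
  t = 0 the ρ factor lives in L's initialisation (M is recorded before
  it). This makes `Σ_i L_t(i)M_t(i)` count every event factor exactly
  once, at every recorded time.
* Two *data* events at exactly the same time abort with an error: the
  model is almost-surely tie-free, so a tie indicates malformed input,
  and silent ordering choices would change the density.
* Newick ages are anchored by the youngest tip at age 0 unless a
  `present_offset` is supplied (required for fully extinct trees).

## Backward sweep (L) and forward sweep (M)

`L_t(i) = P(data below t | I_t = k_t+i)` starts at
`L_0(i) = ρ^{k0}(1−ρ)^i` and evolves across an epoch by the truncated
tridiagonal system `dL/dt(i) = −γ(k+i)L(i) + λ(2k+i)L(i+1) + μiL(i−1)`,
computed as the action of the matrix exponential
(`scipy.sparse.linalg.expm_multiply`; never the dense exponential). Event
updates multiply by ψr (removed leaf), shift with ψ(1−r) (non-removed
leaf, top entry set to 0), ψ(1−r) (sampled ancestor), ωri with an index
shift (removed occurrence; state 0 is annihilated by the factor i),
ω(1−r)(k+i) (non-removed occurrence), λ (branching). Reaching the origin,
`L_{t_or}(0)` is the density `P(T, O)`.

`M_t(i) = P(data above t, I_t = k_t+i)` starts as a point mass at the
origin. Its epoch step uses the characteristic solution of the
generating-function PDE: with elapsed time s,
`M̂ = R(s,z)^k · Σ_l M(l) u(s,z)^l`, `R(s,z) = p(s,z)/(1−z)`. Taylor
coefficients at z = 0 are extracted by truncated power-series
composition: u's coefficients are `u_0 = x1x2G/c`,
`u_j = e(Δ/λ)²G^{j−1}/c^{j+1}` (e = e^{−Δs}, G = 1−e, c = x2−x1e) and the
`R^k` series is a binomial series in G/c — all non-negative, so Horner
composition is cancellation-free at *every* step size, including s → 0
where explicit double-sum expansions of the same derivative degenerate.
`R^k` coefficients are assembled in log space to tame the binomials. The
first N+1 output coefficients are exact for the truncated input (series
truncation commutes with multiplication), so the only approximation is
the shared state-space truncation. A matrix-exponential integration of
the forward master equation is retained behind `method="ode"` as a
verification path.

The density follows a second way as `Σ_i ρ^{k0}(1−ρ)^i M_{0}(i)`;
backward/forward agreement (typically ~1e-14 relative at adequate N) is
the pipeline's sharpest internal check, together with the time-invariance
of `Σ_i L_t(i)M_t(i)`.

**Scaling.** Every vector carries an explicit `log_scale`, refreshed
after each epoch and event; densities are returned in log form, exact at
any data size.

**Truncation.** The hidden count is capped at N; the top boundary drops
the upward birth flux, so mass leaks one-sidedly and the density
approaches its limit monotonically from below as N grows. The working
recommendation is N = 4 × (largest plausible population) + 20;
`recommend_truncation` doubles N until the log density moves by less than
1e-6 relative.

## Closed forms for ω = 0

Without occurrences, `L_t(i) = u_t^i W_t` with `W_t` a product over the
observed events, giving the fossilised birth–death tree density with
partial removal

    P(T) = λ^{w+y+k0−1} ψ^{v+w+y} (1−r)^{v+y} r^w
           · Π_{X∪{t_or}} p_{t_j} · Π_Y u_{t_j}/p_{t_j} · Π_W 1/p_{t_j}

(v sampled ancestors, removed leaves at W, non-removed leaves at Y,
branchings at X). For M, the generating function is a product of R- and
u-factors and its coefficients satisfy the log-derivative recursion
`M_t(i) = (1/i) Σ_α M_t(i−α) C(α)` with
`C(α) = 2Σ_{X∪{t_or}} a^α − 2Σ_W a^α − Σ_Y (a^α + b^α)`,
`a_s = (1−e)/(x2−x1e)` and `b_s = (x1−x2e)/(x1x2(1−e))`. Two properties
of this recursion are worth stating plainly:

* `b_s` diverges as s → 0 — not a typo: `M̂` then carries a factor
  `u(0,z) = z`, whose logarithm is singular at z = 0. The closed form is
  therefore only evaluated strictly below every non-removed leaf.
* The recursion is exact in exact arithmetic but amplifies roundoff by
  ~|b|^i; when any event has max(|a|,|b|) ≥ 1 (t shortly below a
  non-removed leaf) the tail of the vector diverges numerically while the
  head stays accurate. It is validated against, and should be replaced
  by, the epoch/update sweep wherever the two disagree.

## Posterior and conditioned trajectories

`K_t(i) ∝ L_t(i)M_t(i)`, normalised per row; the pre-normalisation row
sum is reported and must equal `P(T, O)` at every time. Quantiles use the
lower convention (smallest n with CDF ≥ p), stated in the output
metadata.

Trajectories of `I_t` are simulated calendar-forward from the origin
(initial state I = 1 is deterministic there — the reason this direction
was chosen over the M-based reverse form) with the Doob h-transform
rates `λ(2k+j)L(j+1)/L(j)` up and `μjL(j−1)/L(j)` down, re-derived from
the requirement that the posterior marginal flow satisfies the
L-transformed master equation. At data events the hidden count shifts
deterministically: a non-removed leaf sends the sampled individual into
the hidden pool (k→k−1, i→i+1, total unchanged), a removed occurrence
removes a hidden individual (i→i−1), branchings raise k, removed leaves
lower it; unknown labels are resolved by their posterior odds given the
below-event L vector. Inhomogeneity is handled by thinning against
per-step envelopes on a fine grid of stored L vectors (default step
0.01·t_or, log-linear interpolation; the interpolated per-state rates are
monotone within a step, so endpoint envelopes with a 1.3 safety margin
are effectively exact). Trajectories reaching a zero-probability state
are redrawn and counted; more than ~1% of redraws signals a too-coarse
grid or too-small N. The empirical marginals of 10⁴ draws match the
analytic `K` rows to total-variation distance well below 0.03 in the
tested regimes.

## Simulator and particle-filter oracle

The simulator is an exact Gillespie scheme on the aggregate rates
(total rate γ·n, affected individual uniform), recording the full
genealogy, every sample with its removal flag, and the true trajectory.
`reconstruct` prunes lineages without sampled descent-or-self, turns
non-removed ψ-samples with later-sampled descent into sampled ancestors,
writes Newick with `[&rm=]` labels, and returns the occurrence record.
`require_observation` rejection-samples until the reconstructed tree is
non-empty (at least one ψ- or ρ-sample), the empirical counterpart of
conditioning on observation.

The bootstrap particle filter propagates hidden counts calendar-forward
with the proposal rates λ(2k+i) up / μi down, accumulates the
Feynman–Kac potential (ψ+ω)(k+i) + (μ−λ)k along each path, reweights by
the event-rate factors (unknown labels: a Bernoulli branch with the
summed weight), resamples systematically at every data event, and reads
smoothed marginals off the surviving ancestral paths. Its marginal
likelihood estimates `P(T, O)` (validated against both sweeps within
Monte-Carlo error) and its quantiles validate `K` in a regime with very
sparse through-time sampling (ψ = ω = 0.001, ρ = 0.1). Path degeneracy
makes early-time smoothed marginals conservative at very long horizons;
the desk-scale comparisons stay within one individual of the analytic
quantiles at 10⁴ particles.

## What the synthetic data does and does not emulate

All tests run on data generated by the package's own exact simulator of
the generative model, so they verify the *internal consistency chain*
(simulator → density → posterior → trajectories, plus independent
enumeration, ODE and SMC oracles at small sizes). They do not probe
model misspecification in real data: time-varying or density-dependent
rates, lineage-specific sampling, phylogenetic reconstruction error or
misdated samples are all outside the model, and a real dataset violating
them can be fit without warning. Problem sizes were chosen at desk scale
(populations of order 10–100, hundreds of simulated datasets); the
calibration check uses the randomised-boundary (randomised-PIT) form of
the 90% equal-tailed interval because a deterministic interval on an
integer support necessarily over-covers at these population sizes.

## Numerical choices, in brief

* All probability vectors non-negative; max-rescaling into `log_scale`
  after every step; log densities exact at any size.
* `expm_multiply` for the tridiagonal action (dense matrices never
  formed); series composition for the M epoch step (stable for all dt);
  `solve_ivp` only inside test oracles.
* Epoch-solver comparisons are meaningful only on adequately truncated
  states (top entry ≤ 1e-10 of the max — the same adequacy rule the
  sweeps use); outside that domain the truncated master equation and the
  exact coefficient extraction legitimately differ at the boundary.
* Zero-probability data (ψ = 0 with tree events, r = 1 with sampled
  ancestors, ρ = 0 with present tips…) yields a zero vector/−inf log
  density, not an exception, except where the input itself is malformed.
* Ties between data events are errors; grid/event collisions follow the
  t⁻ convention above.

## Known limitations

* Constant rates only; no multi-type or density-dependent variants.
* The ω = 0 closed-form M recursion has the stability domain described
  above; the numeric sweep is the general tool.
* The particle filter is an oracle, not a production inference engine:
  no adaptive resampling schedule tuning, and smoothed marginals suffer
  ancestral degeneracy on long histories.
* No inference over (λ, μ, ψ, ω, ρ, r) themselves: parameters are taken
  as known, as when embedding these densities in an external MCMC.
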