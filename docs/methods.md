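# Methods

## Model

A single biallelic autosomal locus in a diploid Wright–Fisher population of
constant effective size Nₑ with discrete, non-overlapping generations. The
recipient population is fixed for *A*, the donor for *B*; secondary contact
at t = 0 produces one F1 hybrid at t = 1, i.e. the marker allele starts at
frequency q₀ = 1/(2Nₑ) unless overridden. Mutation is neglected (2Nₑμ ≪ 1).

Selection on the marker is semidominant: intrinsic fitnesses 1, 1+s, 1+2s.
A dominance hook (heterozygote factor 1+2hs, default h = 0.5) exists for
exploration, but every closed form and every test uses semidominance.

Hybrid carriers additionally experience genome-wide hybrid fitness effects.
Both are treated as highly polygenic aggregates — only their total strengths
η₁ (heterosis) and δ₁ (DMIs) enter the model, not the number or positions of
the underlying loci. Assuming infinitely many unlinked loci and a large Nₑ,
each backcross generation halves the introgressed genome fraction
deterministically, which gives the decay laws

- η_t = η₁·2^−(t−1) — heterosis proportional to the introgressed fraction;
- δ_t = δ₁·[2^−(t−1) + (1−2^−(t−1))·2^−(t−1)] — pairwise incompatibilities
  between introgressed and native alleles inherited from *different* parents
  (first term, halving) plus, once recombinant parents exist, pairs
  inherited from the *same* parent (second term). Hence the slightly slower
  decay 1, 3/4, 7/16, 15/64, …

Genotype fitnesses at generation t: w_AA = 1 exactly (rare introgression —
HFEs do not measurably touch residents), w_AB = (1+s)·H_t,
w_BB = (1+2s)·H_t with H_t = 1+η_t+δ_t. When H_t ≤ 0 both carrier fitnesses
are clamped to exactly 0 (sterility/lethality), not treated as an error.
Canonically η ≥ 0 ≥ δ, but both signs are accepted.

The faster decay of heterosis means η₁ = |δ₁| is *not* neutral: the effects
cancel only in the F1, and breakdown dominates afterwards. Vigor followed by
breakdown (e.g. η₁ = 0.5, δ₁ = −0.45) emerges the same way.

## Compounded factor α

α = Π_{t≥1} max(0, H_t), truncated at 20 generations by default (the decay
terms are < 1e−14 by t ≈ 50; the residual tail at truncation 20 changes α by
~2η₁·2^−20 relative, i.e. ~5e−6 absolute for η₁ = 0.8 — the truncation is a
parameter so convergence can be checked). Any zero factor makes α = 0. The
weak-effect linearisation uses the series sums Ση_t = 2η₁, Σδ_t = (8/3)δ₁:
α̃ = 1 + 2η₁ + (8/3)δ₁, so α ≥ 1 iff η₁ ≥ (4/3)|δ₁| approximately.

## Fixation probability

**Diffusion.** Kimura's semidominant formula with the initial frequency
rescaled by α: u(x) = (1−e^(−4Nₑsαx))/(1−e^(−4Nₑs)); s = 0 is handled by the
limit αx (capped at 1). For strongly deleterious alleles the exponents
overflow; the implementation switches to the asymptotically exact
exp(4Nₑs(1−αx)) form above exponent 700. Valid for any s and any x, which is
why it is the more general route.

**Branching process.** A time-heterogeneous Galton–Watson process with
Poisson offspring, mean λ_t = w_AB,t (clamped ≥ 0). Survival by generation t
is u_t = 1−G_t(0), computed by seeding g = 0 at the horizon and iterating
g ← exp(λ_τ(g−1)) backwards. The infinite-horizon value solves the constant
tail (λ = 1+s after generation 50) first — Newton on u + expm1(−λu), which
is convex, so iteration from u = 1 converges monotonically to the positive
root, tolerance 1e−14 — and then folds in the 50 inhomogeneous generations.
This is exact in the decayed regime and avoids arbitrarily long recursions.
For weak effects u ≈ 2αs. Branching survival approximates fixation only for
s > 0 in a large population; for s ≤ 0 the estimate is returned as 0 with an
explicit out-of-regime flag rather than raising.

The two routes agree within ~10% relative error for s ≤ 0.05 and moderate α.
The diffusion over-estimates when heterosis is strong *and* selection large
(the separation of timescales weakens); empirically the over-estimate
exceeds Monte-Carlo resolution at 2×10⁴ replicates once η₁ ≥ 0.5 and
s ≥ 0.05, and the tests assert only diffusion ≥ branching there. Branching
matches simulation within 3 SE everywhere tested.

**Contour.** For each η₁ on a 50-point grid over [0, 1], bisection on
|δ₁| ∈ [0, 1] (tolerance 1e−10 on the probability scale) finds where the
branching fixation probability equals the classical no-HFE value at the same
s. The contour is summarised by OLS of η₁ on |δ₁| using absolute values —
this orientation is the headline because its weak-effect limit is the
analytic ratio η₁ = (4/3)|δ₁|; the reversed slope is also reported. At
s = 0.01 the fitted slope is ≈ 1.353 with R² > 0.999. The grid density and
regression orientation are choices of this package; the reversed-orientation
slope is carried in `ContourResult.slope_reversed` for comparison.

## Wright–Fisher simulator

Discretisation: Hardy–Weinberg genotype formation at frequency q,
deterministic viability selection
q* = (q²w_BB + q(1−q)w_AB)/(q²w_BB + 2q(1−q)w_AB + (1−q)²), then
Binomial(2Nₑ, q*)/2Nₑ. This standard scheme reproduces all the model's
theory limits (neutral fixation = q₀, Kimura/Haldane for constant s).
HFE decay inside the simulator is deterministic per the decay laws
(stochastic dilution with finite chromosome numbers is out of scope); after
generation 50 fitness is exactly classical, avoiding underflow churn.

All replicates are advanced together as one cohort by a single seeded numpy
Generator — they share the same generation clock and fitness schedule, so
vectorised binomial draws apply; identical (config, seed) reproduces the
outcome bit for bit, which is the determinism contract (per-replicate
independent streams would only matter for out-of-order execution, which the
implementation does not do). `max_generations` defaults to 100,000 (~10Nₑ at
the default Nₑ = 10,000) so unresolved replicates essentially never occur;
they are counted and flagged, never silently dropped.

## Conditional DFE

Selection coefficients are drawn from f(s): Normal(mean −0.001, SD 0.05) as
the default illustration, or an exponential. The exponential is implemented
on positive support (rate 1/scale) — a *beneficial*-s DFE; the sign
convention for exponential DFEs is genuinely ambiguous in the literature, so
it is a documented choice rather than an assertion, and the qualitative
HFE-shift direction is what the tests pin down.

Two routes to E[s | fixation]:

- *Simulation*: one WF replicate per draw (per-replicate s vectorised in the
  same cohort kernel), retaining s where the replicate fixes. Default
  10⁶ draws (configurable) — at the default parameters ≈ 3.6% of draws fix,
  giving a standard error of ≈ 2e−4 on the conditional mean.
- *Integration*: E[s|fix] = ∫s·u(s)f(s)ds / ∫u(s)f(s)ds with u(s) the
  infinite-horizon branching survival (0 for s ≤ 0), adaptive quadrature
  over [max(0, μ−8σ), μ+8σ] (or [0, 8·scale]), relative tolerance 1e−9.
  Branching rather than diffusion because it matches simulation where they
  differ. Taking u = 0 for s ≤ 0 ignores drift-driven fixations of neutral
  and deleterious alleles; their weight is O(1/2Nₑ) per draw at Nₑ = 10,000
  and shifts the mean by far less than the Monte-Carlo error of the
  simulated route, which retains full fidelity.

Because u(s) ≈ 2αs, HFEs rescale the joint density s·f(s) almost uniformly —
which is why the conditional mean moves only subtly (0.0578–0.0634 across
the four scenarios) even though α spans 0.03–3.7.

## Sojourn times

Extinction happens on the same ~20-generation timescale the HFEs act on, so
heterosis delays loss and DMIs expedite it (lethal DMIs, η₁+δ₁ ≤ −1, force
extinction in generation 1). Fixation happens on the drift/selection
timescale (thousands of generations at Nₑ = 10,000, s = 0.01), long after
the HFEs have decayed, so fixation times are essentially unchanged (< 5%
in the tests). Comparisons use the Mann–Whitney rank-sum test at α = 0.01 on
2×10⁴ replicates per scenario.

## Problem sizes in the test suite

The suite runs the published analyses at reduced replication chosen so the
Monte-Carlo tolerances stay meaningful: 10⁶ DFE draws (vs 10⁷), 10⁵
replicates for neutral α-scaling at Nₑ = 1,000 (the α·q₀ relation is
Nₑ-free), 2×10⁴ replicates per point for the concordance and sojourn checks
at Nₑ = 10,000, and 10⁵ Monte-Carlo Galton–Watson realisations for the
branching-recursion oracle. Closed-form identities are checked to 1e−12 or
exactly where the arithmetic is dyadic.

## What the synthetic scenarios do and do not show

All inputs are model parameters; there is no data ingestion. The simulator
emulates the idealised regime the theory assumes: deterministic HFE decay
(infinite loci, rare introgression, no double-hybrid matings), a single
founding copy, constant Nₑ, no linkage, no demography. Passing tests
therefore validate the mathematics and its internal consistency, not the
adequacy of those assumptions for any real admixture event. In particular:
larger introgression pulses slow HFE decay and would inflate HFE impact;
finite genomes make dilution stochastic; selection on introgressed
background DNA could perturb resident fitness. None of these are modeled.

## Known limitations

- Branching-based quantities silently understate fixation of s ≤ 0 alleles
  (flagged, and bounded by 1/2Nₑ effects); use the diffusion for deleterious
  alleles.
- The contour regression slope depends mildly on the η₁ grid range; 1.35 is
  specific to the [0, 1] grid at s = 0.01 (the weak-effect limit is 4/3).
- `FitnessTrajectory` and the CLI tables are not memory-frugal for horizons
  of millions of generations; they are meant for the ≤ 10²-generation window
  where HFEs exist.
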