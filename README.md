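# introfix

Fixation probabilities of introgressed alleles under time-decaying hybrid
fitness effects.

When two diverged populations hybridize, an allele *B* carried into the
recipient population by a single hybrid does not evolve like a de novo
mutation: its carriers are hybrids, and hybrids experience genome-wide
**hybrid fitness effects (HFEs)** — **heterosis** (hybrid vigor from the
masking of recessive deleterious alleles, strength η₁ in the F1) and
**Dobzhansky–Muller incompatibilities** (hybrid breakdown from deleterious
epistasis between alleles fixed in the two source populations, strength δ₁).
Repeated backcrossing halves the introgressed genome fraction every
generation, so both effects decay:

    η_t = η₁ · 2^−(t−1)
    δ_t = δ₁ · [2^−(t−1) + (1 − 2^−(t−1)) · 2^−(t−1)]

(DMI effects decay slightly slower: 3/4, 7/16, 15/64, … of δ₁). Genotype
fitnesses at generation t are w_AA = 1, w_AB = (1+s)(1+η_t+δ_t),
w_BB = (1+2s)(1+η_t+δ_t), clamped at 0 when 1+η_t+δ_t ≤ 0 (sterile/inviable
hybrids). Because the HFEs vanish within ~20 generations, their compounded
effect is a single factor

    α = Π_t max(0, 1 + η_t + δ_t)  ≈  1 + 2η₁ + (8/3)δ₁   (weak effects)

that linearly rescales the allele's effective initial frequency. The package
provides:

- **Closed forms** (`introfix.core`): decay laws, fitness trajectories, α.
- **Fixation theory** (`introfix.fixation`): the α-rescaled Kimura diffusion
  u(x) = (1 − e^(−4Nₑsαx)) / (1 − e^(−4Nₑs)); the time-heterogeneous
  branching process u_t = 1 − G_t(0) with Poisson offspring mean w_AB,t
  (≈ 2αs for weak selection); and the iso-probability contour in
  (η₁, |δ₁|) space where HFEs exactly cancel.
- **Wright–Fisher simulator** (`introfix.wf`): binomial-resampling forward
  simulation under the time-varying fitnesses, giving empirical fixation
  probabilities and sojourn-time distributions.
- **Conditional DFE** (`introfix.dfe`): the distribution of selection
  coefficients among alleles that fix, for s drawn from a normal or
  exponential distribution of fitness effects, by simulation and by
  quadrature over u(s)f(s).

Intended for population geneticists studying adaptive introgression and
admixture — e.g. asking whether archaic alleles had to pass a DMI filter, or
how hybrid vigor inflates the fixation chances of weakly selected variants.

## Worked example

The compounded factor for moderate vigor followed by breakdown
(η₁ = 0.5, δ₁ = −0.45 — F1 fitness factor 1.05, F2 factor 0.9125):

```sh
$ introfix alpha --eta1 0.5 --delta1 -0.45
alpha	0.8111407918086384
alpha_weak_approx	0.8
```

α < 1: the early vigor does not compensate the slower-decaying
incompatibilities, so fixation is hindered. For a weakly beneficial allele
(s = 0.01, Nₑ = 10,000, one founding copy):

```sh
$ introfix fixprob --eta1 0.5 --delta1 -0.45 --s 0.01
eta1	delta1	s	Ne	q0	method	probability	std_error	note
0.5	-0.45	0.01	10000	5e-05	diffusion	0.016091934668814017	0.0
0.5	-0.45	0.01	10000	5e-05	branching	0.016127628743663358	0.0
```

Both routes agree: ≈ 0.0161 ≈ 2αs, versus the classical ≈ 2s = 0.02 —
the HFEs cost this allele about a fifth of its fixation probability.
The same rescaling shifts the fitness effects of the alleles that do fix;
under strong heterosis (η₁ = 0.8) the mean selection coefficient conditioned
on fixation, for s ~ Normal(−0.001, 0.05), drops from 0.0609 to:

```sh
$ introfix --quiet dfe --method integrate --eta1 0.8
Ne	delta1	eta1	sd	mean	family	method	mean_s_fixed	n_fixed	std_error
10000	0.0	0.8	0.05	-0.001	normal	integration	0.057746877982235545	0	0.0
```

Other subcommands: `trajectory` (per-generation fitnesses), `contour`
(the iso-probability line and its regression slope), `simulate` and
`sojourn` (Wright–Fisher runs), `dfe --method simulate` (the Monte-Carlo
route), and `suite` (a JSON-driven scenario batch). Every written table gets
a `.manifest.json` sidecar sufficient to reproduce it bit for bit.

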