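# Methods

This note documents the models behind `ruggedpaths`, the parameter choices
that matter, the numerical conventions, and what the synthetic-data
generator does and does not emulate.

## Landscape model and conventions

A landscape is a finite mapping from equal-length genotype strings over an
alphabet Σ to finite real fitness values. Adjacency is Hamming-1 among
*present* genotypes only: genotypes absent from the mapping are treated as
inviable everywhere (walks cannot traverse them, paths through them are
pruned, graph distances are computed within the present set). This matches
how folding landscapes are assembled — only sequences above a
folding-probability cutoff are retained.

Conventions chosen where several readings were defensible:

- **Main peak ties** break lexicographically (smallest genotype), for
  reproducibility independent of hash order.
- **"Fitter" means strictly greater** throughout. Equal-fitness neighbours
  do not disqualify a peak, so plateau members are peaks, and the tree
  component (≤ 1 strictly fitter neighbour) contains all peaks.
- **Experimental tables**: fitness proxies (e.g. an inhibitory
  concentration) can be log10-transformed and then min–max normalized onto
  [0, 1]. Log-then-normalize is the default order; with a single distinct
  value everything maps to 0. [0, 1] was chosen as the common scale so
  that roughness measures are comparable across landscapes.
- **TSV dialect**: UTF-8, `#` comments, fitness serialized with 17
  significant digits and parsed with a round-trip float parser, so
  write→load is bit-exact.

## Additive fit and deviation from additivity

The additive model is anchored at the observed main peak: predicted
fitness is the peak fitness plus one free coefficient per (site, non-peak
state) pair at which a genotype differs from the peak. Coefficients are
the least-squares solution (`numpy.linalg.lstsq`), using the minimum-norm
solution when the design is rank-deficient (e.g. a state observed only
once). Coefficients are *not* sign-constrained, although on
falling-away-from-the-peak landscapes they come out negative. Deviation
from additivity is `SS_residual / SS_fitness` (sums of squares over all
entries, not mean-centred); the unscaled RMS residual is also exposed on
the fit object.

## Path statistics

**Simple paths.** A simple trajectory between genotypes differing at d
sites changes each differing site exactly once, directly to the target
state, giving d! trajectories for any alphabet size. Monotonic means
strictly increasing fitness at every step — in the strong-selection limit
neutral steps are (almost) never fixed, so plateau steps do not count.
Counting uses dynamic programming over subsets of the differing sites
(2^d states instead of d! orderings); the test suite checks it against
explicit permutation enumeration.

**Divergence.** The divergence of two paths is the symmetrized mean of
shortest Hamming distances from the points of one path to the other (the
directed version is available via `symmetric=False`). Bundle divergence is
the expectation over two independent draws with replacement,
`Σ_{ij} P_i P_j D_ij`; the diagonal contributes zero and the normalisation
is unaffected because probabilities sum to one. When probabilities are
empirical frequencies from n sampled walks, this plug-in estimator is
biased low by a factor (n−1)/n; `bundle_mean_divergence(..., unbiased=True)`
applies the standard U-statistic correction, used when comparing sampled
estimates against exact enumeration. Profiles report the arithmetic mean
of bundle divergences at each start-to-end Hamming distance, and an
overall mean weighted by bundle walk counts.

## Adaptive-walk dynamics

Evolution is an origin-fixation (weak-mutation) process: proposals are
single-site mutations, uniform over sites and states; proposals leaving
the landscape are never fixed; acceptance follows Kimura's diploid
fixation probability u(s) = (1 − e^{−2s})/(1 − e^{−4 N_e s}) with
s = A·(f_mutant − f_resident), the continuity limit u(0) = 1/(2N_e), and
clamped exponentials for numerical stability. Walks terminate on arrival
at a genotype with no strictly fitter neighbour (a peak or plateau
member), or at `max_steps` (such truncated walks are excluded from bundles
and counted in diagnostics).

Rather than literally rejecting proposals until one fixes — which costs
~2N_e draws per step near neutrality — the sampler draws the next fixed
mutant directly from the embedded jump chain, i.e. with probability
proportional to u among all present neighbours. Conditional on a fixation
occurring, the two procedures define the same distribution over paths, so
every path statistic is unchanged while the cost per fixed step is
constant.

Selection coefficients use raw fitness differences (unnormalized), so for
misfolding-cost landscapes (f = −A(1−P)/P) the sweep knob is exactly the
product N_e·A; the sweep fixes N_e = 1000 and varies A = pressure/N_e. A
relative-s variant was considered and rejected as the default because it
breaks this product structure. The `strong_limit` mode accepts exactly the
fitness-increasing proposals (all equally likely), and `neutral_limit` is
a uniform random walk over present neighbours.

## Noisy-additive generator (the synthetic-data source)

The generator emulates a smooth landscape roughened by a controlled amount
of noise:

1. The designated peak (all-`alphabet[0]`) has fitness 1 and is left
   unperturbed, so the global optimum stays anchored.
2. Every (site, non-peak state) carries an independent negative
   differential −ε with ε ~ Exp(rate λ). Default λ = 1.25·L for L sites,
   so the expected additive fitness at maximal Hamming distance from the
   peak is 1 − L/λ = 0.2 — genotypes far from the peak sit at a small
   positive fitness, and the positivity filter (step 4) is active but not
   destructive. (A much larger mean differential would drive almost all
   mutants negative and empty the landscape.)
3. A mutant's additive fitness (1 + sum of its differentials) is perturbed
   once per genotype, either by additive Gaussian noise N(0, σ) or, the
   default for all headline comparisons, multiplicatively by U(0,1)^ν.
   ν = 0 leaves the landscape exactly additive; the grid
   ν ∈ {0.5, 1, 2, 4} spans nearly-additive to scrambled-like roughness.
4. Mutants with positive perturbed fitness are retained; the landscape is
   then restricted to the peak's connected component so that path
   statistics are well defined.

What this emulates: continuously tunable ruggedness with a known additive
backbone, the declining fitness profile away from a single main peak, and
incomplete genotype spaces. What it does not emulate: correlated epistasis
(noise is i.i.d. per genotype), multi-peak structure by construction,
biochemical constraints, or any mutation-process structure — so passing
the directional tests shows the statistics behave as designed on this
family, not that any real landscape is smooth.

Useful exact property used by the tests: with zero noise, every genotype
on a monotonic path to the peak has fitness above its start, so positivity
filtering can never sever a monotonic path — zero-noise landscapes have
exactly one peak, zero deviation from additivity, monotonic path fraction
exactly 1, and a tree component equal to the peak plus its present
neighbours, regardless of the seed.

## Null models and Z-scores

Scrambling permutes the fitness multiset uniformly over the fixed genotype
set, preserving topology and the fitness distribution while destroying
correlation. Z-scores compare a characteristic of the original landscape
with the mean and SD over a permutation ensemble (default 100); with zero
permutation SD (constant landscapes) the Z-score is reported as NaN with a
warning. The landscape-wide mean path divergence metric used in Z-scores
and family summaries is the exhaustive strong-selection value: all strictly
uphill trajectories are enumerated from every non-peak start with their
jump-chain probabilities — exact, and affordable on the enumerable
landscapes this package targets.

## Folding model

The polymer is a chain of point monomers over {H, P, +, −} (hydrophobic,
hydrophilic, positively/negatively charged), nearest neighbours connected
by stiff harmonic springs (½·k·T·(r−a)², spring constant proportional to
temperature), bond angles unrestricted, chain endpoints fixed to charged
types. Monomers two or more links apart interact via
A_ij/r¹² − B_ij/r⁶ + q_i q_j e^{−r/λ_D}/r.

Every numeric parameter of the model is a `PhysicsConfig` field in reduced
units (lengths in rest lengths a, energies in k_BT at T = 1). The defaults
are chosen to satisfy the qualitative orderings that define the model —
HH attraction strongest (B_HH = 2), like-type pairs weakly attractive
(B = 0.5), H–P repulsive (B = −0.5), H–charged more repulsive (B = −1),
opposite charges attracted through the screened Coulomb term (λ_D = 1) —
and no analysis result in this package depends on their precise values:
simulation temperature T = 0.3, quench temperature 0.02, k = 200, Δt =
3·10⁻⁴, Brownian noise variance 2TΔt (the factor 2 is isolated in
`noise_coeff`).

Dynamics are overdamped Brownian: x ← x − ∇E·Δt + η. The deterministic
drift is capped at 0.1a per monomer per step so that steep core overlaps
cannot destabilise the integration (the capped step keeps the descent
direction). A quench equilibrates at T, relaxes at the quench temperature
until the *window-averaged* energy is stationary (relative change < 2·10⁻³
between consecutive 400-step windows; instantaneous energies fluctuate
thermally and never meet a tight tolerance), then runs a short noise-free
descent so repeated quenches of the same basin give nearly identical
conformations. Non-convergence within the step budget is flagged on the
result rather than raised.

**Native ensemble.** RMSD uses Kabsch superposition (proper rotations
only). Quenched conformations are clustered by single linkage at RMSD
radius δ (default 0.5a); a clique criterion (all pairs within δ) would be
NP-hard and is not implied by "within distance δ from each other". The
native ensemble is the largest cluster; membership of a new conformation
requires its nearest-member RMSD to be at most m + 3·MAD, where m is the
median nearest-neighbour RMSD within the ensemble (MAD = 0 degenerates to
threshold m). Folding probability is the member fraction among fresh
quenches, with resolution 1/n_samples.

## Landscape assembly and the annealing search

Expansion is breadth-first over single-substitution mutants (endpoints
immutable). Every candidate is scored once against the *seed's* fixed
reference ensemble; candidates with P ≥ p_min (default 0.1) are included
with fitness P and expanded. Examined and included counts are reported as
provenance. The folding oracle is a plain callable, so the expansion and
annealing algorithms are tested with deterministic mocks independently of
the physics. The annealing search maximises P/Rg³ (compact robust folders)
under a geometric cooling schedule with Metropolis acceptance; a
zero-temperature schedule degenerates to a greedy hill climb.

## Problem sizes and determinism

The analyses in the tests, the toy pipeline, and the acceptance script use
landscapes of 5–6 binary sites (32–64 genotypes), 20-seed families, 10⁴
walks for Monte-Carlo/enumeration comparisons, and quenches of chains of
~10 monomers — sizes at which every path quantity can be enumerated
exactly or sampled densely in seconds, so the statistical checks are sharp.
Full-physics folding landscapes of thousands of sequences are out of scope
by design: with this simulator's per-quench cost they would take weeks to
months of CPU, and the package's claims are about the statistics, which
are size-agnostic. All stochastic components draw from explicit
`numpy.random.Generator` streams; the pipeline and acceptance script
derive every stream from a single root seed via `SeedSequence.spawn`, so
runs are bit-reproducible.

## Known limitations

- Exhaustive divergence and monotonic-path enumeration scale with the
  number of uphill trajectories and are intended for enumerable
  landscapes (≲ a few thousand genotypes, short peak distances).
- The generator's noise is independent per genotype; it cannot produce
  correlated (e.g. modular or pairwise-epistatic) deviation structures.
- The folding model is a caricature: four monomer types, point monomers,
  no hydrodynamics or replica exchange; its conformations are "tertiary
  structure"-grade abstractions, not proteins.
- Walk-generated paths below the strong-selection limit may revisit
  genotypes; divergence handles this, but such paths are not "simple" in
  the d!-denominator sense used by the monotonic path fraction.
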