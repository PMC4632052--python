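# Methods

## Model and assumptions

`flucrate` fits the two-parameter Luria–Delbrück model for fluctuation
assays. Mutation events per culture are Poisson(*m*); each event founds a
clone that grows clonally until plating. Division times are modelled as
constant (Dirac): every cell divides after the same interval, so a clone
that has completed *k* doublings has exactly 2^k cells. Weighting mutation
times by the exponentially growing wild-type population and letting the
mutant divide every 1/*b* wild-type generations (*b* = mutant relative
fitness) gives the asymptotic clone-size law

    q_k = P(clone size = 2^k) = 2^(−k/b) · (1 − 2^(−1/b)).

At *b* = 1 this is Haldane's halving law q_k = 2^−(k+1). The law is
asymptotic in the number of generations grown; for realistically grown
cultures (≥ 15 generations) the finite-generation truncation is far below
sampling noise, which the direct-generation oracle (below) confirms. The
Dirac choice is a modelling decision: it is generally the stronger choice
for estimating *b*, and comparable to the exponential-lifetime
(Lea–Coulson) model for *m*, at the cost of a positive bias for very large
*m*; no correction for that bias is applied. Cell death, phenotypic lag
and post-plating growth are out of scope.

The total plated count per culture is compound Poisson with PGF
G(s) = exp(m(ψ_b(s) − 1)), ψ_b(s) = Σ_k q_k s^(2^k). Its pmf is computed
by the Panjer recursion over the power-of-two support,

    p_0 = e^−m,   p_n = (m/n) Σ_{k: 2^k ≤ n} 2^k q_k p_{n−2^k},

which involves only positive terms (numerically stable) and costs
O(nmax·log nmax).

## Estimator

The empirical PGF ĝ(s) = (1/n) Σ s^{X_i} is matched to G at fixed points:

* *b* solves ln ĝ(s₁)/ln ĝ(s₂) = (ψ_b(s₁)−1)/(ψ_b(s₂)−1). The model
  ratio is monotone decreasing in *b* over the search bracket (asserted at
  the endpoints at run time); the root is found by bisection on
  [b_min, b_max] = [0.05, 20] to 10⁻⁶.
* *m* = ln ĝ(s₃)/(ψ_b(s₃) − 1) at the solved (or user-supplied) *b*.

Counts are sorted before the PGF summation so every output is bit-identical
under permutation of the cultures. All estimation uses the plated counts
as-is; the plating efficiency enters only afterwards (Stewart correction).

### Evaluation points

The defaults are (s₁, s₂, s₃) = (0.8, 0.9, 0.9), chosen by a simulation
study over m ∈ {1, 2, 4, 8} × b ∈ {0.5, 1, 2} at 96 and 384 cultures
(100 replicates per cell). Small s₁ (e.g. 0.1) looks attractive because it
probes the zero class, but when every culture carries many mutants
ĝ(0.1) degenerates into a noisy function of the single smallest count:
at s₁ = 0.1 the worst-case median bias on the grid was 37% for m and 31%
for b with frequent estimation failures, versus 3.4% / 1.8% and no
failures at (0.8, 0.9). Points nearer 1 performed indistinguishably. The
points are exposed in `GFConfig` (and `--s1/--s2/--s3` on the CLI) because
other implementations of the GF method use other constants, and exact
reproduction of third-party numbers can require matching them.

### Confidence limits

The empirical PGF vector at the evaluation points is asymptotically normal
with Cov(ĝ(u), ĝ(v)) = (ĝ(uv) − ĝ(u)ĝ(v))/n, estimated by plug-in. This
covariance is pushed through the estimator map with a central-difference
Jacobian (relative step 10⁻⁵, re-solving the bisection at perturbed
values); 95% limits are point ± 1.96·SE, with lower limits clamped at 0.
Limits on m_corr are the m limits times the Stewart factor. Measured
coverage of the m interval at (m=4, b=1, n=96) over 500 assays is 94–96%
depending on seed, and interval width scales as 1/√n (ratio 1.96–2.00 for
n 96→384). Degenerate inputs (all-zero counts) yield explicit
not-available markers, never silent zeros.

## Corrections and rates

Partial plating (a fraction z of each culture plated) thins observed
counts; the fitted m is inflated by the Stewart factor (z−1)/(z ln z)
(= 1 exactly at z = 1, handled as a special case rather than a 0/0 limit).
μ = m/N̄p uses the mean plated cells; μ_corr = m_corr/N̄t uses mean total
cells, derived as N̄t = N̄p/z since users enter plated cells — if z is
known only roughly, both μ_corr ingredients inherit that error. σ_Nc is
the n−1 sample standard deviation.

## Goodness of fit

Pearson chi-square on counts binned greedily left-to-right until each
bin's expected frequency reaches min_expected = 5 (Cochran's rule,
configurable); the final bin is the open tail with expected mass
n·(1 − cdf) computed exactly. The Panjer recursion for binning grows
geometrically and stops once the remaining expected tail frequency drops
below min_expected, so a single jackpot culture cannot force a
million-term recursion. Degrees of freedom are #bins − 1 minus the number
of GF-fitted parameters (2 when b is estimated, 1 when fixed), floored at
1. The fit is flagged (`warning`) exactly when p < 0.01. Type-I error at
the true parameters, measured over 200 null simulations at (m=4, b=1,
n=96), is ~1%. Fewer than two formable bins gives an explicit
"gof unavailable" result, except the exactly-degenerate case (m = 0,
all-zero data), which passes trivially.

## Simulator

`sample_counts` draws K ~ Poisson(m) clones per culture, clone sizes
2^G with G geometric (capped at 2^62, far beyond any countable plate),
and thins the total binomially with z. Plated cell numbers are constant
or lognormal with specified mean and CV. Defaults represent a typical
microtitre assay: 3×10⁶ plated cells per culture (500 μL at
6×10⁶ cells/mL), full plating, CV 0.

`direct_generation_sim` is an independent first-principles oracle for
b = 1: a population doubles synchronously from n₀ cells for g
generations; newborn cells mutate Poisson(μ·births) per generation; a
mutation in generation i yields a clone of exactly 2^(g−i) cells. It
shares no code path with the clone-size law or the Panjer recursion, and
agrees with both (binned total-variation distance ≤ 0.005 at 10⁵ draws
with g=16, n₀=100).

What the simulator does *not* emulate: cell death, lag phases, non-Dirac
division-time variation, double mutants, plating-induced stress, or
counting error on crowded plates. Passing recovery tests therefore
demonstrates correctness of the estimator under its own model, not
robustness to every deviation real assays can show; the chi-square flag
is the run-time guard against gross deviations.

### Distribution comparisons

Sampler/recursion agreement is measured as total variation on a dyadic
partition {0}, {1}, {2,3}, {4,...,7}, …, tail. At heavy-tailed parameter
settings the integer-resolution empirical pmf cannot resolve below
Monte-Carlo noise at feasible draw counts (the noise floor alone exceeds
0.01 at 10⁵ draws for m=4, b=2), while the dyadic partition measures the
same agreement without that floor.

## Dispersion study

`dispersion_study` crosses m, b and cultures-per-assay, re-estimates each
simulated assay, and reports per-cell means, covariances and 95%
concentration-ellipse areas (π·χ²₂,₀.₉₅·√det Σ) of (m̂, b̂). Replicates
whose estimation fails (tiny assays can leave b unidentifiable) are
recorded as NaN, never aborted. All randomness flows from a single seed;
identical spec + seed reproduces the table bit for bit. The bundled
validation (tests and acceptance script) runs a scaled-down grid —
m ∈ {1, 4} × b ∈ {0.5, 1, 2}, 96/384 cultures, 50 replicates — as the
package's own desk-scale choice; the full 200-replicate, six-panel grid
is available through `flucrate dispersion-study --reps 200`.

## Bundled data

`datasets.luria_delbruck_1943()` returns the pooled 42-culture
phage-resistance assay from the classic 1943 report (Table 2, experiments
1, 10, 11, 15, 21 — the experiments whose cultures are printed
individually). Per-culture plated cell numbers were not printed; all
cultures are assigned 1.8×10⁸ cells (0.2 mL samples at ~9×10⁸ cells/mL,
the reported culture scale), so the derived rate — though not m or b —
should be read as order-of-magnitude. The fit of this dataset is computed
live by the test suite and the acceptance script, not stored.

## Known limitations

* The Dirac model's positive bias for large m (roughly m ≳ 10) is
  uncorrected; keep cultures small enough that plates are countable.
* The clone-size law is asymptotic in generations grown; very short
  growth (≲ 8 generations) is not modelled.
* b is weakly identified in small assays (≤ 48 cultures); the estimator
  reports failure rather than guessing when the GF ratio leaves the
  model's range.
* The delta-method limits are asymptotic; below ~48 cultures their
  coverage has not been validated here.
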