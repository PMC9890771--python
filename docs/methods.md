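# Methods

## The problem and the model

A double digest experiment yields three multisets of positive integer
fragment lengths: *A* (p fragments from enzyme α), *B* (q fragments from
enzyme β) and *C* (t fragments from digesting with both). An instance is
*valid* when Σ*A* = Σ*B* = Σ*C* (one molecule, three partitions); invalid
read-outs are representable but refused before encryption. A candidate
solution is a pair of permutations (μ, ν). Arranging *A* by μ and *B* by ν,
the cut-site coordinates are the accumulative (prefix) sums of each
arrangement; merging the two site lists, prepending the origin, and taking
step differences yields the implied simultaneous-digest spectrum. Both
accumulated lists end at the total length, so the merged list contains at
least one duplicated terminal site; with interior coincidences there can be
more. We therefore compute all p+q step differences and drop the p+q−t
smallest — deterministically removing the zero-length artifacts — leaving
exactly t values whose sum is conserved.

Fitness is f(μ,ν) = 1/(1+D) with D the elementwise L1 distance between the
ascending implied spectrum and ascending *C*. D = 0 (f = 1) is an exact
reconstruction; for data with partial-cleavage errors D quantifies the
misfit but no probabilistic error model is implemented. The distance-based
reading of the fitness (rather than counting mismatched elements) follows
the optimization objective min Σ|C′\_{μ,ν} − C|; for error-free data the
two coincide at the optimum.

## The cipher scheme and its noise budget

Plaintext m encrypts to c with cᵢ = kᵢ·m + rᵢ (i ≤ n−1) and cₙ = kₙ·R,
R = Σrᵢ. Keys are drawn from Normal(512, 170²) truncated to (0, 2¹⁰];
noise rᵢ is half-normal. The scheme is an *index*: no decryption exists
anywhere in the package, and nothing needs it — the server compares and
adds ciphertexts, and the owner verifies on plaintexts they already hold.

The original order-preservation argument covers fresh ciphertexts: if
0 < R < kᵢ·p for the minimum plaintext gap p, then m₁ > m₂ forces every
informative coordinate of Enc(m₁) above Enc(m₂). Solving the DDP requires
more: comparisons between *sums* of up to p+q ciphertexts, and between
*differences* of such sums. Two refinements make those safe:

* Per-encryption noise cap `R_bound = min(k)·p_min/(2·L_max)`, so any
  combination of ≤ L_max ciphertexts carries total noise below
  min(k)·p_min/2 and distinct accumulated plaintexts still compare
  strictly on every coordinate.
* The instance encryptor sets `L_max = 2(p+q)` — twice the deepest sum the
  solver forms. Step-difference comparisons see noise from two accumulated
  sums on each side; the doubled headroom keeps even those strictly
  ordered. p_min is fixed at 1: fragment lengths and all partial-sum gaps
  are integers.

Equal plaintexts are a genuine edge: their coordinate differences are pure
noise, and with n−1 = 2 informative coordinates the signs agree by chance
about half the time, which would present a spurious strict order.
`compare` therefore accepts an optional public tie threshold; the solver
passes 2T/(n−1) (see below), which is provably between the largest possible
noise difference of equal plaintexts and the smallest signal of distinct
ones under the budget. With the default threshold 0 the raw rule applies,
and ties surface only through mixed coordinate signs.

The public acceptance threshold shipped with an encrypted instance is
T = (n−1)(p+q)·R_bound. For a correct mapping the encrypted residual (the
coordinate-sum L1 distance between the implied and the target encrypted
spectra) is pure noise and falls well below T with overwhelming margin at
the half-normal noise scale used (R_bound/(4(n−1)) per component); for any
wrong mapping it is at least Σᵢkᵢ·1 minus noise, which exceeds T by
construction. T leaks only a noise-scale bound, never key components.
Server-side fitness normalizes the residual by 4T (a key-free proxy for
Σkᵢ) so reported fitness magnitudes are commensurate with plaintext D;
only the ordering matters to the search, and the ordering provably equals
the plaintext fitness ordering — the package's headline correctness
property, exercised exhaustively on 100 instances in the test suite.

Arithmetic is 64-bit floating point: with keys ≤ 2¹⁰ and plaintexts ≤ 10⁷
every quantity stays far below 2⁵³, so all comparisons are exact.
Ciphertext files serialize coordinates with 12 significant digits.

## The solver

The server searches permutation pairs with a quantum-inspired genetic
algorithm. Each of the p+q genes holds b = ⌈log₂ max(p,q)⌉ + 3 qubits
stored as amplitude angles (α, β) = (cos θ, sin θ). Measurement collapses
every qubit with P(1) = β², the per-gene bit strings become integer sort
keys, and stable rank ordering (ties by gene index) decodes the first p
genes into μ and the rest into ν — every measurement is a feasible
candidate. Defaults follow the published configuration: population N = 50,
g_max = 10000 generations, crossover probability 0.85, mutation
probability 0.5 (midpoint of the customary 0.45–0.55 band).

Per generation: measure all individuals, evaluate the encrypted fitness,
keep the generation best (elitism) plus N−1 binary-tournament winners,
rotate every qubit by Δθ = 0.025π toward the bit the best measurement took
(clamped to β² ∈ [0.001, 0.999] so no qubit becomes deterministic),
then single-point crossover over the flattened amplitude sequence and a
single-qubit NOT mutation per chromosome. Two standard refinements are
enabled by default:

* *neutral drift* — when a generation ties the best fitness without
  beating it, the rotation attractor moves to the new representative, so
  the search walks along equal-fitness plateaus instead of freezing;
* *catastrophe restart* (`restart_after`, default 300) — after 300
  improvement-free generations the population returns to the uniform
  superposition while the best-so-far record is retained.

Ablation on generated instances with |C| = 10 raised per-run success from
about a third to essentially always within the generation budget; neither
refinement changes the operator set, the monotonicity of the best-so-far
record, or determinism under the seed.

The inner loop is vectorized across the population (one (N, p+q, b) angle
array; measurement, decoding, selection, rotation, crossover and mutation
as array operations) and the batched fitness kernel sorts merged encrypted
sites by their first coordinate — justified by the order-preservation
guarantee, and tested against the reference path that uses only the
ciphertext operations one at a time.

## The instance generator

The generator reproduces the digest experiment: t−1 distinct integer cut
sites are placed uniformly at random on a molecule of length L = 100·t and
split between the two enzymes (⌊(t−1)/2⌋ α-sites); A, B, C are the gap
multisets of the α-sites, β-sites and their union. Instances are valid by
construction, always admit an exact solution (the planted order, retained
for diagnostics only), and satisfy |A|+|B| = t+1. A flag allows coincident
interior sites, in which case t shrinks below p+q−1. The default length
scale makes fragment lengths almost surely distinct — the *hardest*
regime, since duplicate lengths multiply the number of exact solutions.
What passing tests on these synthetics do not show: behavior under
measurement noise in the lengths (no error model) or on instance
distributions with heavy duplication, which are substantially easier.

## Experiment protocols

The success-rate experiment generates one instance per group
(|C| ∈ {10, 20, 30, 40} by default), runs the five-stage pipeline 25 times
per group with distinct GA seeds (no owner-side retries, so each run is an
independent Bernoulli trial), and reports per-group success rates, mean
generations and mean residuals. The paired comparison repeats the
{10, 20, 30} groups twice with identical instances and GA seeds — one arm
evaluating fitness on ciphertexts, one on plaintexts — isolating the cost
of privacy from the cost of search. 25 runs per group keeps the default
experiment within desk-scale minutes; a `--full` flag restores 100.

### What the solver does and does not reproduce

On groups with |C| ≈ 10 (p, q ≤ 6) the encrypted pipeline solves
essentially every run within the generation budget, and on p, q ≤ 5 it
always returns a brute-force optimum. From |C| = 20 upward
(p, q ≥ 10) the published success rates (above 88% through |C| = 80) are
**not** reproduced by this implementation: success collapses to near zero.
This is a property of the search problem, not of the encryption — the
paired plaintext arm fails identically, and the encrypted/plaintext
ranking equivalence holds throughout. Internal probes corroborate the
difficulty: simulated annealing over permutation pairs with swap,
insertion and reversal moves (5·10⁵ evaluations) stalls at distance 8–50
from the optimum at |C| ∈ {20, 40}, and feasibility-pruned backtracking
over cut-site interleavings exceeds 2·10⁵ nodes by |C| = 30. On this
generator's near-duplicate-free instances the exact solution is
essentially unique among p!·q! ≥ 10¹³ candidates, and no evaluation-budget
search of the operators described here closes that gap. Published
success at |C| = 80 is plausible only for instance distributions with
massive fragment-length duplication (many equivalent optima) or solver
internals beyond what the source describes; both are flagged as unknowns
in the generator's design notes.

## Security analyses

One-wayness arithmetic is computed exactly as rationals: per-fragment
recovery probability 1/(k·|M|) with k = 2¹⁰ and |M| = 2⁷ (the minimal
plaintext-space cardinality consistent with the printed 2⁻¹⁷ bound,
exposed as a parameter), and its (m+n+k)-th power for a whole instance,
≤ 2⁻¹¹⁰ whenever m+n+k ≥ 7. The lazy-server probability 1/(p!·q!) is the
chance a random mapping equals one designated solution; owner-side
acceptance is larger by the number of equivalent solutions (reversal
always contributes one), which the Monte-Carlo tests verify separately.

The distribution experiment draws 50,000 (k, r) pairs per family and
examines c = k·m + r. The QQ statistic standardizes the sample, pairs its
order statistics with reference quantiles at plotting positions
(i−0.5)/n, and reports the Pearson correlation plus the maximum absolute
deviation from y = x over the central 98% of quantiles — the extreme
order statistics fluctuate too much to be informative even for a true
reference sample. "Coincides with y = x" is operationalized as
correlation ≥ 0.999 and central deviation ≤ 0.05, calibrated by
simulation against true normal samples at n = 50,000. Normal keys and
noise pass (a sum of normals is normal); uniform keys and noise produce a
triangular sum whose deviation is several times larger — the leakage
contrast that motivates the normal-family default.

## Numerical and interface choices

* Permutations are 1-based in files and printed output, 0-based in memory.
* Merged equal cut sites sort stably with α-derived sites first; the
  dropped-zeros rule makes the choice outcome-neutral.
* `brute_force_solve` refuses instances with p!·q! above a configurable
  cap (default 10⁶).
* The owner retries a rejected mapping up to 3 times (reseeded GA) in the
  interactive session runner; experiment runners disable retries.
* All randomness flows through two seeds per session (crypto seed, GA
  seed), recorded in the session report; experiments derive per-run seeds
  from one master seed via a seed sequence.

## Known limitations

* No error model for partial cleavage or length-measurement noise; the
  residual D is reported but never thresholded against experimental error.
* Solution equivalence classes (cassette transformations) are not
  enumerated; the solver returns one mapping pair.
* The scheme's security is the one-wayness argument plus distribution
  indistinguishability; no indistinguishability-style game is modeled,
  and known weaknesses of linear order-preserving indexes under
  duplicate-heavy plaintext distributions are documented, not exploited.
* Roles are simulated in-process/CLI with file handoff; no network
  transport or authentication.
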