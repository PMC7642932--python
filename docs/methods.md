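# Methods

## Model

Under the neutral infinite-alleles model with scaled mutation rate θ, the
number of distinct alleles K in a sample of n sequences follows the Ewens
sampling formula marginal

    P(K = k) = c(n, k) θᵏ / (θ)ₙ,

where c(n, k) is the unsigned Stirling number of the first kind (the
number of permutations of n elements with k cycles) and
(θ)ₙ = Γ(θ+n)/Γ(θ) the rising factorial. The tail S'ₙ,ₘ(θ) = P(K ≥ m),
its complement T' = P(K < m), and Fu's Fs = ln(S'/T') are the quantities
this package computes. θ is in units of pairwise nucleotide differences
per sequence (θπ when estimated from data); n and m are counts.

## Exact engine

All mass computations live in natural-log space. Row n of ln c(n, ·) is
built from row 1 by the magnitude recurrence
c(n+1, k) = c(n, k−1) + n·c(n, k) using vectorized `logaddexp`; only the
current row is kept (O(n) memory, O(n²) time, ~1 s at n = 2001). Because
every addend c(n,k)θᵏ is nonnegative, log-sum-exp evaluation involves no
cancellation. With ℓₖ = ln c(n,k) + k ln θ,

    ln S' = LSE(ℓₘ..ℓₙ) − LSE(ℓ₀..ℓₙ),   Fs = LSE(ℓₘ..ℓₙ) − LSE(ℓ₀..ℓₘ₋₁),

so Fs never subtracts nearly equal probabilities on either side of
S' = 1/2, and the Pochhammer normalizer cancels without being formed.
The normalizer's scaling ratio fₙ(θ) = n!Γ(θ)/Γ(θ+n) is nevertheless
implemented (log-gamma form plus its recursion as an independent
cross-check) because it documents the overflow-control structure and is
cheap to test. The stored probability in an `FsResult` is the directly
summed small tail (T' when S' ≥ 0.5, S' otherwise — ties take the
T-branch, where both branches agree to machine precision); the other is
its complement, so S' + T' = 1 exactly.

The practical ceiling is n ≤ 20 000: beyond that the O(n²) build is
refused explicitly rather than silently taking minutes. Degenerate
m = 1 returns Fs = +∞ with a `closed-form` flag (S' = 1 exactly; callers
need a sentinel, not an exception).

Two independent oracles validate this path in the test suite: exact
integer arithmetic over the same recurrence (arbitrary-precision Python
ints, with rational evaluation of S' via `fractions.Fraction`), and the
identity E[K] = Σᵢ θ/(θ+i) of the allele-count distribution.

## Asymptotic estimator

The estimator evaluates S' (or T') in a single step instead of an
O(n)-term Stirling sum. Writing n' = n−1, m' = m−1 (the representation
naturally raises both indices by one; the shift is applied in
`fs_asymptotic` only, so the saddle solver itself is frame-agnostic):

    S'ₙ,ₘ(θ) ≈ I_x(m', n'−m'+1) + e^{−χ(τ)} C(n', m'−1) g(t₀),
    x = τ/(1+τ),

with phase functions

    φ(z) = lnΓ(z+n'+1) − lnΓ(z+1) − m' ln z,
    χ(t) = n' ln(1+t) − m' ln t,  t₀ = m'/(n'−m'),

the saddle point z₀ the positive root of
φ'(z) = ψ(z+n'+1) − ψ(z+1) − m'/z, and τ the solution of
χ(τ) = χ(t₀) + φ(θ) − φ(z₀) on the branch with
sign(τ−t₀) = sign(θ−z₀). The correction factor is

    g(t₀) = f(t₀) − 1/(t₀−τ),   f(t₀) = √(χ''(t₀)/φ''(z₀)) / (z₀−θ),

where the square root is the positive branch of (dz/dt)² at the saddle
(forced by the sign condition) and C(n', m'−1) is the binomial
coefficient extracted from the t^{m'−1} coefficient of (1+t)^{n'}. Both
readings are confirmed numerically: the benchmark table reproduces to
all printed digits, including its error column.

z₀ doubles as the transition value of θ at which S' crosses 1/2. For
θ < z₀ the S' form above is used and Fs = ln(S'/(1−S')); for θ > z₀ the
complementary form T' ≈ I_{1−x}(n'−m'+1, m') − R' with
Fs = ln((1−T')/T'), so the directly estimated quantity is always the
small tail.

### Numerical choices

- **Root finding.** Both solvers use bracketed Brent iteration at
  near-machine relative tolerance (`rtol ≈ 8.9e−16`, 200 iterations max,
  hard failure with diagnostics after safeguarded bracket expansion).
  For z₀ the upper bracket starts at max(m, 1) and doubles until φ' > 0;
  φ' → −∞ at 0⁺ guarantees the lower end. For τ the initial width is the
  local quadratic step √(2Δ/χ''(t₀)), Δ = φ(θ) − φ(z₀), halved/doubled
  until the target is bracketed on the selected branch.
- **Incomplete beta.** `scipy.special.betainc` where the tail is
  representable; when it underflows (|Fs| beyond ~575) the code switches
  to the exact finite binomial-tail identity
  I_{τ/(1+τ)}(m', n'−m'+1) = (1+τ)^{−n'} Σ_{j≥m'} C(n',j) τʲ evaluated
  by log-sum-exp, keeping ln of the probability. The whole pipeline —
  main term, correction (assembled as exp(−χ(τ) + ln C) with the
  coefficient as a log-gamma binomial), their combination, and the logit
  — stays in log space, so Fs values of magnitude thousands are computed
  accurately even though the probability itself underflows a double. The
  *reported* probability field then saturates at 0/1 while `fs` is exact.
- **Near the transition.** g(t₀) is a difference of two diverging terms
  as τ → t₀; when |τ−t₀| < 10⁻⁴·max(t₀, 1) the implementation falls back
  to the exact oracle (n ≤ 20 000) or drops the correction (main term
  only) beyond it, recording which in the diagnostics. Near the
  transition Fs ≈ 0 and the main term alone is accurate, so the fallback
  costs nothing measurable in mollified error.
- **Clamping.** A combined probability that lands outside (0, 1) — the
  correction can exceed the main term at extreme parameters — is clamped
  into [10⁻³⁰⁰, 1−10⁻¹⁶] with a `clamped` diagnostic rather than raising,
  to keep batch scans running.
- **Dispatch.** `fs_auto` uses the exact oracle below n = 50 (where it is
  effectively free) and the estimator above; the threshold is a keyword.

## Alignment summaries

θπ is the average pairwise difference 2·Σᵢ<ⱼ dist(Dᵢ,Dⱼ)/(n(n+1)) by
default. That denominator is the one printed alongside this statistic's
source; the conventional unbiased mean over C(n,2) pairs divides by
n(n−1) instead and is available as `convention="tajima"`. The two differ
by a factor (n+1)/(n−1) (~2% at n = 100) — neither is silently
"corrected", and callers comparing against other software will usually
want `tajima`. Sequences are uppercased with U read as T. The default
pairwise-deletion policy skips, per pair, columns where either sequence
has a character outside A/C/G/T; `strict` raises on any such character.
Allele identity is string identity of normalized sequences, so gaps do
distinguish alleles (two haplotypes differing only by an indel are
different alleles) while never counting toward distance under
pairwise-deletion.

## Validation harness

Accuracy is measured by the mollified error
δ = |Fs − F̃s| / max(|Fs|, 1): relative error except near the transition,
where Fs → 0 and relative error is meaningless. `run_table1` recomputes
the seven published benchmark rows with both engines; `run_sweep` draws
(n, m, θ) from the published protocol (n uniform on [50, 500], m on
[2, n], θ on [1, 50]) with a single seeded generator, drawing in the
fixed order n, m, θ so runs are byte-reproducible; the baseline is this
package's exact oracle. The deterministic accuracy grid (n ∈ {100, 500},
m = round(f·n) for f ∈ {0.1, …, 0.9}, θ ∈ {10, 20, …, 500}; 900 points)
yields a maximum mollified error of ~3.6 × 10⁻⁴, with every point below
10⁻³. Timing comparisons are never asserted in tests
(hardware-dependent).

Problem sizes in the default test run are chosen to keep the whole suite
in seconds: sweeps of a few hundred points instead of the published
10 000, and exact-oracle cross-checks at n ≤ 30 where rational
arithmetic is instant. Since every sweep point is an independent draw
from the same parameter distribution, the scaled-down fraction-accurate
summaries estimate the same quantity with wider confidence bands.

## What the synthetic inputs do and do not show

All inputs here are parameter triples or toy alignments; the package
needs no external data. The sweep emulates the published benchmark's
parameter distribution, not real sequence data: real alignments bring
recombination, sequencing error, missing data and selection, which
affect the *interpretation* of Fs but not its computation. Passing tests
therefore demonstrate numerical correctness of the statistic given
(n, m, θπ), not the statistical power of Fs on any particular organism.

## Known limitations

- One published worked example of the complementary branch could not be
  reproduced from its stated inputs by exact rational arithmetic; the
  package reports the mathematically implied values for those inputs
  (the branch logic the example illustrates is tested on verifiable
  parameters instead).
- Only the first-order correction is implemented; no higher-order terms
  of the expansion, and no inversion (recovering θ from a target S' or
  Fs).
- The exact oracle refuses n > 20 000; the estimator has no such ceiling
  but its error is only characterized here for n ≤ 2001 against the
  oracle.
- m = 1 yields Fs = +∞ by convention; downstream code must handle the
  sentinel.
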