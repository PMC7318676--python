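# Methods

## The model

Nucleoside phosphorylases catalyze the reversible phosphorolysis of a
nucleoside into its free base and a pentose-1-phosphate. A transglycosylation
couples two such half-reactions in one pot:

    I.   N1 + P  ⇌  B1 + P1P        K1 = [B1][P1P] / ([N1][P])
    II.  N2 + P  ⇌  B2 + P1P        K2 = [B2][P1P] / ([N2][P])

Half-reaction I cleaves the sugar donor N1 (e.g., uridine); half-reaction II,
run in reverse, glycosylates the acceptor base B2 to give the product
nucleoside N2. K1 and K2 are *apparent* equilibrium constants — valid only at
the temperature, pH and buffer at which they were measured — and the package
carries that metadata alongside each constant. The observable of interest is
the yield, the product formed relative to the starting acceptor base B2_0.

Phosphate is catalytic (consumed in I, released in II), but it is not
innocent: any phosphate present at equilibrium holds some sugar hostage as
P1P and phosphorolyzes product. The model captures both regimes:

**Ideal yield (closed form).** In the vanishing-phosphate limit the P and P1P
terms cancel and the net reaction N1 + B2 ⇌ B1 + N2 with constant
K_N = K1/K2 alone fixes the equilibrium. With x the product formed,

    K_N = x² / ((N1_0 − x)(B2_0 − x))

is a quadratic with exactly one root in [0, min(N1_0, B2_0)]. We compute it
as x = K_N·N1_0·B2_0 / q with q = (K_N(N1_0+B2_0) + √disc)/2, which is the
feasible root for every K_N and is free of subtractive cancellation (the
"minus" branch written as a difference loses all digits when K_N is large or
the pools are very unequal). When |K_N − 1| < 1e-9 the quadratic degenerates
and the exact linear solution x = N1_0·B2_0/(N1_0+B2_0) is used instead.

**Full equilibrium (numerical).** At finite phosphate all six species are
unknowns. We parametrize the state by two reaction extents — ξ₂, the product
formed, and δ = ξ₁ − ξ₂, the net P1P accumulated — so that the four linear
conservation laws (donor pool, acceptor pool, ribose, phosphorus) hold
*exactly by construction* for any (δ, ξ₂), and only the two equilibrium
quotients remain to be enforced. Solving in δ rather than ξ₁ matters
numerically: near the zero-phosphate limit both P and P1P are tiny while the
extents are O(1), and forming them as ξ₁ − ξ₂ would lose every significant
digit to cancellation.

For fixed ξ₂ the K1 constraint is a quadratic in δ whose residual is strictly
increasing on the feasible bracket, so it has a unique feasible root (closed
form, with a monotone-bisection fallback for degenerate coefficients). The
outer K2 residual is then a monotone function of ξ₂ bracketed on
[−N2_0, B2_0] with opposite signs at the ends; Brent's method finds the root.
A final 2×2 Newton polish in extended precision (`numpy.longdouble`) pushes
both relative quotient residuals to the 1e-12 default tolerance, which plain
float64 cannot always reach when one constant is very small (the residual,
measured against its own tiny terms, is limited by the ulp resolution of the
extent). Extents may be negative when product or P1P is supplied initially —
the net reaction then relaxes in reverse; the usual synthetic setup
(B1_0 = N2_0 = P1P_0 = 0) uses only the non-negative part of the domain.

A system containing no phosphorus at all (P_0 = P1P_0 = 0) cannot react; the
solver returns the initial state unchanged. The ideal yield is deliberately
*not* that frozen state but the catalytic limit P_0 → 0⁺, and
`yield_vs_phosphate` reports a requested loading of exactly 0 as that limit.
Uniqueness of the feasible root is an empirical assertion (verified against a
brute-force residual-minimizing grid search on random systems), not a proof;
a residual above tolerance raises `ConvergenceError` rather than returning a
near-miss.

## Reaction design

All inversions exploit monotonicity. Donor-for-target-yield in the ideal
regime is analytic: N1_0 = x + x²/(K_N(B2_0 − x)) with x = target·B2_0. At
finite phosphate the smallest sufficient donor is found by bisection on the
full solver (to 1e-9 mM). Because donor phosphorolysis keeps generating P1P,
the yield tends to 1 as the donor excess grows without bound even at high
phosphate, so every target below 1 is *eventually* reachable; the search is
capped at 1e4 donor equivalents — far beyond synthetic sense — and a target
above the cap yield raises an infeasibility error carrying that yield.

The phosphate budget (largest loading whose yield loss stays within a given
number of percentage points) is likewise bisected; the gap saturates at
100·ideal_yield, so a budget no loading can exceed returns an infinite
sentinel (comparable, unlike an exception, when tabulated). The probe stops
at 1e6 equivalents, far past saturation. The yield landscape enumerates
K1 × K2 × donor × phosphate grids in lexicographic order as a long-format
table, one observation per row, ideal rows flagged separately.

Units: all concentrations in mM; "equiv" always means multiples of the
starting acceptor base B2_0.

## Constant fitting

`fit_constants` minimizes the sum of squared differences between measured and
model-predicted *yield fractions* over (log K1, log K2). Yields are the
observable that endpoint HPLC reports and are comparable in scale across
conditions, so uniform weighting is the default (per-record weights are
accepted). Log-parametrization enforces positivity with bounds
K ∈ [1e-6, 1e3]; the optimizer (`scipy.optimize.least_squares`, trust-region
reflective) is started from a coarse 3×3 log₁₀-grid and polished from the
three most promising corners, stopping early on a numerically perfect fit.

Identifiability: the ideal-yield level pins down only the ratio K_N, and the
phosphate response separates K1 from K2. With every record at a single
phosphate level and both constants free, the likelihood has a ridge; the
fitter raises `IdentifiabilityError` instead of returning an arbitrary point
on it. Fixing K1 (donor constant known independently) restores
identifiability from one level.

Uncertainty is a case-resampling bootstrap over records with percentile
intervals — no parametric error model is assumed, matching the fact that the
measurement error of endpoint HPLC yields is not characterized here.
Resamples that fail to fit are skipped and counted; more than 20 % failures
aborts.

## The synthetic-measurement generator

`simulate_measurements` emulates endpoint HPLC yield determinations: the true
equilibrium yield of each condition (default 60 °C, pH 9) is perturbed by a
mean-one multiplicative lognormal factor with coefficient of variation
`noise_cv`, then clipped to [0, 1]. The default recovery-study design mirrors
the reference experiments: one donor level at 2 equivalents (1 mM donor,
0.5 mM base) and a phosphate ladder of 0.2, 1 and 10 equivalents, 3
replicates, 5 % CV.

What the generator does *not* emulate — and hence what passing recovery tests
do not demonstrate about real data: systematic HPLC calibration error,
incomplete equilibration (kinetic shortfall), enzyme-mediated side reactions
(e.g., slow nucleoside hydrolysis), phosphate speciation shifts with pH, and
condition-to-condition drift of the apparent constants. Parameter-recovery
results quantify only the statistical identifiability of (K1, K2) under the
stated design and noise model. At that design, K2 (which controls the
phosphate response directly) is recovered with a median relative error of
roughly 5–7 %, while K1 — identified only through the combination of ratio
and response — carries roughly 9–14 % median error across independent
100-seed batches.

## Numerical choices

- Solver residual tolerance 1e-12 (relative, each quotient normalized by its
  largest term), iteration cap 200; both configurable.
- Brent root-finding at xtol 1e-15; design bisections to 1e-9 mM.
- Ties and degeneracies: K_N within 1e-9 of 1 → linear ideal-yield formula;
  zero-width inner bracket → boundary extent; endpoint root of the outer
  residual short-circuits the search.
- Problem sizes in the test suite — 100 systems for oracle comparisons,
  200–1000 for conservation and monotonicity sweeps, 100 seeds for the
  recovery study, 100 bootstrap resamples — were chosen to make the suites
  statistically meaningful while keeping a full run in the low minutes.

## Known limitations

- No kinetics: the model says nothing about time to equilibrium or enzyme
  loading, and the phosphate budget trades off against reaction speed in a
  way only the yield side of which is modeled.
- Apparent constants are taken as given at fixed temperature/pH; no
  activity-coefficient, ionic-strength or phosphate acid–base corrections.
- Yield convention is product formed over B2_0 even when the donor limits,
  which matches how transglycosylation yields are reported.
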