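# Methods

## The models

All three models are covariance-structure models for the family variable
vector (NT_p, T_p, NT_m, T_m, Y_o) — Model 2 with parental phenotypes adds
(Y_p, Y_m) — under the standard path-tracing rules, with assortative mating
represented by a copath between the parental phenotypes. Every expected
variance and covariance is a polynomial in the free structural parameters

| symbol | meaning | units |
|---|---|---|
| δ | effect of a haplotypic PGS on the phenotype | trait per PGS unit |
| a | effect of a haplotypic latent genetic score (LGS) | trait per LGS unit |
| f | vertical-transmission path Y_parent → F_offspring | dimensionless |
| μ | AM copath, cov(Y_p, Y_m)/V_Y² | 1/V_Y² |
| V_ε | residual (unique-environment) variance | trait² |

plus the base-population constants k and j (haplotypic PGS and LGS
variances before any AM or VT). k is fixed by the user's scaling
convention: 1/2 if the full PGS is standardized in the base population,
1/2 − 2g if it is standardized in the current generation, 1/2 − g if each
haplotypic score is scaled to variance 1/2 now; j is defined analogously
from h. Parameter estimates other than δ (whose scale follows the score)
are invariant to this choice, which the test suite verifies.

The derived quantities obey nonlinear constraints that are solved, not
estimated: the AM-induced (co)variances g = Ω²μ, h = Γ²μ = g a²/δ²,
i = ΩΓμ = √(gh); genetic nurture w = 2fΩ(1 + μV_Y) and v = wa/δ;
V_F = 2f²V_Y(1 + μV_Y); and the phenotypic variance identity
V_Y = V_A + V_F + 2(av + δw) + V_ε with V_A = 2a²(j+2h) + 2δ²(k+2g) + 8aiδ.

Since μ is neither the spousal covariance nor the spousal correlation and
is unintuitive, the user-facing parameterisation is the spousal
correlation r_mate = μV_Y; μ is recovered inside the fixed point. Both are
reported.

## Fixed-point solution and its use inside the likelihood

Because Ω depends on w, w on Ω, V_F on V_Y and so on, the whole derived
system is solved by successive substitution from null start values
(g = h = i = w = v = 0, V_Y = 2δ²k + 2a²j + V_ε), iterating all quantities
together until the largest absolute change falls below 1e-12 (at most
10 000 iterations; non-convergence is flagged, divergence of V_Y raises an
error naming the offending parameter combination). One iteration
corresponds to one generation of AM + VT acting on the previous
generation's moments, so truncating the iteration (`tol=0, max_iter=g`)
yields the approach-to-equilibrium trajectory; for realistic parameter
values the system is within half a percent of its fixed point by
generation 10, and typically by generation 5–7. After convergence a single
consistency pass re-expresses every derived quantity as an exact function
of the final V_Y, so the equilibrium identities hold to 1e-10 or better at
the reported state. The stopping tolerance of 1e-12 (rather than a looser
1e-10) exists precisely so that this pass leaves the V_Y identity intact.

Estimation re-architects the usual constrained-SEM setup as a nested
procedure: the outer optimizer (Nelder–Mead on transformed, unbounded
scales: f = 0.95·tanh, r_mate = 0.95·tanh, V_ε = 1e-6 + exp, δ and a raw)
moves only the free parameters, and each likelihood evaluation solves the
fixed point exactly, which enforces the constraints by construction. Five
starts are used — one moment-based (θ̂_NT/θ̂_T for f, θ̂_T − θ̂_NT for δ,
the observed spousal correlation or the trans-covariance-implied one for
r_mate) plus four jittered copies — and the best optimum is kept, ties
broken by the smaller parameter norm. The likelihood is even in a, so |a|
is reported.

The likelihood itself is full-information: families are grouped by
missingness pattern, each pattern reduced to its scatter matrix, and each
contributes the zero-mean multivariate-normal log-density of its observed
variables (data are centred per variable first; the models are
covariance-structure-only, means fixed at zero). This makes the cost of an
evaluation independent of sample size and handles designs as sparse as
"two variables per family" — provided every variable pair occurs, all 28
moments are informed and the estimates match complete-data fits with
wider standard errors. Non-positive-definite implied matrices return a
penalised objective so the optimizer retreats.

Standard errors come from the numerically differentiated observed
information at the optimum, with delta-method propagation to the derived
quantities (V_F, w, v, V_A, ...; these are reported but flagged as
derived); a family-level bootstrap (resample, refit from the point
estimate) is available as an alternative and as the fallback when the
information matrix is singular.

Model 2 can be fitted without parental phenotypes by assuming the
base-population heritability of the standardized trait: a² = h²_base − δ²,
substituted during optimisation with δ bounded by |δ| < √h²_base. An
optimum pinned at that bound means no admissible a exists and the fit
raises. Setting h²_base too high biases w and V_F downward (and vice
versa), which the tests assert as a sign, not a magnitude.

## AM regimes

The equilibrium regime assumes enough generations of assortment that cis
(within-person) and trans (across-mate) score covariances are equal. The
disequilibrium regime models a single recent generation of assortment by
zeroing cis g, h, i in within-person terms while keeping the μ-mediated
trans covariances (= Ω²μ etc.). It is exposed as a flag, not a separate
model. One simplification: a single V_Y is used for parents and offspring
in this regime, ignoring the offspring-generation variance inflation that
one round of AM produces; the mechanism tests do not depend on this, but
disequilibrium-mode point estimates should be read as first-order.

## Mechanism tests

The four haplotypic score variances (minus k) and six covariances give ten
estimates of g — six cis, four trans. Two Wald χ²(1) statistics are
formed from plain group averages (the average is a fixed linear
combination, so the statistic is calibrated even though the ten estimates
are strongly dependent): the average of all available estimates against
zero (primary-AM signal; a one-sided version is also reported since the
alternative is g > 0), and cis-average minus trans-average (equilibrium
check; trans > cis indicates recent-onset assortment). The sampling
covariance of the ten comes from a family-level nonparametric bootstrap
(default 500 replicates, seeded), implemented as multinomial resampling
weights applied to per-family product columns. The single-generation-AM
verdict requires trans significantly positive and cis not significantly
different from zero, each at α = 0.05; no multiplicity correction is
applied across the battery, which is reported jointly and labelled.

For scores scaled in the current generation the variance-based estimates
need k while k = 1/2 − 2g needs g; the one-dimensional consistency
equation (mean of the six cis estimates equals g) is solved jointly in
closed form. For base-standardized scores, k is the known base variance;
if it is genuinely unknown the variance-based estimates are excluded with
a warning and the tests run on the remaining six.

The homogamy diagnostic recovers μ from g = Ω²μ (Ω estimated from
cov(Y_*, [N]T_*)) and compares the implied spousal covariance μV_Y² with
the observed cov(Y_p, Y_m); a bootstrap CI on the difference gates the
direction label (observed > implied: social-homogamy-like; observed <
implied: genetic-homogamy-like).

## The simulator

The forward-time engine is the oracle for every analytic expectation. The
base generation draws haplotypes at m_obs observed plus m_lat latent
biallelic loci, independent within and across individuals (linkage
equilibrium), with allele frequencies uniform on the configured interval
(default 0.1–0.5; defaults m_obs = m_lat = 50). Per-locus weights are
standard normal, rescaled so each realised base-generation haplotypic
score variance is exactly 1/2 — making k = j = 1/2 exact constants rather
than estimates. Scores are raw weighted allele counts (uncentred);
estimators centre the data, and the exported weight table reproduces the
internal scores exactly.

Each generation: spouses are paired by matching phenotype ranks to a
bivariate Gaussian copula sample with the target correlation (exact in
expectation for near-normal phenotypes; no iterative rejection), each
couple produces exactly two offspring (constant population size, one of
each sex, deterministic halves), transmission is fair Mendelian sampling
with free recombination across loci, the familial environment is
F_o = f(Y_p + Y_m), and Y = δ(PGS₁+PGS₂) + a(LGS₁+LGS₂) + F + ε with ε
drawn at the configured V_ε, held constant across generations. `am_onset`
delays assortment to a chosen mating event, which produces the
disequilibrium (trans-without-cis) scenario when set to the final one.
Haplotype 1 is always the paternally derived gamete, so T/NT scores are
read off directly and the exported trio VCF is phased paternal|maternal.

What the generator does not emulate: linkage/LD maps, selection, mutation,
sibling effects, sex-specific effects, parent-of-origin effects,
population stratification, and genotyping error. Passing tests therefore
demonstrate correctness of the estimators under the models' own
assumptions, not robustness to these real-data complications.

One real consequence of the finite design surfaced during validation:
when the entire simulated population is used as the sample, families share
the finite causal-locus panel and, after a few generations, pedigree
ancestors, so the ten g moments acquire a common fluctuation that a
family-level bootstrap cannot see and the χ² tests over-reject. Study
samples are therefore drawn from a larger simulated population
(`extract_family_table(..., n_sample=...)`) when calibration is the
question — matching the real-data situation of a cohort sampled from a
much larger population. With that design both tests hold their nominal
5% level.

## Problem sizes and numerical choices

Oracle comparisons of the implied covariance matrices use 200 000 families
per parameter set with a 4-Monte-Carlo-SE criterion per entry, run for 25
generations (the population converges more slowly than the recursion);
replicate studies of estimator bias use 100 replicates of 5 000 families;
test calibration uses 500 null replicates of 5 000 families sampled from
20 000; 30 loci per score suffice for moderate parameter sets because only
score moments matter and the weights are rescaled exactly. The analytic
expectations are infinitesimal-model results: with m causal loci the
equilibrium AM-induced variance falls short of them by O(1/m), a deficit
of roughly 1% of V_Y at 30 loci (and ~0.3% at 100) for the strongest
parameter set examined, which is why that comparison runs with a denser
panel (100 loci per score, 30 generations). These sizes are the package's chosen
study conditions; the same code scales to larger runs. Fixed-point
tolerance 1e-12; optimizer xatol 1e-7, fatol 1e-10, maxfev 6000; hessian
steps 1e-4·max(|θ|, 0.05); all random streams are seeded and reproducible.

## Known limitations

Bivariate/cross-trait extensions, sibling (horizontal) transmission,
parent-of-origin effects, separate parent/offspring δ, latent-trait
social/genetic homogamy models (only the diagnostic direction is given)
and IBD detection/statistical phasing for real data are out of scope.
Unphased trios are supported through Mendelian deduction; triple-
heterozygous sites are irreducibly ambiguous and either split between T
and NT (unbiased for the sums, attenuates the T/NT contrast) or dropped.
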