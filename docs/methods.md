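# Methods

## The model

Each contact group is a closed, randomly mixing population following SIR
dynamics.  Individual *j*'s force of infection is
`lambda_j = beta * exp(G_z) * exp(g_j) * sum_i exp(f_i)`, the sum running
over currently infected group members; its infectious duration is gamma
distributed with mean `1/(gamma * exp(r_j))` and shape `k`.  The log-scale
trait deviations decompose as `g = g_SNP + X b_g + eps_g` (likewise f, r):
a SNP term mapping genotype to `+a`, `a*Delta`, `-a` for AA, AB, BB;
optional fixed effects; and residuals drawn multivariate normal with a
3×3 covariance `Sigma` shared across the three traits, independent across
individuals.  `G_z ~ N(0, sigma_G^2)` is a per-group random effect on the
transmission rate.

Key modelling conventions, stated once because the literature is not
uniform about them:

* **Transmission is density dependent exactly as written** — the
  infectivity sum is not divided by group size.  `beta` is therefore a
  per-pair rate, and the basic reproduction number convention used
  everywhere in this package is `R0 = beta * G_size / gamma` at baseline
  traits.
* **Time unit**: `gamma = 1` by default, so one time unit is the mean
  baseline infectious period.
* **Seeders** are infected at t = 0 and are epidemiologically identical to
  contacts; their infectious periods start at t = 0.  Simulations run to
  epidemic extinction (no censoring).

## Analytic precision

For small effects and fully observed infection/recovery times, the
marginal likelihood of `(a_g, a_f)` is approximately Gaussian with the
2×2 information matrix

```
M = N_group*phi*N_cont * [[<H_cont> - <chi_cont>^2, Var(chi_cont)],
                          [Var(chi_cont),           Var(chi_cont)]]
  + N_group*N_seed *     [[0, W], [W, 2W + Y]]
```

with `W = -log(h) <(chi_cont - <chi_cont>)(chi_seed - chi_cont)>` and
`Y = (1-h)<(chi_seed - chi_cont)^2>
     - (N_seed/(phi N_cont)) log(h)^2 <chi_seed - chi_cont>^2`.
SDs are the square roots of the diagonal of `M^{-1}`, computed by direct
2×2 inversion rather than from a scalar expansion: the widely quoted
expanded form of SD(a_f) carries a sign error on its `Var(chi_cont)` term
(with a minus sign the optimal two-group mixed design would have negative
information; inversion gives the plus sign and reproduces every
design-specific closed form to machine precision, which the test suite
asserts at relative error < 1e-6).

Recoverability decouples:
`SD(a_r) = 1/sqrt(k N_group (N_seed + phi N_cont)(Hbar - chibar^2))`,
where `Hbar, chibar` average the composition over the final infected
population (seeders plus the `phi` fraction of contacts).  Dominance
factors have the analogous expressions with homozygosity `H` in the role
of the balance `chi` and a `1/|a|` prefactor — dominance is not estimable
when the additive effect vanishes, or when the contacts contain no
heterozygotes.

Numerical conventions in the analytic layer:

* Group averages `<.>` are contact-count (seeder-count) weighted, which
  coincides with the unweighted average for the equal-sized groups of all
  canonical designs; `Var(.)` is the population (divide-by-N) variance
  across the distinct groups of one replicate, so replication changes no
  summary and scales every SD by exactly `replicates^(-1/2)`.
* Any non-positive expression under a square root (non-identifiable
  design, or the small-effect approximation breaking down) maps to `+inf`
  with a structured `NonEstimableWarning`, never an exception, so
  optimisers can traverse bad regions.
* A design with zero seeders is accepted as the idealised limit in which
  the `N_seed*W`, `N_seed*Y` products vanish; this is the form in which
  the mixed-design closed form is quoted.
* Complete dominance is handled by recoding (`recode_complete_dominance`):
  heterozygotes merge into the dominant homozygote class, after which the
  no-dominance machinery applies.  Intermediate dominance precision is
  available through the simulation/fit route, not analytically.
* `phi` is one experiment-wide scalar; it can be supplied directly or
  derived from `R0` via the deterministic final-size fixed point
  `phi = 1 - exp(-R0*(h0 + (1-h0)*phi))`, solved by damped fixed-point
  iteration to 1e-10 with a bisection fallback.

## Optimal designs

The optimizer minimises the analytic SD of `a_f` (the hardest parameter,
being an indirect effect) by bounded scalar search on the smooth closed
forms (tolerance 1e-4 in the argument; no stochastic optimiser is
needed).  The recovered optima: seeder fraction `h* = 0.47` for the
four-group pure design; contact balance `chi* = 1/sqrt(2)` (≈ 85%/15%
AA/BB) for the two-group mixed design; for the single group the numerical
argmin of the seeder fraction is ≈ 0.141 on an extremely flat objective
(< 0.5% above the value at the conventionally quoted 0.15 — tests assert
the flatness, not a sharp location).  For the single group the contact
balance trades susceptibility against infectivity precision; the
recommended compromise `chi_cont = 0.8` is reported as a heuristic
together with the point where the two precisions are exactly equal.
Mixed designs default to 3 seeders per group: the mathematical optimum is
the zero-seeder limit, but a couple of seeders are needed to make
epidemic extinction (probability ≈ `(1/R0)^N_seed`) unlikely.

Integer designs are realised from the ideal proportions by
largest-remainder rounding within each role; the realised (not target)
composition is what the summaries report.

## Published coefficient table

`table3_report` evaluates the general pipeline on the five idealised
blueprints (phi = 1; zero-seeder limit for mixed) and reports each SD as
a coefficient of `1/sqrt(N_total)` (or `1/sqrt(k N_total)`,
`1/(|a| sqrt(N_total))`), rounded to 2 d.p.  The nine-group dominance
design reproduces the `sqrt(3/2)` inflation of the pure-design a_f
coefficient (2.40 = 1.96·1.22) directly from the general expressions.
Known discrepancies with the published table, retained as-computed rather
than tuned: the single-group a_g (general expression gives 1.81 at the
quoted composition, published 1.08) and a_r (1.18 vs 1); the
mixed-dominance a_g (1.71 vs 1.73) and the dominance-row Delta_f/Delta_r
entries for the mixed design and Delta_r for the pure design (the
published values appear to carry an additional joint-estimation factor
whose derivation is not in the main text).

## Simulator

The simulator is event-driven and exact: recovery times are scheduled at
the moment of infection (gamma durations make the process
non-Markovian), and between events the total infection hazard is
constant, so the next infection is an exponential race against the
earliest scheduled recovery, with the infectee chosen proportional to
`exp(g_j)`.  Same seed, same event table, bit for bit.

The synthetic experiments it generates emulate the idealised study
conditions under which the analytic expressions were derived: exactly
known infection and recovery times, closed groups, exchangeable
individuals within genotype class, and optional group effects, fixed
effects and correlated residuals.  They do not emulate censored or
periodically observed data, between-group contact, pedigree/relatedness
structure, or seeders that behave differently from naturally infected
animals — so passing validation here demonstrates correctness of the
method under its own assumptions, not robustness to those real-data
complications.

## Inference and validation

The fitter maximises the complete-data likelihood (quasi-Newton from a
neutral start: effects zero, `beta/gamma/k` from moments; rates on the
log scale).  Standard errors come from the pseudo-inverse of the observed
information (central finite differences, relative step 1e-4); eigenvalues
below 1e-8 of the largest are treated as non-identifiable directions and
surface as SE = +inf.  With flat priors and complete data these MLE +
Laplace quantities are asymptotically equivalent to the Bayesian
posterior mean and SD; full MCMC is deliberately out of scope, as are
latent infection times and residual-trait estimation.  Group effects,
when requested, enter as per-group parameters with a known-`sigma_G`
normal penalty.

Each likelihood evaluation is O(N): because traits take one of three
values per genotype, the infectivity sum collapses to three occupancy
counts, and the per-class exposure integrals are precomputed once from
the event table.

`validate_precision` simulates many experiments, fits each, and compares
three numbers per parameter: the empirical SD of the estimates, the mean
model-based SE, and the analytic SD with `phi` plugged in from the mean
realised infected fraction (removing final-size approximation error from
the comparison).  Problem sizes used in the shipped validation tests —
200 replicates of a 1000-animal pure design, 400 replicates of a
400-animal pure design for interval coverage, 100 replicates of a
500-animal single group — were chosen as the smallest sizes at which the
Monte-Carlo error is comfortably below the tolerances being asserted.
Validation epidemics use `R0 = 10` (so `phi ≈ 1`, the regime in which the
published coefficients are quoted), `k = 1`, and small effects
`a = 0.2`; the branching-approximation extinction check uses `k = 1`,
where the geometric-offspring result `(1/R0)^N_seed` is exact.

## Known limitations

* The analytic SDs assume small effects; for large effects they are
  conservative (they overstate the SD, most visibly for `a_f` in
  low-information designs), which the test suite asserts directionally.
* SI/SEIR variants, environmental transmission, open groups and
  diagnostic-test observation models are out of scope.
* The per-group `phi` is a single scalar; designs whose groups differ
  strongly in expected final size are summarised by one average.
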