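# sirdesign

Design and power analysis of disease transmission experiments for
estimating the effects of a SNP — or any categorical factor such as
vaccination status, breed, line or sex — on the three host traits that
govern epidemic spread: **susceptibility** (risk of acquiring infection),
**infectivity** (propensity to transmit it) and **recoverability**
(propensity to recover or die, the inverse mean infectious period in an
SIR model).

It is aimed at quantitative geneticists and epidemiologists planning
challenge experiments in livestock or aquaculture: given a proposed
allocation of genotypes to seeder (initially infected) and contact
(initially susceptible) animals across closed contact groups, the package
answers "how precisely will each effect be estimated?" and "what
allocation would estimate them best?".

## Model

Within each contact group, individual *j* is infected with force

```
lambda_j = beta * exp(G_z) * exp(g_j) * sum_{i infected} exp(f_i)
```

and, once infected, stays infectious for a gamma-distributed time with
mean `1/(gamma * exp(r_j))` and shape `k`.  The log-scale deviations
`(g, f, r)` carry the SNP effect: `+a` for genotype AA, `a*Delta` for AB,
`-a` for BB, where `a_g, a_f, a_r` are half the AA–BB trait differences
and `Delta` is the scaled dominance factor.

With infection and recovery times observed and effects small, the
precision (posterior SD) of the estimates has closed analytic form.  For
`(a_g, a_f)` it is the inverse of a 2×2 Fisher information matrix built
from just a handful of design summaries per group — the homozygosity `H`
(proportion AA+BB), the homozygote balance `chi` (proportion AA − BB) of
seeders and contacts, the seeder fraction of the final infected
population `h = N_seed/(N_seed + phi*N_cont)`, and the fraction of
contacts ultimately infected `phi`.  Recoverability decouples:
`SD(a_r) = 1/sqrt(k * N_group * (N_seed + phi*N_cont) * (Hbar - chibar^2))`.

Maximising these precisions yields three named design families — a
**single-group** design (~15% all-BB seeders, contacts ~90/10 AA/BB), a
multi-group **pure** design (47% seeders; genotypically uniform seeder and
contact sets, combinations permuted across four groups, nine when
dominance is of interest) and a multi-group **mixed** design (very few
seeders; complementary ~85/15 contact mixtures across two groups,
`chi_cont = ±1/sqrt(2)`) — all reproduced by the optimizer in this
package.

## Worked example

Find the optimal pure design and evaluate its precision for a planned
experiment with 400 animals in four groups of 100:

```
$ sirdesign optimize --design-type pure --out opt.json --design-out pure.json
{
  "objective": "min_sd_af",
  "design_type": "pure",
  "argmin": {
    "h": 0.46986542827927436
  },
  "sd_af": 0.061945494453188456,
  ...
}

$ sirdesign precision --config pure.json --phi 1 --k 1 --out report.json
N_total = 400, phi = 1.0000
  sd_ag = 0.07592
  sd_af = 0.09794
  sd_ar = 0.05
  sd_dg = inf
  ...
```

Reading: the seeder fraction minimising the infectivity SD is `h = 0.47`
(the `sd_af` in the optimizer output is quoted per 1000 animals).  At 400
animals the susceptibility effect `a_g` will be estimated with SD ≈ 0.076
(= 1.52/sqrt(400)), the infectivity effect `a_f` with SD ≈ 0.098
(= 1.96/sqrt(400)) — infectivity is always the hardest, being an indirect
effect — and the recoverability effect `a_r` with SD = 0.05
(= 1/sqrt(400) at k = 1).  The dominance SDs are infinite because this
design contains no heterozygotes.

The same quantities are available from Python:

```python
from sirdesign import canonical_design, PrecisionInputs, precision_report

design = canonical_design("pure", g_size=100)
report = precision_report(design, PrecisionInputs(phi=1.0, k=1.0))
print(report.sd_af)           # 0.0979...
```

The simulator and fitter close the loop: `sirdesign simulate` draws
stochastic epidemics from the model above, `sirdesign fit` recovers the
parameters by maximum likelihood with observed-information standard
errors, and `sirdesign validate` repeats that over many simulated
experiments and tabulates empirical SD vs mean model SE vs analytic SD.

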