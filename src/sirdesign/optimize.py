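"""Numerical optimisation of transmission-experiment designs.

The objective throughout is the analytic SD of the infectivity SNP effect
a_f, the hardest of the three traits to estimate: for a single group and
for the pure design the seeder fraction h is tuned; for the mixed design
the contact genotype mix chi_cont.  The closed forms are smooth in one
scalar, so bounded (Brent) scalar search suffices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .design import ExperimentDesign, canonical_design, summarize_design
from .precision import (
    INF,
    NonEstimableWarning,
    PrecisionInputs,
    PrecisionReport,
    precision_report,
    sd_closed_form,
    sd_snp_effects,
)

__all__ = [
    "OptimizationResult",
    "optimize_seeder_fraction",
    "optimize_contact_mix",
    "compare_designs",
]

#: Fewest seeders worth using in mixed designs: the mathematical optimum is
#: N_seed -> 0 but a couple of seeders are needed to reliably start an
#: epidemic (extinction risk grows as (1/R0)^N_seed).
MIN_SEEDERS_MIXED = 3


@dataclass(frozen=True)
class OptimizationResult:
    objective: str
    design_type: str
    argmin: dict
    sd_af: float
    extras: dict = field(default_factory=dict)
    trace: tuple = ()

    def as_dict(self) -> dict:
        return {
            "objective": self.objective,
            "design_type": self.design_type,
            "argmin": self.argmin,
            "sd_af": self.sd_af,
            "extras": self.extras,
        }


def _minimize_scalar_traced(fun, lo, hi, xatol=1e-6):
    trace: list[tuple[float, float]] = []

    def wrapped(x):
        v = fun(x)
        trace.append((x, v))
        return v

    res = minimize_scalar(
        wrapped, bounds=(lo, hi), method="bounded", options={"xatol": xatol}
    )
    return float(res.x), float(res.fun), tuple(trace)


def optimize_seeder_fraction(
    design_type: str,
    n_total: float = 1.0,
    *,
    phi_of_h=None,
) -> OptimizationResult:
    """Seeder fraction h minimising the closed-form SD(a_f).

    For the pure design the optimum is h* = 0.47; for a single group the
    objective is extremely flat around its minimum near h ~ 0.14-0.15.
    ``phi_of_h`` optionally maps the initial seeder fraction to a final
    infected fraction phi < 1 (e.g. from the final-size relation at a given
    R0), in which case the general information pipeline is used instead of
    the phi = 1 closed form.
    """
    if design_type not in ("single", "pure"):
        raise ValueError("seeder-fraction optimisation applies to single/pure")

    if phi_of_h is None:
        fun = lambda h: sd_closed_form(design_type, h, n_total=n_total)
    else:

        def fun(rho: float) -> float:
            phi = phi_of_h(rho)
            g_size = 100.0
            design = canonical_design(
                design_type, g_size=int(g_size), exact=True, n_seed=rho * g_size
            )
            summary = summarize_design(design, phi)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", NonEstimableWarning)
                _, sd_af, _ = sd_snp_effects(summary)
            return sd_af * math.sqrt(summary.n_total / n_total)

    h_star, sd_star, trace = _minimize_scalar_traced(fun, 0.01, 0.99, xatol=1e-4)
    return OptimizationResult(
        objective="min_sd_af",
        design_type=design_type,
        argmin={"h": h_star},
        sd_af=sd_star,
        trace=trace,
    )


def _single_constrained_chi(h: float, chi_seed: float) -> float:
    """chi_cont where SD(a_g) = SD(a_f) for the single-group design.

    SD(a_g) = 1/sqrt(N (1+chi)/2 ... ) -- with all-homozygote contacts,
    <H_cont> = 1 and the susceptibility information is N_cont(1 - chi^2);
    equate with the Eq.-14 infectivity information and solve for chi in
    (chi_heuristic, 1)."""

    def gap(chi: float) -> float:
        info_g = (1.0 - h) * (1.0 - chi * chi)
        base = h * (1.0 - h) - h * h * math.log(h) ** 2 / (1.0 - h)
        info_f = base * (chi_seed - chi) ** 2
        return info_g - info_f

    lo, hi = 0.0, 1.0 - 1e-9
    if gap(lo) * gap(hi) > 0:  # constraint never binds
        return float("nan")
    return float(brentq(gap, lo, hi, xtol=1e-10))


def optimize_contact_mix(design_type: str) -> OptimizationResult:
    """Optimal contact genotype mix for a design family.

    mixed            minimises (1-chi^2)chi^2 information inverse: the
                     optimum is chi* = 1/sqrt(2), i.e. ~85%/15% AA/BB in
                     group 1 (mirrored in group 2);
    single           reports the recommended heuristic chi_cont = 0.8
                     (trading a_f precision for finite a_g information)
                     together with the chi where SD(a_g) = SD(a_f) binds;
    mixed_dominance  grid search over homozygote fraction and permutation
                     structure, returning the 80/10/10 cyclic blueprint.
    """
    if design_type == "mixed":
        fun = lambda chi: sd_closed_form("mixed", 0.0, chi_cont=chi)
        chi_star, sd_star, trace = _minimize_scalar_traced(fun, 1e-6, 1.0 - 1e-6)
        aa = (1.0 + chi_star) / 2.0
        return OptimizationResult(
            objective="min_sd_af",
            design_type="mixed",
            argmin={"chi_cont_1": chi_star},
            sd_af=sd_star,
            extras={
                "prop_AA_group1": aa,
                "prop_BB_group1": 1.0 - aa,
                "pct_BB_group1": round((1.0 - aa) * 100.0),
            },
            trace=trace,
        )

    if design_type == "single":
        h, chi_seed, chi_heuristic = 0.15, -1.0, 0.8
        chi_eq = _single_constrained_chi(h, chi_seed)
        sd_at_heuristic = sd_closed_form("single", h, chi_seed, chi_heuristic)
        return OptimizationResult(
            objective="min_sd_af_subject_to_ag",
            design_type="single",
            argmin={"chi_cont": chi_heuristic},
            sd_af=sd_at_heuristic,
            extras={
                "chi_cont_equal_precision": chi_eq,
                "note": "chi_cont = 0.8 is the recommended compromise; "
                "the equal-precision point is also reported",
            },
        )

    if design_type == "mixed_dominance":
        # grid over (proportion of the majority genotype, cyclic permutations);
        # objective: SD(a_f) with Delta information retained (Var(H_cont) > 0)
        best = None
        for p_major in np.linspace(0.5, 0.95, 46):
            rest = (1.0 - p_major) / 2.0
            design = _mixed_dominance_design(p_major, rest)
            summary = summarize_design(design, 1.0, allow_empty_seeders=True)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", NonEstimableWarning)
                _, sd_af, _ = sd_snp_effects(summary)
            if summary.var_H_cont <= 1e-12:  # no dominance information
                continue
            if best is None or sd_af < best[1]:
                best = (p_major, sd_af)
        p_major, sd_star = best
        return OptimizationResult(
            objective="min_sd_dominance",
            design_type="mixed_dominance",
            argmin={"prop_major": float(p_major)},
            sd_af=float(sd_star),
            extras={"blueprint": "cyclic permutations of (0.8, 0.1, 0.1)"},
        )

    raise ValueError(f"unknown design type {design_type!r}")


def _mixed_dominance_design(p_major: float, p_minor: float) -> ExperimentDesign:
    from .design import GenotypeCounts, GroupDesign

    nc = 100.0
    props = [
        (p_major, p_minor, p_minor),
        (p_minor, p_major, p_minor),
        (p_minor, p_minor, p_major),
    ]
    groups = tuple(
        GroupDesign(GenotypeCounts(0, 0, 0), GenotypeCounts(*(x * nc for x in p)))
        for p in props
    )
    return ExperimentDesign(groups)


def compare_designs(
    designs: dict[str, ExperimentDesign] | list[ExperimentDesign],
    inputs: PrecisionInputs,
) -> "pd.DataFrame":
    """Rank designs by SD(a_f) at equal N_total.

    Returns one row per design with the analytic SDs plus the SD ratio and
    squared ratio (relative sample-size requirement) against the best
    design.  All designs must share N_total so ratios are meaningful.
    """
    import pandas as pd

    if not isinstance(designs, dict):
        designs = {f"design_{i}": d for i, d in enumerate(designs)}
    totals = {name: d.n_total for name, d in designs.items()}
    if len(set(round(t, 6) for t in totals.values())) > 1:
        raise ValueError(f"designs must share N_total, got {totals}")

    rows = []
    for name, d in designs.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NonEstimableWarning)
            rep = precision_report(d, inputs)
        rows.append({"design": name, **{k: v for k, v in rep.as_dict().items() if k.startswith("sd_")}})
    out = pd.DataFrame(rows).set_index("design").sort_values("sd_af")
    best = out["sd_af"].iloc[0]
    out["af_ratio_vs_best"] = out["sd_af"] / best
    out["sample_size_ratio_vs_best"] = out["af_ratio_vs_best"] ** 2
    return out
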