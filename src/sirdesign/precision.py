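"""Analytic precision (posterior SD) formulas for SNP effects in
transmission experiments.

With infection and recovery times known and effect sizes small, the
marginal likelihood of the susceptibility and infectivity SNP effects
(a_g, a_f) is approximately Gaussian with a 2x2 Fisher information matrix

    M = N_group * phi * N_cont * [[<H_cont> - <chi_cont>^2,  Var(chi_cont)],
                                  [Var(chi_cont),            Var(chi_cont)]]
      + N_group * N_seed *       [[0,  W],
                                  [W,  2W + Y]],

where the first matrix counts information from the infections observed
during the epidemics and the second information from the seeder/contact
composition contrast early in each epidemic, mediated by the intermediates

    W = -log(h) <(chi_cont - <chi_cont>)(chi_seed - chi_cont)>,
    Y = (1 - h) <(chi_seed - chi_cont)^2>
        - N_seed/(phi N_cont) log(h)^2 <chi_seed - chi_cont>^2,

with h = N_seed / (N_seed + phi N_cont) the seeder fraction of the final
infected population.  Posterior SDs are the square roots of the diagonal of
M^-1.  (The published scalar expansion of SD(a_f) carries a sign typo on
its Var(chi_cont) term; inverting M directly is exact and reproduces every
published closed form.)  Recoverability has the decoupled form

    SD(a_r) = 1 / sqrt(k N_group (N_seed + phi N_cont)(Hbar - chibar^2)),

and dominance factors have analogous expressions with homozygosity H taking
the role of the balance chi.  All SDs scale as N_group^-1/2 and are
independent of the effect sizes themselves (dominance SDs carry a 1/|a|
prefactor).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .design import (
    DesignSummary,
    ExperimentDesign,
    canonical_design,
    summarize_design,
)

__all__ = [
    "PrecisionInputs",
    "FisherInfo",
    "PrecisionReport",
    "DegenerateDesignError",
    "NonEstimableWarning",
    "compute_WY",
    "fisher_gf",
    "sd_snp_effects",
    "sd_dominance",
    "sd_closed_form",
    "gwas_sd",
    "table3_report",
    "precision_report",
    "JOINT_DOMINANCE_FACTOR",
]

INF = float("inf")

#: Inflation of the a_g/a_f/a_r SDs when dominance parameters are estimated
#: jointly alongside them (sqrt(3/2) ~ 1.22).
JOINT_DOMINANCE_FACTOR = math.sqrt(1.5)


class DegenerateDesignError(ValueError):
    """Raised when a quantity diverges for the supplied design (e.g. h = 0)."""


class NonEstimableWarning(UserWarning):
    """A parameter is not estimable from this design; its SD is +inf."""


@dataclass(frozen=True)
class PrecisionInputs:
    """Scalar epidemic inputs of the calculator.

    phi  fraction of contacts ultimately infected, in [0, 1];
    k    gamma shape of the infectious-duration distribution (> 0);
    a_g, a_f, a_r  SNP effect magnitudes, only needed for dominance SDs.
    """

    phi: float = 1.0
    k: float = 1.0
    a_g: float | None = None
    a_f: float | None = None
    a_r: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must lie in [0, 1]")
        if self.k <= 0:
            raise ValueError("k must be positive")


@dataclass(frozen=True)
class FisherInfo:
    """2x2 Fisher information for (a_g, a_f) plus scalar intermediates."""

    M: np.ndarray
    W: float
    Y: float
    W_H: float
    Y_H: float


@dataclass(frozen=True)
class PrecisionReport:
    sd_ag: float
    sd_af: float
    sd_ar: float
    sd_dg: float = INF
    sd_df: float = INF
    sd_dr: float = INF
    method: str = "analytic_general"
    n_total: float | None = None

    def as_dict(self) -> dict:
        return {
            "sd_ag": self.sd_ag,
            "sd_af": self.sd_af,
            "sd_ar": self.sd_ar,
            "sd_dg": self.sd_dg,
            "sd_df": self.sd_df,
            "sd_dr": self.sd_dr,
            "method": self.method,
            "n_total": self.n_total,
        }


def _mean(values, weights) -> float:
    return float(np.average(np.asarray(values, float), weights=np.asarray(weights, float)))


def _wy(summary: DesignSummary, seed_vals, cont_vals, mean_cont: float) -> tuple[float, float]:
    """Shared structure of (W, Y) and (W_H, Y_H): Eqs. for chi resp. H."""
    s, c, phi, h = summary.n_seed, summary.n_cont, summary.phi, summary.h
    # per-group contact counts as weights (equal groups -> unweighted)
    cont_w = np.asarray(summary.cont_counts, float)
    cv = np.asarray(cont_vals, float)
    sv = np.asarray(seed_vals, float)
    diff = sv - cv
    log_h = math.log(h)
    W = -log_h * _mean((cv - mean_cont) * diff, cont_w)
    Y = (1.0 - h) * _mean(diff**2, cont_w) - (s / (phi * c)) * log_h**2 * _mean(
        diff, cont_w
    ) ** 2
    return W, Y


def compute_WY(summary: DesignSummary) -> tuple[float, float]:
    """Seeder-contrast information intermediates W and Y.

    W vanishes for any single-group design (chi_cont equals its average) and
    whenever chi_seed = chi_cont in every group; Y vanishes in the latter
    case too.  Requires h in (0, 1): a design with no seeders has no seeder
    information (the N_seed * W / N_seed * Y products tend to zero) and is
    handled by :func:`fisher_gf` as that limit.
    """
    if summary.n_seed == 0 or summary.h == 0:
        raise DegenerateDesignError("h = 0: W and Y diverge (no seeders)")
    if summary.phi == 0 or summary.n_cont == 0:
        raise DegenerateDesignError("phi * N_cont = 0: Y diverges")
    return _wy(summary, summary.chi_seed, summary.chi_cont, summary.mean_chi_cont)


def _compute_WY_H(summary: DesignSummary) -> tuple[float, float]:
    """Dominance analogues W_H, Y_H (H replaces chi in the W/Y structure)."""
    if summary.n_seed == 0 or summary.h == 0:
        raise DegenerateDesignError("h = 0: W_H and Y_H diverge (no seeders)")
    if summary.phi == 0 or summary.n_cont == 0:
        raise DegenerateDesignError("phi * N_cont = 0: Y_H diverges")
    return _wy(summary, summary.H_seed, summary.H_cont, summary.mean_H_cont)


def fisher_gf(summary: DesignSummary) -> FisherInfo:
    """Fisher information matrix for (a_g, a_f).

    The contact term carries the factor N_group * phi * N_cont (expected
    number of infected contacts); the seeder term the factor
    N_group * N_seed.  A design with no seeders keeps only the contact term
    (the exact N_seed -> 0 limit); a design with phi * N_cont = 0 keeps only
    the seeder term, which contributes no susceptibility information.
    """
    n, s, c, phi = summary.n_group, summary.n_seed, summary.n_cont, summary.phi
    D = summary.mean_H_cont - summary.mean_chi_cont**2
    V = summary.var_chi_cont
    M = n * phi * c * np.array([[D, V], [V, V]])
    if s > 0 and phi * c > 0:
        W, Y = compute_WY(summary)
        W_H, Y_H = _compute_WY_H(summary)
        M = M + n * s * np.array([[0.0, W], [W, 2 * W + Y]])
    else:
        W = Y = W_H = Y_H = 0.0
    return FisherInfo(M=M, W=W, Y=Y, W_H=W_H, Y_H=Y_H)


def _inv_sqrt(x: float, what: str) -> float:
    """1/sqrt(x) mapping non-positive information to +inf with a warning."""
    if x <= 0 or not math.isfinite(x):
        warnings.warn(
            f"{what} is not estimable from this design (information {x:g} <= 0)",
            NonEstimableWarning,
            stacklevel=3,
        )
        return INF
    return 1.0 / math.sqrt(x)


def sd_snp_effects(
    summary: DesignSummary, inputs: PrecisionInputs | None = None
) -> tuple[float, float, float]:
    """Posterior SDs of (a_g, a_f, a_r).

    a_g and a_f come from inverting the 2x2 Fisher matrix; a_r from the
    decoupled recoverability expression with the infected-population
    averages Hbar, chibar.  Non-positive information (non-identifiable or
    outside the small-effect regime) yields +inf, never an exception.
    """
    inputs = inputs or PrecisionInputs(phi=summary.phi)
    info = fisher_gf(summary)
    (A, B), (_, C) = info.M
    det = A * C - B * B
    # sd_ag = sqrt(C/det) = 1/sqrt(A - B^2/C); same guarded logic for a_f
    sd_ag = _inv_sqrt(det / C if C > 0 else -1.0, "a_g")
    sd_af = _inv_sqrt(det / A if A > 0 else -1.0, "a_f")

    info_ar = (
        inputs.k
        * summary.n_group
        * (summary.n_seed + summary.phi * summary.n_cont)
        * (summary.H_bar - summary.chi_bar**2)
    )
    sd_ar = _inv_sqrt(info_ar, "a_r")
    return sd_ag, sd_af, sd_ar


def sd_dominance(
    summary: DesignSummary, inputs: PrecisionInputs
) -> tuple[float, float, float]:
    """Posterior SDs of the dominance factors (Delta_g, Delta_f, Delta_r).

    Each carries a 1/|a| prefactor: dominance is unidentifiable when the
    corresponding additive effect is zero (SD -> +inf).  Delta_g information
    is maximal at mean contact homozygosity 1/2 and diverges at 0 or 1.
    """
    n, s, c, phi, k = (
        summary.n_group,
        summary.n_seed,
        summary.n_cont,
        summary.phi,
        inputs.k,
    )

    def scaled(a: float | None, raw: float) -> float:
        if not a:
            warnings.warn(
                "dominance SD requires a nonzero additive effect",
                NonEstimableWarning,
                stacklevel=3,
            )
            return INF
        return raw / abs(a)

    Hc = summary.mean_H_cont
    sd_dg = scaled(inputs.a_g, _inv_sqrt(n * phi * c * (Hc - Hc * Hc), "Delta_g"))

    if s > 0 and phi * c > 0:
        W_H, Y_H = _compute_WY_H(summary)
        info_df = n * phi * c * summary.var_H_cont + n * s * (2 * W_H + Y_H)
    else:
        info_df = n * phi * c * summary.var_H_cont
    sd_df = scaled(inputs.a_f, _inv_sqrt(info_df, "Delta_f"))

    Hb = summary.H_bar
    sd_dr = scaled(
        inputs.a_r, _inv_sqrt(k * n * (s + phi * c) * (Hb - Hb * Hb), "Delta_r")
    )
    return sd_dg, sd_df, sd_dr


def sd_closed_form(
    design_type: str,
    h: float,
    chi_seed: float = -1.0,
    chi_cont: float = 0.8,
    n_total: float = 1.0,
) -> float:
    """Design-specific closed forms for SD(a_f) (phi = 1 assumption).

    single  1/sqrt(N (h(1-h) - h^2 log^2 h /(1-h)) (chi_seed - chi_cont)^2)
    pure    1/sqrt(N (2h(1-h) - h^2 log^2 h /(1-h)))
    mixed   1/sqrt(N (1 - chi_cont^2) chi_cont^2)   (zero-seeder limit;
            group 2 holds the negated balance)
    """
    if design_type in ("single", "pure"):
        if not 0.0 < h < 1.0:
            return INF
        base = h * (1.0 - h) - h * h * math.log(h) ** 2 / (1.0 - h)
        if design_type == "single":
            info = n_total * (base) * (chi_seed - chi_cont) ** 2
        else:
            info = n_total * (base + h * (1.0 - h))
    elif design_type == "mixed":
        info = n_total * (1.0 - chi_cont**2) * chi_cont**2
    else:
        raise ValueError(f"unknown closed-form design type {design_type!r}")
    return _inv_sqrt(info, "a_f")


def gwas_sd(
    p: float,
    n_total: float,
    n_group: float,
    g_size: float,
    k: float = 1.0,
) -> tuple[float, float, float]:
    """SDs of (a_g, a_f, a_r) for Hardy-Weinberg genotype allocation.

    For an arbitrary SNP with allele frequency p in a randomly-allocated
    population (few seeders), SD(a_g) = 1/sqrt(2p(1-p) N_total),
    SD(a_f) = 1/sqrt(2p(1-p)(2 - 1/(G_size-1)) N_group) and
    SD(a_r) = 1/sqrt(2p(1-p) k N_total): infectivity precision is governed
    by the number of groups, not the number of individuals.
    """
    if not 0.0 < p < 1.0:
        warnings.warn("p on the boundary: no SNP variation", NonEstimableWarning)
        return INF, INF, INF
    if g_size < 2:
        raise ValueError("g_size must be >= 2")
    het = 2.0 * p * (1.0 - p)
    sd_ag = _inv_sqrt(het * n_total, "a_g")
    sd_af = _inv_sqrt(het * (2.0 - 1.0 / (g_size - 1.0)) * n_group, "a_f")
    sd_ar = _inv_sqrt(het * k * n_total, "a_r")
    return sd_ag, sd_af, sd_ar


_TABLE3_ROWS = (
    ("single", "single", False),
    ("pure", "pure", False),
    ("pure_dominance", "pure_dominance", True),
    ("mixed", "mixed", False),
    ("mixed_dominance", "mixed_dominance", True),
)


def _exact_summary(name: str, phi: float) -> DesignSummary:
    """Idealised blueprint summary: exact target proportions, phi as given,
    zero-seeder limit for the mixed designs."""
    n_seed = 0.0 if name.startswith("mixed") else None
    design = canonical_design(name, g_size=100, exact=True, n_seed=n_seed)
    return summarize_design(design, phi, allow_empty_seeders=True)


def table3_report(inputs: PrecisionInputs | None = None, decimals: int | None = 2) -> pd.DataFrame:
    """Coefficient table for the five optimal designs.

    Each SD is reported as coefficient/sqrt(N_total) (a_g, a_f),
    coefficient/sqrt(k N_total) (a_r, Delta_r) or
    coefficient/(|a| sqrt(N_total)) (Delta_g, Delta_f), i.e. the dependence
    on N_total, k and the effect sizes is divided out.  Evaluating the
    general expressions on the nine-group dominance design reproduces the
    sqrt(3/2) inflation of the a_f coefficient relative to the four-group
    pure optimum directly.  Coefficients are rounded to ``decimals`` (None
    disables rounding).
    """
    inputs = inputs or PrecisionInputs()
    unit = PrecisionInputs(phi=1.0, k=1.0, a_g=1.0, a_f=1.0, a_r=1.0)
    rows = []
    for label, name, dominance in _TABLE3_ROWS:
        summ = _exact_summary(name, phi=1.0)
        rtN = math.sqrt(summ.n_total)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NonEstimableWarning)
            sd_ag, sd_af, sd_ar = sd_snp_effects(summ, unit)
            if dominance:
                sd_dg, sd_df, sd_dr = sd_dominance(summ, unit)
            else:
                sd_dg = sd_df = sd_dr = INF
        rows.append(
            {
                "design": label,
                "a_g": sd_ag * rtN,
                "a_f": sd_af * rtN,
                "a_r": sd_ar * rtN,  # coefficient of 1/sqrt(k N_total)
                "Delta_g": sd_dg * rtN,
                "Delta_f": sd_df * rtN,
                "Delta_r": sd_dr * rtN,  # coefficient of 1/(|a_r| sqrt(k N_total))
            }
        )
    table = pd.DataFrame(rows).set_index("design")
    if decimals is not None:
        table = table.round(decimals)
    return table


def precision_report(
    design: ExperimentDesign,
    inputs: PrecisionInputs,
    *,
    include_dominance: bool | None = None,
) -> PrecisionReport:
    """Full analytic precision report for an arbitrary design."""
    summary = summarize_design(design, inputs.phi)
    sd_ag, sd_af, sd_ar = sd_snp_effects(summary, inputs)
    if include_dominance is None:
        include_dominance = any(
            a is not None for a in (inputs.a_g, inputs.a_f, inputs.a_r)
        )
    if include_dominance:
        sd_dg, sd_df, sd_dr = sd_dominance(summary, inputs)
    else:
        sd_dg = sd_df = sd_dr = INF
    return PrecisionReport(
        sd_ag=sd_ag,
        sd_af=sd_af,
        sd_ar=sd_ar,
        sd_dg=sd_dg,
        sd_df=sd_df,
        sd_dr=sd_dr,
        method="analytic_general",
        n_total=summary.n_total,
    )
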