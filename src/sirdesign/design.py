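"""Transmission-experiment designs and their genotype-composition summaries.

A transmission experiment consists of one or more closed "contact groups".
Each group starts with ``seeders`` (infected at t = 0) and ``contacts``
(initially susceptible).  For a bi-allelic SNP with genotypes AA/AB/BB the
composition of each role within a group is captured by two numbers:

* homozygosity ``H``   -- proportion of AA plus BB individuals,
* homozygote balance ``chi`` -- proportion of AA minus proportion of BB.

All the analytic precision formulas consume only these per-group quantities,
their across-group averages/variances, and the seeder fraction of the final
infected population ``h = N_seed / (N_seed + phi * N_cont)`` where ``phi`` is
the fraction of contacts ultimately infected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml

GENOTYPES = ("AA", "AB", "BB")

__all__ = [
    "GENOTYPES",
    "GenotypeCounts",
    "GroupDesign",
    "ExperimentDesign",
    "DesignSummary",
    "InvalidDesignError",
    "genotype_effect",
    "summarize_design",
    "canonical_design",
    "largest_remainder_round",
    "recode_complete_dominance",
    "load_design",
    "dump_design",
]


class InvalidDesignError(ValueError):
    """Raised when a design violates a structural invariant."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Counts of AA/AB/BB individuals in one role (seeders or contacts).

    Counts are normally integers; fractional values are accepted so that
    idealised blueprint compositions (e.g. exactly 85.36% AA) can be analysed
    before rounding to a realisable design.
    """

    n_AA: float = 0
    n_AB: float = 0
    n_BB: float = 0

    def __post_init__(self) -> None:
        if min(self.n_AA, self.n_AB, self.n_BB) < 0:
            raise InvalidDesignError("genotype counts must be non-negative")

    @property
    def total(self) -> float:
        return self.n_AA + self.n_AB + self.n_BB

    @property
    def H(self) -> float:
        """Proportion of homozygotes (AA or BB)."""
        if self.total == 0:
            raise InvalidDesignError("H undefined for empty genotype counts")
        return (self.n_AA + self.n_BB) / self.total

    @property
    def chi(self) -> float:
        """Homozygote balance: proportion AA minus proportion BB."""
        if self.total == 0:
            raise InvalidDesignError("chi undefined for empty genotype counts")
        return (self.n_AA - self.n_BB) / self.total

    def as_dict(self) -> dict:
        return {"AA": self.n_AA, "AB": self.n_AB, "BB": self.n_BB}


@dataclass(frozen=True)
class GroupDesign:
    """Genotype composition of seeders and contacts in one contact group."""

    seeders: GenotypeCounts
    contacts: GenotypeCounts

    @property
    def n_seed(self) -> float:
        return self.seeders.total

    @property
    def n_cont(self) -> float:
        return self.contacts.total

    @property
    def g_size(self) -> float:
        return self.n_seed + self.n_cont


@dataclass(frozen=True)
class ExperimentDesign:
    """An ordered list of contact groups, replicated ``replicates`` times.

    Replication repeats the listed blueprint; averages and variances across
    groups are unchanged by it, while every information count (and hence
    every analytic SD, by a factor replicates**-1/2) scales with it.
    """

    groups: tuple[GroupDesign, ...]
    replicates: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        if self.replicates < 1:
            raise InvalidDesignError("replicates must be >= 1")
        if not self.groups:
            raise InvalidDesignError("design must contain at least one group")

    @property
    def n_group(self) -> int:
        """Total number of contact groups across all replicates."""
        return len(self.groups) * self.replicates

    @property
    def n_total(self) -> float:
        return sum(g.g_size for g in self.groups) * self.replicates

    def replicate(self, m: int) -> "ExperimentDesign":
        return ExperimentDesign(self.groups, self.replicates * m)


@dataclass(frozen=True)
class DesignSummary:
    """All per-group and aggregated composition quantities used by the
    analytic precision formulas.

    Aggregates over groups are contact- (resp. seeder-) count weighted; for
    equal-sized groups this coincides with the unweighted average.  Variances
    use the population (divide-by-N) convention across the distinct groups of
    one replicate.  ``H_bar``/``chi_bar`` are averages over the entire final
    infected population (seeders plus the phi fraction of contacts).
    """

    phi: float
    n_group: int
    n_seed: float          # per-group (weighted mean when unequal)
    n_cont: float
    n_total: float
    seed_counts: tuple[float, ...]
    cont_counts: tuple[float, ...]
    H_seed: tuple[float, ...]
    H_cont: tuple[float, ...]
    chi_seed: tuple[float, ...]
    chi_cont: tuple[float, ...]
    mean_H_seed: float
    mean_H_cont: float
    mean_chi_seed: float
    mean_chi_cont: float
    var_chi_cont: float
    var_H_cont: float
    h: float
    H_bar: float
    chi_bar: float

    @property
    def g_size(self) -> float:
        return self.n_seed + self.n_cont


def genotype_effect(genotype: str, a: float, delta: float = 0.0) -> float:
    """Log-scale trait contribution of one SNP genotype.

    ``a`` is half the AA-BB difference; ``delta`` is the scaled dominance
    factor (+1: A completely dominant, -1: B dominant, 0: additive), so
    AA -> +a, AB -> a*delta, BB -> -a.
    """
    if genotype == "AA":
        return a
    if genotype == "AB":
        return a * delta
    if genotype == "BB":
        return -a
    raise ValueError(f"unknown genotype label {genotype!r}")


def _weighted_mean(values: Sequence[float], weights: Sequence[float]) -> float:
    w = np.asarray(weights, dtype=float)
    if w.sum() == 0:
        return float("nan")
    return float(np.average(np.asarray(values, dtype=float), weights=w))


def _weighted_popvar(values: Sequence[float], weights: Sequence[float]) -> float:
    m = _weighted_mean(values, weights)
    return _weighted_mean([(v - m) ** 2 for v in values], weights)


def summarize_design(
    design: ExperimentDesign,
    phi: float,
    *,
    allow_empty_seeders: bool = False,
) -> DesignSummary:
    """Compute every composition summary the precision formulas need.

    ``phi`` is the fraction of contacts ultimately infected.  Averaging over
    groups is contact-count (seeder-count) weighted, which reduces to the
    unweighted average for equal-sized groups.  ``allow_empty_seeders``
    permits the idealised zero-seeder limit used for closed-form analysis of
    mixed designs (h -> 0; all seeder information terms vanish).
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"phi must lie in [0, 1], got {phi}")
    groups = design.groups
    for g in groups:
        if g.g_size <= 0:
            raise InvalidDesignError("group with zero individuals")
        if g.n_seed < 1 and not allow_empty_seeders:
            raise InvalidDesignError(
                "every group needs at least one seeder to instigate an epidemic"
            )

    seed_w = [g.n_seed for g in groups]
    cont_w = [g.n_cont for g in groups]
    have_seed = sum(seed_w) > 0
    have_cont = sum(cont_w) > 0
    if not have_cont:
        raise InvalidDesignError("design has no contact individuals")

    H_seed = tuple(g.seeders.H if g.n_seed > 0 else math.nan for g in groups)
    chi_seed = tuple(g.seeders.chi if g.n_seed > 0 else math.nan for g in groups)
    H_cont = tuple(g.contacts.H for g in groups)
    chi_cont = tuple(g.contacts.chi for g in groups)

    n_seed = float(np.mean(seed_w))
    n_cont = float(np.mean(cont_w))
    mean_H_cont = _weighted_mean(H_cont, cont_w)
    mean_chi_cont = _weighted_mean(chi_cont, cont_w)
    var_chi_cont = _weighted_popvar(chi_cont, cont_w)
    var_H_cont = _weighted_popvar(H_cont, cont_w)
    if have_seed:
        mean_H_seed = _weighted_mean(H_seed, seed_w)
        mean_chi_seed = _weighted_mean(chi_seed, seed_w)
    else:
        mean_H_seed = math.nan
        mean_chi_seed = math.nan

    denom = n_seed + phi * n_cont
    h = n_seed / denom if denom > 0 else math.nan
    if have_seed:
        H_bar = (n_seed * mean_H_seed + phi * n_cont * mean_H_cont) / denom
        chi_bar = (n_seed * mean_chi_seed + phi * n_cont * mean_chi_cont) / denom
    else:
        H_bar = mean_H_cont
        chi_bar = mean_chi_cont

    return DesignSummary(
        phi=phi,
        n_group=design.n_group,
        n_seed=n_seed,
        n_cont=n_cont,
        n_total=design.n_total,
        seed_counts=tuple(float(x) for x in seed_w),
        cont_counts=tuple(float(x) for x in cont_w),
        H_seed=H_seed,
        H_cont=H_cont,
        chi_seed=chi_seed,
        chi_cont=chi_cont,
        mean_H_seed=mean_H_seed,
        mean_H_cont=mean_H_cont,
        mean_chi_seed=mean_chi_seed,
        mean_chi_cont=mean_chi_cont,
        var_chi_cont=var_chi_cont,
        var_H_cont=var_H_cont,
        h=h,
        H_bar=H_bar,
        chi_bar=chi_bar,
    )


def largest_remainder_round(targets: Sequence[float], total: int) -> list[int]:
    """Round non-negative proportions*total to integers summing to ``total``.

    Floors each target then distributes the remaining units by descending
    fractional part; ties broken by position (earlier entry first), making
    the rounding deterministic.
    """
    targets = [max(0.0, t) for t in targets]
    scale = sum(targets)
    if scale == 0:
        raise ValueError("cannot round all-zero targets")
    exact = [t / scale * total for t in targets]
    floors = [math.floor(x) for x in exact]
    short = total - sum(floors)
    order = sorted(range(len(exact)), key=lambda i: (-(exact[i] - floors[i]), i))
    for i in order[:short]:
        floors[i] += 1
    return floors


_CHI_STAR = 1.0 / math.sqrt(2.0)


def _counts_from_chi(n: float, chi: float, *, exact: bool) -> GenotypeCounts:
    """All-homozygote composition (H = 1) with balance chi on n individuals."""
    aa = n * (1 + chi) / 2
    bb = n * (1 - chi) / 2
    if exact:
        return GenotypeCounts(aa, 0, bb)
    aa_i, bb_i = largest_remainder_round([aa, bb], int(round(n)))
    return GenotypeCounts(aa_i, 0, bb_i)


def _pure(genotype: str, n: float) -> GenotypeCounts:
    return GenotypeCounts(**{f"n_{genotype}": n})


def canonical_design(
    name: str,
    g_size: int = 100,
    replicates: int = 1,
    *,
    exact: bool = False,
    n_seed: float | None = None,
) -> ExperimentDesign:
    """Construct one of the five optimal design blueprints.

    ``single``          one group, 15% all-BB seeders, contacts AA/BB with
                        homozygote balance 0.8 (about 10% BB);
    ``pure``            four groups, 47% seeders, seeder/contact genotype
                        combinations (AA,AA),(AA,BB),(BB,AA),(BB,BB);
    ``pure_dominance``  nine groups, 47% seeders, all 3x3 seeder/contact
                        combinations of AA/AB/BB;
    ``mixed``           two groups, 3 all-AA seeders, contacts at homozygote
                        balance +-1/sqrt(2) (about 85%/15% AA/BB, mirrored);
    ``mixed_dominance`` three groups, 3 all-AA seeders, contacts 80/10/10
                        with the three cyclic permutations of (AA,AB,BB).

    With ``exact=True`` the target proportions are kept as (possibly
    fractional) counts, which is the form the closed-form coefficients are
    quoted for; otherwise counts are integers via largest-remainder rounding
    and the realised (not target) composition is what gets reported.
    ``n_seed`` overrides the blueprint seeder count (``n_seed=0`` with
    ``exact=True`` gives the zero-seeder limit of the mixed designs).
    """
    if g_size < 20 and not exact:
        raise InvalidDesignError("g_size >= 20 required to realise the blueprint")

    def seeders_of(n: float) -> float | int:
        return n if exact else int(round(n))

    if name == "single":
        ns = seeders_of(0.15 * g_size if n_seed is None else n_seed)
        nc = g_size - ns
        groups = [GroupDesign(_pure("BB", ns), _counts_from_chi(nc, 0.8, exact=exact))]
    elif name == "pure":
        ns = seeders_of(0.47 * g_size if n_seed is None else n_seed)
        nc = g_size - ns
        groups = [
            GroupDesign(_pure(s, ns), _pure(c, nc))
            for s, c in (("AA", "AA"), ("AA", "BB"), ("BB", "AA"), ("BB", "BB"))
        ]
    elif name == "pure_dominance":
        ns = seeders_of(0.47 * g_size if n_seed is None else n_seed)
        nc = g_size - ns
        groups = [
            GroupDesign(_pure(s, ns), _pure(c, nc))
            for s in GENOTYPES
            for c in GENOTYPES
        ]
    elif name == "mixed":
        ns = seeders_of(3 if n_seed is None else n_seed)
        nc = g_size - ns
        groups = [
            GroupDesign(_pure("AA", ns), _counts_from_chi(nc, chi, exact=exact))
            for chi in (+_CHI_STAR, -_CHI_STAR)
        ]
    elif name == "mixed_dominance":
        ns = seeders_of(3 if n_seed is None else n_seed)
        nc = g_size - ns
        props = [(0.8, 0.1, 0.1), (0.1, 0.8, 0.1), (0.1, 0.1, 0.8)]
        groups = []
        for p in props:
            if exact:
                counts = GenotypeCounts(*(x * nc for x in p))
            else:
                counts = GenotypeCounts(*largest_remainder_round(p, int(round(nc))))
            groups.append(GroupDesign(_pure("AA", ns), counts))
    else:
        raise ValueError(f"unknown canonical design {name!r}")

    return ExperimentDesign(tuple(groups), replicates)


def recode_complete_dominance(
    design: ExperimentDesign, dominant: str = "A"
) -> ExperimentDesign:
    """Recode a design for analysis under complete dominance.

    When allele A is completely dominant, AA and AB are phenotypically
    indistinguishable, so the analytic machinery applies after merging the
    heterozygotes into the dominant homozygote class: the balance chi then
    counts (AA+AB) minus BB and the homozygosity H becomes 1.  With
    ``dominant="B"`` the heterozygotes merge into BB instead.
    """
    if dominant not in ("A", "B"):
        raise ValueError("dominant allele must be 'A' or 'B'")

    def recode(c: GenotypeCounts) -> GenotypeCounts:
        if dominant == "A":
            return GenotypeCounts(c.n_AA + c.n_AB, 0, c.n_BB)
        return GenotypeCounts(c.n_AA, 0, c.n_BB + c.n_AB)

    return ExperimentDesign(
        tuple(
            GroupDesign(recode(g.seeders), recode(g.contacts)) for g in design.groups
        ),
        design.replicates,
    )


# ---------------------------------------------------------------------------
# config file IO


def _design_to_obj(design: ExperimentDesign) -> dict:
    return {
        "groups": [
            {"seeders": g.seeders.as_dict(), "contacts": g.contacts.as_dict()}
            for g in design.groups
        ],
        "replicates": design.replicates,
    }


def _obj_to_design(obj: dict) -> ExperimentDesign:
    try:
        groups = tuple(
            GroupDesign(
                seeders=GenotypeCounts(
                    n_AA=g["seeders"].get("AA", 0),
                    n_AB=g["seeders"].get("AB", 0),
                    n_BB=g["seeders"].get("BB", 0),
                ),
                contacts=GenotypeCounts(
                    n_AA=g["contacts"].get("AA", 0),
                    n_AB=g["contacts"].get("AB", 0),
                    n_BB=g["contacts"].get("BB", 0),
                ),
            )
            for g in obj["groups"]
        )
    except KeyError as exc:
        raise InvalidDesignError(f"design config missing key: {exc}") from exc
    return ExperimentDesign(groups, int(obj.get("replicates", 1)))


def load_design(path: str) -> ExperimentDesign:
    """Read a design from a YAML or JSON config file."""
    with open(path) as fh:
        text = fh.read()
    obj = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(obj, dict):
        raise InvalidDesignError("design config must be a mapping")
    return _obj_to_design(obj)


def dump_design(design: ExperimentDesign, path: str) -> None:
    """Write a design config as canonical JSON."""
    with open(path, "w") as fh:
        json.dump(_design_to_obj(design), fh, indent=2, sort_keys=True)
        fh.write("\n")
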