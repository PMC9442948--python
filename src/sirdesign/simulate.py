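"""Stochastic SIR epidemics with genotype-dependent host traits.

Each contact group runs a continuous-time SIR epidemic in which individual
j is infected with force

    lambda_j = beta * exp(G_z) * exp(g_j) * sum_{i infected} exp(f_i),

and, once infected, carries a gamma-distributed infectious duration with
mean w_j = 1 / (gamma * exp(r_j)) and shape k.  The log-scale trait
deviations (g, f, r) decompose into a SNP term (+a for AA, a*Delta for AB,
-a for BB), optional fixed effects X b and multivariate-normal residuals
with 3x3 covariance Sigma shared across the three traits.

Transmission is density dependent exactly as written above (the infectivity
sum is not divided by group size); beta is a per-pair rate and the basic
reproduction number convention used throughout is

    R0 = beta * G_size / gamma            (at baseline traits).

Time units: gamma = 1 makes the mean baseline infectious period the unit of
time.  Simulations run until no infected individuals remain (no censoring);
seeders start infected at t = 0 and are epidemiologically identical to
contacts.

Because recovery is non-Markovian (gamma durations) the simulation is
event-driven rather than a pure Gillespie chain: each individual's recovery
time is scheduled at the moment of infection, and between consecutive
events the total infection hazard is constant, so the next infection time
is an exponential race against the earliest scheduled recovery.
"""

from __future__ import annotations

import heapq
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import GENOTYPES, ExperimentDesign, genotype_effect

__all__ = [
    "EpidemicParams",
    "assign_genotypes",
    "draw_traits",
    "simulate_group",
    "simulate_experiment",
    "final_size_phi",
    "extinction_probability",
    "write_events",
    "read_events",
    "EVENT_COLUMNS",
]

EVENT_COLUMNS = [
    "id",
    "group",
    "replicate",
    "role",
    "genotype",
    "t_inf",
    "t_rec",
    "G_z",
]


@dataclass(frozen=True)
class EpidemicParams:
    """Parameters of the genetic-epidemiological SIR model.

    beta      per-pair transmission rate; gamma: baseline recovery rate;
    k         gamma shape of the infectious duration (>0, k=1 exponential);
    a_*       SNP effects (half the AA-BB log-scale difference);
    delta_*   scaled dominance factors in [-1, 1];
    sigma_G   SD of the normal per-group random effect on log transmission;
    Sigma     3x3 residual covariance across (g, f, r), symmetric PSD;
    b_g/f/r   fixed-effect coefficient vectors sharing design matrix X.
    """

    beta: float = 0.02
    gamma: float = 1.0
    k: float = 1.0
    a_g: float = 0.0
    a_f: float = 0.0
    a_r: float = 0.0
    delta_g: float = 0.0
    delta_f: float = 0.0
    delta_r: float = 0.0
    sigma_G: float = 0.0
    Sigma: np.ndarray | None = None
    b_g: np.ndarray | None = None
    b_f: np.ndarray | None = None
    b_r: np.ndarray | None = None

    def __post_init__(self) -> None:
        if min(self.beta, self.gamma, self.k) < 0 or self.gamma == 0 or self.k == 0:
            raise ValueError("beta >= 0 and gamma, k > 0 required")
        for d in (self.delta_g, self.delta_f, self.delta_r):
            if not -1.0 <= d <= 1.0:
                raise ValueError("dominance factors must lie in [-1, 1]")
        if self.sigma_G < 0:
            raise ValueError("sigma_G must be >= 0")
        if self.Sigma is not None:
            S = np.asarray(self.Sigma, float)
            if S.shape != (3, 3) or not np.allclose(S, S.T):
                raise ValueError("Sigma must be a symmetric 3x3 matrix")
            if np.linalg.eigvalsh(S).min() < -1e-10:
                raise ValueError("Sigma must be positive semi-definite")
            object.__setattr__(self, "Sigma", S)

    @classmethod
    def from_r0(cls, r0: float, g_size: int, **kwargs) -> "EpidemicParams":
        """beta from the R0 = beta * G_size / gamma convention."""
        gamma = kwargs.pop("gamma", 1.0)
        return cls(beta=r0 * gamma / g_size, gamma=gamma, **kwargs)

    def r0(self, g_size: float) -> float:
        return self.beta * g_size / self.gamma


def assign_genotypes(
    design: ExperimentDesign | None = None,
    *,
    hwe_p: float | None = None,
    n: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Genotype assignment, either exact design counts or HWE draws.

    Design mode returns one row per individual with columns group,
    replicate, role, genotype in deterministic order (counts must be
    integral).  HWE mode draws ``n`` i.i.d. genotypes with probabilities
    (p^2, 2p(1-p), (1-p)^2) for (AA, AB, BB) where p is the A-allele
    frequency.
    """
    if (design is None) == (hwe_p is None):
        raise ValueError("supply exactly one of design or hwe_p")
    if hwe_p is not None:
        if not 0.0 <= hwe_p <= 1.0:
            raise ValueError("allele frequency must lie in [0, 1]")
        if n is None:
            raise ValueError("n required in HWE mode")
        rng = np.random.default_rng(rng)
        p = hwe_p
        probs = [p * p, 2 * p * (1 - p), (1 - p) * (1 - p)]
        geno = rng.choice(GENOTYPES, size=n, p=probs)
        return pd.DataFrame({"genotype": geno})

    rows = []
    for rep in range(design.replicates):
        for gi, grp in enumerate(design.groups):
            for role, counts in (("seeder", grp.seeders), ("contact", grp.contacts)):
                for geno in GENOTYPES:
                    cnt = getattr(counts, f"n_{geno}")
                    if abs(cnt - round(cnt)) > 1e-9:
                        raise ValueError("design mode needs integer genotype counts")
                    rows.extend(
                        {
                            "group": rep * len(design.groups) + gi,
                            "replicate": rep,
                            "role": role,
                            "genotype": geno,
                        }
                        for _ in range(int(round(cnt)))
                    )
    df = pd.DataFrame(rows)
    df.insert(0, "id", np.arange(len(df)))
    return df


def draw_traits(
    params: EpidemicParams,
    genotypes: pd.DataFrame,
    rng: np.random.Generator | int | None = None,
    X: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-individual log-scale trait deviations (g, f, r).

    Adds the SNP contribution, optional fixed effects X b and correlated
    residuals; also draws one group effect G_z ~ N(0, sigma_G^2) per group
    (returned as a ``G_z`` column, constant within group).
    """
    rng = np.random.default_rng(rng)
    out = genotypes.copy()
    n = len(out)
    geno = out["genotype"].to_numpy()
    g = np.array([genotype_effect(x, params.a_g, params.delta_g) for x in geno])
    f = np.array([genotype_effect(x, params.a_f, params.delta_f) for x in geno])
    r = np.array([genotype_effect(x, params.a_r, params.delta_r) for x in geno])
    if X is not None:
        X = np.atleast_2d(np.asarray(X, float))
        for vec, b in ((g, params.b_g), (f, params.b_f), (r, params.b_r)):
            if b is not None:
                vec += X @ np.asarray(b, float)
    if params.Sigma is not None and np.any(params.Sigma):
        eps = rng.multivariate_normal(np.zeros(3), params.Sigma, size=n)
        g, f, r = g + eps[:, 0], f + eps[:, 1], r + eps[:, 2]
    out["g"], out["f"], out["r"] = g, f, r

    if "group" in out.columns:
        group_ids = out["group"].unique()
        gz = {
            gid: (rng.normal(0.0, params.sigma_G) if params.sigma_G > 0 else 0.0)
            for gid in sorted(group_ids)
        }
        out["G_z"] = out["group"].map(gz)
    else:
        out["G_z"] = 0.0
    return out


def simulate_group(
    traits: pd.DataFrame,
    params: EpidemicParams,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Exact event-driven SIR simulation of one contact group.

    ``traits`` needs columns role, genotype, g, f, r (and optionally G_z,
    id, group, replicate).  Returns the rows with t_inf / t_rec filled in
    (NaN for never-infected contacts; t_inf = 0 for seeders).  Runs until
    no infected individuals remain.
    """
    rng = np.random.default_rng(rng)
    out = traits.reset_index(drop=True).copy()
    n = len(out)
    role = out["role"].to_numpy()
    g = out["g"].to_numpy(float)
    f = out["f"].to_numpy(float)
    r = out["r"].to_numpy(float)
    gz = out["G_z"].to_numpy(float) if "G_z" in out else np.zeros(n)
    if not (role == "seeder").any():
        raise ValueError("group needs at least one seeder")

    w_mean = 1.0 / (params.gamma * np.exp(r))  # mean infectious duration
    sus_rate = np.exp(g)  # susceptibility multiplier
    inf_weight = np.exp(f)  # infectivity contribution

    t_inf = np.full(n, np.nan)
    t_rec = np.full(n, np.nan)
    base = params.beta * math.exp(gz[0]) if n else 0.0

    recovery_heap: list[tuple[float, int]] = []
    susceptible = role == "contact"
    F = 0.0  # sum of exp(f_i) over currently infected
    for j in np.flatnonzero(role == "seeder"):
        t_inf[j] = 0.0
        dur = rng.gamma(shape=params.k, scale=w_mean[j] / params.k)
        t_rec[j] = dur
        heapq.heappush(recovery_heap, (dur, int(j)))
        F += inf_weight[j]

    t = 0.0
    sus_idx = list(np.flatnonzero(susceptible))
    sus_total = float(sus_rate[sus_idx].sum())
    while recovery_heap:
        hazard = base * F * sus_total
        if hazard > 0.0 and sus_idx:
            dt = rng.exponential(1.0 / hazard)
        else:
            dt = math.inf
        t_next_rec = recovery_heap[0][0]
        if t + dt < t_next_rec:
            t += dt
            # choose the newly infected individual proportional to exp(g_j)
            weights = sus_rate[sus_idx]
            j = sus_idx[rng.choice(len(sus_idx), p=weights / weights.sum())]
            t_inf[j] = t
            dur = rng.gamma(shape=params.k, scale=w_mean[j] / params.k)
            t_rec[j] = t + dur
            heapq.heappush(recovery_heap, (t + dur, int(j)))
            F += inf_weight[j]
            sus_idx.remove(j)
            sus_total -= sus_rate[j]
        else:
            t = t_next_rec
            _, j = heapq.heappop(recovery_heap)
            F -= inf_weight[j]
            if F < 1e-12:  # guard against drift when the last infected leaves
                F = sum(
                    inf_weight[k]
                    for _, k in recovery_heap
                )

    out["t_inf"] = t_inf
    out["t_rec"] = t_rec
    return out


def simulate_experiment(
    design: ExperimentDesign,
    params: EpidemicParams,
    seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Simulate every group of a (replicated) design; returns an event table.

    One row per individual: id, group, replicate, role, genotype, t_inf,
    t_rec, G_z.  The same seed gives a bit-identical table.
    """
    rng = np.random.default_rng(seed)
    geno = assign_genotypes(design)
    traits = draw_traits(params, geno, rng)
    parts = []
    for gid, sub in traits.groupby("group", sort=True):
        parts.append(simulate_group(sub, params, rng))
    events = pd.concat(parts, ignore_index=True)
    return events[EVENT_COLUMNS + [c for c in ("g", "f", "r") if c in events]]


def final_size_phi(r0: float, h0: float, tol: float = 1e-10) -> float:
    """Deterministic SIR final-size: fraction of contacts ever infected.

    Solves phi = 1 - exp(-R0 (h0 + (1 - h0) phi)) where h0 is the initial
    seeder fraction of the group, by damped fixed-point iteration with a
    bisection fallback.  Uses the R0 = beta G_size / gamma convention.
    """
    if r0 < 0:
        raise ValueError("R0 must be >= 0")
    if not 0.0 <= h0 < 1.0:
        raise ValueError("h0 must lie in [0, 1)")
    if r0 == 0.0:
        return -math.expm1(-r0 * h0)  # 0 unless seeded externally

    func = lambda p: 1.0 - math.exp(-r0 * (h0 + (1.0 - h0) * p))
    phi, damp = 0.5, 0.5
    for _ in range(10_000):
        nxt = (1 - damp) * phi + damp * func(phi)
        if abs(nxt - phi) < tol:
            return nxt
        phi = nxt
    # bisection fallback on g(p) = func(p) - p, decreasing-slope fixed point
    lo, hi = 0.0, 1.0
    g = lambda p: func(p) - p
    # largest root: start from p=1 side
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def extinction_probability(
    r0: float,
    n_seed: int,
    mode: str = "branching",
    *,
    g_size: int = 200,
    n_runs: int = 2000,
    params: EpidemicParams | None = None,
    seed: int | np.random.Generator | None = 0,
    threshold: float = 0.1,
) -> float:
    """Probability that the epidemic goes extinct without taking off.

    ``branching``: min(1, (1/R0)^N_seed), the geometric-offspring branching
    approximation (exact for exponential infectious periods, k = 1).
    ``monte_carlo``: fraction of simulated groups infecting fewer than
    ``threshold`` of their contacts.
    """
    if r0 <= 0 or n_seed < 1:
        raise ValueError("R0 > 0 and N_seed >= 1 required")
    if mode == "branching":
        return min(1.0, (1.0 / r0) ** n_seed)
    if mode != "monte_carlo":
        raise ValueError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed)
    params = params or EpidemicParams.from_r0(r0, g_size)
    n_cont = g_size - n_seed
    traits = pd.DataFrame(
        {
            "role": ["seeder"] * n_seed + ["contact"] * n_cont,
            "genotype": ["AA"] * g_size,
            "g": 0.0,
            "f": 0.0,
            "r": 0.0,
            "G_z": 0.0,
        }
    )
    extinct = 0
    for _ in range(n_runs):
        ev = simulate_group(traits, params, rng)
        frac = (
            ev.loc[ev["role"] == "contact", "t_inf"].notna().mean()
            if n_cont
            else 0.0
        )
        extinct += frac < threshold
    return extinct / n_runs


def write_events(events: pd.DataFrame, path: str, metadata: dict | None = None) -> None:
    """Event table to CSV (+ optional JSON sidecar with params and seed)."""
    events.to_csv(path, index=False)
    if metadata is not None:
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(metadata, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def read_events(path: str) -> pd.DataFrame:
    events = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    return events
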