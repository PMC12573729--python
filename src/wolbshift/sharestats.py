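"""Occurrence-matrix statistics: strain sharing, randomization tests,
incidence/prevalence, and a Bayesian logistic model of sharing.

The central object is the species x strain occurrence matrix of specimen
counts.  Strain sharing between true host sister pairs is compared against
a null of uniformly random perfect matchings of the (filtered) species:
each replicate shuffles the species list and takes consecutive disjoint
pairs, and the empirical p-value counts null replicates with a statistic at
least as large as the observed one, with the observed value itself included
as a replicate — so p is never exactly zero.

The logistic model regresses pair-level strain sharing on host split time,
degree of sympatry and their interaction, fitted by random-walk Metropolis
with weakly informative Normal(0, 5^2) priors on standardized coefficients.
Coefficient significance is summarized with pMCMC: twice the smaller of the
posterior probabilities of the coefficient being above or below zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

FILTERS = ("all", "any_infected", "both_infected")
STATISTICS = ("shared_count", "mean_ani_incl", "mean_ani_excl")


@dataclass
class OccurrenceMatrix:
    """Species x strain specimen counts.

    A species is infected iff any strain count is positive.  n_specimens
    gives the number of screened specimens per species (for prevalence).
    """

    counts: pd.DataFrame  # index: species, columns: strain ids, int counts
    n_specimens: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("occurrence counts must be non-negative")
        if self.n_specimens is None:
            self.n_specimens = self.counts.sum(axis=1).clip(lower=1)

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)

    def strains_of(self, species: str) -> frozenset:
        if species not in self.counts.index:
            raise KeyError(f"unknown species {species!r}")
        row = self.counts.loc[species]
        return frozenset(row.index[row > 0])

    def is_infected(self, species: str) -> bool:
        return len(self.strains_of(species)) > 0

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="species")

    @classmethod
    def from_tsv(cls, path) -> "OccurrenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col="species")
        return cls(counts=df)


@dataclass(frozen=True)
class PairRecord:
    """A host sister-species pair with split-time and sympatry metadata."""

    species_a: str
    species_b: str
    split_gen: float
    split_my: float
    sympatry: float
    d_xy: float | None = None

    def __post_init__(self) -> None:
        if self.split_gen <= 0 or self.split_my <= 0:
            raise ValueError("split times must be positive")
        if not 0 <= self.sympatry <= 1:
            raise ValueError("sympatry must be in [0, 1]")


@dataclass
class SharingTestResult:
    statistic_name: str
    observed: float
    null_values: np.ndarray
    n_reps: int
    p_emp: float
    filter: str
    seed: int


@dataclass
class PrevalenceSummary:
    species: str
    n_infected: int
    n_total: int
    prevalence: float
    ci_lo: float
    ci_hi: float


def shared_strain_count(matrix: OccurrenceMatrix, pair: tuple[str, str]) -> int:
    """Number of strains occurring in both species of the pair."""
    a, b = pair
    return len(matrix.strains_of(a) & matrix.strains_of(b))


def mean_cross_ani(
    matrix: OccurrenceMatrix,
    ani: dict[tuple[str, str], float],
    pair: tuple[str, str],
    include_shared: bool = True,
) -> float | None:
    """Mean directed ANI over all cross-species strain occurrence pairs.

    Shared strains contribute 100 (both directions) when included and are
    skipped when excluded.  Returns None when no cross pair remains after
    exclusion (reported as missing, never as 0).
    """
    a, b = pair
    strains_a, strains_b = matrix.strains_of(a), matrix.strains_of(b)
    if not strains_a or not strains_b:
        raise ValueError("mean_cross_ani requires both species infected")
    values: list[float] = []
    for s in strains_a:
        for t in strains_b:
            if s == t:
                if include_shared:
                    values.extend([100.0, 100.0])
                continue
            values.append(ani[(s, t)])
            values.append(ani[(t, s)])
    if not values:
        return None
    return float(np.mean(values))


def _filter_species(
    matrix: OccurrenceMatrix, pairs: Sequence[PairRecord], filter: str
) -> list[str]:
    if filter not in FILTERS:
        raise ValueError(f"filter must be one of {FILTERS}")
    species: list[str] = []
    for pr in pairs:
        inf_a, inf_b = matrix.is_infected(pr.species_a), matrix.is_infected(pr.species_b)
        keep = (
            filter == "all"
            or (filter == "any_infected" and (inf_a or inf_b))
            or (filter == "both_infected" and inf_a and inf_b)
        )
        if keep:
            species.extend([pr.species_a, pr.species_b])
    return species


def _pair_stat_matrix(
    matrix: OccurrenceMatrix,
    species: list[str],
    statistic: str,
    ani: dict[tuple[str, str], float] | None,
) -> np.ndarray:
    """Symmetric lookup S[i, j] of the pair statistic; NaN where undefined."""
    n = len(species)
    s = np.full((n, n), np.nan)
    strain_sets = [matrix.strains_of(sp) for sp in species]
    for i in range(n):
        for j in range(i + 1, n):
            if statistic == "shared_count":
                val: float | None = float(len(strain_sets[i] & strain_sets[j]))
            else:
                if not strain_sets[i] or not strain_sets[j]:
                    val = None
                else:
                    val = mean_cross_ani(
                        matrix,
                        ani,
                        (species[i], species[j]),
                        include_shared=(statistic == "mean_ani_incl"),
                    )
            if val is not None:
                s[i, j] = s[j, i] = val
    return s


def sharing_permutation_test(
    matrix: OccurrenceMatrix,
    pairs: Sequence[PairRecord],
    filter: str = "both_infected",
    statistic: str = "shared_count",
    n_reps: int = 30_000,
    seed: int = 0,
    ani: dict[tuple[str, str], float] | None = None,
) -> SharingTestResult:
    """Randomization test of the mean pair statistic over true sister pairs.

    Null replicates re-pair the filtered species uniformly at random
    (shuffle then chunk into consecutive disjoint pairs).  The statistic is
    the mean over pairs with a defined value.  p_emp counts replicates >=
    the observed value out of n_reps, the observed value included.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    if statistic != "shared_count" and ani is None:
        raise ValueError("ANI lookup required for mean-ANI statistics")
    species = _filter_species(matrix, pairs, filter)
    n = len(species)
    if n < 4 or n % 2:
        raise ValueError(
            f"cannot form disjoint pairs from {n} filtered species (need even, >= 4)"
        )
    s = _pair_stat_matrix(matrix, species, statistic, ani)

    idx = {sp: i for i, sp in enumerate(species)}
    true_vals = []
    for pr in pairs:
        if pr.species_a in idx and pr.species_b in idx:
            true_vals.append(s[idx[pr.species_a], idx[pr.species_b]])
    observed = float(np.nanmean(true_vals))

    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_reps - 1, n)), axis=1)
    left, right = perms[:, 0::2], perms[:, 1::2]
    vals = s[left, right]
    with np.errstate(invalid="ignore"):
        null = np.nanmean(vals, axis=1)
    null = null[~np.isnan(null)]
    n_total = null.size + 1  # observed value is one replicate
    p_emp = (1 + int(np.sum(null >= observed))) / n_total
    return SharingTestResult(
        statistic_name=statistic,
        observed=observed,
        null_values=null,
        n_reps=n_total,
        p_emp=p_emp,
        filter=filter,
        seed=seed,
    )


def enumerate_matchings(species: Sequence[str]) -> list[list[tuple[str, str]]]:
    """All perfect matchings of a species list (exact null enumeration)."""
    species = list(species)
    if not species:
        return [[]]
    first, rest = species[0], species[1:]
    out = []
    for i, partner in enumerate(rest):
        remaining = rest[:i] + rest[i + 1 :]
        for sub in enumerate_matchings(remaining):
            out.append([(first, partner)] + sub)
    return out


def incidence(status_vector: Sequence[bool]) -> int:
    """Percent of species with >= 1 infected specimen, rounded to integer."""
    status = list(status_vector)
    if not status:
        raise ValueError("empty status vector")
    return int(round(100.0 * sum(status) / len(status)))


def prevalence_ci(
    n_infected: int, n_total: int, species: str = ""
) -> PrevalenceSummary:
    """Within-species prevalence with a Wilson 95% confidence interval."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_infected <= n_total:
        raise ValueError("n_infected must be in [0, n_total]")
    lo, hi = proportion_confint(n_infected, n_total, alpha=0.05, method="wilson")
    prev = n_infected / n_total
    # guard against floating-point jitter at the boundaries
    lo, hi = min(float(lo), prev), max(float(hi), prev)
    return PrevalenceSummary(
        species=species,
        n_infected=n_infected,
        n_total=n_total,
        prevalence=prev,
        ci_lo=lo,
        ci_hi=hi,
    )


@dataclass
class SamplerSettings:
    n_iter: int = 60_000
    burn_in: int = 10_000
    thin: int = 10
    prior_sd: float = 5.0
    proposal_scale: float = 0.25


@dataclass
class PosteriorDraws:
    """Posterior draws for the sharing model coefficients.

    names order: intercept, time, sympatry, time:sympatry.  ``draws`` are on
    the standardized-predictor scale; ``draws_raw`` are transformed back to
    the original predictor units.
    """

    names: tuple[str, ...]
    draws: np.ndarray  # n_kept x 4, standardized scale
    draws_raw: np.ndarray  # n_kept x 4, original scale
    acceptance_rate: float

    @property
    def n_kept(self) -> int:
        return self.draws.shape[0]


def _log_posterior(beta: np.ndarray, x: np.ndarray, y: np.ndarray, prior_sd: float) -> float:
    eta = x @ beta
    # numerically stable Bernoulli log-likelihood
    loglik = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    logprior = float(-0.5 * np.sum((beta / prior_sd) ** 2))
    return loglik + logprior


def fit_share_model(
    pairs: Sequence[PairRecord],
    responses: Sequence[int],
    time_unit: str = "generations",
    settings: SamplerSettings | None = None,
    seed: int = 0,
) -> PosteriorDraws:
    """Bayesian logistic regression of strain sharing on split time,
    sympatry and their interaction, via random-walk Metropolis.

    ``responses`` is 1 for pairs sharing >= 1 strain, else 0.  Predictors
    are standardized internally; the interaction is the product of the
    standardized main effects.  The proposal scale adapts toward a ~25%
    acceptance rate during burn-in, then stays fixed.
    """
    settings = settings or SamplerSettings()
    if len(pairs) < 6:
        raise ValueError("need at least 6 pairs to fit the sharing model")
    if len(responses) != len(pairs):
        raise ValueError("responses length mismatch")
    if time_unit not in ("generations", "My"):
        raise ValueError("time_unit must be 'generations' or 'My'")
    t = np.array(
        [p.split_gen if time_unit == "generations" else p.split_my for p in pairs]
    )
    sym = np.array([p.sympatry for p in pairs])
    y = np.asarray(responses, dtype=float)
    if y.min() == y.max():
        raise ValueError("response has no variation")

    mt, st = t.mean(), t.std() or 1.0
    ms, ss = sym.mean(), sym.std() or 1.0
    tz, sz = (t - mt) / st, (sym - ms) / ss
    x = np.column_stack([np.ones_like(tz), tz, sz, tz * sz])

    rng = np.random.default_rng(seed)
    beta = np.zeros(4)
    lp = _log_posterior(beta, x, y, settings.prior_sd)
    scale = settings.proposal_scale
    kept = []
    n_accept = 0
    n_after_burn = 0
    for it in range(settings.n_iter):
        prop = beta + rng.normal(scale=scale, size=4)
        lp_prop = _log_posterior(prop, x, y, settings.prior_sd)
        accept = np.log(rng.random()) < lp_prop - lp
        if accept:
            beta, lp = prop, lp_prop
        if it < settings.burn_in:
            # Robbins-Monro adaptation toward 25% acceptance
            scale *= np.exp(0.01 * ((1.0 if accept else 0.0) - 0.25))
        else:
            n_after_burn += 1
            n_accept += int(accept)
            if (it - settings.burn_in) % settings.thin == 0:
                kept.append(beta.copy())
    draws = np.array(kept)
    if draws.shape[0] < 1000:
        raise ValueError("fewer than 1000 kept draws; increase n_iter")

    # back-transform to the original predictor scale:
    # eta = b0 + b1*tz + b2*sz + b3*tz*sz with tz=(t-mt)/st, sz=(s-ms)/ss
    b0, b1, b2, b3 = draws.T
    raw3 = b3 / (st * ss)
    raw1 = b1 / st - raw3 * ms
    raw2 = b2 / ss - raw3 * mt
    raw0 = b0 - b1 * mt / st - b2 * ms / ss + raw3 * mt * ms
    draws_raw = np.column_stack([raw0, raw1, raw2, raw3])

    return PosteriorDraws(
        names=("intercept", "time", "sympatry", "time:sympatry"),
        draws=draws,
        draws_raw=draws_raw,
        acceptance_rate=n_accept / max(n_after_burn, 1),
    )


def pmcmc(draws: np.ndarray) -> float:
    """Twice the smaller tail probability of a coefficient's posterior."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty draws")
    above = float(np.mean(draws > 0))
    below = float(np.mean(draws < 0))
    return min(2.0 * min(above, below), 1.0)
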