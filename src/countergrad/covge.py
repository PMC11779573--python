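"""The Cov_GE countergradient-variation statistic with resampling inference.

Cov_GE measures the covariance between genetic and environmental influences
on a phenotype across native genotype-environment pairings.  Here the
genotype is the source population (N or S), the environment is the thermal
extreme (cold or heat), the native pairing is N<->cold / S<->heat (the
northern site has the colder climate), and the phenotype is the
replicate-level proportion of snails surviving at the 48-h checkpoint.
Negative Cov_GE is countergradient variation: genetic differences oppose,
and thereby mask, the environmental gradient.

The estimator follows the standardization-based recipe: phenotypes are
centered on the overall mean and divided by the standard deviation of the
genotype x environment group means; genotype means are averaged across
environments and environment means across genotypes (equal-weight margins,
as a two-factor ANOVA's estimated marginal means give in a balanced
design); then

    Cov_GE = 1/(n-1) * sum_i  G_i * E_pair(i)

over the n native pairs (divisor 1 when n = 2), clipped to [-1, 1].  With
the population (divide-by-k) SD convention the perfect additive
countergradient case attains exactly -1; the sample (k-1) convention, with
additive bound 0.75, is available behind a flag.

Uncertainty: percentile bootstrap CIs (individual snails resampled with
replacement within each group, default 999 runs) and a two-sided
permutation test of Cov_GE = 0 (replicate phenotypes shuffled across
groups, add-one p-value).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from countergrad.core_data import ReplicateSummary

logger = logging.getLogger(__name__)

DEFAULT_PAIRING = {"N": "cold", "S": "heat"}
DEFAULT_ENVIRONMENTS = ("heat", "cold")


class DegeneratePhenotypesError(ValueError):
    """All group means equal: the standardization divisor is zero."""


@dataclass
class StandardizedPhenotypes:
    """Phenotypes centered on the grand mean and scaled by the SD of group means."""

    values: np.ndarray
    grand_mean: float
    sd_group: float
    group_keys: list[tuple[str, str]]  # (genotype, environment) per observation
    genotypes: tuple[str, ...]
    environments: tuple[str, ...]
    sd_convention: str = "population"


@dataclass
class GroupMeans:
    """Equal-weight marginal means of standardized phenotypes."""

    genotype_means: dict[str, float]
    environment_means: dict[str, float]


@dataclass
class CovGEResult:
    """Per-species Cov_GE estimate with bootstrap CI and permutation p."""

    species: str
    estimate: float
    ci_low: float
    ci_high: float
    p_perm: float
    n_boot: int
    n_perm: int
    seed: int
    pairing: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_PAIRING))
    n_degenerate_redraws: int = 0

    @property
    def significant_by_ci(self) -> bool:
        """CI-based call: significant when the 95% interval excludes zero."""
        return self.ci_low > 0 or self.ci_high < 0

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_perm": self.p_perm,
            "n_boot": self.n_boot,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "pairing": dict(self.pairing),
            "n_degenerate_redraws": self.n_degenerate_redraws,
        }


# ---------------------------------------------------------------------------
# array extraction and the vectorized estimator core
# ---------------------------------------------------------------------------


def _extract_arrays(
    summaries: list[ReplicateSummary],
    environments: tuple[str, ...] = DEFAULT_ENVIRONMENTS,
):
    """Replicate-level arrays for one species restricted to the extreme
    environments: phenotype values, genotype/environment indices, and the
    underlying counts (for individual-level bootstrap)."""
    subset = [s for s in summaries if s.treatment in environments]
    if not subset:
        raise ValueError("no observations in the requested environments")
    genotypes = tuple(sorted({s.population for s in subset}))
    values = np.array([s.prop_surviving for s in subset])
    g_idx = np.array([genotypes.index(s.population) for s in subset])
    e_idx = np.array([environments.index(s.treatment) for s in subset])
    n_start = np.array([s.n_start for s in subset])
    n_alive = np.array([s.n_alive_endpoint for s in subset])
    return values, g_idx, e_idx, n_start, n_alive, genotypes


def _covge_batch(
    V: np.ndarray,
    g_idx: np.ndarray,
    e_idx: np.ndarray,
    n_g: int,
    n_e: int,
    pair_env_of_gen: np.ndarray,
    ddof: int = 0,
):
    """Cov_GE for a batch of phenotype vectors.

    ``V`` is (B, R): B datasets over the same R replicates' group labels.
    Returns (estimates, degenerate_mask).  Implements the full
    standardize -> marginal means -> native-pair covariance chain; the
    whole chain only depends on the data through the grand mean and the
    group (cell) means, which is what makes the batch form exact.
    """
    V = np.atleast_2d(V)
    n_cells = n_g * n_e
    cell = g_idx * n_e + e_idx
    onehot = np.zeros((V.shape[1], n_cells))
    onehot[np.arange(V.shape[1]), cell] = 1.0
    counts = onehot.sum(axis=0)
    if np.any(counts == 0):
        missing = [(g, e) for g in range(n_g) for e in range(n_e) if counts[g * n_e + e] == 0]
        raise ValueError(f"empty genotype x environment cell(s): {missing}")
    grand = V.mean(axis=1)
    M = (V @ onehot) / counts  # (B, n_cells) cell means
    mm = M.mean(axis=1, keepdims=True)
    dev = M - mm
    denom = n_cells - ddof
    sd = np.sqrt((dev**2).sum(axis=1) / denom)
    degenerate = sd == 0
    sd_safe = np.where(degenerate, 1.0, sd)
    Ms = (M - grand[:, None]) / sd_safe[:, None]
    Mg = Ms.reshape(-1, n_g, n_e)
    G = Mg.mean(axis=2)  # (B, n_g)
    E = Mg.mean(axis=1)  # (B, n_e)
    cov = (G * E[:, pair_env_of_gen]).sum(axis=1) / max(n_g - 1, 1)
    cov = np.clip(cov, -1.0, 1.0)
    return cov, degenerate


# ---------------------------------------------------------------------------
# the step-by-step public operations
# ---------------------------------------------------------------------------


def standardize_phenotypes(
    summaries: list[ReplicateSummary],
    environments: tuple[str, ...] = DEFAULT_ENVIRONMENTS,
    sd_convention: str = "population",
) -> StandardizedPhenotypes:
    """Center phenotypes on the overall mean; scale by the SD of group means.

    Groups are genotype (population) x environment (treatment) pairs.  The
    SD divisor uses the population (divide-by-k) convention by default,
    which calibrates the perfect additive countergradient case to
    Cov_GE = -1; ``sd_convention="sample"`` selects the k-1 convention.
    """
    if sd_convention not in ("population", "sample"):
        raise ValueError("sd_convention must be 'population' or 'sample'")
    subset = [s for s in summaries if s.treatment in environments]
    keys = [(s.population, s.treatment) for s in subset]
    if len(set(keys)) < 2:
        raise ValueError("need at least 2 genotype x environment groups")
    values = np.array([s.prop_surviving for s in subset])
    grand = float(values.mean())
    group_mean = {k: float(np.mean([v for v, kk in zip(values, keys) if kk == k]))
                  for k in set(keys)}
    means = np.array(list(group_mean.values()))
    ddof = 0 if sd_convention == "population" else 1
    sd = float(np.sqrt(((means - means.mean()) ** 2).sum() / (len(means) - ddof)))
    if sd == 0:
        raise DegeneratePhenotypesError("degenerate phenotypes: all group means equal")
    return StandardizedPhenotypes(
        values=(values - grand) / sd,
        grand_mean=grand,
        sd_group=sd,
        group_keys=keys,
        genotypes=tuple(sorted({g for g, _ in keys})),
        environments=tuple(e for e in environments if any(k[1] == e for k in keys)),
        sd_convention=sd_convention,
    )


def marginal_means(std: StandardizedPhenotypes) -> GroupMeans:
    """Equal-weight marginal means of the standardized phenotypes.

    Genotype means average each genotype's cell means across environments;
    environment means average across genotypes — the estimated marginal
    means of a two-factor linear model with interaction, which in the
    balanced design reduce to simple averages of cell means.  An unobserved
    genotype x environment cell is an error (the margins would need an
    explicit imbalance policy).
    """
    cells: dict[tuple[str, str], list[float]] = {}
    for v, k in zip(std.values, std.group_keys):
        cells.setdefault(k, []).append(float(v))
    for g in std.genotypes:
        for e in std.environments:
            if (g, e) not in cells:
                raise ValueError(f"genotype {g!r} unobserved in environment {e!r}")
    cell_mean = {k: float(np.mean(v)) for k, v in cells.items()}
    gmeans = {
        g: float(np.mean([cell_mean[(g, e)] for e in std.environments]))
        for g in std.genotypes
    }
    emeans = {
        e: float(np.mean([cell_mean[(g, e)] for g in std.genotypes]))
        for e in std.environments
    }
    return GroupMeans(genotype_means=gmeans, environment_means=emeans)


def covge_estimate(means: GroupMeans, pairing: dict[str, str] | None = None) -> float:
    """Native-pair covariance of genotype and environment marginal means.

    ``pairing`` maps each genotype to its home environment.  The sum of
    G_i * E_pair(i) over the n pairs is divided by n - 1 (so the divisor is
    1 for the two-population case) and clipped to [-1, 1].
    """
    pairing = pairing or DEFAULT_PAIRING
    total = 0.0
    n = 0
    for g, gm in means.genotype_means.items():
        if g not in pairing:
            raise ValueError(f"pairing has no native environment for genotype {g!r}")
        env = pairing[g]
        if env not in means.environment_means:
            raise ValueError(f"pairing references unknown environment {env!r}")
        total += gm * means.environment_means[env]
        n += 1
    cov = total / max(n - 1, 1)
    return float(np.clip(cov, -1.0, 1.0))


def covge_from_summaries(
    summaries: list[ReplicateSummary],
    pairing: dict[str, str] | None = None,
    environments: tuple[str, ...] = DEFAULT_ENVIRONMENTS,
    sd_convention: str = "population",
) -> float:
    """The full standardize -> marginal means -> estimate chain in one call."""
    std = standardize_phenotypes(summaries, environments, sd_convention)
    return covge_estimate(marginal_means(std), pairing)


def _pairing_index(
    genotypes: tuple[str, ...],
    environments: tuple[str, ...],
    pairing: dict[str, str],
) -> np.ndarray:
    idx = []
    for g in genotypes:
        if g not in pairing:
            raise ValueError(f"pairing has no native environment for genotype {g!r}")
        if pairing[g] not in environments:
            raise ValueError(f"pairing references unknown environment {pairing[g]!r}")
        idx.append(environments.index(pairing[g]))
    return np.array(idx)


def bootstrap_ci(
    summaries: list[ReplicateSummary],
    pairing: dict[str, str] | None = None,
    n_boot: int = 999,
    seed: int | np.random.SeedSequence | None = None,
    environments: tuple[str, ...] = DEFAULT_ENVIRONMENTS,
    sd_convention: str = "population",
    unit: str = "individual",
    level: float = 0.95,
    return_extras: bool = False,
):
    """Percentile bootstrap CI for Cov_GE.

    ``unit="individual"`` (default) resamples individual snails with
    replacement within each genotype x environment group — matching the
    binomial observation unit — and re-forms replicates of the original
    sizes before re-running the full estimation chain.
    ``unit="replicate"`` resamples replicate-level phenotypes with
    replacement within each group instead.  Resamples whose group means are
    all equal cannot be standardized and are redrawn (count logged).
    """
    pairing = pairing or DEFAULT_PAIRING
    values, g_idx, e_idx, n_start, n_alive, genotypes = _extract_arrays(
        summaries, environments
    )
    ddof = 0 if sd_convention == "population" else 1
    n_g, n_e = len(genotypes), len(environments)
    pair_idx = _pairing_index(genotypes, environments, pairing)
    rng = np.random.default_rng(seed)

    cell = g_idx * n_e + e_idx
    n_rep = len(values)

    def draw(n: int) -> np.ndarray:
        if unit == "individual":
            # resampling with replacement from the pooled 0/1 outcomes of a
            # group is exactly a binomial draw at the group's pooled rate
            q_cell = np.zeros(n_g * n_e)
            for c in range(n_g * n_e):
                mask = cell == c
                q_cell[c] = n_alive[mask].sum() / n_start[mask].sum()
            counts = rng.binomial(n_start[None, :], q_cell[cell][None, :], size=(n, n_rep))
            return counts / n_start[None, :]
        elif unit == "replicate":
            V = np.empty((n, n_rep))
            for c in range(n_g * n_e):
                mask = np.flatnonzero(cell == c)
                picks = rng.integers(0, len(mask), size=(n, len(mask)))
                V[:, mask] = values[mask][picks]
            return V
        raise ValueError("unit must be 'individual' or 'replicate'")

    estimates = np.empty(0)
    n_redraws = 0
    want = n_boot
    for _ in range(1000):
        V = draw(want)
        est, degen = _covge_batch(V, g_idx, e_idx, n_g, n_e, pair_idx, ddof)
        estimates = np.concatenate([estimates, est[~degen]])
        n_redraws += int(degen.sum())
        want = n_boot - len(estimates)
        if want <= 0:
            break
    else:
        raise RuntimeError("bootstrap: too many degenerate resamples")
    if n_redraws:
        logger.info("bootstrap_ci: redrew %d degenerate resamples", n_redraws)
    alpha = (1 - level) / 2
    lo, hi = np.percentile(estimates[:n_boot], [100 * alpha, 100 * (1 - alpha)])
    if return_extras:
        return float(lo), float(hi), {"n_redraws": n_redraws, "estimates": estimates[:n_boot]}
    return float(lo), float(hi)


def permutation_test(
    summaries: list[ReplicateSummary],
    pairing: dict[str, str] | None = None,
    n_perm: int = 999,
    seed: int | np.random.SeedSequence | None = None,
    environments: tuple[str, ...] = DEFAULT_ENVIRONMENTS,
    sd_convention: str = "population",
) -> float:
    """Two-sided permutation p-value for H0: Cov_GE = 0.

    The null distribution permutes replicate-level phenotypes across
    genotype x environment groups (within the species), recomputing the
    full chain each time; p = (1 + #{|T*| >= |T|}) / (n_perm + 1), so
    p >= 1/(n_perm + 1) always.  Degenerate inputs (all phenotypes equal
    after permutation regardless of labels) give p = 1.
    """
    pairing = pairing or DEFAULT_PAIRING
    values, g_idx, e_idx, _, _, genotypes = _extract_arrays(summaries, environments)
    ddof = 0 if sd_convention == "population" else 1
    n_g, n_e = len(genotypes), len(environments)
    pair_idx = _pairing_index(genotypes, environments, pairing)
    rng = np.random.default_rng(seed)

    obs, obs_degen = _covge_batch(values[None, :], g_idx, e_idx, n_g, n_e, pair_idx, ddof)
    if obs_degen[0]:
        return 1.0
    t_obs = abs(float(obs[0]))

    V = np.tile(values, (n_perm, 1))
    V = rng.permuted(V, axis=1)
    t_perm, degen = _covge_batch(V, g_idx, e_idx, n_g, n_e, pair_idx, ddof)
    # a degenerate permutation has no G or E structure at all: |T*| = 0
    t_abs = np.where(degen, 0.0, np.abs(t_perm))
    return float((1 + np.sum(t_abs >= t_obs - 1e-12)) / (n_perm + 1))


def run_covge_per_species(
    summaries: list[ReplicateSummary],
    pairing: dict[str, str] | None = None,
    n_boot: int = 999,
    n_perm: int = 999,
    seed: int = 0,
    environments: tuple[str, ...] = DEFAULT_ENVIRONMENTS,
    sd_convention: str = "population",
    bootstrap_unit: str = "individual",
) -> list[CovGEResult]:
    """Estimate Cov_GE with bootstrap CI and permutation p for every species.

    Environments default to the two thermal extremes (control is excluded:
    it represents neither home climate), genotypes to the N/S populations
    with the native pairing N<->cold / S<->heat.  A species missing an
    environment or population is skipped with a warning.  The global seed is
    fanned out to independent per-species bootstrap and permutation streams.
    """
    pairing = pairing or DEFAULT_PAIRING
    species_present = sorted({s.species for s in summaries})
    results: list[CovGEResult] = []
    root = np.random.SeedSequence(seed)
    for i, sp in enumerate(species_present):
        sub = [s for s in summaries if s.species == sp]
        present_envs = {s.treatment for s in sub}
        present_pops = {s.population for s in sub}
        if not set(environments) <= present_envs or not set(pairing) <= present_pops:
            logger.warning("run_covge_per_species: skipping %s (missing groups)", sp)
            continue
        boot_seed, perm_seed = root.spawn(2 * len(species_present))[2 * i : 2 * i + 2]
        est = covge_from_summaries(sub, pairing, environments, sd_convention)
        lo, hi, extras = bootstrap_ci(
            sub, pairing, n_boot, boot_seed, environments, sd_convention,
            unit=bootstrap_unit, return_extras=True,
        )
        p = permutation_test(sub, pairing, n_perm, perm_seed, environments, sd_convention)
        results.append(
            CovGEResult(
                species=sp,
                estimate=est,
                ci_low=lo,
                ci_high=hi,
                p_perm=p,
                n_boot=n_boot,
                n_perm=n_perm,
                seed=seed,
                pairing=dict(pairing),
                n_degenerate_redraws=extras["n_redraws"],
            )
        )
    return results
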