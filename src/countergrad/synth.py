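"""Synthetic factorial survival datasets emulating the thermal-assay design.

The generator reproduces the study layout: 3 species x 2 populations (N/S)
x 3 treatments (control/heat/cold) x 2 blocks with 10 snails per replicate
cell, i.e. 180 snails per block.  Survival is generated from a logit-linear
model of the *per-cycle* survival probability; a snail must survive two
consecutive exposure cycles to be alive at the 48-h checkpoint, mirroring
the assay in which only survivors of the first 3-h exposure are exposed
again.  Optional beta-binomial overdispersion injects the extra-binomial
variance a quasibinomial analysis expects.

Effects are expressed on the logit scale as a map from a term string to a
coefficient, e.g. ``{"treatment=heat": -3.0, "population=N:treatment=cold": 1.5}``.
A term applies additively to every cell matching all of its
``factor=level`` conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy.special import expit

from countergrad.core_data import (
    SnailRecord,
    SPECIES_LEVELS,
    POPULATION_LEVELS,
    TREATMENT_LEVELS,
)

_FACTOR_LEVELS = {
    "species": SPECIES_LEVELS,
    "population": POPULATION_LEVELS,
    "treatment": TREATMENT_LEVELS,
    "block": ("A", "B"),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative survival model.

    ``beta0`` is the baseline logit of the per-cycle survival probability
    (the reference cell); ``effects`` add to it per matching cell.  ``rho``
    is the intra-replicate correlation of a beta-binomial perturbation
    (0 = pure binomial).  ``two_cycle`` composes 48-h survival as the
    product of two conditional per-cycle Bernoulli outcomes.  Weights are
    log-normal in grams, truncated so that under the defaults the 1-g
    exclusion filter is a no-op.
    """

    n_per_replicate: int = 10
    blocks: tuple[str, ...] = ("A", "B")
    beta0: float = 4.0
    effects: dict[str, float] = field(default_factory=dict)
    rho: float = 0.0
    two_cycle: bool = True
    weight_mean_g: float = 0.35
    weight_sd_g: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_replicate < 1:
            raise ValueError("n_per_replicate must be a positive integer")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")
        if self.weight_sd_g < 0:
            raise ValueError("weight_sd_g must be non-negative")

    def cell_logit(self, species: str, population: str, treatment: str, block: str) -> float:
        """Linear predictor (per-cycle survival logit) for one design cell."""
        cell = {
            "species": species,
            "population": population,
            "treatment": treatment,
            "block": block,
        }
        eta = self.beta0
        for term, coef in self.effects.items():
            if _term_matches(term, cell):
                eta += coef
        return eta

    def cell_prob_48h(self, species: str, population: str, treatment: str, block: str) -> float:
        """Expected 48-h survival probability of a cell (per-cycle prob squared
        under the two-cycle model)."""
        p = float(expit(self.cell_logit(species, population, treatment, block)))
        return p * p if self.two_cycle else p


def _term_matches(term: str, cell: dict[str, str]) -> bool:
    """True if every ``factor=level`` condition of ``term`` holds for ``cell``."""
    for cond in term.split(":"):
        if "=" not in cond:
            raise ValueError(f"malformed effect term {term!r}: expected factor=level[:...]")
        factor, level = cond.split("=", 1)
        if factor not in _FACTOR_LEVELS:
            raise ValueError(f"effect term {term!r} references unknown factor {factor!r}")
        if level not in _FACTOR_LEVELS[factor]:
            raise ValueError(
                f"effect term {term!r} references unknown level {level!r} of {factor!r}"
            )
        if cell[factor] != level:
            return False
    return True


def _validate_effects(config: SimulationConfig) -> None:
    dummy = {"species": "littorea", "population": "N", "treatment": "control", "block": "A"}
    for term in config.effects:
        _term_matches(term, dummy)


def make_design(config: SimulationConfig) -> list[SnailRecord]:
    """Lay out the full factorial crossing with simulated wet weights.

    Returns record "skeletons": survival flags are set to 1 (alive) and are
    overwritten by :func:`simulate_survival`.  Exactly ``n_per_replicate``
    rows per species x population x treatment x block cell; with the
    defaults that is 180 snails per block.  Weights are log-normal with the
    configured mean/SD, clipped to 1 g so the weight filter retains all
    simulated snails under defaults.
    """
    _validate_effects(config)
    rng = np.random.default_rng(config.seed)
    # log-normal parameterized by the desired arithmetic mean/SD
    m, s = config.weight_mean_g, max(config.weight_sd_g, 1e-12)
    sigma2 = np.log1p((s / m) ** 2)
    mu = np.log(m) - sigma2 / 2
    records: list[SnailRecord] = []
    counter = 0
    for block in config.blocks:
        for species in SPECIES_LEVELS:
            for population in POPULATION_LEVELS:
                for treatment in TREATMENT_LEVELS:
                    weights = rng.lognormal(mu, np.sqrt(sigma2), config.n_per_replicate)
                    weights = np.minimum(weights, 1.0)
                    for w in weights:
                        records.append(
                            SnailRecord(
                                snail_id=f"sim{counter:05d}",
                                species=species,
                                population=population,
                                treatment=treatment,
                                block=block,
                                wet_weight_g=float(w),
                                alive_24h=1,
                                alive_48h=1,
                            )
                        )
                        counter += 1
    return records


def simulate_survival(design: list[SnailRecord], config: SimulationConfig) -> list[SnailRecord]:
    """Draw survival outcomes for a design under the logit-linear model.

    Per replicate cell the latent per-cycle survival probability is
    ``expit(beta0 + sum of matching effects)``; with ``rho > 0`` it is
    replaced by a beta draw with that mean and intra-class correlation
    ``rho`` (shared by all snails of the replicate, inducing extra-binomial
    count variance ``n*p*(1-p)*(1 + (n-1)*rho)``).  Each snail survives
    cycle 1 with the replicate probability (the 24-h flag); survivors
    independently survive cycle 2 (the 48-h flag).  Snails dead at 24 h stay
    dead.  Deterministic under ``config.seed``.
    """
    _validate_effects(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    by_cell: dict[tuple[str, str, str, str], list[int]] = {}
    for i, r in enumerate(design):
        by_cell.setdefault(r.cell, []).append(i)
    out = list(design)
    for cell_key in sorted(by_cell):
        species, population, treatment, block = cell_key
        p = float(expit(config.cell_logit(species, population, treatment, block)))
        if config.rho > 0:
            a = p * (1 - config.rho) / config.rho
            b = (1 - p) * (1 - config.rho) / config.rho
            p_rep = float(rng.beta(a, b))
        else:
            p_rep = p
        for i in by_cell[cell_key]:
            alive1 = int(rng.random() < p_rep)
            if config.two_cycle:
                alive2 = int(alive1 and rng.random() < p_rep)
            else:
                alive2 = alive1
            out[i] = replace(design[i], alive_24h=alive1, alive_48h=alive2)
    return out


def simulate_dataset(config: SimulationConfig) -> list[SnailRecord]:
    """Convenience: design + survival in one call."""
    return simulate_survival(make_design(config), config)


PRESET_NAMES = ("countergradient", "null", "cogradient", "separation")


def preset_scenarios(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Named generative scenarios for the downstream analyses.

    - ``countergradient``: near-certain control survival; cold harsher than
      heat; northern populations survive both extremes better, so genetic
      (population) differences oppose the environmental gradient and the
      expected Cov_GE of the generating means is negative.
    - ``cogradient``: the mirror image (southern advantage), expected
      Cov_GE positive.
    - ``null``: no population, treatment, or interaction effects; all cells
      share one survival probability, so phenotypes are exchangeable across
      genotype-environment groups and expected Cov_GE is 0.
    - ``separation``: one treatment with survival probability
      indistinguishable from 1, producing complete separation so that
      maximum-likelihood logits diverge while bias-reduced fits stay finite.
    """
    if name == "countergradient":
        cfg = SimulationConfig(
            beta0=4.0,
            effects={
                "treatment=heat": -3.0,
                "treatment=cold": -4.0,
                "population=N:treatment=heat": 1.5,
                "population=N:treatment=cold": 1.5,
                "species=obtusata:treatment=cold": 0.5,
                "species=saxatilis:treatment=heat": -0.5,
                "treatment=cold:block=B": -0.3,
            },
            seed=seed,
        )
    elif name == "cogradient":
        cfg = SimulationConfig(
            beta0=4.0,
            effects={
                "treatment=heat": -3.0,
                "treatment=cold": -4.0,
                "population=S:treatment=heat": 1.5,
                "population=S:treatment=cold": 1.5,
            },
            seed=seed,
        )
    elif name == "null":
        cfg = SimulationConfig(beta0=0.85, effects={}, seed=seed)
    elif name == "separation":
        cfg = SimulationConfig(
            beta0=1.0,
            effects={"treatment=control": 30.0, "treatment=cold": -1.5},
            seed=seed,
        )
    else:
        raise ValueError(
            f"unknown preset {name!r}; available presets: {', '.join(PRESET_NAMES)}"
        )
    return replace(cfg, **overrides) if overrides else cfg


def expected_cell_probs(config: SimulationConfig, endpoint: str = "48h") -> dict[tuple[str, str, str], float]:
    """Block-averaged expected survival probability per species x population x
    treatment cell.  This is the generating truth downstream estimators are
    checked against (note: with ``rho > 0`` the beta perturbation preserves
    the per-cycle mean, not exactly the squared two-cycle mean; the
    approximation error is O(rho * p * (1-p)))."""
    out: dict[tuple[str, str, str], float] = {}
    for species in SPECIES_LEVELS:
        for population in POPULATION_LEVELS:
            for treatment in TREATMENT_LEVELS:
                ps = []
                for block in config.blocks:
                    p = float(expit(config.cell_logit(species, population, treatment, block)))
                    if endpoint == "48h" and config.two_cycle:
                        p = p * p
                    ps.append(p)
                out[(species, population, treatment)] = float(np.mean(ps))
    return out


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["blocks"] = list(d["blocks"])
    return d
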