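"""Mean-bias-reduced binomial-logit GLM with quasibinomial dispersion.

Estimation maximizes the Jeffreys-penalized binomial log-likelihood

    l*(beta) = l(beta) + (1/2) log det X'WX,   W = diag(n_i pi_i (1 - pi_i)),

which for the binomial/logit family coincides with Firth's mean-bias-reduced
adjusted-score estimator.  The penalty keeps estimates finite under complete
separation (control treatments with 100% survival are the practical case
here) and shrinks small-sample bias.  The adjusted score has the closed form

    U*(beta) = X' (y - n pi + h (1/2 - pi)),

with h the leverages of the weighted projection, which Fisher scoring drives
to zero.  Dispersion is quasibinomial: phi = Pearson X^2 / residual df,
scaling the coefficient covariance; Wald inference uses a t reference with
residual df.  AIC is computed from the binomial log-likelihood at the
bias-reduced estimates (quasi-likelihoods have no AIC; this matches what the
standard bias-reduction software reports).

Model selection (:func:`backward_select`) removes interactions backward by
stage — first the four-way term, then three-way terms, then two-way terms —
greedily dropping, one term per step, whichever removal lowers AIC the most,
preserving marginality and never removing main effects.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from scipy.special import expit, logit

from countergrad.core_data import (
    ReplicateSummary,
    SPECIES_LEVELS,
    POPULATION_LEVELS,
    TREATMENT_LEVELS,
    BLOCK_LEVELS,
    summaries_to_frame,
)

logger = logging.getLogger(__name__)

FACTORS = ("species", "population", "treatment", "block")
_LEVELS = {
    "species": SPECIES_LEVELS,
    "population": POPULATION_LEVELS,
    "treatment": TREATMENT_LEVELS,
    "block": BLOCK_LEVELS,
}

Term = tuple[str, ...]


class RankDeficiencyError(ValueError):
    """The design matrix is not full rank."""


@dataclass(frozen=True)
class ModelSpec:
    """An ordered set of model terms over the four design factors.

    Terms are tuples of factor names (``("species",)`` a main effect,
    ``("species", "treatment")`` an interaction).  Dummy (treatment-contrast)
    coding with reference levels littorea / N / control / A.  Marginality is
    enforced: every interaction's lower-order margins must be present.
    """

    terms: tuple[Term, ...]
    endpoint: str = "48h"

    def __post_init__(self) -> None:
        seen = set()
        for t in self.terms:
            if not t or any(f not in FACTORS for f in t) or len(set(t)) != len(t):
                raise ValueError(f"malformed term {t!r}; factors are {FACTORS}")
            seen.add(frozenset(t))
        for t in self.terms:
            if len(t) > 1:
                for k in range(1, len(t)):
                    for sub in itertools.combinations(t, k):
                        if frozenset(sub) not in seen:
                            raise ValueError(
                                f"hierarchy violated: {t} present but margin {sub} absent"
                            )

    @property
    def formula_rhs(self) -> str:
        return " + ".join(":".join(t) for t in self.terms) if self.terms else "1"

    def drop(self, term: Term) -> "ModelSpec":
        return ModelSpec(
            terms=tuple(t for t in self.terms if frozenset(t) != frozenset(term)),
            endpoint=self.endpoint,
        )

    def order_terms(self, order: int) -> list[Term]:
        return [t for t in self.terms if len(t) == order]

    def is_removable(self, term: Term) -> bool:
        """A term may be removed only if no retained higher-order term contains it,
        and main effects are never removed."""
        if len(term) == 1:
            return False
        fs = frozenset(term)
        return not any(
            len(t) > len(term) and fs < frozenset(t) for t in self.terms
        )


def full_factorial_spec(endpoint: str = "48h") -> ModelSpec:
    """All terms up to the four-way interaction, main effects first."""
    terms: list[Term] = []
    for order in (1, 2, 3, 4):
        terms.extend(itertools.combinations(FACTORS, order))
    return ModelSpec(terms=tuple(terms), endpoint=endpoint)


def spec_from_formula(rhs: str, endpoint: str = "48h") -> ModelSpec:
    """Parse a formula-like right-hand side, e.g.
    ``"species + population + treatment + block + species:treatment"``."""
    terms = []
    for chunk in rhs.replace("~", "").split("+"):
        chunk = chunk.strip()
        if chunk in ("", "1"):
            continue
        terms.append(tuple(f.strip() for f in chunk.split(":")))
    return ModelSpec(terms=tuple(terms), endpoint=endpoint)


def _design_frame(data: list[ReplicateSummary]) -> pd.DataFrame:
    df = summaries_to_frame(data)
    for f in FACTORS:
        df[f] = pd.Categorical(df[f], categories=_LEVELS[f])
    return df


def build_design(spec: ModelSpec, data: list[ReplicateSummary]):
    """Design matrix, successes, and trials for a replicate-level dataset."""
    df = _design_frame(data)
    X = patsy.dmatrix("1 + " + spec.formula_rhs, df, return_type="dataframe")
    successes = np.array(
        [s.n_alive_48h if spec.endpoint == "48h" else s.n_alive_24h for s in data],
        dtype=float,
    )
    trials = np.array([s.n_start for s in data], dtype=float)
    return X, successes, trials


@dataclass
class BRGLMFit:
    """A fitted (penalized) binomial-logit model.

    ``beta`` is on the logit scale; ``hat`` are the leverages of the final
    weighted projection (they sum to the parameter count); ``phi`` is the
    Pearson dispersion (NaN when the model is saturated); ``cov_beta`` is the
    phi-scaled covariance; ``aic`` uses the binomial log-likelihood.
    """

    spec: ModelSpec
    beta: np.ndarray
    names: list[str]
    hat: np.ndarray
    phi: float
    cov_unscaled: np.ndarray
    loglik_binomial: float
    aic: float
    converged: bool
    n_iter: int
    fitted_prob: np.ndarray
    successes: np.ndarray
    trials: np.ndarray
    design_info: object = field(repr=False, default=None)
    penalized: bool = True

    @property
    def n_params(self) -> int:
        return len(self.beta)

    @property
    def df_resid(self) -> int:
        return len(self.successes) - self.n_params

    @property
    def cov_beta(self) -> np.ndarray:
        scale = self.phi if np.isfinite(self.phi) else 1.0
        return scale * self.cov_unscaled

    def summary_frame(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov_beta))
        tstat = np.divide(self.beta, se, out=np.full_like(self.beta, np.nan), where=se > 0)
        df = max(self.df_resid, 1)
        p = 2 * stats.t.sf(np.abs(tstat), df)
        return pd.DataFrame(
            {"term": self.names, "estimate": self.beta, "se": se, "statistic": tstat, "p": p}
        )


def _binom_loglik(successes, trials, prob) -> float:
    return float(np.sum(stats.binom.logpmf(successes, trials, prob)))


def _hat_values(Xm: np.ndarray, w: np.ndarray, xtwx_inv: np.ndarray) -> np.ndarray:
    WX = Xm * w[:, None]
    return np.einsum("ij,jk,ik->i", WX, xtwx_inv, Xm)


def fit_brglm(
    spec: ModelSpec,
    data: list[ReplicateSummary],
    penalized: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> BRGLMFit:
    """Fit the (Jeffreys-penalized) binomial-logit GLM by Fisher scoring.

    With ``penalized=False`` the unpenalized maximum-likelihood fit is
    computed instead (it may fail to converge under separation; the fit is
    then returned with ``converged=False`` and a warning).

    Starting values come from weighted least squares on the adjusted working
    response ``logit((y + 0.5) / (n + 1))``.  Convergence is declared when
    the (adjusted) score max-norm drops below ``tol``.
    """
    X, successes, trials = build_design(spec, data)
    if np.any(trials < 1):
        raise ValueError("every replicate must have at least one trial")
    Xm = X.to_numpy()
    n_obs, n_par = Xm.shape
    rank = np.linalg.matrix_rank(Xm)
    if rank < n_par:
        # identify aliased columns via pivoted QR
        _, R, piv = _qr_pivot(Xm)
        aliased = [X.columns[j] for j in piv[rank:]]
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {n_par} columns; aliased terms: {aliased}"
        )

    z = logit((successes + 0.5) / (trials + 1.0))
    beta, *_ = np.linalg.lstsq(Xm, z, rcond=None)

    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = Xm @ beta
        pi = expit(eta)
        w = trials * pi * (1 - pi)
        xtwx = Xm.T @ (Xm * w[:, None])
        xtwx_inv = np.linalg.inv(xtwx)
        if penalized:
            h = _hat_values(Xm, w, xtwx_inv)
            score = Xm.T @ (successes - trials * pi + h * (0.5 - pi))
        else:
            score = Xm.T @ (successes - trials * pi)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        step = xtwx_inv @ score
        # step-halving guard against overshoot in near-separated fits
        obj0 = _objective(Xm, successes, trials, beta, penalized)
        for _ in range(30):
            cand = beta + step
            if _objective(Xm, successes, trials, cand, penalized) >= obj0 - 1e-12:
                break
            step = step / 2
        beta = beta + step

    eta = Xm @ beta
    pi = expit(eta)
    w = trials * pi * (1 - pi)
    xtwx = Xm.T @ (Xm * w[:, None])
    xtwx_inv = np.linalg.inv(xtwx)
    h = _hat_values(Xm, w, xtwx_inv)
    ll = _binom_loglik(successes, trials, pi)
    aic = -2.0 * ll + 2.0 * n_par

    df_resid = n_obs - n_par
    if df_resid > 0:
        pearson = float(np.sum((successes - trials * pi) ** 2 / np.maximum(w, 1e-300)))
        phi = pearson / df_resid
    else:
        phi = float("nan")

    if not converged:
        warnings.warn(
            f"fit did not converge in {max_iter} iterations "
            f"(penalized={penalized}); partial fit returned",
            RuntimeWarning,
        )

    return BRGLMFit(
        spec=spec,
        beta=beta,
        names=list(X.columns),
        hat=h,
        phi=phi,
        cov_unscaled=xtwx_inv,
        loglik_binomial=ll,
        aic=aic,
        converged=converged,
        n_iter=n_iter,
        fitted_prob=pi,
        successes=successes,
        trials=trials,
        design_info=X.design_info,
        penalized=penalized,
    )


def _objective(Xm, successes, trials, beta, penalized) -> float:
    eta = Xm @ beta
    pi = expit(eta)
    eps = 1e-12
    pi = np.clip(pi, eps, 1 - eps)
    ll = float(np.sum(successes * np.log(pi) + (trials - successes) * np.log1p(-pi)))
    if penalized:
        w = trials * pi * (1 - pi)
        sign, logdet = np.linalg.slogdet(Xm.T @ (Xm * w[:, None]))
        ll += 0.5 * logdet if sign > 0 else -np.inf
    return ll


def _qr_pivot(A: np.ndarray):
    from scipy.linalg import qr

    Q, R, piv = qr(A, pivoting=True)
    return Q, R, piv


def penalized_loglik(spec: ModelSpec, data: list[ReplicateSummary], beta: np.ndarray) -> float:
    """The Jeffreys-penalized binomial log-likelihood at ``beta`` (kernel form,
    without the binomial coefficient); exposed so independent optimizers can
    cross-check the fit."""
    X, successes, trials = build_design(spec, data)
    return _objective(X.to_numpy(), successes, trials, np.asarray(beta, dtype=float), True)


def estimate_dispersion(fit: BRGLMFit) -> float:
    """Quasibinomial dispersion: Pearson statistic over residual df.

    The Pearson statistic compares survivor counts with trials x fitted
    probability, scaled by the binomial variance.  A saturated model
    (residual df <= 0) has no dispersion estimate and raises.
    """
    if fit.df_resid <= 0:
        raise ValueError("saturated model: residual df <= 0, dispersion not estimable")
    w = fit.trials * fit.fitted_prob * (1 - fit.fitted_prob)
    pearson = float(
        np.sum((fit.successes - fit.trials * fit.fitted_prob) ** 2 / np.maximum(w, 1e-300))
    )
    return pearson / fit.df_resid


def backward_select(
    data: list[ReplicateSummary],
    full_spec: ModelSpec | None = None,
    penalized: bool = True,
) -> tuple[ModelSpec, BRGLMFit, list[dict]]:
    """AIC-guided staged backward elimination of interaction terms.

    Starting from the full model (all interactions up to four-way unless a
    spec is given), the four-way term is considered first, then three-way
    terms, then two-way terms.  Within a stage, removal proceeds greedily one
    term at a time: every currently removable term of that order is refit
    without, and the removal that lowers AIC the most is applied; the stage
    ends when no removal lowers AIC.  Main effects are never candidates and
    marginality is always preserved.  The trace records every candidate AIC.
    """
    spec = full_spec or full_factorial_spec()
    fit = fit_brglm(spec, data, penalized=penalized)
    trace: list[dict] = [
        {"stage": "start", "action": "fit full model", "terms": spec.formula_rhs, "aic": fit.aic}
    ]
    for order in (4, 3, 2):
        while True:
            candidates = [t for t in spec.order_terms(order) if spec.is_removable(t)]
            if not candidates:
                break
            best_term, best_fit, best_aic = None, None, fit.aic
            for term in candidates:
                cand_spec = spec.drop(term)
                cand_fit = fit_brglm(cand_spec, data, penalized=penalized)
                trace.append(
                    {
                        "stage": f"{order}-way",
                        "action": f"try drop {':'.join(term)}",
                        "terms": cand_spec.formula_rhs,
                        "aic": cand_fit.aic,
                    }
                )
                if cand_fit.aic < best_aic:
                    best_term, best_fit, best_aic = term, cand_fit, cand_fit.aic
            if best_term is None:
                break
            spec, fit = spec.drop(best_term), best_fit
            trace.append(
                {
                    "stage": f"{order}-way",
                    "action": f"drop {':'.join(best_term)}",
                    "terms": spec.formula_rhs,
                    "aic": fit.aic,
                }
            )
    return spec, fit, trace
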