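"""Bayesian posterior of regulation for ortholog-cluster promoter sets.

Per promoter, every window score is evaluated under a background normal
model B and a regulated mixture model R (see :class:`~metaregulon.motifs.
ScoreModel`); assuming independence across windows and across promoters,
the cluster posterior is a logistic function of the accumulated
log-likelihood ratio plus the prior log-odds:

    P(R|D) = 1 / (1 + exp( sum_i [log P(D_i|B) - log P(D_i|R)]
                           + log P(B) - log P(R) ))

A cluster with no mapped promoters keeps a likelihood-ratio product of 1
and returns the prior. The sensitivity-adjusted variant restricts the set
to promoters with at least one window score >= theta and renormalises both
likelihoods and priors by the models' threshold-exceedance probabilities.

All probability arithmetic is carried out in natural-log space; log2 is
used only at the scoring layer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .motifs import ScoreModel, ScoreVector

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PriorSpec:
    """Prior probability of regulation from reference-genome counts.

    Defaults follow the copper-repressor reference: 3 regulated operons of
    1811 annotated in *B. subtilis*, P(R) = 3/1811. ``p_regulated``
    overrides the ratio (used by threshold adjustment) while keeping the
    counts for provenance.
    """

    n_regulated: int = 3
    n_total: int = 1811
    p_regulated: float | None = None

    def __post_init__(self):
        if not 0 < self.n_regulated < self.n_total:
            raise ValueError("need 0 < n_regulated < n_total")
        if self.p_regulated is not None and not 0.0 < self.p_regulated < 1.0:
            raise ValueError("p_regulated must lie in (0, 1)")

    @property
    def p_r(self) -> float:
        if self.p_regulated is not None:
            return self.p_regulated
        return self.n_regulated / self.n_total

    @property
    def p_b(self) -> float:
        return 1.0 - self.p_r

    @property
    def log_odds_background(self) -> float:
        """log(P(B)/P(R))."""
        return math.log(self.p_b) - math.log(self.p_r)


@dataclass
class ClusterPromoterSet:
    """Promoter score vectors mapped to one ortholog-cluster identifier."""

    cluster_id: str
    promoters: list

    def __post_init__(self):
        ids = [sv.promoter_id for sv in self.promoters if sv.promoter_id is not None]
        if len(ids) != len(set(ids)):
            raise ValueError(
                f"duplicate promoter ids in cluster {self.cluster_id}: "
                "independent-evidence assumption violated"
            )


@dataclass
class PosteriorRecord:
    """Posterior of regulation for one cluster, with audit fields."""

    cluster_id: str
    posterior: float
    n_promoters_total: int
    n_promoters_analyzed: int
    log_likelihood_ratio_sum: float  # sum_i log[P(D_i|B)/P(D_i|R)]
    priors_used: PriorSpec = field(default_factory=PriorSpec)


# ---------------------------------------------------------------------------
# densities

def log_background_pdf(scores, model: ScoreModel) -> np.ndarray:
    """Natural-log density of scores under the background normal."""
    s = np.asarray(scores, dtype=np.float64)
    z = (s - model.mu_g) / model.sigma_g
    return -0.5 * z * z - math.log(model.sigma_g) - 0.5 * _LOG_2PI


def log_mixture_pdf(scores, model: ScoreModel) -> np.ndarray:
    """Natural-log density under the regulated two-component mixture.

    Evaluated with log-sum-exp of the weighted component log-densities.
    """
    s = np.asarray(scores, dtype=np.float64)
    zm = (s - model.mu_m) / model.sigma_m
    lp_m = -0.5 * zm * zm - math.log(model.sigma_m) - 0.5 * _LOG_2PI
    lp_g = log_background_pdf(s, model)
    return np.logaddexp(math.log(model.alpha) + lp_m,
                        math.log1p(-model.alpha) + lp_g)


def _scores_of(scores) -> np.ndarray:
    if isinstance(scores, ScoreVector):
        return scores.scores
    return np.asarray(scores, dtype=np.float64)


# ---------------------------------------------------------------------------
# likelihoods and posteriors

def promoter_loglik_background(scores, model: ScoreModel) -> float:
    """log P(D_i|B): sum of background log-densities over the windows."""
    s = _scores_of(scores)
    if s.size == 0:
        return 0.0
    return float(np.sum(log_background_pdf(s, model)))


def promoter_loglik_regulated(scores, model: ScoreModel) -> float:
    """log P(D_i|R): sum of mixture log-densities over the windows."""
    s = _scores_of(scores)
    if s.size == 0:
        return 0.0
    return float(np.sum(log_mixture_pdf(s, model)))


def promoter_log_ratio(scores, model: ScoreModel) -> float:
    """lambda_i = log[P(D_i|B)/P(D_i|R)] for one promoter."""
    return promoter_loglik_background(scores, model) - promoter_loglik_regulated(
        scores, model
    )


def promoter_posterior(scores, model: ScoreModel,
                       priors: PriorSpec | None = None) -> float:
    """Posterior probability of regulation from a single promoter."""
    priors = priors or PriorSpec()
    lam = promoter_log_ratio(scores, model)
    return float(expit(-(lam + priors.log_odds_background)))


def cluster_posterior(cluster: ClusterPromoterSet, model: ScoreModel,
                      priors: PriorSpec | None = None) -> PosteriorRecord:
    """Posterior of regulation for a cluster of promoters.

    Accumulates per-promoter log-likelihood ratios; an empty cluster keeps
    a ratio product of 1 and returns exactly the prior. Invariant under
    promoter reordering.
    """
    priors = priors or PriorSpec()
    lam_sum = sum(promoter_log_ratio(sv, model) for sv in cluster.promoters)
    posterior = float(expit(-(lam_sum + priors.log_odds_background)))
    return PosteriorRecord(
        cluster_id=cluster.cluster_id,
        posterior=posterior,
        n_promoters_total=len(cluster.promoters),
        n_promoters_analyzed=len(cluster.promoters),
        log_likelihood_ratio_sum=float(lam_sum),
        priors_used=priors,
    )


# ---------------------------------------------------------------------------
# sensitivity adjustment

def _log1mexp(x):
    """log(1 - exp(x)) for x <= 0, numerically stable at both ends."""
    x = np.asarray(x, dtype=np.float64)
    with np.errstate(divide="ignore"):
        out = np.where(
            x < -math.log(2.0),
            np.log1p(-np.exp(x)),
            np.log(-np.expm1(np.minimum(x, 0.0))),
        )
    return out


def _log_no_exceedance(n_windows: int, theta: float, model: ScoreModel):
    """(log U_B, log U_R): log-probability that no window reaches theta."""
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    log_phi_g = norm.logcdf(theta, loc=model.mu_g, scale=model.sigma_g)
    log_phi_m = norm.logcdf(theta, loc=model.mu_m, scale=model.sigma_m)
    log_phi_r = np.logaddexp(math.log(model.alpha) + log_phi_m,
                             math.log1p(-model.alpha) + log_phi_g)
    return n_windows * log_phi_g, n_windows * log_phi_r


def survival_probabilities(n_windows: int, theta: float, model: ScoreModel):
    """(U_B, U_R): probability that no window of a promoter scores >= theta.

    U_B = Phi_g(theta)^n; U_R = [alpha*Phi_m(theta) +
    (1-alpha)*Phi_g(theta)]^n, computed in log space to resist underflow
    for large window counts.
    """
    log_ub, log_ur = _log_no_exceedance(n_windows, theta, model)
    return float(np.exp(log_ub)), float(np.exp(log_ur))


def _adjust_priors_from_masses(priors: PriorSpec, mass_b: float,
                               mass_r: float) -> PriorSpec:
    w_r = priors.n_regulated * mass_r
    w_b = (priors.n_total - priors.n_regulated) * mass_b
    if w_r + w_b <= 0.0:
        raise ValueError("both survival-weighted operon counts are zero")
    return PriorSpec(priors.n_regulated, priors.n_total,
                     p_regulated=w_r / (w_r + w_b))


def adjust_priors(priors: PriorSpec, u_b: float, u_r: float) -> PriorSpec:
    """Renormalise the priors for the thresholded promoter set.

    The reference-genome regulated count is weighted by the probability
    (1 - U_R) that a regulated promoter survives thresholding, the
    non-regulated count by (1 - U_B):

        P(R)' = n_reg (1-U_R) / [ n_reg (1-U_R) + n_nonreg (1-U_B) ]
    """
    if not (0.0 <= u_b <= 1.0 and 0.0 <= u_r <= 1.0):
        raise ValueError("U_B and U_R must be probabilities")
    return _adjust_priors_from_masses(priors, 1.0 - u_b, 1.0 - u_r)


def adjusted_cluster_posterior(cluster: ClusterPromoterSet, model: ScoreModel,
                               priors: PriorSpec | None = None,
                               theta: float = -np.inf,
                               prior_n_windows: int | None = None) -> PosteriorRecord:
    """Sensitivity-adjusted cluster posterior at score threshold theta.

    Restricts the cluster to promoters whose best window score reaches
    theta; each retained promoter's likelihoods are divided by the
    exceedance probabilities (1-U) computed for that promoter's own window
    count, and the priors are renormalised with the window count of the
    configured maximum promoter length (``prior_n_windows``, default: the
    largest window count in the cluster). At theta = -inf this reduces
    exactly to :func:`cluster_posterior`.
    """
    priors = priors or PriorSpec()
    if math.isnan(theta):
        raise ValueError("theta must not be NaN")
    scored = [sv for sv in cluster.promoters if sv.n_windows > 0]
    retained = [sv for sv in scored if sv.max_score() >= theta]

    if prior_n_windows is None:
        prior_n_windows = max((sv.n_windows for sv in scored), default=1)

    log_ub_g, log_ur_g = _log_no_exceedance(prior_n_windows, theta, model)
    mass_b = float(-np.expm1(log_ub_g))
    mass_r = float(-np.expm1(log_ur_g))
    try:
        adj_priors = _adjust_priors_from_masses(priors, mass_b, mass_r)
    except ValueError:
        warnings.warn(
            "threshold leaves no survival mass under either model; "
            "falling back to the unadjusted posterior"
        )
        return cluster_posterior(cluster, model, priors)

    lam_sum = 0.0
    for sv in retained:
        log_ub, log_ur = _log_no_exceedance(sv.n_windows, theta, model)
        log_mass_b = float(_log1mexp(log_ub))
        log_mass_r = float(_log1mexp(log_ur))
        if not (np.isfinite(log_mass_b) and np.isfinite(log_mass_r)):
            warnings.warn(
                "exceedance probability underflow at this theta; "
                "falling back to the unadjusted posterior"
            )
            return cluster_posterior(cluster, model, priors)
        lam_sum += (promoter_loglik_background(sv, model) - log_mass_b) - (
            promoter_loglik_regulated(sv, model) - log_mass_r
        )

    posterior = float(expit(-(lam_sum + adj_priors.log_odds_background)))
    return PosteriorRecord(
        cluster_id=cluster.cluster_id,
        posterior=posterior,
        n_promoters_total=len(cluster.promoters),
        n_promoters_analyzed=len(retained),
        log_likelihood_ratio_sum=float(lam_sum),
        priors_used=adj_priors,
    )


# ---------------------------------------------------------------------------
# discretisation

def select_regulated_clusters(records: Iterable[PosteriorRecord], phi: float,
                              min_promoters: int = 0) -> list:
    """Largest high-posterior prefix with mean posterior >= 1 - phi.

    Records are sorted by posterior (descending, cluster_id as a
    deterministic tie-break); the longest prefix whose average posterior is
    at least 1-phi is retained, then clusters with fewer than
    ``min_promoters`` analysed promoters are dropped. Because the sorted
    prefix means are non-increasing, the greatest qualifying prefix length
    equals the last index at which the running mean still qualifies.
    """
    if not 0.0 < phi < 1.0:
        raise ValueError("phi must lie in (0, 1)")
    order = sorted(records, key=lambda r: (-r.posterior, r.cluster_id))
    best_n = 0
    running = 0.0
    for i, rec in enumerate(order, start=1):
        running += rec.posterior
        if running / i >= 1.0 - phi:
            best_n = i
    prefix = order[:best_n]
    return [r for r in prefix if r.n_promoters_analyzed >= min_promoters]


def resolve_theta(theta_spec, model: ScoreModel) -> float:
    """Resolve a threshold given absolutely or as "sd:k" (mu_m - k*sigma_m)."""
    if theta_spec is None:
        return -np.inf
    if isinstance(theta_spec, str):
        spec = theta_spec.strip().lower()
        if spec.startswith("sd:"):
            k = float(spec[3:])
            return model.mu_m - k * model.sigma_m
        return float(spec)  # handles "-inf" and plain numbers
    return float(theta_spec)
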