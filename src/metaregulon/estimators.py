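"""scikit-learn style estimators wrapping the inference pipeline.

``MotifScorer`` is a transformer: fit on aligned binding sites, transform
promoter sequences into combined-strand score vectors. ``RegulonClassifier``
is the full Bayesian model: fit on labelled sequences (y=1 for binding
sites, y=0 for background-pool promoters), then ``predict_proba`` returns
the posterior probability of regulation for each *cluster* of promoter
sequences. ``MotifPermutationTest`` is the frequentist baseline with the
same fit signature.

Samples at predict time are clusters (each an iterable of promoter
strings), mirroring the unit at which regulation is inferred.
"""

from __future__ import annotations

import math
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from ._sequences import encode_batch, is_valid_dna
from . import inference as inf
from .inference import (
    ClusterPromoterSet,
    PosteriorRecord,
    PriorSpec,
    log_background_pdf,
    log_mixture_pdf,
    resolve_theta,
)
from .motifs import (
    BindingSiteCollection,
    ScoreModel,
    build_matrix,
    background_score_statistics,
    motif_score_statistics,
    score_batch,
    score_sequence,
)
from .permutation import permutation_test


def _split_training_data(X, y):
    y = np.asarray(y)
    X = list(X)
    if y.shape[0] != len(X):
        raise ValueError("X and y have inconsistent lengths")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("y must contain both classes 0 (background "
                         "promoters) and 1 (binding sites)")
    sites = [x for x, lab in zip(X, y) if lab == 1]
    background = [x for x, lab in zip(X, y) if lab == 0]
    return BindingSiteCollection(tuple(sites)), background


class MotifScorer(TransformerMixin, BaseEstimator):
    """Score promoters against a PSSM built from aligned binding sites.

    Parameters
    ----------
    pseudocount : float, default 1.0
        Laplacian pseudocount used when building the log2-odds matrix.

    Attributes
    ----------
    matrix_ : PSSM
        The fitted scoring matrix.
    """

    def __init__(self, pseudocount: float = 1.0):
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        sites = X if isinstance(X, BindingSiteCollection) else \
            BindingSiteCollection(tuple(X))
        self.matrix_ = build_matrix(sites, self.pseudocount)
        self.sites_ = sites
        return self

    def transform(self, X):
        """Combined-strand ScoreVector for each promoter in X."""
        if not hasattr(self, "matrix_"):
            raise AttributeError("MotifScorer is not fitted yet")
        return [score_sequence(self.matrix_, seq, promoter_id=f"seq_{i}")
                for i, seq in enumerate(X)]


class RegulonClassifier(ClassifierMixin, BaseEstimator):
    """Bayesian classifier of TF regulation for promoter clusters.

    ``fit`` learns the PSSM from the y=1 sequences (aligned binding
    sites) and the background score statistics from the y=0 sequences
    (a pool of genomic promoters). ``predict_proba`` evaluates clusters:
    each sample is an iterable of promoter sequences mapping to one
    ortholog cluster, and the returned probability is the posterior
    P(R|D) of the cluster being regulated.

    Parameters
    ----------
    pseudocount : float
        Laplacian pseudocount of the PSSM.
    alpha : float
        Per-window probability of a functional site in a regulated
        promoter (one expected site per 300 bp by default).
    n_regulated, n_total : int
        Reference-genome operon counts behind the prior P(R).
    theta : float, str or None
        Optional sensitivity threshold; ``"sd:k"`` means
        mu_m - k*sigma_m. None disables thresholding.
    phi : float
        Discretisation parameter: ``predict`` returns the largest
        posterior-sorted prefix with mean posterior >= 1 - phi.
    min_promoters : int
        Minimum analysed promoters for a cluster to be selectable.
    motif_stats_combined : bool
        Use combined-strand instead of forward-only site scores for
        (mu_m, sigma_m).
    sigma_floor : float
        Lower bound for degenerate score standard deviations.
    max_promoter_length : int
        Promoter-length convention behind the global adjusted prior.
    """

    def __init__(self, pseudocount: float = 1.0, alpha: float = 1.0 / 300.0,
                 n_regulated: int = 3, n_total: int = 1811,
                 theta=None, phi: float = 0.1, min_promoters: int = 0,
                 motif_stats_combined: bool = False,
                 sigma_floor: float = 1e-6,
                 max_promoter_length: int = 300):
        self.pseudocount = pseudocount
        self.alpha = alpha
        self.n_regulated = n_regulated
        self.n_total = n_total
        self.theta = theta
        self.phi = phi
        self.min_promoters = min_promoters
        self.motif_stats_combined = motif_stats_combined
        self.sigma_floor = sigma_floor
        self.max_promoter_length = max_promoter_length

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y):
        """Fit PSSM, score model and priors from labelled sequences."""
        sites, background = _split_training_data(X, y)
        self.sites_ = sites
        self.matrix_ = build_matrix(sites, self.pseudocount)
        mu_m, sigma_m = motif_score_statistics(
            self.matrix_, sites, combined=self.motif_stats_combined,
            sigma_floor=self.sigma_floor)
        mu_g, sigma_g = background_score_statistics(self.matrix_, background)
        self.model_ = ScoreModel(mu_g=mu_g, sigma_g=sigma_g, mu_m=mu_m,
                                 sigma_m=sigma_m, alpha=self.alpha)
        self.priors_ = PriorSpec(self.n_regulated, self.n_total)
        self.theta_ = resolve_theta(self.theta, self.model_)
        self.prior_n_windows_ = self.max_promoter_length - self.matrix_.width + 1
        if self.theta is not None:
            ub, ur = inf.survival_probabilities(self.prior_n_windows_,
                                                self.theta_, self.model_)
            self.adjusted_priors_ = inf.adjust_priors(self.priors_, ub, ur)
        else:
            self.adjusted_priors_ = self.priors_
        self.classes_ = np.array([0, 1])
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise AttributeError("RegulonClassifier is not fitted yet")

    # -- cluster evaluation -----------------------------------------------
    def _records_fast(self, clusters) -> list:
        """Vectorised path for clean, equal-length promoters."""
        flat = [p for cl in clusters for p in cl]
        sizes = np.array([len(cl) for cl in clusters])
        enc = encode_batch(flat)
        scores = score_batch(self.matrix_, enc, dtype=np.float32)
        lam = (log_background_pdf(scores, self.model_)
               - log_mixture_pdf(scores, self.model_))
        per_prom = lam.sum(axis=1)
        n_windows = scores.shape[1]
        cluster_index = np.repeat(np.arange(len(clusters)), sizes)
        adjusted = self.theta is not None
        if adjusted:
            log_ub, log_ur = inf._log_no_exceedance(n_windows, self.theta_,
                                                    self.model_)
            log_mass_b = float(inf._log1mexp(log_ub))
            log_mass_r = float(inf._log1mexp(log_ur))
            if not (math.isfinite(log_mass_b) and math.isfinite(log_mass_r)):
                import warnings

                warnings.warn("exceedance probability underflow at this "
                              "theta; using the unadjusted posterior")
                adjusted = False
        if adjusted:
            keep = scores.max(axis=1) >= self.theta_
            adj = per_prom - log_mass_b + log_mass_r
            lam_sum = np.bincount(cluster_index[keep], weights=adj[keep],
                                  minlength=len(clusters))
            n_analyzed = np.bincount(cluster_index, weights=keep,
                                     minlength=len(clusters)).astype(int)
            priors = self.adjusted_priors_
        else:
            lam_sum = np.bincount(cluster_index, weights=per_prom,
                                  minlength=len(clusters))
            n_analyzed = sizes
            priors = self.priors_
        from scipy.special import expit

        post = expit(-(lam_sum + priors.log_odds_background))
        return [
            PosteriorRecord(cluster_id=f"cluster_{c}",
                            posterior=float(post[c]),
                            n_promoters_total=int(sizes[c]),
                            n_promoters_analyzed=int(n_analyzed[c]),
                            log_likelihood_ratio_sum=float(lam_sum[c]),
                            priors_used=priors)
            for c in range(len(clusters))
        ]

    def evaluate_clusters(self, X, cluster_ids=None) -> list:
        """PosteriorRecord for every cluster of promoter sequences in X."""
        self._check_fitted()
        clusters = [list(cl) for cl in X]
        flat = [p for cl in clusters for p in cl]
        lengths = {len(p) for p in flat}
        if flat and len(lengths) == 1 and all(is_valid_dna(p) for p in flat):
            records = self._records_fast(clusters)
        else:
            records = []
            for c, cl in enumerate(clusters):
                svs = [score_sequence(self.matrix_, seq, promoter_id=f"p{i}")
                       for i, seq in enumerate(cl)]
                cps = ClusterPromoterSet(f"cluster_{c}", svs)
                if self.theta is None:
                    rec = inf.cluster_posterior(cps, self.model_, self.priors_)
                else:
                    rec = inf.adjusted_cluster_posterior(
                        cps, self.model_, self.priors_, self.theta_,
                        prior_n_windows=self.prior_n_windows_)
                records.append(rec)
        if cluster_ids is not None:
            for rec, cid in zip(records, cluster_ids):
                rec.cluster_id = str(cid)
        return records

    # -- sklearn surface ---------------------------------------------------
    def decision_function(self, X) -> np.ndarray:
        """Log posterior odds of regulation per cluster."""
        records = self.evaluate_clusters(X)
        return np.array([
            -(r.log_likelihood_ratio_sum + r.priors_used.log_odds_background)
            for r in records
        ])

    def predict_proba(self, X) -> np.ndarray:
        records = self.evaluate_clusters(X)
        p = np.array([r.posterior for r in records])
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        """Discretised regulated set via the mean-posterior prefix rule.

        Joint over the batch: clusters are sorted by posterior and the
        largest prefix with mean posterior >= 1 - phi (and at least
        ``min_promoters`` analysed promoters each) is labelled 1.
        """
        records = self.evaluate_clusters(X)
        selected = inf.select_regulated_clusters(records, self.phi,
                                                 self.min_promoters)
        chosen = {r.cluster_id for r in selected}
        return np.array([1 if r.cluster_id in chosen else 0 for r in records])


class MotifPermutationTest(BaseEstimator):
    """Permutation-test baseline with the RegulonClassifier fit signature.

    ``p_values`` returns the empirical probability, over column-permuted
    motif models, of a cluster log-likelihood at least as high as the
    observed one (add-one corrected).
    """

    def __init__(self, n_permutations: int = 100, pseudocount: float = 1.0,
                 alpha: float = 1.0 / 300.0, symmetric: bool = False,
                 reestimate_background: bool = True, random_state=None):
        self.n_permutations = n_permutations
        self.pseudocount = pseudocount
        self.alpha = alpha
        self.symmetric = symmetric
        self.reestimate_background = reestimate_background
        self.random_state = random_state

    def fit(self, X, y):
        sites, background = _split_training_data(X, y)
        self.sites_ = sites
        self.background_ = background
        self.matrix_ = build_matrix(sites, self.pseudocount)
        return self

    def p_values(self, X, cluster_ids=None) -> np.ndarray:
        if not hasattr(self, "sites_"):
            raise AttributeError("MotifPermutationTest is not fitted yet")
        results = permutation_test(
            [list(cl) for cl in X], self.sites_, self.background_,
            n_permutations=self.n_permutations,
            pseudocount=self.pseudocount, alpha=self.alpha,
            symmetric=self.symmetric, random_state=self.random_state,
            cluster_ids=cluster_ids,
            reestimate_background=self.reestimate_background)
        self.results_ = results
        return np.array([r.p_value for r in results])
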