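"""Permutation-test baseline for cluster regulation.

The frequentist alternative to the Bayesian posterior. The motif's PSSM
columns are permuted F times; for each permutation the promoters are
rescored with the permuted matrix and the score model is re-estimated
from scratch (site statistics by rescoring the known sites, background
statistics by rescanning the promoter pool -- never copied from the
original model). The cluster statistic compared across permutations is
the regulated-vs-background log-likelihood ratio

    T_f = log P(D|R_f) - log P(D|B_f),

the permutation analogue of the Bayes factor accumulated by the
posterior. Comparing raw regulated likelihoods P(D|R_f) across rescored
datasets is degenerate: each permuted model's total likelihood is
dominated by how its re-fitted background describes its own score
distribution, a baseline shared by every cluster; the ratio cancels that
baseline. Under the null (background promoters) rescoring with a column
permutation leaves the statistic's distribution invariant, so the
add-one-corrected empirical p-value

    p = (1 + #{f : T_f >= T_obs}) / (F + 1)

is uniform on its achievable grid and confined to [1/(F+1), 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._sequences import encode_batch, is_valid_dna
from .motifs import (
    PSSM,
    BindingSiteCollection,
    ScoreModel,
    build_matrix,
    fit_score_model,
    motif_score_statistics,
    score_batch,
    score_sequence,
)
from .inference import log_background_pdf, log_mixture_pdf


@dataclass(frozen=True)
class PermutedModel:
    """A column permutation of the motif with its re-estimated score model."""

    permutation: np.ndarray
    matrix: PSSM
    model: ScoreModel


@dataclass
class PermutationResult:
    """Observed and permuted log-likelihood-ratio statistics for one cluster."""

    cluster_id: str
    observed_loglik: float          # log P(D|R) - log P(D|B), true motif
    permuted_logliks: np.ndarray    # same statistic under each permutation
    p_value: float


def permute_columns(matrix: PSSM, permutation: Sequence[int]) -> PSSM:
    """Reorder PSSM columns; the per-column weight multiset is preserved."""
    perm = np.asarray(permutation, dtype=np.int64)
    if sorted(perm.tolist()) != list(range(matrix.width)):
        raise ValueError("not a permutation of the motif columns")
    return PSSM(matrix.weights[perm], matrix.pseudocount, matrix.background)


def random_column_permutation(width: int, rng: np.random.Generator,
                              symmetric: bool = False) -> np.ndarray:
    """A uniformly random column permutation.

    ``symmetric=True`` restricts to permutations commuting with the
    reverse-complement pairing i <-> width-1-i (intended for
    pseudo-palindromic motifs): pairs are permuted among themselves and
    each pair may be flipped; an odd-width centre column stays fixed.
    """
    if width < 2:
        raise ValueError("width must be >= 2")
    if not symmetric:
        return rng.permutation(width)
    half = width // 2
    pair_perm = rng.permutation(half)
    flips = rng.integers(0, 2, size=half)
    perm = np.empty(width, dtype=np.int64)
    if width % 2:
        perm[half] = half
    for j in range(half):
        q = int(pair_perm[j])
        left, right = q, width - 1 - q
        if flips[j]:
            left, right = right, left
        perm[j] = left
        perm[width - 1 - j] = right
    return perm


def permute_motif(matrix: PSSM, sites: BindingSiteCollection,
                  background_promoters: Sequence[str],
                  random_state=None, symmetric: bool = False,
                  alpha: float = 1.0 / 300.0,
                  permutation: Sequence[int] | None = None,
                  reestimate_background: bool = True,
                  base_model: ScoreModel | None = None) -> PermutedModel:
    """Build one permuted model with statistics re-estimated from scratch.

    The motif statistics are always recomputed by rescoring the sites
    with the permuted matrix; ``reestimate_background=False`` reuses the
    original background statistics (fast mode, with a warning).
    """
    rng = (random_state if isinstance(random_state, np.random.Generator)
           else np.random.default_rng(random_state))
    if permutation is None:
        permutation = random_column_permutation(matrix.width, rng, symmetric)
    perm = np.asarray(permutation, dtype=np.int64)
    pm_matrix = permute_columns(matrix, perm)
    # the permutation applies to the whole motif: the aligned sites'
    # columns are reordered together with the matrix, so each permuted
    # site scored by the permuted matrix keeps its original score and the
    # recomputed motif statistics coincide with the original ones
    permuted_sites = BindingSiteCollection(
        tuple("".join(s[j] for j in perm) for s in sites.sites),
        source_label=f"{sites.source_label} (permuted)")
    mu_m, sigma_m = motif_score_statistics(pm_matrix, permuted_sites)
    if reestimate_background:
        from .motifs import background_score_statistics

        mu_g, sigma_g = background_score_statistics(pm_matrix,
                                                    background_promoters)
    else:
        if base_model is None:
            raise ValueError("fast mode needs the original model")
        warnings.warn("reusing original background statistics for the "
                      "permuted model (fast mode)")
        mu_g, sigma_g = base_model.mu_g, base_model.sigma_g
    model = ScoreModel(mu_g=mu_g, sigma_g=sigma_g, mu_m=mu_m,
                       sigma_m=sigma_m, alpha=alpha)
    return PermutedModel(permutation=perm, matrix=pm_matrix, model=model)


def permuted_cluster_loglik(promoters: Sequence[str], pm: PermutedModel) -> float:
    """log P(D|R_f): promoters rescored with the permuted matrix and
    evaluated under the permuted regulated mixture."""
    total = 0.0
    for i, seq in enumerate(promoters):
        sv = score_sequence(pm.matrix, seq, promoter_id=f"p{i}")
        if sv.n_windows:
            total += float(np.sum(log_mixture_pdf(sv.scores, pm.model)))
    return total


def empirical_pvalue(observed: float, permuted: Sequence[float]) -> float:
    """(1 + #{f : permuted_f >= observed}) / (F + 1); ties count as >=."""
    permuted = np.asarray(permuted, dtype=np.float64)
    if permuted.size < 1:
        raise ValueError("need at least one permuted log-likelihood")
    return float((1 + np.sum(permuted >= observed)) / (permuted.size + 1))


def _cluster_ratio_stats(matrix: PSSM, model: ScoreModel, enc: np.ndarray,
                         cluster_index: np.ndarray, n_clusters: int,
                         sizes: np.ndarray) -> np.ndarray:
    """Per-cluster log-LR statistic for a clean flat batch."""
    scores = score_batch(matrix, enc, dtype=np.float32)
    lr = log_mixture_pdf(scores, model) - log_background_pdf(scores, model)
    per_promoter = lr.sum(axis=1)
    return np.bincount(np.repeat(cluster_index, sizes), weights=per_promoter,
                       minlength=n_clusters)


def permutation_test(clusters: Sequence[Sequence[str]],
                     sites: BindingSiteCollection,
                     background_promoters: Sequence[str],
                     n_permutations: int = 100,
                     pseudocount: float = 1.0, alpha: float = 1.0 / 300.0,
                     symmetric: bool = False, random_state=None,
                     cluster_ids: Sequence[str] | None = None,
                     reestimate_background: bool = True) -> list:
    """Empirical p-values of regulation for many clusters at once.

    ``clusters`` holds each cluster's raw promoter sequences; every
    permutation rescans them with its permuted matrix. Permutation f
    derives its RNG stream from (seed, f), so extending F leaves earlier
    permutations unchanged. Clean equal-length promoters are scored in
    one vectorised batch.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    seed = random_state if random_state is not None else 0
    matrix = build_matrix(sites, pseudocount)
    model = fit_score_model(matrix, sites, background_promoters, alpha=alpha)
    if cluster_ids is None:
        cluster_ids = [f"cluster_{i}" for i in range(len(clusters))]
    n_clusters = len(clusters)

    flat = [p for cl in clusters for p in cl]
    sizes = np.array([len(cl) for cl in clusters], dtype=np.int64)
    cluster_index = np.arange(n_clusters)
    lengths = {len(p) for p in flat}
    fast = bool(flat) and len(lengths) == 1 and all(is_valid_dna(p) for p in flat)
    enc = encode_batch(flat) if fast else None

    def ratio_stats(mat: PSSM, mod: ScoreModel) -> np.ndarray:
        if fast:
            return _cluster_ratio_stats(mat, mod, enc, cluster_index,
                                        n_clusters, sizes)
        out = np.zeros(n_clusters)
        for c, cl in enumerate(clusters):
            for i, seq in enumerate(cl):
                sv = score_sequence(mat, seq, promoter_id=f"p{i}")
                if sv.n_windows:
                    out[c] += float(np.sum(
                        log_mixture_pdf(sv.scores, mod)
                        - log_background_pdf(sv.scores, mod)))
        return out

    observed = ratio_stats(matrix, model)
    exceed = np.zeros(n_clusters, dtype=np.int64)
    permuted_store = np.empty((n_permutations, n_clusters))
    for f in range(1, n_permutations + 1):
        rng_f = np.random.default_rng([seed, f])
        pm = permute_motif(matrix, sites, background_promoters,
                           random_state=rng_f, symmetric=symmetric,
                           alpha=alpha,
                           reestimate_background=reestimate_background,
                           base_model=model)
        stat_f = ratio_stats(pm.matrix, pm.model)
        permuted_store[f - 1] = stat_f
        exceed += stat_f >= observed

    pvals = (1 + exceed) / (n_permutations + 1)
    return [
        PermutationResult(cluster_id=cid, observed_loglik=float(observed[c]),
                          permuted_logliks=permuted_store[:, c].copy(),
                          p_value=float(pvals[c]))
        for c, cid in enumerate(cluster_ids)
    ]
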