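"""PSSM construction and two-strand promoter scoring.

A transcription-factor binding motif is summarised from a collection of
aligned, equal-length binding sites as a position-specific scoring matrix
(PSSM) of log2-odds weights with a Laplacian pseudocount and an
equiprobable (0.25) background. Promoters are scored on both strands and
the two strand scores at each window start are combined with a soft-max
(log-sum-exp in base 2), so the combined score never falls below the best
single-strand score and never exceeds it by more than one bit.

The motif and background score statistics estimated here parametrise the
normal score models used downstream for inference:

* ``(mu_m, sigma_m)`` -- mean/SD of the scores of the known sites;
* ``(mu_g, sigma_g)`` -- mean/SD of the pooled combined-strand scores of
  all windows of a genomic promoter pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._sequences import INVALID, decode, encode, encode_batch

#: default sigma floor for degenerate score distributions
SIGMA_FLOOR = 1e-6


@dataclass(frozen=True)
class BindingSiteCollection:
    """Aligned, equal-length TF-binding sites defining a motif."""

    sites: tuple
    source_label: str = ""

    def __post_init__(self):
        sites = tuple(str(s).upper() for s in self.sites)
        object.__setattr__(self, "sites", sites)
        if len(sites) < 2:
            raise ValueError("a binding-site collection needs at least 2 sites")
        width = len(sites[0])
        for s in sites:
            if len(s) != width:
                raise ValueError(
                    f"ragged site lengths: {s!r} has length {len(s)}, expected {width}"
                )
            if np.any(encode(s) == INVALID):
                raise ValueError(f"site {s!r} contains non-ACGT symbols")
        if width < 4:
            raise ValueError(f"motif width {width} < 4")

    @property
    def width(self) -> int:
        return len(self.sites[0])

    def __len__(self) -> int:
        return len(self.sites)

    def counts(self) -> np.ndarray:
        """(width, 4) base counts per alignment column."""
        enc = encode_batch(self.sites)
        out = np.zeros((self.width, 4), dtype=np.int64)
        for b in range(4):
            out[:, b] = (enc == b).sum(axis=0)
        return out

    def frequencies(self, pseudocount: float = 1.0) -> np.ndarray:
        """Pseudocounted per-column base frequencies, rows summing to 1."""
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        c = self.counts().astype(float) + pseudocount
        return c / c.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class PSSM:
    """Immutable log2-odds scoring matrix (width x 4, columns A,C,G,T)."""

    weights: np.ndarray
    pseudocount: float = 1.0
    background: float = 0.25

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2 or w.shape[1] != 4:
            raise ValueError("PSSM weights must have shape (width, 4)")
        w = w.copy()
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)

    @property
    def width(self) -> int:
        return int(self.weights.shape[0])

    @property
    def max_score(self) -> float:
        """Best achievable single-strand window score."""
        return float(self.weights.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return decode(self.weights.argmax(axis=1).astype(np.uint8))

    def reverse_complement(self) -> "PSSM":
        return PSSM(self.weights[::-1, ::-1], self.pseudocount, self.background)


@dataclass
class ScoreVector:
    """Combined-strand scores of one promoter, one entry per scorable window.

    ``positions`` are 1-based window starts on the promoter's 5'->3'
    orientation; windows containing non-ACGT symbols are omitted.
    """

    promoter_id: str | None
    scores: np.ndarray
    positions: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.positions is None:
            self.positions = np.arange(1, self.scores.size + 1)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.positions.shape != self.scores.shape:
            raise ValueError("positions and scores must have equal length")

    @property
    def n_windows(self) -> int:
        return int(self.scores.size)

    def max_score(self) -> float:
        return float(self.scores.max()) if self.scores.size else -np.inf


def build_matrix(sites, pseudocount: float = 1.0) -> PSSM:
    """Build the log2-odds PSSM from a binding-site collection.

    weight[k, b] = log2( (count[k, b] + pseudocount) / (N + 4*pseudocount)
                        / 0.25 )
    """
    if not isinstance(sites, BindingSiteCollection):
        sites = BindingSiteCollection(tuple(sites))
    freqs = sites.frequencies(pseudocount)
    weights = np.log2(freqs / 0.25)
    return PSSM(weights, pseudocount=pseudocount)


def combine_strand_scores(forward_score, reverse_score):
    """Soft-max combination of the two strand scores at one window.

    Returns ``log2(2**f + 2**r)``, evaluated stably by factoring out the
    larger exponent. Accepts scalars or arrays.
    """
    f = np.asarray(forward_score, dtype=np.float64)
    r = np.asarray(reverse_score, dtype=np.float64)
    if not (np.all(np.isfinite(f)) and np.all(np.isfinite(r))):
        raise ValueError("strand scores must be finite")
    out = np.logaddexp2(f, r)
    if out.ndim == 0:
        return float(out)
    return out


def _strand_window_scores(weights: np.ndarray, enc: np.ndarray,
                          dtype=np.float64) -> np.ndarray:
    """Single-strand window scores of encoded rows (codes must be < 4)."""
    n, length = enc.shape
    w = weights.shape[0]
    n_windows = length - w + 1
    out = np.zeros((n, n_windows), dtype=dtype)
    wt = weights.astype(dtype)
    for k in range(w):
        out += wt[k][enc[:, k:k + n_windows]]
    return out


def score_batch(matrix: PSSM, enc: np.ndarray, dtype=np.float64) -> np.ndarray:
    """Combined-strand window scores for an (n, L) encoded batch.

    Fast path for clean equal-length sequences; the reverse-strand score of
    a window equals the forward score of the reverse-complemented matrix at
    the same start.
    """
    if enc.ndim != 2:
        raise ValueError("expected a 2-D encoded batch")
    if enc.shape[1] < matrix.width:
        raise ValueError("sequences shorter than the motif width")
    fwd = _strand_window_scores(matrix.weights, enc, dtype)
    rev = _strand_window_scores(matrix.reverse_complement().weights, enc, dtype)
    return np.logaddexp2(fwd, rev)


def score_sequence(matrix: PSSM, promoter: str,
                   promoter_id: str | None = None) -> ScoreVector:
    """Score every window of one promoter on both strands (combined).

    Windows containing non-ACGT symbols are skipped. A promoter shorter
    than the motif yields an empty vector with a warning.
    """
    enc = encode(promoter)
    w = matrix.width
    if enc.size < w:
        warnings.warn(
            f"promoter {promoter_id or ''!s} shorter than motif width "
            f"({enc.size} < {w}); no windows scored"
        )
        return ScoreVector(promoter_id, np.empty(0), np.empty(0, dtype=np.int64))
    invalid = enc == INVALID
    clean = np.where(invalid, 0, enc)[None, :]
    scores = score_batch(matrix, clean)[0]
    if invalid.any():
        bad_windows = np.convolve(invalid.astype(np.int64), np.ones(w, dtype=np.int64),
                                  mode="valid") > 0
        keep = ~bad_windows
        if not keep.any():
            warnings.warn(
                f"promoter {promoter_id or ''!s} has no window free of "
                "ambiguous symbols; dropped"
            )
        positions = np.flatnonzero(keep) + 1
        return ScoreVector(promoter_id, scores[keep], positions)
    return ScoreVector(promoter_id, scores, np.arange(1, scores.size + 1))


def score_sites_forward(matrix: PSSM, sites: BindingSiteCollection) -> np.ndarray:
    """Forward-strand score of each site in its curated orientation."""
    enc = encode_batch(sites.sites)
    if enc.shape[1] != matrix.width:
        raise ValueError("site length does not match matrix width")
    return _strand_window_scores(matrix.weights, enc)[:, 0]


def motif_score_statistics(matrix: PSSM, sites,
                           combined: bool = False,
                           sigma_floor: float = SIGMA_FLOOR):
    """Mean and sample SD of the known-site scores (mu_m, sigma_m).

    Sites are scored in their curated orientation with the forward matrix
    by default; ``combined=True`` switches to the two-strand soft-max score
    for sensitivity analysis. Degenerate collections (fewer than two
    distinct scores) get ``sigma_floor`` with a warning.
    """
    if not isinstance(sites, BindingSiteCollection):
        sites = BindingSiteCollection(tuple(sites))
    scores = score_sites_forward(matrix, sites)
    if combined:
        enc = encode_batch(sites.sites)
        rev = _strand_window_scores(matrix.reverse_complement().weights, enc)[:, 0]
        scores = np.logaddexp2(scores, rev)
    mu = float(np.mean(scores))
    if np.unique(scores).size < 2:
        warnings.warn("fewer than 2 distinct site scores; sigma_m set to floor")
        return mu, float(sigma_floor)
    sigma = float(np.std(scores, ddof=1))
    return mu, max(sigma, float(sigma_floor))


def background_score_statistics(matrix: PSSM, promoters: Iterable[str]):
    """Mean and sample SD of pooled window scores over a promoter pool.

    Pools the combined-strand scores of every scorable window of every
    supplied promoter (mu_g, sigma_g). Order-free by construction.
    """
    pooled = []
    for i, p in enumerate(promoters):
        sv = score_sequence(matrix, p, promoter_id=f"pool_{i}")
        if sv.n_windows:
            pooled.append(sv.scores)
    if not pooled:
        raise ValueError("no scorable window in the promoter pool")
    scores = np.concatenate(pooled)
    if scores.size < 2:
        raise ValueError("need at least 2 pooled window scores to estimate sigma_g")
    return float(np.mean(scores)), float(np.std(scores, ddof=1))


@dataclass(frozen=True)
class ScoreModel:
    """Normal score models for background and regulated promoters.

    Background windows score as N(mu_g, sigma_g^2); windows of a regulated
    promoter as the mixture alpha*N(mu_m, sigma_m^2) +
    (1-alpha)*N(mu_g, sigma_g^2), where alpha is the per-window
    probability of a functional site (one expected site in a 300 bp
    promoter -> alpha = 1/300).
    """

    mu_g: float
    sigma_g: float
    mu_m: float
    sigma_m: float
    alpha: float = 1.0 / 300.0

    def __post_init__(self):
        if self.sigma_g <= 0 or self.sigma_m <= 0:
            raise ValueError("sigma_g and sigma_m must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def with_alpha(self, alpha: float) -> "ScoreModel":
        return ScoreModel(self.mu_g, self.sigma_g, self.mu_m, self.sigma_m, alpha)


def fit_score_model(matrix: PSSM, sites, background_promoters: Sequence[str],
                    alpha: float = 1.0 / 300.0,
                    motif_stats_combined: bool = False,
                    sigma_floor: float = SIGMA_FLOOR) -> ScoreModel:
    """Estimate the five score-model parameters from sites and a pool."""
    mu_m, sigma_m = motif_score_statistics(
        matrix, sites, combined=motif_stats_combined, sigma_floor=sigma_floor
    )
    mu_g, sigma_g = background_score_statistics(matrix, background_promoters)
    return ScoreModel(mu_g=mu_g, sigma_g=sigma_g, mu_m=mu_m, sigma_m=sigma_m,
                      alpha=alpha)
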