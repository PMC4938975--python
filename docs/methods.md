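# Methods

## The inference problem

A metagenome assembly yields, per sample and scafftig, predicted genes
grouped into operons, and each operon contributes the upstream region of
its lead gene as a promoter. Promoters are grouped by ortholog-cluster
identifier (eggNOG/COG); the question asked of each cluster is whether a
transcription factor (TF) with a known binding motif regulates it in the
population. Because any single metagenomic promoter carries little
evidence, the unit of inference is the cluster: all promoters mapping to
it are combined into one posterior probability of regulation.

## Scoring model

The TF's aligned binding sites (width *w*) define a position-specific
scoring matrix of log2-odds weights with a Laplacian pseudocount (default
1) and an equiprobable background:

    weight[k, b] = log2( (count[k, b] + c) / (N + 4c) / 0.25 ).

Every window of every promoter is scored on both strands and combined
with a soft-max, `log2(2^f + 2^r)`, so the combined score is within one
bit of the better strand. Windows containing non-ACGT symbols are
skipped; a promoter with no clean window is dropped with a warning
(metagenomic scafftigs contain Ns, and imputing scores would bias the
background fit).

Two normal score models are fitted:

* **Background** `B ~ N(mu_g, sigma_g^2)` from the pooled combined-strand
  scores of all windows of a genomic promoter pool. Pooling is the plain
  reading of "the positional scores of all promoters"; the alternative
  (per-promoter fits averaged) differs only at second order.
* **Regulated** `R ~ alpha N(mu_m, sigma_m^2) + (1-alpha) N(mu_g,
  sigma_g^2)`, where `(mu_m, sigma_m)` are the mean and sample SD
  (n−1 denominator throughout) of the known sites' scores and `alpha` is
  the per-window probability of a functional site. The default
  `alpha = 1/300` encodes one expected site per 300 bp promoter.

Site statistics use forward-strand scores of the sites in their curated
orientation; combining strands would inflate `mu_m` by up to one bit for
non-palindromic motifs. A `motif_stats_combined` switch enables the
combined variant for sensitivity analysis. Degenerate collections
(identical sites) receive a SD floor of 1e-6.

## Posterior of regulation

With priors from reference-genome counts (`P(R) = n_regulated/n_total`,
default 3/1811 — the copper-repressor regulon of *B. subtilis*), window
and promoter independence give the cluster posterior

    P(R|D) = 1 / (1 + exp( sum_i lambda_i + log P(B)/P(R) )),
    lambda_i = log P(D_i|B) - log P(D_i|R),

with all probability arithmetic in natural-log space (log-sum-exp for the
mixture density). A cluster with no mapped promoters keeps a likelihood
ratio product of one and returns exactly the prior.

The independence assumptions are approximations: overlapping windows
share bases, and clonal metagenomic fragments repeat the same promoter.
The mixture form itself mitigates the clonal case: one shared site is a
single draw from the site-score distribution, so a cluster of clonal
site-bearing sequences has a high-variance evidence sum whose sigmoid
average falls below that of independently sampled sites.

## Sensitivity adjustment

Restricting analysis to promoters whose best window reaches a threshold
`theta` (given absolutely or as `sd:k`, meaning `mu_m - k sigma_m`)
speeds up computation and sharpens inference in heterogeneous clusters
where only a minority of orthologs is regulated. The per-promoter
no-exceedance probabilities over its `n` scorable windows,

    U_B = Phi_g(theta)^n,
    U_R = [alpha Phi_m(theta) + (1-alpha) Phi_g(theta)]^n,

renormalise each retained promoter's likelihoods (division by `1-U`), and
the priors are renormalised by weighting the reference counts with the
probability that a promoter of the configured maximum length (300 bp)
survives thresholding: regulated count × (1-U_R), non-regulated count ×
(1-U_B), so the adjusted prior for regulation *grows* with `theta`. All
survival arithmetic uses `log1mexp`; if `1-U` underflows the code falls
back to the unadjusted posterior with a warning, and `theta = -inf`
reproduces the unadjusted posterior exactly.

## Discretisation

Clusters are sorted by posterior (ties broken by identifier) and the
longest prefix whose mean posterior is at least `1-phi` is called
regulated; a minimum count of analysed promoters (the paper-style usage
is 5) is applied afterwards. Because sorted prefix means are
non-increasing, the greatest qualifying prefix is found by a single scan,
and the returned set carries the interpretable guarantee that a cluster
drawn from it uniformly at random is regulated with probability at least
`1-phi`.

## Permutation baseline

The frequentist comparator permutes the motif's columns F times (default
100; an option restricts to permutations commuting with the
reverse-complement pairing, for pseudo-palindromic motifs). The
permutation applies to the whole motif — site alignment together with the
matrix — so the recomputed site statistics coincide with the original
ones, while the background statistics are genuinely re-estimated by
rescanning the promoter pool with the permuted matrix (a fast mode reuses
them, with a warning). The cluster statistic compared across
permutations is the regulated-vs-background log-likelihood ratio
`log P(D|R_f) - log P(D|B_f)` on the rescored data: comparing raw
regulated likelihoods is dominated by how each re-fitted background
describes its own score distribution, a baseline common to all clusters
that the ratio cancels. Under the null the statistic is exchangeable
across permutations, making the add-one-corrected p-value uniform on its
grid `{k/(F+1)}`. Each permutation's RNG stream derives from (seed, f),
so F is extensible without reshuffling earlier permutations.

## Operons and promoters

Genes on one strand of a contig with intergenic gaps below 50 bp
(`gap = next.start - prev.end - 1`; overlaps merge) form an operon; a
strand switch always breaks the run. Operons qualify when the lead gene
(first in transcription direction) has a predicted start codon and at
least 60 bp of contig sequence upstream of its translational start; the
available upstream region, up to 300 bp, is extracted 5'→3' relative to
transcription. Promoters are truncated only by the 300 bp cap and the
contig edge, not by upstream genes — the length cap is the only stated
constraint, and scafftigs are fragments. Coordinates are 1-based
inclusive internally; BED6 output converts to 0-based half-open.

## Synthetic data

Generators are pure functions of their parameters and seed and emulate
the validation conditions: 300 bp i.i.d. backgrounds at 40 % G+C,
clusters of 100 promoters, sites sampled per-column from the motif's
pseudocounted frequencies and planted by substitution (window counts stay
constant across experiment arms), placed uniformly without overlap. The
labelled benchmark assigns regulated clusters per-promoter site counts
from a geometric distribution on {0, 1, 2, ...} with expectation 0.33
(success parameter 1/1.33). Not emulated: assembly chimeras, coverage
bias, sequencing error, codon structure or real promoter composition —
passing tests demonstrate the statistical machinery, not robustness to
real assembly artifacts.

Two surrogate motifs are provided. `surrogate_motif` (default width 16,
50 sites, per-column consensus probability 0.85, optionally a per-column
profile) is the workhorse for the benchmark, sigmoid, clonal and
site-count experiments. `curated_surrogate_motif` is a deterministic
construction emulating a *compiled* collection of functionally selected
sites: ramped per-column degeneracy with deviations dealt round-robin so
each site carries a similar mismatch load. Its site-score SD is about
0.3 background-SDs — like the published copper-repressor motif, whose
threshold six site-SDs below the motif mean still sits in the far upper
tail of background scores. A column-sampled surrogate cannot reach this
regime: with independent columns the site-score SD is tied to the
background window-score SD (ratio ≳ 0.5), so `mu_m - 6 sigma_m` lands
inside the background bulk and thresholding is a no-op, while sharper or
narrower constructions make the background score lattice so discrete
that the normal tail badly under-predicts threshold exceedance. The
threshold-adjustment experiment therefore uses the curated surrogate;
with it, the adjusted prior grows from 0.0037 (k=10) through 0.02 (k=8)
to 0.15 (k=6) — the published real-data anchor (~0.01) falls inside the
swept range.

## Experiment and problem sizes

The validation experiments run at the following scales, chosen to give
stable statistics at interactive run times: ROC benchmark 1,000 clusters
× 100 promoters with 20 regulated and F=25 permutations; single-sequence
sigmoid 1,000 replicates; clonal penalty 10 replicates per arm;
site-count sweep 6 levels × 100 replicates; threshold adjustment 100
replicates at 12/100 site-bearing promoters. Background pools of 300
promoters (≈ 85,000 pooled window scores) fit `(mu_g, sigma_g)` to well
under 1 % relative error. Batch scoring is vectorised over encoded
sequence matrices (float32 accumulation for large batches; likelihoods
in float64).

## Numerical choices and edge cases

* Strand combination via `logaddexp2`; no overflow for any finite input.
* Sample SD (ddof=1) everywhere; sigma floor 1e-6 for degenerate cases.
* Posterior via the logistic of the accumulated natural-log ratio;
  survival probabilities via `n * logcdf` and `log1mexp`.
* Promoters shorter than the motif contribute nothing (warning); empty
  clusters return the prior; duplicate promoter identifiers in a cluster
  raise (the independence assumption would be knowingly violated).
* Ties in discretisation break deterministically by cluster identifier.

## Known limitations

* The normal approximations misrepresent the discrete upper tail of PSSM
  score distributions; threshold-exceedance probabilities at deep
  thresholds are under-predicted for narrow or highly conserved motifs.
  The exact score distribution could replace the normal background, at
  computational cost.
* High-scoring clonal sequences with near-average sites can still reach
  high posteriors; a variance-based heuristic over high-confidence site
  scores would be needed to flag them and is not implemented.
* `alpha` is treated as constant per window; site-density variation
  between promoters is not modelled.
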