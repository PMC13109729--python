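# Methods

## Model and procedure

The demultiplexing problem: each droplet of a multiplexed single-cell
capture carries counts for N sample-identifying hashtag oligos (HTOs), and
must be called as a singlet of one hashtag, a doublet, or a negative.
hashdemux treats the HTO counts of a droplet as a composition and works in
within-cell centred log-ratio (CLR) space throughout.

**Local CLR.** With pseudo-count ψ (default 1), droplet c's proportions are
π_ic = (HTO_ic + ψ)/(HTO_+c + Nψ) and its CLR profile
h_ic = log(π_ic / GM(π_·c)), natural log. Adding the pseudo-count inside
the proportion (numerator +ψ, denominator +Nψ) keeps the transform defined
at zero counts. Every profile sums to exactly zero, so the N CLR
coordinates are linearly dependent — the geometric fact the covariance
handling below is built around. The across-cell ("global") CLR, in which
each hashtag column is centred on its own geometric mean over droplets, is
provided in `hashdemux.comparison` strictly for contrasting with
threshold-based methods; the classifier never touches it.

**Clustering.** Droplets are clustered by Euclidean k-medoids on CLR
profiles with k = N by default (one cluster per hashtag). Medoids are
actual droplets, which keeps centroids robust against the doublets and
negatives mixed into every cluster. Two engines are implemented in
`_kmedoids.py`: exact PAM (greedy BUILD, then best-improvement SWAP with
cached nearest/second-nearest distances) used below 10 000 droplets, and
CLARA (best of 5 PAM runs on subsamples of size 40 + 2k) above. All ties
break on lowest index; only CLARA's subsampling consumes the seed, so runs
are reproducible bit for bit.

**Choosing k.** `select_k(clr, k1, k2)` clusters at both candidate values
and computes, per hashtag, the gain f_i in its best within-cluster median
CLR when moving from k1 to k2. If max_i f_i exceeds a log-fold-change
threshold (default 1), k2 is recommended. This is deliberately opt-in: on
clean data the extra cluster merely splits noise and f_i ≤ 0, while on data
with a contamination or empty-droplet blob the blob swallows one hashtag's
cluster at k = N and releases it at k = N+1 with a large gain. The
per-cluster hashtag-CLR boxplot CSV exported by the CLI backs the
recommended visual check.

**Core cells.** Within each cluster, droplets at or below the cluster's
empirical `core_quantile` (default 0.9) of Euclidean distance to the medoid
are core. The quantile uses the inverted-CDF estimator (smallest observed
distance with at least that fraction of droplets at or below it, ties
inclusive), so the core fraction is always ≥ the quantile — with 10
distinct distances and quantile 0.9, exactly 9 droplets are core. All
droplets of negative clusters (below) are forced non-core. Core cells alone
estimate the covariance, so edge-of-cluster outliers cannot inflate it.

**Cluster labelling.** Hashtag i is assigned to the cluster whose medoid
has the highest h_i (medoid mode, default); ties go to the lowest cluster
id. If two hashtags claim one cluster, labelling automatically retries in
average mode (argmax over clusters of the median CLR across the cluster's
core cells, non-core excluded first); a persistent conflict raises an error
naming the hashtags, since it indicates conflicting labelling that needs
inspection. Clusters claimed by no hashtag become negative-cluster
candidates when their median HTO library size is below the global median;
both conditions are logged, and cluster ids can also be forced negative in
the configuration. This reconstruction of the empty-droplet rule is a
design choice of this package: unclaimed but library-rich clusters are left
alone deliberately, as they usually indicate a labelling problem rather
than empty droplets.

**Covariance and distances.** The pooled covariance
Γ = Σ_l Σ_{c∈core(l)} (h_c − M⁽ˡ⁾)(h_c − M⁽ˡ⁾)ᵀ / Σ_l n_l uses deviations
from the cluster medoid, with n_l the number of *core* cells of cluster l
and no Bessel correction; at least N+1 core cells are required. Because the
sum-zero constraint puts the all-ones direction in Γ's null space, Γ is
singular (rank ≤ N−1) on every dataset, and its Moore–Penrose
pseudoinverse Γ⁺ — SVD with singular values below 1e−10 × the largest
truncated — replaces the inverse. The distance is the quadratic form
MD_cl = (h_c − M⁽ˡ⁾)ᵀ Γ⁺ (h_c − M⁽ˡ⁾), kept on the squared scale: under a
Gaussian working model within clusters, MD is approximately χ²-distributed
on N−1 degrees of freedom (one degree lost to the sum-zero constraint),
which is what the chi-square cutoff calibrates against. If every singular
value is below tolerance, Γ⁺ is the zero matrix (warned): all distances
collapse to zero and everything is called singlet, the only defensible
reading of a dataset with no covariance structure.

**Classification.** Each droplet's candidate identity is the hashtag whose
labelled cluster is nearest in MD (ties by hashtag input order; droplets of
negative clusters are outliers unconditionally). Two cutoffs are available:
the χ²(N−1) quantile at p = 0.975, and the empirical q = 0.95 quantile of
the observed minimum distances. The chi-square cutoff is the workflow
default because it adapts to the data's actual outlier fraction, whereas an
empirical 0.95 quantile by construction flags ~5% of droplets however many
doublets and negatives are present; the quantile mode remains available
(and is `initial_classify`'s own default) for the visual-inspection
workflow where q is tuned on the minimum-distance histogram the CLI
exports. Comparison is strict: min MD < cutoff → singlet.

**Outlier split.** Outliers are negatives (too little hashtag material) or
doublets (two cells' worth), so their log(HTO_+ + 1) is bimodal. A Gaussian
KDE (Silverman bandwidth, 512-point grid over the data range) estimates the
density; modes are local maxima, and the antimode is the density minimum
strictly between the two highest modes. Outliers below it are negatives,
at/above doublets. With fewer than `min_outliers` (default 10) outliers, a
unimodal density, or a degenerate KDE, the boundary falls back to the
median singlet log library size — a deliberate, deterministic fallback that
never crashes a run. The log(x+1) scale tolerates zero library sizes and
makes the mixture location-symmetric. Each doublet is annotated with its
two nearest hashtags as the plausible donor pair.

**mRNA reclassification.** With a paired transcriptome, T = median over
current singlets of log(L_c + 1), where L_c is the droplet's gene-count
total. Negatives strictly above T and doublets strictly below T become
singlets of their best hashtag (flagged `reclassified_by_mrna`); singlets
are never demoted. Skipped with a log message when no mRNA sizes are
attached or no singlets exist.

**Weak-hashtag rescue.** Opt-in only, with explicit thresholds: a negative
droplet is promoted to Singlet(target) when log(count_target + 1) ≥
`min_log_count` and the target's CLR exceeds the droplet's second-highest
CLR by ≥ `min_clr_margin`. No defaults are provided on purpose — sensible
values depend on the dataset and should be read off the CLR distributions.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `pseudo_count` | 1 | additive offset inside the CLR proportion |
| `k` | N | clusters; one per hashtag |
| `k2` | off | alternative k for `select_k` (typically N+1) |
| `lfc_threshold` | 1 | median-CLR gain (log units) that favours k2 |
| `core_quantile` | 0.9 | per-cluster distance quantile defining core cells |
| `cutoff_mode` | chisq | `chisq` (χ²(N−1) at `chisq_p`=0.975) or `quantile` (`cutoff_q`=0.95) |
| `min_outliers` | 10 | below this, the antimode fallback applies |
| `rank_tolerance` | 1e−10 | relative singular-value cutoff for Γ⁺ |

## The synthetic generator

Counts are negative binomial (mean m, size r = 5, variance m + m²/r), the
standard overdispersion model for UMI data: singlets draw their own hashtag
at `signal_mean` (300) and the rest at `background_mean` (10); doublets are
the entrywise sum of two independent singlet profiles of distinct donors;
negatives are all-background. Categories are drawn per droplet at 8%
doublets and 5% negatives. The six archetypes modify this scheme: one
hashtag's signal × 0.1 (weak), one hashtag's signal and background × 10
(over-labelled), 20% of droplets replaced by intermediate-mean counts at
√(background·signal) on all hashtags (contaminated), 15% of droplets
replaced by 0.2 × background counts and relabelled Negative (empty
cluster), all means × 0.1 (low input). mRNA library sizes are log-normal
(meanlog 8, sdlog 0.4) for singlets, the sum of two draws for doublets and
a 0.15-scaled draw for negatives, giving the Negative < Singlet < Doublet
median ordering the reclassification step relies on.

What the generator does *not* emulate: ambient-RNA gradients, cell-type
structure in the transcriptome, batch effects across lanes, same-sample
doublets (invisible to hashing by construction), or hashtag cross-talk
beyond the contamination archetype. Passing tests on these simulations
therefore demonstrate correctness of the algorithmic machinery and
robustness to the modelled quality regimes, not performance on any
particular real dataset.

One structural consequence worth knowing: because contaminated droplets'
counts are fully replaced by the intermediate-mean profile, their HTO data
carry no information about the underlying singlet/doublet/negative state.
The pipeline resolves them into singlets (via mRNA rescue) and negatives;
it cannot produce doublet calls among them, since a doublet call requires a
log library size above the antimode and the contaminated blob sits entirely
below it. Their true doublet fraction is unrecoverable from hashing alone.

## Numerical choices

- All ties (argmin/argmax, label claims, hashtag ordering) break on input
  order; with a fixed seed the whole pipeline is bit-reproducible.
- Quantiles for core-cell flagging use the inverted-CDF estimator (see
  above); the classification cutoff uses the default linear-interpolation
  quantile, where the ≥-fraction guarantee is not needed.
- `md_ratio` is defined as 1 when both distances are zero (droplet
  coincides with two centroids — maximally ambiguous).
- The Calinski–Harabasz index is computed directly so that a zero
  within-group dispersion reports +inf rather than an arbitrary finite
  value; the silhouette is the exact per-sample formula (not a subsampled
  approximation), making the evaluation deterministic; the Dunn index is
  the minimum between-cluster distance over the maximum cluster diameter.
- Micro-averaged metrics include Negative as a category by default;
  `exclude_negatives` restricts the one-vs-rest set to singlet and doublet
  categories for comparability with conventions that drop negatives.

## Problem sizes

Simulated studies use 3000 droplets × 4 hashtags (1000–2000 in unit
tests), sizes at which exact PAM, the full distance matrix and the exact
silhouette are all comfortably cheap while preserving the regimes of
interest (≥ 150 outliers for the antimode KDE, ≥ 600 contaminated droplets
for the blob cluster).

## Known limitations

- Same-sample doublets are invisible to hashing data and are not modelled.
- The negative-cluster rule (unclaimed + below-median library size) is a
  heuristic; forced cluster ids override it when it misfires.
- CLARA trades exactness for speed; with very small clusters a subsample
  can miss a cluster entirely. It only engages above 10 000 droplets or on
  request.
- The KDE antimode assumes the outlier pool is large enough to show its
  two modes; the fallback boundary is crude by design and logged loudly.
- No probabilistic posterior is produced; calls are hard assignments with
  distances and ratios exposed for inspection.
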