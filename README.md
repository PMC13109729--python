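# hashdemux

Demultiplexing of cell-hashing (hashtag-oligo, HTO) single-cell data:
assigning every droplet back to its sample of origin as a **singlet** of one
hashtag, a **doublet**, or a **negative** — including on the low-quality
data regimes (weakly bound hashtags, over-labelled hashtags, ambient
contamination, empty-droplet clusters, shallow input) where threshold-based
demultiplexers break down.

It is a library first (importable API plus narrative scripts under
`examples/`), with a thin `hashdemux` CLI for shell-driven workflows.

## Method

HTO counts are compositional within a droplet, so the working space is the
**within-cell centred log-ratio**: with pseudo-count 1,

```
π_ic = (HTO_ic + 1) / (HTO_+c + N),      h_ic = log( π_ic / GM(π_·c) )
```

where `HTO_+c` is droplet *c*'s total HTO count over the *N* hashtags and
`GM` the geometric mean over the droplet's proportions. Droplets are then
clustered by Euclidean **k-medoids** (exact PAM below 10 000 cells, CLARA
above) with *k = N* by default, one cluster per hashtag; each cluster's
medoid — an actual droplet — serves as its centroid `M⁽ˡ⁾`. Only **core
cells** (the 90% of each cluster nearest its medoid) feed the pooled
covariance

```
Γ = Σ_l Σ_{c ∈ core(l)} (h_c − M⁽ˡ⁾)(h_c − M⁽ˡ⁾)ᵀ / Σ_l n_l ,
```

which is singular by construction (every CLR profile sums to zero), so the
squared **Mahalanobis distance** of each droplet to each labelled centroid
uses the Moore–Penrose pseudoinverse:

```
MD_cl = (h_c − M⁽ˡ⁾)ᵀ Γ⁺ (h_c − M⁽ˡ⁾).
```

A droplet whose minimum distance clears a cutoff — by default the 0.975
quantile of χ²(N−1), or an empirical 0.95 quantile of the observed minima —
is a singlet of the nearest hashtag; the rest are outliers, split into
negatives (low HTO library size) versus doublets (high) at the antimode of
a kernel density estimate of their log library sizes. With a paired
transcriptome, outlier calls contradicted by the mRNA library size are
reclassified as singlets. No bimodality of per-hashtag counts is assumed
anywhere, which is what keeps the approach robust on skewed hashtags.

A seeded synthetic generator (`hashdemux.synthetic`) reproduces six
data-quality archetypes with known ground truth, so every stage is testable
without external downloads.

## Worked example

```bash
python examples/01_demultiplex_synthetic.py
```

```
cutoff (chisq): 9.348
antimode (log HTO library size): 4.883
category counts: {'Doublet': 251, 'HTO1': 629, 'HTO2': 631, 'HTO3': 663, 'HTO4': 670, 'Negative': 156}
overall accuracy vs ground truth: 0.985
  HTO1: singlet recall 0.981
  HTO2: singlet recall 0.992
  HTO3: singlet recall 0.988
  HTO4: singlet recall 0.984
```

The cutoff 9.348 is the 0.975 quantile of χ² with 3 degrees of freedom:
droplets whose minimum squared Mahalanobis distance exceeds it are
outliers. The antimode 4.88 is the log-library-size valley separating the
outliers' negative mode from their doublet mode. On this 3000-droplet
simulation (8% doublets, 5% negatives) the recovered composition (251
doublets, 156 negatives) tracks the generated one, 98.5% of droplets get
their true category, and every hashtag's singlets are recovered at ≥ 98%
recall. The other example scripts cover the six quality archetypes,
reference-based scoring, diagnostic plots and weak-hashtag rescue.

The same run from the shell:

```bash
hashdemux simulate --archetype standard --n-cells 3000 --out sim/
hashdemux demux --mtx sim/ --mrna-sizes sim/mrna_sizes.csv --out run/ --seed 1
hashdemux evaluate run/result.csv sim/truth.csv
```

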