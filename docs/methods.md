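# Methods

`methgate` implements the analytic machinery for asking whether DNA
methylation gates the transcriptional response to an inducible
transcription factor (a Gata4–glucocorticoid-receptor fusion switched on
by dexamethasone, "Dex") in two cell contexts: embryonic stem (ES) cells
and Flk1(+) mesoderm progenitors, each in wild-type (WT) and
Dnmt3a/Dnmt3b double-knockout (DKO, de-novo-methylation-deficient)
genotypes. The package provides the statistical pipeline plus a seeded
synthetic-data generator that emulates the study design so that every
stage can be validated against planted ground truth without any
external download.

## Differential expression

Probe-level log2 intensities are quantile-normalized (every sample
column is forced onto the mean-of-sorted-columns reference; tied values
within a column receive the mean of the reference values across the
tied rank run, so ties stay tied). Probes sharing a gene symbol are
averaged into one gene row; unmapped probes are dropped.

For a two-group contrast with n_a and n_b samples, each gene g gets a
pooled variance s²_g on d = n_a + n_b − 2 degrees of freedom. The
moderated t shrinks s²_g toward a prior via empirical Bayes:

    s̃²_g = (d0·s0² + d·s²_g) / (d0 + d)
    t_g   = log2FC_g / (s̃_g · sqrt(1/n_a + 1/n_b)),   p from t(d0 + d)

The hyperparameters (d0, s0²) are estimated by moment-matching the
marginal distribution of log s²_g (under the scaled-inverse-χ² prior,
s²_g ~ s0²·F(d, d0)):

    E[log s²]   = log s0² + ψ(d/2) − ψ(d0/2) + log(d0/d)
    Var[log s²] = ψ′(d/2) + ψ′(d0/2)

with ψ, ψ′ the digamma/trigamma functions; d0 solves the trigamma
equation by Newton iteration. When the observed spread of log s²_g does
not exceed ψ′(d/2) the equations imply d0 = ∞ and the common variance
(mean of s²_g) is used for every gene — in the exact-zero-variance
degenerate case this yields t = ±∞ (p = 0) for nonzero fold changes and
t = 0 (p = 1) otherwise, so noiseless fixtures reduce cleanly to pure
fold-change selection. The estimator agrees with an independent
root-finder on the same equations to 1e−9 and with Bioconductor
limma's `fitFDist` to ~1e−4 (both checked in tests).

Gene selection uses strict inequalities: p < 0.01 and linear fold
change > 2 (or > 4), directionally signed. Fold change is computed on
log2 means (a ratio of geometric means); variances are pooled within
the two contrasted groups only, since each comparison in the design is
a named pairwise condition contrast; no multiple-testing correction is
applied (raw p < 0.01 is the published rule). These three choices are
deliberate and documented here because the alternatives (linear-mean
fold change, a global linear model, FDR control) would give slightly
different gene counts.

## The hyper-responsive cascade

A gene is *hyper-responsive* at time t when it is >2-fold up (p < 0.01)
in all three comparisons, evaluated in mesoderm:

  (i)   WT Dex+  vs DKO Dex+  at t  — removes genes that respond in both
        genotypes;
  (ii)  DKO Dex− vs DKO Dex+  at t  — removes constitutively DKO-up
        (methylation-sensitive but induction-independent) genes;
  (iii) DKO 0 h  vs DKO Dex+  at t  — anchors the gain to the
        post-sorting, pre-induction baseline.

The triple intersection defines the hyper-responsive set; the full
7-region partition of the three up-sets is reported. *Persistent*
responders are the 24 h ∩ 72 h intersection; *immediate* responders are
the >2-fold up-set of DKO Dex+ 3 h vs DKO 0 h in the short-term design.
The "DKO 0 h" baseline is the mesoderm sample taken immediately after
Flk1(+) sorting, before induction. The gene universe is all genes with
a symbol surviving probe merging, and no expression floor is applied.

## Clustering and the group-1/group-2 split

Persistent responders are clustered on their per-condition replicate-
mean profiles over the combined mesoderm + ES time courses, rows
centered and unit-scaled (cosmetic: correlation is scale-free), with
distance 1 − Pearson r and average linkage (UPGMA). The agglomeration
is implemented directly: among equally close pairs the pair containing
the lowest original leaf index merges first, making the tree fully
deterministic; merge heights are checked for monotonicity rather than
assumed (average linkage on correlation distance can in principle
invert; violations are logged). The tree is cut at the root into two
clusters; the cluster with the higher mean ES response (log2FC, ES Dex+
vs Dex− at 72 h, genotypes pooled) is labeled group 1 (ES-responsive,
endoderm-like), the other group 2 (mesoderm-restricted, cardiac-like).
An exact tie falls back to the cluster holding the lowest-index leaf,
with a warning.

## ChIP peak calling and annotation

Tag tracks are strandless fragment midpoints on one synthetic
chromosome. The tag density is a Gaussian KDE (bandwidth 30 bp) scaled
to expected tags per bp, evaluated at every integer position with edge
reflection so the density sums exactly to the tag count. Candidate
regions are maximal runs where the experiment density reaches 5.0× the
genome-wide mean; a candidate becomes a peak when the experiment/
background density ratio at its summit — tracks scaled to equal totals,
background floored at its genome-wide mean — reaches 3.0. Differential
("target-specific") peaks re-apply the same summit-ratio rule against a
second experiment track. Summit-point rather than region-average ratios
are used; the repetitive-mapping filter of the original proprietary
caller has no meaning for synthetic tags and is intentionally omitted.

Peaks are associated with the nearest gene interval within 5 kb, with
distance measured peak-interval to gene-body interval (not TSS; bound
peaks in the study sit in introns and 3′ regions), ties broken toward
the smaller gene start, coordinates 0-based half-open throughout.

Central motif enrichment takes equal-length summit-centered windows and
an IUPAC consensus (default WGATAR, scanned on both strands). Per
window the match closest to the center is taken; `bin_sites` counts
windows whose best match center lies within the central bin (default
100 bp of a 500 bp window) and the p-value is the one-sided binomial
tail with q = (exact count of start positions whose match center falls
in the bin) / (searchable start positions). Note a known property of
the closest-to-center tie rule: when a window contains several
consensus matches the selected one is biased toward the bin, so the
null bin fraction exceeds q for match-dense backgrounds; the binomial
calibration is exact only in the one-match-per-window regime (the test
suite checks exactly that regime).

## Bisulfite methylation scoring

Clone reads are globally aligned to the reference top strand with match
+1, mismatch −1, linear gap −2, and reference-C vs read-T scored as a
match (the expected conversion outcome). Clones with alignment identity
< 90% or with a non-CpG-cytosine conversion rate < 95% are excluded
(the documented defaults of the QUMA analysis tool; the study names the
tool but not thresholds). Per clone, each reference CpG is called
methylated (C), unmethylated (T) or missing (gap/other). The summary
percentage pools calls across all included clones — matching the single
number reported per 24-clone panel — rather than averaging per-clone
percentages. Profile comparisons report the difference in percent
methylation with a two-sided Fisher's exact p-value on the pooled 2×2
table; the study reports no statistical test here, so the test is this
package's addition and is labeled as such.

## The synthetic-data generator

The generator emulates the study design: mesoderm sampled at 0, 12, 24,
36, 48, 72 h and ES at 0, 3, 6, 12, 24, 48, 72 h; mesoderm 0 h and Dex+
samples in triplicate, everything else in duplicate; a separate
short-term mesoderm design at 0, 1, 2, 3 h in duplicate. Each gene has
one archetype:

| archetype              | fraction | behaviour |
|------------------------|---------:|-----------|
| group1_endoderm        | 0.025 | induction response in ES (both genotypes) and DKO mesoderm |
| group2_cardiac         | 0.020 | induction response in DKO mesoderm only |
| methylation_sensitive  | 0.040 | constitutive +2.5 log2 in DKO, induction-independent |
| wt_and_dko_responder   | 0.050 | induction response in both genotypes |
| non_responder          | 0.865 | flat |

Induction effects are additive +2.0 log2, ramping linearly from zero at
t = 0 to full size at 24 h and persisting to 72 h (the study's
responders rise within 24 h and last ≥72 h; the exact curve shape is
not published, so a linear ramp to plateau is used). A planted subset
of genes is *immediate* (full effect by 1 h): 15 from the
hyper-responsive archetypes and 49 from the shared responders, giving
64 immediate genes of which 15 overlap the persistent panel — the same
64/15 structure as the study's 3-h analysis. The constitutive DKO shift
is +2.5 log2, strictly above the 4-fold bar so the strict ">4-fold"
rule selects these genes.

Noise model (the study publishes none): per-probe Gaussian noise on the
log2 scale (sd 0.25), probes sharing the gene mean; a per-array global
offset (sd 0.1) that quantile normalization removes; baselines N(8,1.5)
for non-responders. Responder and methylation-silenced genes draw low
baselines N(6.5, 0.75): in the study these are silenced developmental
and germline genes, essentially off before induction or demethylation.
This choice also matters statistically — quantile normalization assumes
most genes are exchangeable across samples, and at a 1000-gene desk
scale (vs ~20,000 on a real array) a large differential fraction with
high baselines would pile induced genes into the sparse upper tail and
attenuate their fold changes. With differential archetypes totalling
13.5% of genes and induced values landing mid-distribution, the
residual attenuation leaves planted 2.0 log2 effects at ≈1.4–1.6
post-normalization, comfortably above the 1.0 cut.

ChIP tracks: background tags uniform over a 100 kb chromosome (20,000
tags by default); the experiment track adds, per planted peak, a
Poisson number of excess tags drawn from a Gaussian around the center
(sd = width/6, truncated to the peak interval). "Enrichment" is defined
as the expected experiment/background density ratio at the center, so
an enrichment-2 peak sits below the 5.0 candidate threshold and an
enrichment-10 peak is called with a sharp, well-defined summit. Gene
intervals are placed at configured offsets from successive peak
centers. Bisulfite clones: each CpG cytosine is retained as C with its
per-CpG probability, every other cytosine converts to T except with a
0.5% failure rate.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: probe-specific affinity and saturation,
intensity-dependent (heteroskedastic) noise, correlated genes,
down-regulation, batch structure beyond a global array offset,
mappability/repeat structure and fragment-length effects in ChIP, PCR
duplicates and bisulfite PCR bias, and a real genome's annotation
density. Recovery rates reported here are properties of this generative
model at these settings, not of the original arrays.

## Pipeline sizes and defaults

The end-to-end run uses 1000 genes × 3 probes (108 arrays in the main
design, 16 in the short-term design), 12 planted DKO peaks of which 6
are shared with WT, 200 motif windows of 500 bp, and 24 clones per
bisulfite sample — sizes chosen so a full run takes about a second on
one core while keeping every planted count comfortably away from
small-number noise. All thresholds are named `RunConfig` fields (fc 2/4,
p 0.01, bandwidth 30, candidate 5.0, enrichment 3.0, 5 kb association,
95%/90% bisulfite QC) and are never hard-coded inline.

## Known limitations

- Exact reproduction of the study's headline gene counts (941/710/974/
  320/146/94) requires the deposited arrays and a contemporaneous
  probe→symbol annotation; the synthetic design reproduces the
  cascade's *structure* (and the 64/15 immediate-responder counts by
  construction), not those absolute numbers.
- The peak caller is an interpretation of a proprietary tool's
  published settings ("candidate threshold 5.0" is read as fold over
  the genome-wide mean normalized density); its absolute peak counts on
  real data would not be comparable.
- With heavy ties (exactly duplicated values) quantile normalization is
  not idempotent: the tie rule averages reference mass on the first
  pass. Continuous intensities make this a non-issue in practice.
- Fisher's exact test on pooled clone calls treats CpG calls as
  independent; within-clone correlation (co-methylation) makes it
  anti-conservative for strongly patchy regions.
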