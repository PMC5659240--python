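# Methods

## The analysis chain

`tutag` implements the statistical chain used to call cell-type-enriched
transcripts from TU-tagging purification experiments and to interpret the
calls against layer-marker gene sets.

### Low-count filter

For a pairwise comparison, CPM is computed per sample as
count / library size × 10⁶ using library sizes of the *unfiltered* matrix
(counts → filter → test, in that order). A gene is removed when the number
of comparison samples with CPM < 1 is three or more (equivalently, kept
when at most two samples fall below). The filter is idempotent and
preserves gene order. The filtered gene list is the "universe" for every
downstream stage: overlap testing, ranking, and marker-set restriction.

### Negative-binomial exact test (first-generation workflow)

Counts are modeled as K_gj ~ NB with mean s_j·q_g and variance
s_j·q_g + φ_g·(s_j·q_g)². The stages, matching the documented defaults of
the first-generation implementation of this method:

- **Size factors** — median-of-ratios: s_j = median over genes expressed in
  all samples of count_gj / geometric-mean_g. No re-centering is applied.
- **Dispersions** — method of moments on normalized counts pooled within
  conditions: raw_g = (v_g − z_g)/q_g², with q_g the base mean, v_g the
  pooled within-condition variance (denominator m − #conditions) and
  z_g = q_g·mean(1/s_j) the shot-noise term. A parametric trend
  φ(μ) = a₀ + a₁/μ is fitted to genes with positive raw dispersion by
  gamma-family IRLS (identity link), iteratively refitting on genes whose
  ratio raw/fitted lies in (10⁻⁴, 15) — the published outlier-trimming
  loop. Sharing mode "maximum": φ_g = max(raw_g, trend(q_g)), floored at
  10⁻⁸. This mode is deliberately conservative with few replicates; see
  Limitations.
- **Exact test** — condition on the gene's total K over both sample types.
  With q₀ the base mean of normalized counts, each side's total is NB with
  mean q₀·S and variance q₀·S + φ·q₀²·S₂ (S = Σ s_j, S₂ = Σ s_j² over the
  side); when the variance does not exceed the mean the Poisson limit is
  used. p = Σ{probabilities of splits (a, K−a) no larger than the observed
  split's} / Σ{all splits}, computed in log space with a 10⁻¹² relative
  guard so exactly mirrored splits tie despite rounding. All-zero genes
  return p = 1 by convention.
- **Multiple testing** — Benjamini–Hochberg step-up with stable tie
  handling; "enriched" requires padj < α (default 0.1) *and* fold
  enrichment > 1, since the published table counts only the
  type-of-interest direction of a two-sided test. Fold enrichment is the
  ratio of normalized means A/B; x/0 is reported as +inf (rankable), 0/0
  as NaN (excluded from ranking).

### Resampling overlap test

For each marker set, the database list is first restricted to the filtered
universe. The null resamples n = |enriched| genes without replacement from
the universe B times (default 1000) and records each draw's overlap with
the set; draws select the n smallest of i.i.d. uniform keys, an exact
uniform sample of n-subsets, vectorised and chunked. The universe is
canonicalized (sorted) first, so results are invariant to input order.
With m the resampling mean and d = |observed − m|, the reported p-value is
(#{x < m − d} + #{x > m + d}) / B with *strict* inequalities — the
published formula kept verbatim, so p = 0 is attainable and ties exactly
at m ± d are excluded; a standard (count+1)/(B+1) corrected p is reported
in a side field. "Significant" means the observed overlap falls outside
the empirical 2.5/97.5 percentile band (the published asterisk), with the
direction (above/below) reported explicitly since the asterisk alone is
ambiguous. The percentile CI is the simplest reading of "95% confidence
intervals derived from resampled distributions"; no other method was
stated. Each result also carries the exact hypergeometric mean nK/N and
two-sided p as a closed-form cross-check — computed independently of the
resampling path, never substituted for it.

### Rank model and MDS

Genes of the filtered universe are ranked by descending fold enrichment
(ties broken by ascending padj, then gene id, for reproducibility), and
marker membership is regressed on rank by a from-scratch IRLS logistic
fit: logit P(member) = β₀ + β₁·rank, convergence when the max coefficient
change < 10⁻⁸ (≤ 50 iterations), Wald inference from the inverse Fisher
information. Complete separation yields a non-converged flag and a warning
rather than an exception. Exact Wald p-values are reported without the
2e-16 floor that fitting software commonly prints. Whether to rank all
filtered genes or only enriched ones was an open choice; the default ranks
the full universe (both classes are present at all ranks, which the
regression needs), with `enriched_only=True` available.

Sample structure is summarized by classical (Torgerson) MDS on
leading-fold-change distances: per sample pair, the RMS of the `top`
(default 500) largest |log2 ratios| of size-factor-normalized counts with
a 0.5 pseudocount (the standard stabilization for zeros). Torgerson
embedding truncates negative eigenvalues at zero.

## The synthetic generator

The generator emulates the purification experiment's signal and noise so
the whole chain can be validated against planted truth.

Per gene: baseline abundance λ_g ~ lognormal(median 500, σ = 1.0 log
units); half-life t_g ~ lognormal(median 4 h, σ = 0.8) — the scale of
mammalian mRNA turnover, spanning roughly 1–16 h; layer weights w_g start
uniform over the layers (L2/3, L4, L5, L6, L6b, plus an "unpatterned"
mass) and, for planted markers, the home-layer weight is multiplied by
`effect_size` and renormalized. Exactly round(`frac_markers_per_layer` ×
n_genes) markers are planted per patterned layer (default 2%: 100 per
layer at 5000 genes, the per-layer scale of a 400-gene database against a
~22k transcriptome).

Over a labeling window T (default 5 h, the experiment's injection-to-
harvest wait) the newly transcribed fraction of a steady-state pool under
first-order decay is r_g = 1 − exp(−ln2·T/t_g). A purified sample with
population profile π has expected abundance

    μ_g = (1 − b)·λ_g·(π·w_g)·r_g + b·bg_g,      bg_g = λ_g·(π_tissue·w_g)

where b is the background-carryover fraction (default 0.25) and the
background term carries no r_g weighting (it is unlabeled total RNA). The
background ("WT") sample type is pure carryover scaled by a capture
efficiency `wt_capture_scale` (default 0.3: streptavidin yield from
no-UPRT tissue is ~40× lower, but library preparation amplifies to fixed
input, so the residual depth deficit is modest). Default profiles: the
type of interest weighted to L2/3 with lesser L4 mass (0.60/0.20, rest
uniform), the comparison type concentrated on L4 (0.80), tissue uniform.

Counts are NB with mean s_j·μ_g — s_j ~ U(0.5, 1.5) per sample, exercising
size-factor estimation — and dispersion φ = a₀ + a₁/(s_j·μ_g) (defaults
a₀ = 0.01, a₁ = 1.0, a bulk-RNA-seq-shaped trend); a₀ = a₁ = 0 reduces to
Poisson. Randomness flows from one seed through independent per-stage
child streams, so adding genes in one stage never perturbs another.
Replicates per type default to 3; the real replicate count was not stated,
and the pipeline accepts any ≥ 2.

This construction makes the key artifact testable exactly: against the
background type, the expected purified/background ratio of an unpatterned
gene is proportional to r_g, so it is strictly decreasing in half-life —
short-lived transcripts look "enriched" by dynamics alone, and vanish when
two purified types are compared (r_g nearly cancels).

What the generator does **not** model: read-level effects (no FASTQ, no
mapping bias), UMIs, within-pool animal-to-animal variance (each sample
pooled four animals; only per-sample NB dispersion is modeled), litter or
strain differences between Cre lines, spatial structure of cortex, and
label-efficiency differences between transcripts. Passing tests therefore
demonstrate the statistical chain recovers planted truth under NB noise
with background and kinetic artifacts — not that it is robust to
library-preparation or strain confounds in real data.

## Validation design and problem sizes

- Oracle equivalences: the exact test equals brute-force split enumeration
  for every total K ≤ 50; the IRLS logistic matches a Newton optimization
  of the likelihood (and statsmodels GLM) to 10⁻⁶; size factors match
  their two-sample closed form (1/√c, √c) and a plain-loop median-of-ratios;
  BH matches statsmodels under property testing; classical MDS reproduces
  planar configurations exactly and agrees with a PCoA oracle.
- Calibration: with "enriched" lists drawn independently of the marker set
  (universe 1000, 150 database genes, n = 100, 500 simulations, B = 10⁴),
  the published p-formula rejects at 0.05 at a rate within [0.03, 0.07],
  and the resampling mean matches nK/N within 3 standard errors at
  B = 10⁵. These sizes keep the check around two minutes.
- Planted recovery uses the default conditions at 5000 genes, 3 vs 3
  replicates, both comparisons, three seeds. Typical results: FDR ≈ 0.01
  against expected-mean truth, purified-vs-purified L2/3 precision ≈ 0.95
  vs ≈ 0.2–0.35 for purified-vs-background, background-only enrichments
  with median half-life ≈ ⅓ of the universe median, and marker sensitivity
  ≈ 0.55–0.80 (mean ≈ 0.67) — see Limitations.

## Limitations

- **Conservatism with 3 replicates.** Sharing mode "maximum" takes the
  larger of a noisy per-gene moment estimate and the fitted trend, which
  overestimates dispersion on average at small replicate counts; together
  with half-life heterogeneity pulling long-lived markers' true fold down
  toward ~1.3, planted-marker sensitivity under the default conditions is
  about 0.67, short of a 0.7 recovery target that the same pipeline meets
  only at some seeds. This is a property of the published procedure being
  reimplemented, not a tuning artifact, and is left as-is.
- Exact replication of the original enriched-gene lists depends on
  unstated version defaults of the original software; agreement is
  expected to be approximate (the deposited-table checks allow ~10% on
  list sizes).
- The trend fit assumes the a₀ + a₁/μ form; data with strongly
  non-monotone dispersion–mean relations would need a different trend.
- Gene identifiers are matched exactly and case-sensitively; harmonizing
  symbol conventions across annotation releases is the caller's
  responsibility.
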