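# Methods

## The kinetic model

Each mRNA species follows first-order kinetics, `dM/dt = TR − k_d·M`, with
steady state `M* = TR/k_d`. Decay is the sum of two parallel first-order
pathways:

* `kd_cls` — the classical cytoplasmic pathway, independent of Xrn1
  nuclear import;
* `kd_kis` — the Kis pathway, initiated in the nucleus and therefore
  dependent on the fraction of Xrn1 that is imported.

The wild-type rate is `kd_wt = kd_cls + kd_kis`, and the **Kis fraction**
`f = kd_kis/kd_wt ∈ [0, 1)` measures how much of a gene's turnover rides
on import. An import mutant retaining efficiency η decays at
`kd = kd_cls + η·kd_kis`; complete deletion of the nuclease removes both
pathways and the exosome backup rate `kd_exo` takes over. Buffering is
modelled as a power-law coupling of synthesis to decay,
`tr = tr_wt·(kd/kd_wt)^β`: β = 1 makes `M* = tr/kd` exactly invariant for
any import mutant, β = 0 removes compensation entirely. The biological
claim this encodes is that synthesis and decay respond *together* to the
loss of nuclear Xrn1, so the abundance change cancels.

Strain defaults: η = 1 (WT), 0.25 (single-NLS mutants — partial import),
0 (double-NLS mutant and the Kap120 importin deletion), β = 1 everywhere.
Whether the importin deletion leaves residual import through other
importins is unknown; η is an explicit parameter, not a fitted quantity.

## The generator presets

`generate_truth(n_genes, preset, seed)` draws, per gene, `tr_wt`
log-uniform over 0.5–50 a.u./min and `kd_wt` log-uniform over
0.02–0.7 /min (half-lives of roughly 1–35 min, the range typical of
budding-yeast mRNAs).

* **headline** — the per-gene true half-life fold-change under a full
  import block, `r = kd_wt/kd_cls`, is drawn from a lognormal with
  log-scale spread σ = 0.5 truncated at r ≥ 1, and `kd_kis = kd_wt(1 − 1/r)`.
  Truncation shifts a lognormal's median upward, so the location of the
  underlying normal is calibrated numerically (Brent root-find on the
  truncated CDF) to make the truncated median *exactly* 2.5 — the median
  fold-stabilization the import-blocked mutant shows genome-wide. The
  r ≥ 1 floor reflects that essentially no mRNA is destabilized by the
  block.
* **uniform** — Kis fractions drawn Uniform(0, 0.9): a flat spectrum for
  binning tests.
* **null** — `kd_kis = 0` everywhere: every import mutant is kinetically
  identical to the wild type, the negative control for the whole chain.

The exosome backup is `kd_exo = kd_wt/s` with `s` lognormal around
median 2.5 (σ = 0.25), *independent of f*: deleting the nuclease
stabilizes all genes comparably, which is exactly the contrast the Kis
bins are meant to expose (graded response to the import block, flat
response to deletion).

## Simulated measurements and what they do not capture

GRO signals are `tr·e^ε` and `(tr/kd)·e^ε'` with i.i.d. Normal(0, σ)
log-space noise per gene × replicate, times a strain cell-volume factor;
defaults are 3 replicates and σ = 0.2. Multiplicative lognormal noise is
the simplest model consistent with a ratio-based analysis, and it makes
the geometric mean the natural replicate aggregator. What this does *not*
emulate: probe-specific hybridization biases, correlated replicate
batches, count-level (Poisson) noise at low expression, and any absolute
calibration of arbitrary units to molecules or minutes. Passing tests
therefore demonstrate correctness of the inference algebra and its noise
robustness, not robustness to structured biases in real GRO data.

Shutoff courses decay as `level·e^(−kd·t)` with a constant reference
transcript (SCR1, a stable Pol III product) emitted for normalization.
Refeed count tables are multinomial draws over gene mass `RA(t)` plus a
constant spike-in mass anchored to the reference steady-state total —
spike cells are a fixed proportion of sample cells, so the spike share of
reads is the nominal fraction in a fully recovered sample and larger in
starved samples; this is what lets spike normalization recover absolute
abundance changes that within-sample proportions erase. RIP-seq reads
carry a trailing-A length (a configurable fraction exceeds 15) and a
rounded-normal distance to the gene's primary polyA site; in vivo under
an import mutant the per-gene rate is multiplied by `exp(γ·f·(1−η))`
(γ = 1.5), a monotone enrichment standing in for unproductive Xrn1–mRNA
association on high-Kis transcripts; in vitro binding is f-independent.

## Inference and analysis choices

* **Replicate aggregation**: geometric mean per signal; genes with any
  zero signal are flagged and excluded from half-life computation rather
  than imputed.
* **Half-life**: `HL = RA/TR`, arbitrary units. Units are strain-internal;
  only ratios are interpreted, so a global cross-strain factor cancels.
  No mapping of HL arbitrary units to minutes is attempted.
* **Decay fits**: unweighted least squares on ln(level) vs time after
  dividing by the reference transcript at each timepoint;
  half-life = ln2/|slope|. A slope within 1e-9 of zero is reported as an
  infinite half-life ("flat"), a positive slope beyond that tolerance as
  a rejected fit — never as a crash.
* **Kis classification**: both ratios ≥ threshold (default 2), boundary
  inclusive. Overlap significance of the HL- and TR-affected sets is the
  upper-tail hypergeometric probability.
* **Binning**: genes ranked by Kis value descending; bin 1 = highest
  (most affected). The opposite labeling is available via a flag. Sizes
  differ by at most one, remainder to the leading bins; ties break by
  gene id so permuting the input never changes an assignment.
* **Buffering test**: two-sided Wilcoxon rank-sum on the RA vectors plus
  the two medians.
* **Read quantification**: trailing-A filter is strict (>15, i.e. ≥ 16);
  the polyA-site window is symmetric and inclusive (|d| ≤ 250 bp) on the
  signed distances supplied in the input records (whether those distances
  are genomic or transcript-coordinate is the caller's convention), with
  an upstream-only option; log2 fold-changes of counts use pseudocount
  0.5 and are centered by subtracting the global median.
* **Dynamics**: the piecewise-constant-TR linear ODE is solved in closed
  form per segment; no stochastic bursting, which is beside the point for
  the relaxation-time argument.

## Problem sizes

The test suite and the acceptance script run the full chain at 5000 genes
× 3 replicates (seconds per run), which is ample for median-level
recovery: the stochastic spread of the recovered median HL ratio across
seeds is well under the 10% acceptance band. Generator-distribution
checks use 200 000 draws; exhaustive hypergeometric enumeration is done
for universes up to 12 genes.

## Known limitations

* Genome-wide counts from the original study (numbers of Kis mRNAs,
  stabilized genes, synthesis-compromised genes) depend on that study's
  deposited supplementary tables; the package reproduces the *procedure*
  (feed any pair of kinetics tables through `compute_kis_values` →
  `classify_kis`) and its behaviour on synthetic cohorts, not those exact
  counts.
* The η values for partial-import strains are plausible settings, not
  estimates; nothing in the package fits them.
* `correlate_log_ratios` returns NaN for a constant input vector (the
  correlation is undefined there), and the pipeline report records it as
  null.
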