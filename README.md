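# kisflux

Tools for studying **mRNA buffering** — the reciprocal coupling of mRNA
synthesis and decay that holds steady-state mRNA levels constant — through
the lens of Xrn1, the major yeast cytoplasmic 5′→3′ exoribonuclease, whose
nuclear import links the two processes.

## The problem and the model

Genomic run-on (GRO) experiments measure, per gene, a nascent transcription
rate (TR) and a steady-state mRNA abundance (RA). At steady state
`RA = TR / k_d`, so the ratio

```
HL = RA / TR            (half-life, arbitrary units, ∝ 1/k_d)
```

is a decay-rate readout obtained without any shutoff experiment. When Xrn1
nuclear import is blocked (mutating its NLSs or deleting the importin
Kap120), both TR and HL change per gene while RA stays put. kisflux scores
each gene's import sensitivity with a **Kis value**:

```
kis_value = HL_mut / HL_wt  +  TR_wt / TR_mut
```

Both terms equal 1 for an unaffected gene (score 2) and grow together when
import matters. Genes with both terms ≥ 2-fold are **Kis mRNAs** — their
decay pathway initiates in the nucleus. Ranking genes by Kis value into
equal-size bins (bin 1 = most affected) exposes a continuous spectrum of
import dependence rather than a binary class.

The synthetic-data generator makes this model executable: each gene decays
through a classical cytoplasmic pathway (`kd_cls`) plus an import-dependent
Kis pathway (`kd_kis`); import mutants retain a fraction η of the Kis
pathway, buffering rescales synthesis as `tr = tr_wt·(kd/kd_wt)^β`, and an
*xrn1*Δ condition falls back to an exosome rate. Every measurement modality
(GRO triplicates, shutoff decay courses, spike-in count tables, RIP-seq
read records) is simulated with its ground truth stored alongside, so the
whole inference chain is testable without downloading anything.

## Worked example

```bash
kisflux run --preset headline --n-genes 5000 --bins 6 --seed 0 --out demo
```

runs simulate → GRO inference → Kis analysis end-to-end. The same chain as
a library, with the numbers it prints:

```python
>>> from kisflux.pipeline import RunConfig, run_pipeline
>>> report = run_pipeline(RunConfig(n_genes=5000, seed=1, outdir="demo"))
>>> report["median_hl_ratio"]
2.4906402699496306
>>> report["n_kis"], report["n_scored"]
(3092, 5000)
>>> report["buffering_p"]
0.9403462249271596
>>> report["hl_tr_log_ratio_pearson_r"]
0.9471341251834491
```

The headline preset builds genes whose true median half-life fold-change
under a full import block is 2.5; the pipeline recovers 2.49 from noisy
triplicates. 3092 of 5000 genes have both synthesis and decay ≥ 2-fold
affected (Kis mRNAs), yet the Wilcoxon rank-sum test finds no shift in RA
between mutant and wild type (p = 0.94): abundance is buffered because the
per-gene HL and TR fold-changes cancel — which is also why they correlate
(r = 0.95).

The `analysis/` drivers tell the same story step by step
(`01_simulate_cohort.py` → `05_response_dynamics.py`), writing their
tables under `results/`: the import mutant's per-bin median log2 HL ratios
grade smoothly from bin 1 to bin 6 while the *xrn1*Δ strain stabilizes all
bins alike; simulated in vivo RIP-seq binding grades with Kis value while
in vitro binding is flat; and co-scaling TR and k_d leaves steady states
untouched while shrinking the response half-time ln2/k_d.

## Package layout

| module | contents |
| --- | --- |
| `kisflux.simulate` | two-pathway ground truth, condition algebra, GRO/shutoff/count/RIP simulators |
| `kisflux.gro` | volume normalization, replicate aggregation, HL = RA/TR, decay-curve fitting, spike-in normalization |
| `kisflux.kis` | Kis values, ≥2-fold classification, hypergeometric overlap, equal-size binning, buffering rank-sum test |
| `kisflux.ripseq` | poly(A) read filter (>15 A), 250-bp polyA-site window counts, replicate sums, RPKM, binned log2 fold-changes |
| `kisflux.dynamics` | closed-form dM/dt = TR(t) − k_d·M, response half-times |
| `kisflux.pipeline`, `kisflux.cli`, `kisflux.io` | end-to-end driver, `kisflux` CLI subcommands, TSV/BED round-trip formats |
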