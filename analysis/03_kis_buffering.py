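#!/usr/bin/env python
"""The core analysis: Kis values, classification, binning, buffering.

Scores every gene's import sensitivity against the wild type, counts
genes with >= 2-fold effects on synthesis and decay, tests the
significance of their overlap, splits genes into 6 equal-size Kis bins,
contrasts the per-bin half-life response of the import mutant with the
xrn1-null strain, and checks that steady-state abundance is buffered.
Run 01 and 02 first.
"""

import json
import pathlib

import numpy as np
import pandas as pd

from kisflux import io, kis

results = pathlib.Path(__file__).resolve().parent.parent / "results"
kinetics = io.read_tsv(results / "kinetics.tsv", io.KINETICS_COLUMNS)
by_strain = {s: g.reset_index(drop=True) for s, g in kinetics.groupby("strain")}

table = kis.compute_kis_values(by_strain["WT"], by_strain["dNLS12"])
cls = kis.classify_kis(table, threshold=2.0)
table = kis.assign_bins(table, n_bins=6)
io.write_tsv(table, results / "kis_table.tsv", io.KIS_COLUMNS)

overlap_p = kis.overlap_significance(cls.hl_affected, cls.tr_affected, len(table))
print(f"{len(cls.hl_affected)} genes >=2-fold stabilized, "
      f"{len(cls.tr_affected)} >=2-fold synthesis-compromised, "
      f"{len(cls.kis_genes)} Kis mRNAs (overlap p = {overlap_p:.3g})")
print(f"median HL ratio {table['hl_ratio'].median():.3f}, "
      f"median inverse TR ratio {table['tr_ratio_inv'].median():.3f}, "
      f"median Kis value {table['kis_value'].median():.3f}")

# per-bin medians: import mutant grades with Kis value, xrn1-null does not
summaries = []
for strain in ("dNLS12", "dXRN1"):
    ratios = kis.compute_kis_values(by_strain["WT"], by_strain[strain]).set_index("gene_id")
    aligned = ratios.loc[table["gene_id"], "hl_ratio"].to_numpy()
    summary = kis.bin_summary(np.log2(aligned), table["bin"].to_numpy())
    summary.insert(0, "strain", strain)
    summaries.append(summary)
    med = summary["median"].round(2).tolist()
    print(f"{strain}: per-bin median log2 HL ratio (bin 1 -> 6): {med}")
io.write_tsv(pd.concat(summaries, ignore_index=True), results / "bin_summary.tsv")

merged = by_strain["WT"].merge(by_strain["dNLS12"], on="gene_id", suffixes=("_wt", "_mut"))
buf = kis.buffering_test(merged["RA_wt"], merged["RA_mut"])
corr = kis.correlate_log_ratios(table["hl_ratio"], table["tr_ratio_inv"])
print(f"buffering: median RA {buf.median_wt:.2f} (WT) vs {buf.median_mut:.2f} "
      f"(mutant), rank-sum p = {buf.pvalue:.3f} -> "
      f"{'not significant, buffered' if buf.pvalue > 0.05 else 'SHIFTED'}")
print(f"log2 HL-ratio vs log2 inverse-TR-ratio Pearson r = {corr:.3f}")

report = {
    "n_scored": len(table), **cls.counts, "overlap_p": overlap_p,
    "median_hl_ratio": float(table["hl_ratio"].median()),
    "median_tr_ratio_inv": float(table["tr_ratio_inv"].median()),
    "median_kis_value": float(table["kis_value"].median()),
    "buffering_median_ra_wt": buf.median_wt,
    "buffering_median_ra_mut": buf.median_mut,
    "buffering_p": buf.pvalue,
    "hl_tr_log_ratio_pearson_r": corr,
}
(results / "kis_report.json").write_text(json.dumps(report, indent=2) + "\n")
print(f"wrote {results / 'kis_table.tsv'}, bin_summary.tsv, kis_report.json")
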