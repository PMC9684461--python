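"""Read-level quantification for RIP-seq / CRAC-style experiments.

Reads arrive post-alignment as simplified records: gene, signed mapped
distance to the gene's annotated primary polyadenylation site, and the
length of the read's 3' adenine homopolymer. Full-length poly(A) mRNAs
are selected by requiring strictly more than 15 trailing adenines
(degradation intermediates usually carry 10 or fewer), counted within
250 bp of the primary polyA site, summed over replicates, and compared
between strains as centered log2 fold-changes within predefined
Kis-value bins.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO


def filter_polya_reads(reads: pd.DataFrame, min_a_exclusive: int = 15) -> pd.DataFrame:
    """Keep reads whose trailing-A run is strictly longer than the cutoff.

    The default (15) keeps reads with >= 16 adenines — mainly
    full-length mRNAs rather than decay intermediates.
    """
    if min_a_exclusive < 0:
        raise ValueError("min_a_exclusive must be >= 0")
    return reads[reads["trailing_A"] > min_a_exclusive].reset_index(drop=True)


def count_near_polya(
    reads: pd.DataFrame,
    sites: pd.DataFrame,
    window_bp: int = 250,
    upstream_only: bool = False,
) -> pd.Series:
    """Per-gene count of reads mapping near the primary polyA site.

    The window is symmetric and inclusive by default: a read counts when
    |distance_bp| <= window_bp (distance_bp is mapped position minus
    site position, in the coordinate system of the input records).
    With ``upstream_only`` the window is -window_bp <= distance <= 0.
    Every gene in the site annotation is emitted, zero if no reads.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    unknown = set(reads["gene_id"]) - set(sites["gene_id"])
    if unknown:
        raise ValueError(f"reads reference genes absent from annotation: {sorted(unknown)[:5]}")
    d = reads["distance_bp"]
    in_window = (d >= -window_bp) & (d <= 0) if upstream_only else d.abs() <= window_bp
    counts = reads[in_window].groupby("gene_id").size()
    return counts.reindex(sites["gene_id"].sort_values(), fill_value=0).rename("count")


def sum_replicates(count_tables: list[pd.Series]) -> pd.Series:
    """Element-wise sum of per-gene counts across replicates.

    All replicates must cover the identical gene universe.
    """
    if not count_tables:
        raise ValueError("no count tables given")
    universe = set(count_tables[0].index)
    for t in count_tables[1:]:
        if set(t.index) != universe:
            raise ValueError("count tables have different gene universes")
    total = count_tables[0].copy()
    for t in count_tables[1:]:
        total = total.add(t)
    return total.rename("count")


def rpkm(counts, gene_lengths_bp, total_mapped: float):
    """Reads per kilobase of transcript per million mapped reads.

    RPKM = counts / (length_kb * total_mapped_millions).
    """
    lengths = np.asarray(gene_lengths_bp, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    return np.asarray(counts, dtype=float) / (lengths / 1e3 * total_mapped / 1e6)


def binned_log2fc(
    counts_mut: pd.Series,
    counts_wt: pd.Series,
    bins: pd.Series,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Centered per-bin medians of mutant/WT log2 fold-changes.

    Per gene: log2((mut + pseudocount) / (wt + pseudocount)); the global
    median over all genes is then subtracted (computational centering,
    removing any depth offset between libraries), and the median of the
    centered values is reported within each predefined Kis bin.

    All three inputs are indexed by gene_id and must align.
    """
    if not (counts_mut.index.equals(counts_wt.index)):
        counts_wt = counts_wt.reindex(counts_mut.index)
        if counts_wt.isna().any():
            raise ValueError("count tables are not aligned")
    bins = bins.reindex(counts_mut.index)
    if bins.isna().any():
        raise ValueError("bin assignment missing for some genes")
    lfc = np.log2((counts_mut + pseudocount) / (counts_wt + pseudocount))
    lfc = lfc - lfc.median()
    out = (
        pd.DataFrame({"lfc": lfc, "bin": bins.astype(int)})
        .groupby("bin")["lfc"]
        .agg(n_genes="size", median_lfc="median")
        .reset_index()
        .sort_values("bin")
        .reset_index(drop=True)
    )
    return out


def crac_rpkm_correlation(rpkm_a, rpkm_b, pseudocount: float = 0.5) -> float:
    """Pearson correlation of two samples' log2(RPKM + pseudocount)."""
    a = np.log2(np.asarray(rpkm_a, dtype=float) + pseudocount)
    b = np.log2(np.asarray(rpkm_b, dtype=float) + pseudocount)
    if a.size != b.size:
        raise ValueError("RPKM vectors must be aligned")
    from scipy.stats import pearsonr

    return float(pearsonr(a, b).statistic)


def extract_trailing_a(fastq_path) -> pd.DataFrame:
    """Count trailing 3' adenines for each read in a plain FASTQ file.

    Returns ``read_id, trailing_A``. Qualities are ignored; only the
    terminal A-homopolymer length is measured (case-insensitive).
    """
    rows = []
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        seq = str(rec.seq).upper()
        n = len(seq) - len(seq.rstrip("A"))
        rows.append({"read_id": rec.id, "trailing_A": n})
    return pd.DataFrame(rows, columns=["read_id", "trailing_A"])
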