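"""Kis-value scoring, classification, binning and buffering tests.

The Kis value of a gene quantifies how strongly both of its kinetic
features respond to blocking Xrn1 nuclear import:

    kis_value = HL_mut / HL_wt  +  TR_wt / TR_mut

Both terms exceed 1 when import matters for the gene (decay slows, so
HL rises; synthesis slows, so TR falls), and each equals 1 when it does
not; an unaffected gene therefore scores 2. A gene is called a "Kis
mRNA" when both terms are >= 2-fold. Genes ranked by Kis value are
split into equal-size bins (bin 1 = highest, most import-sensitive) to
summarize gradual responses, and buffering is tested by comparing RA
distributions between strains with a Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def compute_kis_values(wt: pd.DataFrame, mut: pd.DataFrame) -> pd.DataFrame:
    """Per-gene fold-changes and Kis values from two kinetics tables.

    Both inputs need columns ``gene_id, TR, HL``. Genes missing from
    either table, or with nonpositive/undefined TR or HL in either
    strain, are dropped (the count is logged).

    Returns ``gene_id, hl_ratio, tr_ratio_inv, kis_value``.
    """
    merged = wt.merge(mut, on="gene_id", suffixes=("_wt", "_mut"))
    n_union = len(set(wt["gene_id"]) | set(mut["gene_id"]))
    cols = ["TR_wt", "HL_wt", "TR_mut", "HL_mut"]
    ok = (merged[cols] > 0).all(axis=1) & merged[cols].notna().all(axis=1)
    dropped = n_union - int(ok.sum())
    if dropped:
        logger.info("compute_kis_values: dropped %d gene(s) missing or undefined", dropped)
    merged = merged[ok]
    out = pd.DataFrame(
        {
            "gene_id": merged["gene_id"].to_numpy(),
            "hl_ratio": (merged["HL_mut"] / merged["HL_wt"]).to_numpy(),
            "tr_ratio_inv": (merged["TR_wt"] / merged["TR_mut"]).to_numpy(),
        }
    )
    out["kis_value"] = out["hl_ratio"] + out["tr_ratio_inv"]
    return out


@dataclass(frozen=True)
class KisClassification:
    """Affected-gene sets at a fold-change threshold."""

    hl_affected: frozenset
    tr_affected: frozenset
    kis_genes: frozenset  # intersection: both criteria met

    @property
    def counts(self) -> dict:
        return {
            "n_hl_affected": len(self.hl_affected),
            "n_tr_affected": len(self.tr_affected),
            "n_kis": len(self.kis_genes),
        }


def classify_kis(table: pd.DataFrame, threshold: float = 2.0) -> KisClassification:
    """Classify Kis mRNAs: both HL and TR affected >= threshold-fold.

    The boundary is inclusive: a gene with hl_ratio exactly equal to the
    threshold counts as affected. Adds/overwrites an ``is_kis`` column
    on the input table in place.
    """
    if threshold <= 1:
        raise ValueError("threshold must be > 1")
    hl_hit = table["hl_ratio"] >= threshold
    tr_hit = table["tr_ratio_inv"] >= threshold
    table["is_kis"] = hl_hit & tr_hit
    genes = table["gene_id"]
    return KisClassification(
        hl_affected=frozenset(genes[hl_hit]),
        tr_affected=frozenset(genes[tr_hit]),
        kis_genes=frozenset(genes[hl_hit & tr_hit]),
    )


def overlap_significance(set_a, set_b, universe_size: int) -> float:
    """Upper-tail hypergeometric p-value for a gene-set overlap.

    Probability of drawing at least the observed intersection when a
    set of size |B| is sampled without replacement from a universe that
    contains |A| marked genes.
    """
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("set larger than universe")
    k = len(a & b)
    return float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))


def assign_bins(
    table: pd.DataFrame, n_bins: int, highest_first: bool = True
) -> pd.DataFrame:
    """Split genes ranked by Kis value into equal-size bins.

    Bin 1 holds the highest Kis values (the most import-sensitive
    mRNAs) by default; pass ``highest_first=False`` to label from the
    low end instead. Bin sizes differ by at most one (remainder genes
    go to the leading bins); ties in kis_value are broken by gene_id so
    the assignment is deterministic.

    Returns a copy of the table with a ``bin`` column (1..n_bins).
    """
    n = len(table)
    if not (1 <= n_bins <= n):
        raise ValueError("n_bins must be between 1 and the gene count")
    ranked = table.sort_values(
        ["kis_value", "gene_id"], ascending=[not highest_first, True]
    ).reset_index(drop=True)
    edges = np.array_split(np.arange(n), n_bins)
    bins = np.empty(n, dtype=int)
    for i, idx in enumerate(edges, start=1):
        bins[idx] = i
    ranked["bin"] = bins
    return ranked


def bin_summary(values_log2, bins) -> pd.DataFrame:
    """Per-bin medians and quartiles of log2-scale values.

    Returns ``bin, n_genes, median, q1, q3`` sorted by bin.
    """
    df = pd.DataFrame({"value": np.asarray(values_log2, dtype=float), "bin": bins})
    if len(df) == 0:
        raise ValueError("no values to summarize")
    out = (
        df.groupby("bin")["value"]
        .agg(
            n_genes="size",
            median="median",
            q1=lambda v: float(np.percentile(v, 25)),
            q3=lambda v: float(np.percentile(v, 75)),
        )
        .reset_index()
        .sort_values("bin")
        .reset_index(drop=True)
    )
    return out


@dataclass(frozen=True)
class BufferingResult:
    median_wt: float
    median_mut: float
    pvalue: float


def buffering_test(ra_wt, ra_mut) -> BufferingResult:
    """Test whether steady-state mRNA abundance differs between strains.

    Buffering predicts no shift: reciprocal changes in synthesis and
    decay leave RA unchanged, so the two-sided Wilcoxon rank-sum test
    should be non-significant despite large kinetic differences.
    """
    wt = np.asarray(ra_wt, dtype=float)
    mut = np.asarray(ra_mut, dtype=float)
    if wt.size == 0 or mut.size == 0:
        raise ValueError("empty abundance vector")
    stat = stats.ranksums(wt, mut)
    return BufferingResult(
        median_wt=float(np.median(wt)),
        median_mut=float(np.median(mut)),
        pvalue=float(stat.pvalue),
    )


def correlate_log_ratios(x_ratios, y_ratios) -> float:
    """Pearson correlation between two sets of log2 fold-changes."""
    x = np.log2(np.asarray(x_ratios, dtype=float))
    y = np.log2(np.asarray(y_ratios, dtype=float))
    if x.size != y.size:
        raise ValueError("ratio vectors must be aligned")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("ratios must be finite and positive")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")  # correlation undefined for a constant vector
    return float(stats.pearsonr(x, y).statistic)
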