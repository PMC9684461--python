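"""Table formats: TSV with a single header row, BED for genomic sites.

Every writer has a matching reader that round-trips to an identical
in-memory table; column order is stable so seeded runs are
byte-reproducible.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

TRUTH_COLUMNS = ["gene_id", "tr_wt", "kd_cls", "kd_kis", "kd_exo"]
GRO_COLUMNS = ["gene_id", "strain", "replicate", "ntr", "ra"]
KINETICS_COLUMNS = ["gene_id", "strain", "TR", "RA", "HL"]
KIS_COLUMNS = ["gene_id", "hl_ratio", "tr_ratio_inv", "kis_value", "is_kis", "bin"]
COURSE_COLUMNS = ["gene_id", "minutes", "level"]
COUNT_COLUMNS = ["gene_id", "sample", "count"]
READ_COLUMNS = ["read_id", "gene_id", "distance_bp", "trailing_A"]


def write_tsv(df: pd.DataFrame, path, columns: list[str] | None = None) -> None:
    if columns is not None:
        df = df[columns]
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path, columns: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if columns is not None:
        missing = set(columns) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        df = df[columns]
    return df


def write_bed_sites(sites: pd.DataFrame, path) -> None:
    """Write polyA sites as BED6 single-base intervals (0-based,
    half-open): chrom, position, position+1, gene_id, 0, strand."""
    bed = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "start": sites["position"],
            "end": sites["position"] + 1,
            "name": sites["gene_id"],
            "score": 0,
            "strand": sites["strand"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_bed_sites(path) -> pd.DataFrame:
    """Read a BED6 polyA-site annotation back to the internal table."""
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    if ((bed["end"] - bed["start"]) != 1).any():
        raise ValueError("primary polyA sites must be single-base intervals")
    return pd.DataFrame(
        {
            "gene_id": bed["name"],
            "chrom": bed["chrom"],
            "position": bed["start"],
            "strand": bed["strand"],
        }
    )


def counts_to_series(counts: pd.DataFrame, sample: str) -> pd.Series:
    """Extract one sample's per-gene counts as a gene-indexed Series."""
    sub = counts[counts["sample"] == sample]
    if sub.empty:
        raise ValueError(f"sample {sample!r} not present")
    return sub.set_index("gene_id")["count"].sort_index()


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
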