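"""GRO kinetic inference: TR, RA and half-lives from raw measurements.

At steady state, abundance = synthesis / decay, so the ratio RA/TR is
proportional to 1/decay-rate and serves as a half-life in arbitrary
units. This module turns replicated GRO signals into a per-gene
kinetics table (TR, RA, HL), fits shutoff decay curves normalized to a
stable reference transcript, and applies spike-in normalization to
count tables. Units are strain-internal and arbitrary; only ratios are
meaningful downstream, which makes any global cross-strain factor
cancel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def normalize_to_cell_volume(values: np.ndarray | pd.Series, volume: float):
    """Divide signals by the strain's average cell volume.

    GRO signals scale with cellular content; dividing by the median cell
    volume puts strains with different cell sizes on a per-volume scale.
    """
    if volume <= 0:
        raise ValueError("volume must be > 0")
    return values / volume


def aggregate_replicates(sample: pd.DataFrame) -> pd.DataFrame:
    """Collapse a long-format GRO sample to per-gene (TR, RA).

    Uses the geometric mean across replicates per signal, the natural
    aggregator under multiplicative noise. Genes with any nonpositive
    signal in either channel are flagged (``flagged`` column); their
    aggregate is set to NaN so no half-life is derived from them.
    """
    if sample.empty:
        raise ValueError("empty GRO sample")
    if (sample[["ntr", "ra"]].to_numpy() < 0).any():
        raise ValueError("signals must be nonnegative")

    def geomean(x: pd.Series) -> float:
        if (x <= 0).any():
            return np.nan
        return float(np.exp(np.log(x).mean()))

    agg = sample.groupby("gene_id", sort=True).agg(
        TR=("ntr", geomean), RA=("ra", geomean)
    )
    agg["flagged"] = agg["TR"].isna() | agg["RA"].isna()
    n_flagged = int(agg["flagged"].sum())
    if n_flagged:
        logger.info("aggregate_replicates: %d gene(s) flagged (zero signal)", n_flagged)
    return agg.reset_index()


def compute_half_life(ra, tr):
    """Half-life in arbitrary units: HL = RA / TR.

    Genes with nonpositive TR get NaN (undefined half-life) rather than
    raising; they are excluded from ratio analyses downstream.
    """
    ra = np.asarray(ra, dtype=float)
    tr = np.asarray(tr, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        hl = np.where(tr > 0, ra / tr, np.nan)
    if hl.ndim == 0:
        return float(hl)
    return hl


def build_kinetics_table(
    sample: pd.DataFrame, strain: str, volume: float = 1.0
) -> pd.DataFrame:
    """Full GRO inference for one strain: volume-normalize, aggregate
    replicates, derive HL = RA/TR.

    Returns ``gene_id, strain, TR, RA, HL`` (NaN HL where TR undefined).
    """
    sample = sample.copy()
    sample["ntr"] = normalize_to_cell_volume(sample["ntr"], volume)
    sample["ra"] = normalize_to_cell_volume(sample["ra"], volume)
    agg = aggregate_replicates(sample)
    agg["HL"] = compute_half_life(agg["RA"], agg["TR"])
    agg.insert(1, "strain", strain)
    return agg[["gene_id", "strain", "TR", "RA", "HL"]]


def total_polii_tr(trs) -> float:
    """Whole RNA polymerase II transcription rate: the sum of all
    per-gene TR values."""
    arr = np.asarray(trs, dtype=float)
    if arr.size and not np.isfinite(arr).all():
        raise ValueError("TR values must be finite")
    return float(arr.sum())


@dataclass(frozen=True)
class DecayFit:
    """Result of a log-linear decay fit."""

    half_life: float  # minutes; inf for a flat curve, NaN if rejected
    slope: float  # per-minute slope of ln(level) vs t
    intercept: float
    r_squared: float
    n_points: int
    status: str  # "ok", "flat", or "rejected"


def fit_decay_curve(
    timepoints,
    levels,
    reference_levels=None,
    positive_slope_tol: float = 1e-9,
) -> DecayFit:
    """Fit an exponential decay to a shutoff time course.

    Levels are first normalized by the stable reference transcript at
    each timepoint (loading control), then ln(level) is regressed on
    time by unweighted least squares; half-life = ln2 / |slope|.

    A slope within ``positive_slope_tol`` of zero signals a stable
    transcript (infinite half-life, status "flat"); a positive slope
    beyond tolerance is a failed fit (status "rejected", NaN half-life).
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(levels, dtype=float)
    if reference_levels is not None:
        ref = np.asarray(reference_levels, dtype=float)
        if (ref <= 0).any():
            raise ValueError("reference levels must be positive")
        y = y / ref
    usable = y > 0
    t, y = t[usable], y[usable]
    if t.size < 3:
        raise ValueError("need >= 3 timepoints with positive levels")

    slope, intercept = np.polyfit(t, np.log(y), 1)
    resid = np.log(y) - (slope * t + intercept)
    ss_tot = float(np.sum((np.log(y) - np.log(y).mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0

    if abs(slope) <= positive_slope_tol:
        return DecayFit(np.inf, float(slope), float(intercept), r2, t.size, "flat")
    if slope > positive_slope_tol:
        return DecayFit(np.nan, float(slope), float(intercept), r2, t.size, "rejected")
    return DecayFit(
        float(np.log(2) / -slope), float(slope), float(intercept), r2, t.size, "ok"
    )


def fit_decay_table(
    course: pd.DataFrame, reference: str = "SCR1", **kwargs
) -> pd.DataFrame:
    """Fit every gene in a long-format time course (gene_id, minutes,
    level), normalizing to the named reference transcript."""
    ref = course[course["gene_id"] == reference].sort_values("minutes")
    if ref.empty:
        raise ValueError(f"reference transcript {reference!r} absent from course")
    ref_levels = ref.set_index("minutes")["level"]
    rows = []
    for gene, grp in course[course["gene_id"] != reference].groupby("gene_id", sort=True):
        grp = grp.sort_values("minutes")
        fit = fit_decay_curve(
            grp["minutes"], grp["level"], ref_levels.loc[grp["minutes"]].to_numpy(), **kwargs
        )
        rows.append(
            {
                "gene_id": gene,
                "half_life_min": fit.half_life,
                "slope": fit.slope,
                "r_squared": fit.r_squared,
                "n_points": fit.n_points,
                "status": fit.status,
            }
        )
    return pd.DataFrame(rows)


def spike_normalize(counts, spike_counts: float, reference_spike: float):
    """Scale a sample's counts by its spike-in recovery.

    Exogenous spike-in material is added in a fixed proportion to every
    sample, so the ratio reference_spike / spike_counts removes
    sample-specific depth and recovery differences:
    normalized = counts * reference_spike / spike_counts.
    """
    if spike_counts <= 0:
        raise ValueError("spike_counts must be > 0")
    if reference_spike <= 0:
        raise ValueError("reference_spike must be > 0")
    return counts * (reference_spike / spike_counts)
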