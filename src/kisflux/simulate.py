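"""Synthetic-data generator for the two-pathway decay + buffering model.

Each gene is degraded by two first-order pathways acting in parallel:

* a classical cytoplasmic pathway with rate ``kd_cls`` (unaffected by
  Xrn1 nuclear import), and
* a nuclear-initiated "Kis" pathway with rate ``kd_kis``, whose activity
  scales with the fraction of Xrn1 successfully imported.

The wild-type decay rate is ``kd_wt = kd_cls + kd_kis`` and the Kis
fraction ``f = kd_kis / kd_wt`` in ``[0, 1)`` measures how much of a
gene's turnover depends on Xrn1 import. An *xrn1*-null condition falls
back to an exosome rate ``kd_exo``. Buffering couples synthesis to decay:
under an import mutant the transcription rate follows the decay rate as
``tr = tr_wt * (kd / kd_wt) ** beta`` so that with perfect buffering
(``beta = 1``) the steady-state abundance ``RA = tr / kd`` is invariant.

All randomness flows from explicit integer seeds; every simulated
measurement can be regenerated byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

PRESETS = ("headline", "uniform", "null")

#: Default fraction of Kis-pathway activity retained per strain.
#: Single-NLS mutants import partially; the double mutant and the
#: importin deletion block import entirely. The xrn1-null strain is a
#: special case handled by :func:`apply_condition` via ``kd_exo``.
CONDITION_ETA = {
    "WT": 1.0,
    "dNLS1": 0.25,
    "dNLS2": 0.25,
    "dNLS12": 0.0,
    "dKAP120": 0.0,
    "dXRN1": float("nan"),
}

REFERENCE_GENE = "SCR1"


@dataclass(frozen=True)
class ConditionSpec:
    """A strain condition: import efficiency and buffering strength.

    Parameters
    ----------
    name
        Strain label; one of ``WT, dNLS1, dNLS2, dNLS12, dKAP120, dXRN1``.
    import_efficiency
        eta in [0, 1]: fraction of Kis-pathway activity retained
        (1 for WT, 0 when import is fully blocked). Ignored for dXRN1.
    buffering_strength
        beta in [0, 1]: 1 means synthesis tracks decay perfectly and RA
        is unchanged; 0 means no transcriptional compensation.
    """

    name: str
    import_efficiency: float = 1.0
    buffering_strength: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in CONDITION_ETA:
            raise ValueError(f"unknown condition name: {self.name!r}")
        if self.name != "dXRN1" and not (0.0 <= self.import_efficiency <= 1.0):
            raise ValueError("import_efficiency must lie in [0, 1]")
        if not (0.0 <= self.buffering_strength <= 1.0):
            raise ValueError("buffering_strength must lie in [0, 1]")

    @classmethod
    def from_name(cls, name: str, beta: float = 1.0) -> "ConditionSpec":
        """Build the default spec for a named strain."""
        eta = CONDITION_ETA.get(name)
        if eta is None:
            raise ValueError(f"unknown condition name: {name!r}")
        if name == "dXRN1":
            return cls(name=name, import_efficiency=0.0, buffering_strength=beta)
        return cls(name=name, import_efficiency=eta, buffering_strength=beta)


@dataclass(frozen=True)
class MeasurementConfig:
    """Noise/replication settings for a simulated GRO experiment."""

    n_replicates: int = 3
    sigma_noise: float = 0.2
    cell_volume: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be >= 0")
        if self.cell_volume <= 0:
            raise ValueError("cell_volume must be > 0")


def _headline_r_location(median_r: float, sigma_r: float) -> float:
    """Location mu of the underlying normal for ln(r) such that the
    r >= 1 truncated lognormal has median exactly ``median_r``.

    Truncation at r >= 1 pushes the median of a plain lognormal upward;
    solving for mu keeps the preset's stated true median exact.
    """
    m = np.log(median_r)

    def median_gap(mu: float) -> float:
        lo = norm.cdf(-mu / sigma_r)
        return (norm.cdf((m - mu) / sigma_r) - lo) / (1.0 - lo) - 0.5

    return float(brentq(median_gap, m - 3.0 * sigma_r, m + 1e-9))


def _sample_truncated_lognormal(
    rng: np.random.Generator, n: int, mu: float, sigma: float
) -> np.ndarray:
    """Inverse-CDF sampling of exp(N(mu, sigma)) truncated below at 1."""
    lo = norm.cdf(-mu / sigma)
    u = rng.uniform(lo, 1.0, size=n)
    return np.exp(mu + sigma * norm.ppf(u))


def generate_truth(
    n_genes: int,
    preset: str = "headline",
    seed: int = 0,
    *,
    median_r: float = 2.5,
    sigma_r: float = 0.5,
    kd_range: tuple[float, float] = (0.02, 0.7),
    tr_range: tuple[float, float] = (0.5, 50.0),
    exo_stabilization_median: float = 2.5,
    exo_stabilization_sigma: float = 0.25,
    uniform_f_max: float = 0.9,
) -> pd.DataFrame:
    """Draw a ground-truth gene table under the two-pathway model.

    Presets
    -------
    ``headline``
        Per-gene true half-life fold-change under a full import block,
        r = kd_wt/kd_cls, is drawn from a lognormal truncated at r >= 1
        whose truncated median equals ``median_r`` (default 2.5). Then
        ``kd_kis = kd_wt * (1 - 1/r)``, producing a continuous spectrum
        of Kis fractions.
    ``uniform``
        Kis fraction f drawn Uniform(0, ``uniform_f_max``).
    ``null``
        ``kd_kis = 0`` for every gene: no Kis pathway.

    ``tr_wt`` and ``kd_wt`` are drawn log-uniform over ``tr_range`` and
    ``kd_range`` (a.u./min and 1/min). The xrn1-null backup rate is
    ``kd_exo = kd_wt / s`` with s lognormal around
    ``exo_stabilization_median``, independent of f, so deletion
    stabilizes all genes comparably regardless of Kis value.

    Returns a DataFrame with columns
    ``gene_id, tr_wt, kd_cls, kd_kis, kd_exo``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; expected one of {PRESETS}")

    rng = np.random.default_rng(seed)
    log_kd = rng.uniform(np.log(kd_range[0]), np.log(kd_range[1]), size=n_genes)
    log_tr = rng.uniform(np.log(tr_range[0]), np.log(tr_range[1]), size=n_genes)
    kd_wt = np.exp(log_kd)
    tr_wt = np.exp(log_tr)

    if preset == "headline":
        mu = _headline_r_location(median_r, sigma_r)
        r = _sample_truncated_lognormal(rng, n_genes, mu, sigma_r)
        f = 1.0 - 1.0 / r
    elif preset == "uniform":
        f = rng.uniform(0.0, uniform_f_max, size=n_genes)
    else:  # null
        f = np.zeros(n_genes)

    kd_kis = kd_wt * f
    kd_cls = kd_wt - kd_kis

    s = np.exp(
        rng.normal(np.log(exo_stabilization_median), exo_stabilization_sigma, size=n_genes)
    )
    kd_exo = kd_wt / s

    width = len(str(n_genes))
    gene_ids = [f"gene{str(i).zfill(width)}" for i in range(n_genes)]
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "tr_wt": tr_wt,
            "kd_cls": kd_cls,
            "kd_kis": kd_kis,
            "kd_exo": kd_exo,
        }
    )


def kis_fraction(truth: pd.DataFrame) -> pd.Series:
    """Per-gene Kis fraction f = kd_kis / (kd_cls + kd_kis)."""
    kd_wt = truth["kd_cls"] + truth["kd_kis"]
    return (truth["kd_kis"] / kd_wt).rename("f")


def apply_condition(truth: pd.DataFrame, cond: ConditionSpec) -> pd.DataFrame:
    """Per-gene kinetic rates (tr, kd) realized under a condition.

    Import mutants retain a fraction eta of the Kis pathway:
    ``kd = kd_cls + eta * kd_kis``. The xrn1-null condition ignores eta
    and decays at the exosome backup rate ``kd_exo``. Buffering couples
    synthesis to decay via ``tr = tr_wt * (kd / kd_wt) ** beta``; with
    beta = 1 the steady-state abundance tr/kd equals the wild-type value
    exactly for every import mutant.
    """
    if truth.empty:
        raise ValueError("truth table is empty")
    kd_wt = (truth["kd_cls"] + truth["kd_kis"]).to_numpy()
    if cond.name == "dXRN1":
        kd = truth["kd_exo"].to_numpy()
    else:
        kd = (truth["kd_cls"] + cond.import_efficiency * truth["kd_kis"]).to_numpy()
    tr = truth["tr_wt"].to_numpy() * (kd / kd_wt) ** cond.buffering_strength
    return pd.DataFrame({"gene_id": truth["gene_id"].to_numpy(), "tr": tr, "kd": kd})


def simulate_gro(profile: pd.DataFrame, config: MeasurementConfig) -> pd.DataFrame:
    """Simulate GRO signals for one strain.

    Each gene x replicate yields a nascent-transcription signal
    ``ntr = tr * exp(eps)`` and a hybridization abundance signal
    ``ra = (tr/kd) * exp(eps')`` with i.i.d. Normal(0, sigma_noise)
    log-space noise, both multiplied by the strain's cell-volume factor
    (undone downstream by the pipeline's volume normalization).

    Returns a long-format DataFrame: ``gene_id, replicate, ntr, ra``.
    """
    if (profile["tr"] <= 0).any() or (profile["kd"] <= 0).any():
        raise ValueError("rates must be positive")
    rng = np.random.default_rng(config.seed)
    n_genes = len(profile)
    reps = config.n_replicates
    tr = profile["tr"].to_numpy()
    ra_true = tr / profile["kd"].to_numpy()

    eps = rng.normal(0.0, config.sigma_noise, size=(n_genes, reps))
    eps2 = rng.normal(0.0, config.sigma_noise, size=(n_genes, reps))
    ntr = tr[:, None] * np.exp(eps) * config.cell_volume
    ra = ra_true[:, None] * np.exp(eps2) * config.cell_volume

    return pd.DataFrame(
        {
            "gene_id": np.repeat(profile["gene_id"].to_numpy(), reps),
            "replicate": np.tile(np.arange(1, reps + 1), n_genes),
            "ntr": ntr.ravel(),
            "ra": ra.ravel(),
        }
    )


def simulate_shutoff(
    truth: pd.DataFrame,
    cond: ConditionSpec,
    genes: list[str],
    timepoints: list[float],
    sigma_noise: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Transcription-shutoff decay time course for selected genes.

    Levels follow ``level(g, t) = RA(g) * exp(-kd_cond(g) * t)`` with
    optional multiplicative lognormal noise. A stable reference row
    (SCR1, a Pol III transcript untouched by the shutoff, kd = 0) is
    always emitted for normalization downstream.

    Returns long-format ``gene_id, minutes, level``.
    """
    tp = np.asarray(timepoints, dtype=float)
    if (tp < 0).any():
        raise ValueError("timepoints must be nonnegative")
    if 0.0 not in tp:
        raise ValueError("timepoints must include 0")
    missing = set(genes) - set(truth["gene_id"])
    if missing:
        raise ValueError(f"genes not in truth table: {sorted(missing)[:5]}")

    rates = apply_condition(truth, cond).set_index("gene_id")
    rng = np.random.default_rng(seed)
    rows = []
    for g in list(genes) + [REFERENCE_GENE]:
        if g == REFERENCE_GENE:
            kd, level0 = 0.0, 1.0
        else:
            kd = rates.at[g, "kd"]
            level0 = rates.at[g, "tr"] / kd
        noise = np.exp(rng.normal(0.0, sigma_noise, size=tp.size)) if sigma_noise > 0 else 1.0
        levels = level0 * np.exp(-kd * tp) * noise
        rows.append(pd.DataFrame({"gene_id": g, "minutes": tp, "level": levels}))
    return pd.concat(rows, ignore_index=True)


SPIKE_PREFIX = "spombe_"


def simulate_refeed_counts(
    truth: pd.DataFrame,
    conds: list[ConditionSpec],
    timepoints: list[float],
    spike_fraction: float = 0.1,
    depth: int = 1_000_000,
    library_size_factors: dict[str, float] | None = None,
    n_spike_genes: int = 20,
    starved_level_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sequencing counts for a starvation-exit (refeed) time course.

    Per-gene true abundance relaxes from a starved level (a fraction of
    steady state) back toward the condition's steady state with the
    condition's decay rate: ``RA(t) = RA* + (RA0 - RA*) exp(-kd t)``.
    Counts per sample are multinomial over genes proportional to RA(t)
    plus a spike-in compartment (rows prefixed ``spombe_``) of constant
    mRNA mass per sample — spike cells are added in fixed proportion to
    sample cells, so the spike mass is anchored to the reference
    steady-state total and captures exactly ``spike_fraction`` of reads
    in a fully recovered sample, more in starved samples whose total
    mRNA is lower. This is what lets spike normalization recover
    absolute abundance changes that within-sample proportions erase.

    Returns ``(counts, truth_ra)``: a long count table
    ``gene_id, sample, count`` and the true RA trajectories
    ``gene_id, sample, ra_true`` for recovery tests.
    """
    if not (0.0 < spike_fraction < 1.0):
        raise ValueError("spike_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    tp = np.asarray(timepoints, dtype=float)
    spike_ids = [f"{SPIKE_PREFIX}gene{i:03d}" for i in range(n_spike_genes)]

    # constant spike mRNA mass per sample, anchored so a sample at the
    # reference steady-state total yields exactly spike_fraction of reads
    ref_rates = apply_condition(truth, conds[0])
    total_ss = float((ref_rates["tr"] / ref_rates["kd"]).sum())
    spike_mass = spike_fraction / (1.0 - spike_fraction) * total_ss

    count_rows, truth_rows = [], []
    for cond in conds:
        rates = apply_condition(truth, cond)
        ra_ss = rates["tr"].to_numpy() / rates["kd"].to_numpy()
        ra0 = starved_level_fraction * ra_ss
        for t in tp:
            sample = f"{cond.name}_t{t:g}"
            ra_t = ra_ss + (ra0 - ra_ss) * np.exp(-rates["kd"].to_numpy() * t)
            lib = 1.0 if library_size_factors is None else library_size_factors.get(sample, 1.0)
            n_reads = int(round(depth * lib))
            mass = np.concatenate(
                [ra_t, np.full(n_spike_genes, spike_mass / n_spike_genes)]
            )
            counts = rng.multinomial(n_reads, mass / mass.sum())
            ids = np.concatenate([rates["gene_id"].to_numpy(), spike_ids])
            count_rows.append(pd.DataFrame({"gene_id": ids, "sample": sample, "count": counts}))
            truth_rows.append(
                pd.DataFrame(
                    {"gene_id": rates["gene_id"], "sample": sample, "ra_true": ra_t}
                )
            )
    return (
        pd.concat(count_rows, ignore_index=True),
        pd.concat(truth_rows, ignore_index=True),
    )


def rip_enrichment(f: np.ndarray | float, gamma: float = 1.5) -> np.ndarray | float:
    """Monotone in-vivo RIP enrichment of an import mutant as a function
    of the Kis fraction f: exp(gamma * f).

    Blocking import leaves Xrn1 bound (unproductively) to high-Kis mRNAs
    in vivo, so pulldown recovery rises with f; in vitro binding is
    f-independent.
    """
    return np.exp(gamma * np.asarray(f, dtype=float))


@dataclass(frozen=True)
class RipConfig:
    """Settings for the RIP-seq read simulator."""

    mean_reads_per_gene: float = 20.0
    frac_long_tail: float = 0.8  # fraction of reads with trailing_A > 15
    long_tail_extra_mean: float = 8.0
    distance_sd_bp: float = 80.0
    enrichment_gamma: float = 1.5
    site_spacing_bp: int = 2000
    seed: int = 0


def polya_sites(truth: pd.DataFrame, spacing_bp: int = 2000) -> pd.DataFrame:
    """Synthetic primary polyadenylation-site annotation, one site per
    gene, laid out on a single chromosome (0-based positions)."""
    n = len(truth)
    return pd.DataFrame(
        {
            "gene_id": truth["gene_id"].to_numpy(),
            "chrom": "chrI",
            "position": spacing_bp * (1 + np.arange(n)),
            "strand": "+",
        }
    )


def simulate_rip_reads(
    truth: pd.DataFrame,
    mode: str,
    cond: ConditionSpec,
    config: RipConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate RIP-seq read records for one pulldown.

    Expected reads per gene are proportional to wild-type steady-state
    abundance. In ``in_vivo`` mode under an import mutant (eta < 1),
    counts are additionally multiplied by :func:`rip_enrichment`
    evaluated at each gene's Kis fraction, scaled by the severity of the
    import block; ``in_vitro`` binding is identical across strains.
    Trailing-A lengths are drawn so a configurable fraction exceeds 15
    (full-length poly(A) reads); mapped distances to the primary polyA
    site are rounded Normal(0, distance_sd_bp).

    Returns ``(reads, sites)``: read records
    ``read_id, gene_id, distance_bp, trailing_A`` and the polyA-site
    table.
    """
    if mode not in ("in_vivo", "in_vitro"):
        raise ValueError(f"unknown mode {mode!r}")
    cfg = config or RipConfig()
    rng = np.random.default_rng(cfg.seed)

    ra_wt = truth["tr_wt"].to_numpy() / (truth["kd_cls"] + truth["kd_kis"]).to_numpy()
    lam = cfg.mean_reads_per_gene * ra_wt / ra_wt.mean()
    if mode == "in_vivo" and cond.name != "dXRN1" and cond.import_efficiency < 1.0:
        f = kis_fraction(truth).to_numpy()
        block = 1.0 - cond.import_efficiency
        lam = lam * rip_enrichment(block * f, cfg.enrichment_gamma)

    n_per_gene = rng.poisson(lam)
    total = int(n_per_gene.sum())
    gene_ids = np.repeat(truth["gene_id"].to_numpy(), n_per_gene)

    is_long = rng.random(total) < cfg.frac_long_tail
    tails = np.where(
        is_long,
        16 + rng.poisson(cfg.long_tail_extra_mean, size=total),
        rng.integers(0, 16, size=total),
    )
    dists = np.rint(rng.normal(0.0, cfg.distance_sd_bp, size=total)).astype(int)

    reads = pd.DataFrame(
        {
            "read_id": [f"read{i:07d}" for i in range(total)],
            "gene_id": gene_ids,
            "distance_bp": dists,
            "trailing_A": tails,
        }
    )
    return reads, polya_sites(truth, cfg.site_spacing_bp)
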