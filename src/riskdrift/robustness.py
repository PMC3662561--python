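"""Robustness procedures: outlier removal, ascertainment control, Fst.

Three rerunnable checks accompany the branch test:

* **Outlier removal** — individuals whose risk deviates more than 1.5
  interquartile ranges from their population's median are removed and the
  test rerun; real differentiation should survive.
* **Ascertainment control** — disease SNPs are discovered preferentially in
  well-tagged regions, so the resampling pool can be restricted to SNPs
  reported to be associated with *any* phenotype, which share that
  ascertainment.
* **Fst comparison** — per-SNP Weir–Cockerham (1984) theta, rank-normalised
  within minor-allele-frequency bins and Fisher-combined, shows what a
  single-SNP differentiation scan sees (and misses): a coherent shift
  spread over a panel moves the set-level risk statistic long before any
  individual SNP's Fst becomes extreme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import MISSING, GenotypeMatrix

logger = logging.getLogger("riskdrift.robustness")

IQR_MULTIPLIER = 1.5


# ----------------------------------------------------------------------
# outliers
# ----------------------------------------------------------------------

@dataclass
class OutlierReport:
    """Removed individuals and the IQR rule that removed them."""

    population: str
    removed: list[str]
    median: float
    iqr: float
    p_before: float | None = None
    p_after: float | None = None


def outlier_mask(values: np.ndarray) -> np.ndarray:
    """True for values within 1.5 IQRs of the median (i.e. kept).

    A zero IQR degenerates to "keep exactly the median values"; that case
    is logged as a warning.
    """
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    if iqr == 0:
        keep = values == med
        if not keep.all():
            logger.warning(
                "zero IQR: keeping only the %d value(s) equal to the median",
                int(keep.sum()),
            )
        return keep
    return np.abs(values - med) <= IQR_MULTIPLIER * iqr


def remove_outliers(
    risks: pd.DataFrame, population: str
) -> tuple[OutlierReport, pd.DataFrame]:
    """Drop risk outliers from one population of a cohort-risk table."""
    pop_rows = risks["population"] == population
    members = risks[pop_rows]
    if len(members) < 4:
        logger.warning(
            "population %s has %d member(s); IQR is not meaningful",
            population,
            len(members),
        )
    vals = members["risk"].to_numpy(dtype=float)
    keep = outlier_mask(vals)
    removed = list(members.loc[~keep, "individual"])
    q1, q3 = np.percentile(vals, [25, 75])
    report = OutlierReport(
        population=population,
        removed=removed,
        median=float(np.median(vals)),
        iqr=float(q3 - q1),
    )
    filtered = risks[~risks["individual"].isin(removed)].reset_index(drop=True)
    if removed:
        logger.info(
            "removed %d outlier(s) from %s: %s",
            len(removed),
            population,
            ", ".join(removed),
        )
    return report, filtered


def population_outlier_mask(risks: pd.DataFrame) -> np.ndarray:
    """Per-individual keep mask applying the IQR rule within each population."""
    keep = np.ones(len(risks), dtype=bool)
    for pop, grp in risks.groupby("population"):
        keep[grp.index] = outlier_mask(grp["risk"].to_numpy(dtype=float))
    return keep


# ----------------------------------------------------------------------
# ascertainment control
# ----------------------------------------------------------------------

def ascertainment_pool(annotations: pd.DataFrame) -> pd.DataFrame:
    """Restrict the resampling pool to phenotype-associated SNPs.

    Retained/discarded counts are logged.  Raises when nothing is flagged.
    """
    flagged = annotations["phenotype_associated"].astype(bool)
    retained = int(flagged.sum())
    logger.info(
        "ascertainment pool: discarded %d and retained %d SNPs",
        int((~flagged).sum()),
        retained,
    )
    if retained == 0:
        raise ValueError("no phenotype-associated SNPs available for resampling")
    return annotations[flagged]


# ----------------------------------------------------------------------
# Weir-Cockerham Fst
# ----------------------------------------------------------------------

def _wc_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) variance components a, b, c per SNP.

    ``n``, ``p``, ``h`` are (n_pops, n_snps) arrays of diploid sample
    sizes, counted-allele frequencies and heterozygote frequencies; entries
    with ``n == 0`` are ignored.  Vectorised over SNPs.
    """
    present = n > 0
    r = present.sum(axis=0).astype(float)
    n_sum = n.sum(axis=0).astype(float)
    n_bar = n_sum / r
    n_c = (n_sum - (n ** 2).sum(axis=0) / n_sum) / (r - 1)
    p_bar = (n * p).sum(axis=0) / n_sum
    s2 = (n * (p - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n * h).sum(axis=0) / n_sum
    pq = p_bar * (1 - p_bar)
    a = (n_bar / n_c) * (
        s2 - (pq - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        pq - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    return a, b, c


def global_fst(
    genotypes: GenotypeMatrix, snp_ids: list[str] | None = None
) -> pd.DataFrame:
    """Per-SNP Weir-Cockerham theta across all populations.

    Returns a frame indexed by snp_id with columns ``a``, ``b``, ``c`` and
    ``fst``; monomorphic SNPs (or SNPs typed in fewer than two populations)
    get NaN and are excluded from downstream ranking.  Negative estimates
    are legitimate and preserved.
    """
    if snp_ids is None:
        snp_ids = list(genotypes.snp_ids)
    pops = genotypes.population_labels
    counts = genotypes.dosage_counts(pops, snp_ids=snp_ids)  # (S, P, 3)
    n = counts.sum(axis=2).T.astype(float)  # (P, S) called diploids
    with np.errstate(invalid="ignore", divide="ignore"):
        p = ((2 * counts[:, :, 2] + counts[:, :, 1]).T / (2 * n))
        h = counts[:, :, 1].T / n
        p = np.nan_to_num(p)
        h = np.nan_to_num(h)
        a, b, c = _wc_components(n, p, h)
        theta = a / (a + b + c)
    r = (n > 0).sum(axis=0)
    global_p = (n * p).sum(axis=0) / n.sum(axis=0)
    bad = (r < 2) | (global_p <= 0) | (global_p >= 1)
    theta = np.where(bad, np.nan, theta)
    if bad.any():
        logger.info("Fst undefined for %d SNP(s)", int(bad.sum()))
    return pd.DataFrame(
        {"a": a, "b": b, "c": c, "fst": theta}, index=pd.Index(snp_ids, name="snp_id")
    )


def multilocus_fst(genotypes: GenotypeMatrix, snp_ids: list[str] | None = None) -> float:
    """Ratio-of-sums Weir-Cockerham theta over many SNPs.

    The standard multi-locus estimator: variance components are summed over
    loci before the ratio is taken.
    """
    comp = global_fst(genotypes, snp_ids=snp_ids)
    ok = comp["fst"].notna()
    num = comp.loc[ok, "a"].sum()
    den = (comp.loc[ok, "a"] + comp.loc[ok, "b"] + comp.loc[ok, "c"]).sum()
    return float(num / den)


# ----------------------------------------------------------------------
# rank-normalised Fst p-values
# ----------------------------------------------------------------------

def fst_rank_p(
    panel_fst: pd.Series,
    pool_fst: pd.Series,
    pool_maf: pd.Series,
    panel_maf: pd.Series,
    bin_width: float = 0.02,
    min_bin_size: int = 100,
) -> pd.Series:
    """Rank of each panel SNP's Fst within its minor-allele-frequency bin.

    ``rank_p`` is the fraction of same-bin pool SNPs with strictly lower
    Fst (0 = least, ~1 = most differentiated in its bin).  The SNP itself
    is excluded from its reference bin; bins with fewer than
    ``min_bin_size`` pool SNPs are flagged with a warning.
    """
    pool_bins = np.floor(pool_maf.to_numpy(dtype=float) / bin_width + 1e-9).astype(int)
    out = {}
    for snp_id, fst in panel_fst.items():
        if np.isnan(fst):
            out[snp_id] = np.nan
            continue
        b = int(np.floor(float(panel_maf[snp_id]) / bin_width + 1e-9))
        in_bin = (pool_bins == b) & (pool_fst.index != snp_id)
        ref = pool_fst.to_numpy(dtype=float)[in_bin]
        ref = ref[~np.isnan(ref)]
        if ref.size < min_bin_size:
            logger.warning(
                "MAF bin %d has only %d pool SNPs for %s", b, ref.size, snp_id
            )
        if ref.size == 0:
            out[snp_id] = np.nan
            continue
        out[snp_id] = float((ref < fst).sum() / ref.size)
    return pd.Series(out, name="rank_p")


def combine_rank_p(
    rank_p: pd.Series | np.ndarray,
    method: str = "fisher",
    floor: float | None = None,
) -> float:
    """Combine per-SNP rank fractions into one differentiation p-value.

    Rank fractions are converted to upper-tail p-values ``1 - rank_p``
    ("more differentiated than expected"), floored away from zero, and
    combined with Fisher's method (``-2 sum ln p ~ chi-square(2k)``) or,
    optionally, Stouffer's Z.
    """
    r = np.asarray(pd.Series(rank_p).dropna(), dtype=float)
    if r.size == 0:
        raise ValueError("no rank fractions to combine")
    p = 1.0 - r
    if floor is None:
        floor = 1.0 / max(len(r) * 100, 1000)
    p = np.clip(p, floor, 1.0)
    if method == "fisher":
        x = -2.0 * np.log(p).sum()
        return float(stats.chi2.sf(x, df=2 * p.size))
    if method == "stouffer":
        z = stats.norm.isf(p).sum() / np.sqrt(p.size)
        return float(stats.norm.sf(z))
    raise ValueError(f"unknown combination method {method!r}")


@dataclass
class FstResult:
    """Per-SNP Fst with its in-bin rank fraction."""

    snp_id: str
    fst: float
    rank_p: float
    bin: int


def panel_fst_analysis(
    genotypes: GenotypeMatrix,
    panel_snp_ids: list[str],
    annotations: pd.DataFrame,
    bin_width: float = 0.02,
    method: str = "fisher",
) -> tuple[pd.DataFrame, float]:
    """Full per-SNP Fst scan of a disease panel against the pool.

    Computes Weir-Cockerham theta for every annotated SNP, ranks each panel
    SNP within its MAF bin and Fisher-combines the upper-tail p-values.
    Returns the per-SNP table and the combined p.
    """
    ann = annotations
    if "snp_id" in ann.columns:
        ann = ann.set_index("snp_id")
    pool_ids = [s for s in ann.index if genotypes.has_snp(s)]
    fst = global_fst(genotypes, snp_ids=pool_ids)["fst"]
    maf = ann.loc[pool_ids, "global_maf"]
    present_panel = [s for s in panel_snp_ids if s in fst.index]
    rank = fst_rank_p(
        fst[present_panel], fst, maf, maf[present_panel], bin_width=bin_width
    )
    table = pd.DataFrame(
        {
            "fst": fst[present_panel],
            "rank_p": rank,
            "bin": np.floor(
                maf[present_panel].to_numpy(dtype=float) / bin_width + 1e-9
            ).astype(int),
        }
    )
    combined = combine_rank_p(rank, method=method)
    return table, combined
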