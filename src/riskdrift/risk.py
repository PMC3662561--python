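"""Combined-likelihood-ratio genetic risk scores.

The effect size of a genotype ``g`` at one SNP is its likelihood ratio
``LR(g) = P(g | disease) / P(g | no disease)``.  Effect sizes reported by
several association studies are merged into a single combined likelihood
ratio per genotype, weighting each study by the square root of its sample
size:

    L(g) = sum_i sqrt(A_i) * LR_i(g) / sum_i sqrt(A_i)

An individual's genetic risk ``r`` for a disease is the log of the product
of combined likelihood ratios over the disease's (LD-pruned) SNP panel,
i.e. the sum of ``ln L(g)`` over the person's non-missing genotypes.  A
population's risk ``R`` is the mean of its members' ``r``; the difference
``D_AB = R_A - R_B`` compares two populations (positive = A riskier).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    CombinedEffect,
    DiseasePanel,
    GenotypeMatrix,
    PanelSnp,
    PopulationRisk,
    RiskDifference,
    RiskScore,
    SnpAnnotation,
)

logger = logging.getLogger("riskdrift.risk")

#: Genome-wide significance threshold used to admit an association.
P_VALUE_THRESHOLD = 1e-6
#: A SNP must have been detected in at least this many study populations.
MIN_STUDY_POPULATIONS = 2

_GENOTYPE_COLS = ("hom_protective", "het", "hom_risk")
_LR_COLS = tuple(f"lr_{g}" for g in _GENOTYPE_COLS)
_CASE_COLS = tuple(f"prob_case_{g}" for g in _GENOTYPE_COLS)
_CONTROL_COLS = tuple(f"prob_control_{g}" for g in _GENOTYPE_COLS)


# ----------------------------------------------------------------------
# association records -> combined effects
# ----------------------------------------------------------------------

def _has_lr_info(row: pd.Series) -> bool:
    if all(c in row.index and pd.notna(row[c]) for c in _LR_COLS):
        return True
    return all(
        c in row.index and pd.notna(row[c]) for c in _CASE_COLS + _CONTROL_COLS
    )


def record_likelihood_ratios(row: pd.Series) -> dict[int, float]:
    """Per-genotype LR(g) of one study record, keyed by risk-allele copies.

    Accepts either direct likelihood-ratio columns (``lr_hom_risk`` etc.) or
    case/control genotype probabilities, from which ``LR(g) =
    P(g|disease)/P(g|no disease)`` is formed.
    """
    if all(c in row.index and pd.notna(row[c]) for c in _LR_COLS):
        lrs = {g: float(row[f"lr_{name}"]) for g, name in enumerate(_GENOTYPE_COLS)}
    elif all(c in row.index and pd.notna(row[c]) for c in _CASE_COLS + _CONTROL_COLS):
        lrs = {}
        for g, name in enumerate(_GENOTYPE_COLS):
            denom = float(row[f"prob_control_{name}"])
            if denom <= 0:
                raise ValueError(
                    f"control genotype probability not positive for SNP "
                    f"{row.get('snp_id')} ({row.get('study_population')})"
                )
            lrs[g] = float(row[f"prob_case_{name}"]) / denom
    else:
        raise ValueError(
            f"record for SNP {row.get('snp_id')} carries neither likelihood "
            "ratios nor case/control genotype probabilities"
        )
    for g, lr in lrs.items():
        if not lr > 0:
            raise ValueError(
                f"non-positive likelihood ratio (genotype {g}) in study "
                f"{row.get('study_population')} for SNP {row.get('snp_id')}"
            )
    return lrs


def filter_associations(
    associations: pd.DataFrame,
    p_threshold: float = P_VALUE_THRESHOLD,
    min_populations: int = MIN_STUDY_POPULATIONS,
) -> pd.DataFrame:
    """Apply the publication filters to an association table.

    A SNP is retained when (a) at least one of its associations reaches
    ``p < p_threshold``, (b) it was detected in at least ``min_populations``
    distinct study populations, and (c) its records suffice to compute
    per-genotype likelihood ratios.  Counts in/out are logged.
    """
    keep_snps = []
    for snp_id, grp in associations.groupby("snp_id", sort=False):
        if grp["p_value"].min() >= p_threshold:
            continue
        if grp["study_population"].nunique() < min_populations:
            continue
        if not all(_has_lr_info(row) for _, row in grp.iterrows()):
            continue
        keep_snps.append(snp_id)
    out = associations[associations["snp_id"].isin(keep_snps)].copy()
    logger.info(
        "association filter: %d/%d SNPs retained (%d records -> %d)",
        len(keep_snps),
        associations["snp_id"].nunique(),
        len(associations),
        len(out),
    )
    if out.empty:
        logger.warning("association filter removed every SNP")
    return out


def combine_likelihood_ratios(
    records: pd.DataFrame, method: str = "lr-mean"
) -> CombinedEffect:
    """Merge one SNP's study records into a combined effect L(g).

    ``method="lr-mean"`` (default) takes the sqrt(sample size)-weighted mean
    of per-study likelihood ratios.  ``method="prob-mean"`` averages the
    case and control genotype probabilities separately with the same weights
    and then takes their ratio (requires probability columns).
    """
    if records.empty:
        raise ValueError("no records to combine")
    snp_id = str(records.iloc[0]["snp_id"])
    weights = np.sqrt(records["sample_size"].to_numpy(dtype=float))
    if not (weights > 0).all():
        raise ValueError(f"sample sizes must be >= 1 for SNP {snp_id}")
    if method == "lr-mean":
        lrs = np.array(
            [[record_likelihood_ratios(row)[g] for g in (0, 1, 2)]
             for _, row in records.iterrows()]
        )
        combined = weights @ lrs / weights.sum()
    elif method == "prob-mean":
        for c in _CASE_COLS + _CONTROL_COLS:
            if c not in records.columns or records[c].isna().any():
                raise ValueError(
                    f"method 'prob-mean' needs case/control genotype "
                    f"probabilities for every study of SNP {snp_id}"
                )
        case = weights @ records[list(_CASE_COLS)].to_numpy(float) / weights.sum()
        control = weights @ records[list(_CONTROL_COLS)].to_numpy(float) / weights.sum()
        if not (control > 0).all():
            raise ValueError(f"combined control probabilities not positive ({snp_id})")
        combined = case / control
    else:
        raise ValueError(f"unknown combination method {method!r}")
    return CombinedEffect(
        snp_id=snp_id,
        L={g: float(combined[g]) for g in (0, 1, 2)},
        n_studies=len(records),
        study_weights=tuple(float(w) for w in weights),
    )


def restrict_to_study_populations(
    associations: pd.DataFrame, population_group: Iterable[str]
) -> pd.DataFrame:
    """Keep only records from the given group of study populations.

    Used to recompute risk with population-specific effect sizes (e.g. only
    Asian-based studies).  SNPs left without any record disappear from the
    table and hence from downstream panels; the count is logged.
    """
    group = set(population_group)
    out = associations[associations["study_population"].isin(group)].copy()
    lost = set(associations["snp_id"]) - set(out["snp_id"])
    if lost:
        logger.info(
            "study-population restriction dropped %d SNP(s) with no "
            "qualifying study: %s",
            len(lost),
            ", ".join(sorted(lost)),
        )
    return out


def build_panel(
    associations: pd.DataFrame,
    annotations: pd.DataFrame,
    disease: str,
    method: str = "lr-mean",
) -> DiseasePanel:
    """Assemble the vector H for one disease from association records.

    ``annotations`` must be indexed by (or contain a column) ``snp_id`` and
    provide ``global_maf``, ``functional_category`` and
    ``phenotype_associated`` for every panel SNP.
    """
    ann = annotations
    if "snp_id" in ann.columns:
        ann = ann.set_index("snp_id")
    records = associations[associations["disease"] == disease]
    if records.empty:
        raise ValueError(f"no association records for disease {disease!r}")
    snps: list[PanelSnp] = []
    for snp_id, grp in records.groupby("snp_id", sort=False):
        risk_alleles = grp["risk_allele"].unique()
        if len(risk_alleles) != 1:
            raise ValueError(f"inconsistent risk allele for SNP {snp_id}")
        if snp_id not in ann.index:
            raise ValueError(f"panel SNP {snp_id} has no annotation")
        row = ann.loc[snp_id]
        snps.append(
            PanelSnp(
                snp_id=str(snp_id),
                risk_allele=str(risk_alleles[0]),
                effect=combine_likelihood_ratios(grp, method=method),
                annotation=SnpAnnotation(
                    snp_id=str(snp_id),
                    global_maf=float(row["global_maf"]),
                    functional_category=str(row["functional_category"]),
                    phenotype_associated=bool(row["phenotype_associated"]),
                ),
            )
        )
    return DiseasePanel(disease=disease, snps=snps)


# ----------------------------------------------------------------------
# risk scores
# ----------------------------------------------------------------------

def risk_allele_dosage(genotypes: GenotypeMatrix, snp: PanelSnp) -> np.ndarray:
    """Risk-allele copy number per individual for one panel SNP.

    Calls count the matrix's counted allele; when that is not the risk
    allele the dosage is flipped (2 - calls).  Missing stays missing.
    """
    col = genotypes.column(snp.snp_id)
    counted = genotypes.counted_allele.get(snp.snp_id)
    if counted is None or counted == snp.risk_allele:
        return col
    flipped = col.copy()
    ok = col != MISSING
    flipped[ok] = 2 - col[ok]
    return flipped


def cohort_risks(genotypes: GenotypeMatrix, panel: DiseasePanel) -> pd.DataFrame:
    """Genetic risk r for every individual in the cohort.

    Returns a data frame with columns ``individual``, ``population``,
    ``risk`` and ``n_snps_used``.  Panel SNPs absent from the genotype
    matrix contribute nothing (logged); missing genotypes are skipped.
    """
    n = genotypes.n_individuals
    r = np.zeros(n)
    used = np.zeros(n, dtype=int)
    absent = []
    for snp in panel:
        if not genotypes.has_snp(snp.snp_id):
            absent.append(snp.snp_id)
            continue
        dos = risk_allele_dosage(genotypes, snp)
        ok = dos != MISSING
        logl = snp.effect.log_l()
        r[ok] += logl[dos[ok]]
        used += ok
    if absent:
        logger.info(
            "%d panel SNP(s) not genotyped in cohort: %s",
            len(absent),
            ", ".join(absent),
        )
    if (used == 0).any():
        logger.warning(
            "%d individual(s) have no usable panel genotypes; their risk is 0",
            int((used == 0).sum()),
        )
    return pd.DataFrame(
        {
            "individual": genotypes.individuals,
            "population": genotypes.populations,
            "risk": r,
            "n_snps_used": used,
        }
    )


def individual_risk(
    genotypes: GenotypeMatrix, panel: DiseasePanel, individual: str
) -> RiskScore:
    """Genetic risk of one person (see :func:`cohort_risks`)."""
    df = cohort_risks(genotypes, panel)
    row = df[df["individual"] == individual]
    if row.empty:
        raise KeyError(f"individual {individual!r} not in cohort")
    return RiskScore(
        individual=individual,
        value=float(row["risk"].iloc[0]),
        n_snps_used=int(row["n_snps_used"].iloc[0]),
    )


def population_risk(scores: Iterable[RiskScore], population: str) -> PopulationRisk:
    """Mean member risk R of one population."""
    scores = list(scores)
    if not scores:
        raise ValueError(f"population {population!r} has no members")
    return PopulationRisk(
        population=population,
        members=tuple(s.individual for s in scores),
        value=float(np.mean([s.value for s in scores])),
    )


def population_risks(risks: pd.DataFrame) -> pd.Series:
    """Per-population mean risk from a :func:`cohort_risks` table."""
    return risks.groupby("population")["risk"].mean()


def risk_difference(a: PopulationRisk, b: PopulationRisk) -> RiskDifference:
    """D_AB = R_A - R_B (positive means A's risk is higher)."""
    return RiskDifference(a.population, b.population, a.value - b.value)


# ----------------------------------------------------------------------
# LD pruning
# ----------------------------------------------------------------------

def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns.

    Computed over individuals with both calls present; ``nan`` when either
    column is monomorphic among those individuals.
    """
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan")
    xs, ys = x[ok].astype(float), y[ok].astype(float)
    if xs.std() == 0 or ys.std() == 0:
        return float("nan")
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def ld_prune(
    panel: DiseasePanel,
    genotypes: GenotypeMatrix,
    r2_threshold: float = 0.2,
    population: str | None = None,
) -> tuple[DiseasePanel, list[str]]:
    """Greedy LD pruning of a disease panel.

    SNPs are visited in panel order; a SNP is dropped when its genotype
    r-squared with any already-kept SNP reaches ``r2_threshold``.  By
    default r-squared is computed on the pooled cohort; ``population``
    restricts it to one population's members.  SNPs with undefined
    r-squared (monomorphic) are kept and logged.
    """
    if population is not None:
        rows = np.asarray(genotypes.populations) == population
        if not rows.any():
            raise ValueError(f"no individuals in population {population!r}")
    else:
        rows = np.ones(genotypes.n_individuals, dtype=bool)

    kept: list[PanelSnp] = []
    kept_cols: list[np.ndarray] = []
    dropped: list[str] = []
    for snp in panel:
        if not genotypes.has_snp(snp.snp_id):
            kept.append(snp)  # cannot assess LD; scoring will skip it anyway
            kept_cols.append(None)
            continue
        col = genotypes.column(snp.snp_id)[rows]
        r2s = [genotype_r2(col, kc) for kc in kept_cols if kc is not None]
        defined = [v for v in r2s if not np.isnan(v)]
        if len(defined) < len(r2s):
            logger.info("r2 undefined for some pairs involving %s", snp.snp_id)
        if any(v >= r2_threshold for v in defined):
            dropped.append(snp.snp_id)
        else:
            kept.append(snp)
            kept_cols.append(col)
    logger.info(
        "LD pruning (r2 >= %g): %d/%d SNPs kept, %d dropped",
        r2_threshold,
        len(kept),
        len(panel),
        len(dropped),
    )
    return DiseasePanel(panel.disease, kept), dropped
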