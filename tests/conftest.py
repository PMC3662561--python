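"""Shared fixtures: small simulated cohorts and hand-built toys."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from riskdrift import (
    CombinedEffect,
    DiseasePanel,
    GenotypeMatrix,
    PanelSnp,
    PopulationTree,
    SimulationConfig,
    SnpAnnotation,
    simulate_cohort,
)

BALANCED_8_NEWICK = (
    "(((POP01,POP02),(POP03,POP04)),((POP05,POP06),(POP07,POP08)));"
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-population, 600-SNP synthetic cohort shared across tests."""
    return simulate_cohort(
        SimulationConfig(
            n_populations=6,
            n_individuals_per_pop=20,
            n_pool_snps=600,
            panel_size=8,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def balanced_tree8() -> PopulationTree:
    return PopulationTree.from_newick(BALANCED_8_NEWICK)


def make_panel_snp(
    snp_id: str,
    l_values: tuple[float, float, float] = (1.0, 1.3, 1.69),
    risk_allele: str = "A",
    maf: float = 0.3,
    category: str = "intron",
) -> PanelSnp:
    """Hand-built panel SNP: l_values = L(0), L(1), L(2) risk copies."""
    return PanelSnp(
        snp_id=snp_id,
        risk_allele=risk_allele,
        effect=CombinedEffect(
            snp_id=snp_id,
            L={0: l_values[0], 1: l_values[1], 2: l_values[2]},
            n_studies=1,
            study_weights=(10.0,),
        ),
        annotation=SnpAnnotation(snp_id, maf, category),
    )


def make_genotypes(
    calls: np.ndarray,
    populations: list[str],
    snp_ids: list[str] | None = None,
    counted: dict[str, str] | None = None,
) -> GenotypeMatrix:
    calls = np.asarray(calls, dtype=np.int8)
    if snp_ids is None:
        snp_ids = [f"rs{j + 1}" for j in range(calls.shape[1])]
    if counted is None:
        counted = {s: "A" for s in snp_ids}
    individuals = [f"ind{i + 1}" for i in range(calls.shape[0])]
    return GenotypeMatrix(individuals, populations, snp_ids, calls, counted)


def assoc_record(
    snp_id: str = "rs1",
    disease: str = "toy_disease",
    study_population: str = "European",
    sample_size: int = 100,
    p_value: float = 1e-8,
    risk_allele: str = "A",
    lrs: tuple[float, float, float] | None = (1.0, 1.3, 1.69),
    **extra,
) -> dict:
    """One association-table row (lrs = LR for 0/1/2 risk copies)."""
    row = {
        "snp_id": snp_id,
        "disease": disease,
        "study_population": study_population,
        "sample_size": sample_size,
        "p_value": p_value,
        "risk_allele": risk_allele,
    }
    if lrs is not None:
        row.update(
            lr_hom_protective=lrs[0], lr_het=lrs[1], lr_hom_risk=lrs[2]
        )
    row.update(extra)
    return row


def assoc_table(*rows: dict) -> pd.DataFrame:
    return pd.DataFrame(list(rows))


def annotation_table(*snp_ids: str, maf: float = 0.3) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": list(snp_ids),
            "global_maf": maf,
            "functional_category": "intron",
            "phenotype_associated": False,
        }
    )
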