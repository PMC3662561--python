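"""Core data containers shared across the package.

The central objects are :class:`GenotypeMatrix` (a cohort of diploid
individuals typed at biallelic SNPs, with one population label per
individual) and :class:`DiseasePanel` (the ordered set of SNPs representing
one disease, each carrying a per-genotype combined likelihood ratio and a
genome-wide annotation used for matched resampling).

Genotype calls are stored as counts of a designated *counted allele* per SNP
(0, 1, 2, or :data:`MISSING`).  By convention the counted allele is the
global minor allele; risk-allele orientation is resolved at scoring time by
comparing a panel SNP's risk allele with its counted allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call.  Missing is absent evidence, never
#: a homozygote, so it gets a value outside {0, 1, 2}.
MISSING: int = -1

#: The eight functional categories every pool SNP is annotated with.
FUNCTIONAL_CATEGORIES: tuple[str, ...] = (
    "frameshift",
    "nonsense",
    "missense",
    "untranslated",
    "near-gene",
    "intron",
    "coding-synonymous",
    "unknown",
)

#: Genotypes expressed as risk-allele copy number.
HOM_PROTECTIVE, HET, HOM_RISK = 0, 1, 2


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs genotype calls with population labels.

    Parameters
    ----------
    individuals
        Unique individual identifiers, one per row of ``calls``.
    populations
        Population label per individual (parallel to ``individuals``).
    snp_ids
        Unique SNP identifiers, one per column of ``calls``.
    calls
        ``(n_individuals, n_snps)`` int8 array of counted-allele copies;
        ``MISSING`` (-1) marks missing calls.
    counted_allele
        SNP id -> symbol of the allele whose copies ``calls`` counts.
    """

    individuals: list[str]
    populations: list[str]
    snp_ids: list[str]
    calls: np.ndarray
    counted_allele: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n_ind, n_snp = self.calls.shape
        if len(self.individuals) != n_ind:
            raise ValueError("individuals do not match call matrix rows")
        if len(self.populations) != n_ind:
            raise ValueError("every individual needs exactly one population label")
        if len(self.snp_ids) != n_snp:
            raise ValueError("snp_ids do not match call matrix columns")
        if len(set(self.individuals)) != n_ind:
            dupes = pd.Index(self.individuals)
            raise ValueError(
                "duplicate individual id(s): "
                + ", ".join(sorted(dupes[dupes.duplicated()].unique()))
            )
        if len(set(self.snp_ids)) != n_snp:
            raise ValueError("snp_ids must be unique")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype calls must be 0, 1, 2 or missing")
        self._snp_index = {s: j for j, s in enumerate(self.snp_ids)}

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def population_labels(self) -> list[str]:
        """Sorted unique population labels."""
        return sorted(set(self.populations))

    def population_of(self, individual: str) -> str:
        return self.populations[self.individuals.index(individual)]

    def has_snp(self, snp_id: str) -> bool:
        return snp_id in self._snp_index

    def column(self, snp_id: str) -> np.ndarray:
        """Counted-allele dosages of one SNP across all individuals."""
        return self.calls[:, self._snp_index[snp_id]]

    def population_rows(self) -> dict[str, np.ndarray]:
        """Population label -> row indices of its members."""
        pops = np.asarray(self.populations)
        return {p: np.flatnonzero(pops == p) for p in self.population_labels}

    def dosage_counts(
        self,
        population_order: Sequence[str],
        snp_ids: Sequence[str] | None = None,
        keep_rows: np.ndarray | None = None,
    ) -> np.ndarray:
        """Per-population genotype-count table.

        Returns an ``(n_snps, n_pops, 3)`` int32 array whose ``[s, p, g]``
        entry counts individuals of population ``p`` carrying ``g`` copies
        of SNP ``s``'s counted allele.  Missing calls are not counted
        anywhere.  ``keep_rows`` optionally restricts to a boolean mask of
        individuals (used when outliers are removed).
        """
        cols = (
            np.arange(self.n_snps)
            if snp_ids is None
            else np.array([self._snp_index[s] for s in snp_ids])
        )
        pops = np.asarray(self.populations)
        counts = np.zeros((len(cols), len(population_order), 3), dtype=np.int32)
        for p_idx, pop in enumerate(population_order):
            mask = pops == pop
            if keep_rows is not None:
                mask = mask & keep_rows
            sub = self.calls[np.ix_(mask, cols)]
            for g in (0, 1, 2):
                counts[:, p_idx, g] = (sub == g).sum(axis=0)
        return counts

    def subset_individuals(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            [self.individuals[i] for i in keep],
            [self.populations[i] for i in keep],
            list(self.snp_ids),
            self.calls[keep],
            dict(self.counted_allele),
        )


@dataclass(frozen=True)
class CombinedEffect:
    """Per-genotype combined likelihood ratio L(g) for one SNP.

    ``L`` maps risk-allele copy number (0 = homozygous protective,
    1 = heterozygous, 2 = homozygous risk) to the study-combined likelihood
    ratio; ``study_weights`` are the sqrt(sample size) weights that produced
    it.
    """

    snp_id: str
    L: Mapping[int, float]
    n_studies: int
    study_weights: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        for g in (HOM_PROTECTIVE, HET, HOM_RISK):
            if g not in self.L:
                raise ValueError(f"L(g) missing genotype {g} for {self.snp_id}")
            if not self.L[g] > 0:
                raise ValueError(f"L(g) must be positive for {self.snp_id}")
        if any(w <= 0 for w in self.study_weights):
            raise ValueError("study weights must be positive")

    def log_l(self) -> np.ndarray:
        """ln L indexed by risk-allele copies (0, 1, 2)."""
        return np.log([self.L[0], self.L[1], self.L[2]])


@dataclass(frozen=True)
class SnpAnnotation:
    """Genome-wide annotation of one SNP (defines its resampling pool)."""

    snp_id: str
    global_maf: float
    functional_category: str
    phenotype_associated: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.global_maf <= 0.5:
            raise ValueError(f"global MAF out of [0, 0.5] for {self.snp_id}")
        if self.functional_category not in FUNCTIONAL_CATEGORIES:
            raise ValueError(
                f"unknown functional category {self.functional_category!r} "
                f"for {self.snp_id}"
            )


@dataclass(frozen=True)
class PanelSnp:
    """One element of the disease vector H."""

    snp_id: str
    risk_allele: str
    effect: CombinedEffect
    annotation: SnpAnnotation


@dataclass
class DiseasePanel:
    """The ordered vector H of SNPs representing one disease."""

    disease: str
    snps: list[PanelSnp]

    def __post_init__(self) -> None:
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("panel snp_ids must be unique")

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self):
        return iter(self.snps)

    def subset(self, keep_ids: Iterable[str]) -> "DiseasePanel":
        keep = set(keep_ids)
        return DiseasePanel(self.disease, [s for s in self.snps if s.snp_id in keep])


@dataclass(frozen=True)
class RiskScore:
    """Per-individual genetic risk: the log combined likelihood ratio r."""

    individual: str
    value: float
    n_snps_used: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("risk score must be finite")


@dataclass(frozen=True)
class PopulationRisk:
    """Mean member risk R of a population P."""

    population: str
    members: tuple[str, ...]
    value: float


@dataclass(frozen=True)
class RiskDifference:
    """Signed difference D_AB = R_A - R_B between two population risks."""

    pop_a: str
    pop_b: str
    value: float
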