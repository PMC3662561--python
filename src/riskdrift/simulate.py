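"""Synthetic cohorts with known truth.

Real inputs to this kind of analysis — a worldwide genotype panel, a curated
association database, a population phylogeny — are restricted or
proprietary, so every pipeline stage is exercised on simulated data with the
statistical structure the drift null assumes:

* populations related by a rooted tree, whose allele frequencies drift from
  shared ancestral frequencies under the Balding–Nichols model (child
  frequency ~ Beta with mean equal to the parent frequency and variance
  ``F * p * (1 - p)``, applied branch by branch);
* Hardy–Weinberg genotypes within each population;
* a genome-wide pool of annotated neutral SNPs (global MAF, functional
  category, phenotype-associated flag) from which matched null panels are
  resampled;
* disease panels with per-genotype likelihood ratios derived from synthetic
  association studies, optionally with a risk-allele frequency shift
  ("event") injected on a chosen branch of the tree.

Independent SNPs only: linkage disequilibrium, admixture and coalescent
genealogies are deliberately out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .risk import build_panel
from .tree import PopulationTree
from .types import MISSING, DiseasePanel, GenotypeMatrix

logger = logging.getLogger("riskdrift.simulate")

#: Labels used for synthetic association studies.
STUDY_POPULATIONS = ("European", "EastAsian", "African", "SouthAsian", "American")

#: Default mix of functional categories in the simulated pool.  Genotyping
#: arrays are dominated by intronic/intergenic content; rare coding classes
#: would leave category x frequency matching cells empty at desk scale, so
#: they are omitted from the default mix (the schema supports all eight).
DEFAULT_CATEGORY_WEIGHTS: Mapping[str, float] = {
    "intron": 0.55,
    "unknown": 0.35,
    "near-gene": 0.10,
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_populations: int = 8
    n_individuals_per_pop: int = 30
    n_pool_snps: int = 2000
    panel_size: int = 15
    disease: str = "synthetic_disease"
    drift_f: float = 0.05
    or_range: tuple[float, float] = (1.1, 1.5)
    n_studies_range: tuple[int, int] = (1, 3)
    missing_rate: float = 0.0
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    phenotype_associated_rate: float = 0.07
    category_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_WEIGHTS)
    )
    tree: PopulationTree | None = None
    #: (branch id, risk-allele frequency shift delta) per injected event.
    injected_events: tuple[tuple[str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.drift_f < 1:
            raise ValueError("drift_f must be in [0, 1)")
        if self.n_individuals_per_pop < 1:
            raise ValueError("need at least one individual per population")


@dataclass
class TruthTable:
    """Ground truth of injected differentiation events."""

    event_branches: list[tuple[str, float]]
    shifted_snps: list[str]
    expected_direction: dict[str, str]
    clamped_snps: list[str] = field(default_factory=list)


@dataclass
class SimulatedCohort:
    """Everything one synthetic study produces, in memory."""

    config: SimulationConfig
    tree: PopulationTree
    population_order: list[str]
    frequencies: np.ndarray  # (n_pops, n_snps) risk/allele-1 frequency
    ancestral_frequencies: np.ndarray
    genotypes: GenotypeMatrix
    annotations: pd.DataFrame
    associations: pd.DataFrame
    panel: DiseasePanel
    truth: TruthTable | None


# ----------------------------------------------------------------------
# tree and frequencies
# ----------------------------------------------------------------------

def random_tree(
    n_populations: int,
    rng: np.random.Generator,
    labels: Sequence[str] | None = None,
) -> PopulationTree:
    """Random rooted bifurcating topology over ``n_populations`` leaves."""
    if labels is None:
        labels = [f"POP{i + 1:02d}" for i in range(n_populations)]
    if len(labels) < 2:
        raise ValueError("need at least two populations")
    nodes = [str(lb) for lb in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return PopulationTree.from_newick(nodes[0] + ";")


def balding_nichols_draw(
    parent: np.ndarray, drift_f: float, rng: np.random.Generator
) -> np.ndarray:
    """One Balding–Nichols drift step along a branch.

    Child frequencies are Beta-distributed with mean ``parent`` and variance
    ``drift_f * parent * (1 - parent)``.  Frequencies fixed at 0 or 1 cannot
    drift and are propagated unchanged, as is everything when ``drift_f``
    is 0.
    """
    parent = np.asarray(parent, dtype=float)
    if drift_f == 0:
        return parent.copy()
    out = parent.copy()
    seg = (parent > 0) & (parent < 1)
    scale = (1 - drift_f) / drift_f
    out[seg] = rng.beta(parent[seg] * scale, (1 - parent[seg]) * scale)
    return out


def simulate_frequencies(
    tree: PopulationTree,
    ancestral: np.ndarray,
    drift_f: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Drift ancestral frequencies down every branch of the tree.

    Returns an ``(n_pops, n_snps)`` array ordered like ``tree.leaves``.
    """
    ancestral = np.asarray(ancestral, dtype=float)
    if np.any((ancestral < 0) | (ancestral > 1)):
        raise ValueError("ancestral frequencies must lie in [0, 1]")
    node_freq: dict[str | None, np.ndarray] = {None: ancestral}
    # parents precede children when branches are visited largest clade first
    for branch in sorted(tree.branches, key=lambda b: -len(b.descendants)):
        node_freq[branch.id] = balding_nichols_draw(
            node_freq[branch.parent], drift_f, rng
        )
    leaf_branch = {next(iter(b.descendants)): b.id
                   for b in tree.branches if len(b.descendants) == 1}
    return np.vstack([node_freq[leaf_branch[leaf]] for leaf in tree.leaves])


def simulate_star_frequencies(
    ancestral: np.ndarray,
    drift_f: float,
    n_populations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Independent Balding–Nichols drift of every population from the root.

    The star topology makes the among-population variance of each SNP equal
    to ``drift_f * p * (1 - p)`` exactly, so multi-population Fst estimates
    target ``drift_f`` itself; used by the estimator checks.
    """
    return np.vstack(
        [balding_nichols_draw(ancestral, drift_f, rng) for _ in range(n_populations)]
    )


def inject_event(
    frequencies: np.ndarray,
    population_order: Sequence[str],
    tree: PopulationTree,
    branch_id: str,
    delta: float,
    panel_snp_ids: Sequence[str],
    snp_ids: Sequence[str],
) -> tuple[np.ndarray, TruthTable]:
    """Shift panel risk-allele frequencies below one branch by ``delta``.

    Frequencies are clamped to [0.01, 0.99]; clamped SNPs are recorded in
    the returned :class:`TruthTable`.  Non-panel SNPs are untouched.
    """
    branch = tree.branch(branch_id)  # raises KeyError for unknown branches
    pop_idx = [i for i, p in enumerate(population_order) if p in branch.descendants]
    col_idx = [j for j, s in enumerate(snp_ids) if s in set(panel_snp_ids)]
    out = np.array(frequencies, dtype=float, copy=True)
    shifted = out[np.ix_(pop_idx, col_idx)] + delta
    clamped_cols = np.flatnonzero(
        ((shifted < 0.01) | (shifted > 0.99)).any(axis=0)
    )
    clamped = [snp_ids[col_idx[c]] for c in clamped_cols]
    if clamped:
        logger.warning(
            "event on %s clamped %d SNP frequency(ies) into [0.01, 0.99]",
            branch_id,
            len(clamped),
        )
    out[np.ix_(pop_idx, col_idx)] = np.clip(shifted, 0.01, 0.99)
    direction = "increased" if delta > 0 else "decreased" if delta < 0 else "none"
    truth = TruthTable(
        event_branches=[(branch_id, delta)],
        shifted_snps=[snp_ids[c] for c in col_idx],
        expected_direction={branch_id: direction},
        clamped_snps=clamped,
    )
    return out, truth


# ----------------------------------------------------------------------
# genotypes
# ----------------------------------------------------------------------

def simulate_genotypes(
    frequencies: np.ndarray,
    population_order: Sequence[str],
    n_per_pop: int,
    rng: np.random.Generator,
    snp_ids: Sequence[str] | None = None,
    counted_is_allele1: np.ndarray | None = None,
    allele_symbols: Sequence[tuple[str, str]] | None = None,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Hardy–Weinberg genotypes from per-population allele frequencies.

    ``frequencies[p, s]`` is the allele-1 frequency of SNP ``s`` in
    population ``p``; each call is Binomial(2, frequency).  When
    ``counted_is_allele1`` is given, columns where allele 1 is the global
    major allele are stored flipped so the matrix counts the minor allele.
    A fraction ``missing_rate`` of calls is masked at random.
    """
    if n_per_pop < 1:
        raise ValueError("n_per_pop must be >= 1")
    freqs = np.asarray(frequencies, dtype=float)
    n_pops, n_snps = freqs.shape
    if snp_ids is None:
        snp_ids = [f"snp{j + 1:05d}" for j in range(n_snps)]
    if counted_is_allele1 is None:
        counted_is_allele1 = np.ones(n_snps, dtype=bool)
    calls = np.empty((n_pops * n_per_pop, n_snps), dtype=np.int8)
    individuals: list[str] = []
    populations: list[str] = []
    for p, pop in enumerate(population_order):
        block = rng.binomial(2, freqs[p], size=(n_per_pop, n_snps)).astype(np.int8)
        calls[p * n_per_pop:(p + 1) * n_per_pop] = block
        individuals.extend(f"{pop}_{i + 1:03d}" for i in range(n_per_pop))
        populations.extend([pop] * n_per_pop)
    flip = ~np.asarray(counted_is_allele1, dtype=bool)
    calls[:, flip] = 2 - calls[:, flip]
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls[mask] = MISSING
    if allele_symbols is None:
        counted = {s: "A" for s in snp_ids}
    else:
        counted = {
            s: (a1 if c1 else a2)
            for s, (a1, a2), c1 in zip(snp_ids, allele_symbols, counted_is_allele1)
        }
    return GenotypeMatrix(individuals, populations, list(snp_ids), calls, counted)


# ----------------------------------------------------------------------
# annotations and disease panels
# ----------------------------------------------------------------------

def _genotype_lrs(odds_ratio: float, risk_freq: float) -> np.ndarray:
    """Per-genotype LRs for a multiplicative allelic effect.

    Genotype relative risks ``OR**g`` are normalised by their expectation
    over Hardy–Weinberg genotype frequencies at the global risk-allele
    frequency, so a neutral SNP (OR = 1) has LR identically 1 and the
    cohort-average LR of any SNP is ~1.
    """
    q = risk_freq
    hwe = np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
    raw = odds_ratio ** np.arange(3)
    return raw / (hwe @ raw)


def make_panel(
    pool_snp_ids: Sequence[str],
    annotations: pd.DataFrame,
    risk_freqs: Mapping[str, float],
    risk_alleles: Mapping[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, DiseasePanel]:
    """Draw a disease panel from the pool and invent its study records.

    Each panel SNP receives 1–3 synthetic association studies from distinct
    study populations, with sample sizes, genome-wide-significant p-values
    and per-genotype likelihood ratios consistent with an allelic odds
    ratio drawn from ``config.or_range``.  Annotations are inherited from
    the pool.  Returns the association table together with the
    :class:`DiseasePanel` built from it.
    """
    if config.panel_size > len(pool_snp_ids):
        raise ValueError(
            f"panel of {config.panel_size} SNPs requested from a pool of "
            f"{len(pool_snp_ids)}"
        )
    chosen = list(rng.choice(np.asarray(pool_snp_ids, dtype=object),
                             size=config.panel_size, replace=False))
    lo, hi = config.n_studies_range
    rows = []
    for snp_id in chosen:
        n_studies = int(rng.integers(lo, hi + 1))
        study_pops = rng.choice(STUDY_POPULATIONS, size=n_studies, replace=False)
        for sp in study_pops:
            odds = float(rng.uniform(*config.or_range))
            lrs = _genotype_lrs(odds, risk_freqs[snp_id])
            rows.append(
                {
                    "snp_id": snp_id,
                    "disease": config.disease,
                    "study_population": str(sp),
                    "sample_size": int(rng.integers(500, 5001)),
                    "p_value": float(10 ** -rng.uniform(6.5, 12.0)),
                    "risk_allele": risk_alleles[snp_id],
                    "lr_hom_protective": float(lrs[0]),
                    "lr_het": float(lrs[1]),
                    "lr_hom_risk": float(lrs[2]),
                }
            )
    associations = pd.DataFrame(rows)
    panel = build_panel(associations, annotations, config.disease)
    return associations, panel


def draw_annotations(
    snp_ids: Sequence[str],
    ancestral: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Annotation table for the simulated pool."""
    cats = list(config.category_weights)
    w = np.array([config.category_weights[c] for c in cats], dtype=float)
    w = w / w.sum()
    maf = np.minimum(ancestral, 1 - ancestral)
    return pd.DataFrame(
        {
            "snp_id": list(snp_ids),
            "global_maf": maf,
            "functional_category": rng.choice(cats, size=len(snp_ids), p=w),
            "phenotype_associated": rng.random(len(snp_ids))
            < config.phenotype_associated_rate,
        }
    )


# ----------------------------------------------------------------------
# full cohort
# ----------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a complete synthetic study from one configuration.

    All randomness derives from ``config.seed`` through spawned
    sub-streams, so each stage is individually reproducible.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_tree, rng_freq, rng_ann, rng_panel, rng_geno = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    tree = config.tree or random_tree(config.n_populations, rng_tree)
    pop_order = list(tree.leaves)

    n = config.n_pool_snps
    snp_ids = [f"snp{j + 1:05d}" for j in range(n)]
    lo, hi = config.ancestral_freq_range
    ancestral = rng_freq.uniform(lo, hi, size=n)
    symbols = np.array(list("ACGT"))
    pairs = [tuple(rng_ann.choice(symbols, size=2, replace=False)) for _ in range(n)]
    counted_is_allele1 = ancestral <= 0.5  # counted allele = global minor

    frequencies = simulate_frequencies(tree, ancestral, config.drift_f, rng_freq)

    annotations = draw_annotations(snp_ids, ancestral, config, rng_ann)
    risk_alleles = {s: pairs[j][0] for j, s in enumerate(snp_ids)}  # allele 1
    risk_freqs = {s: float(ancestral[j]) for j, s in enumerate(snp_ids)}
    associations, panel = make_panel(
        snp_ids, annotations, risk_freqs, risk_alleles, config, rng_panel
    )
    # disease-associated SNPs are phenotype-associated by construction
    annotations.loc[
        annotations["snp_id"].isin(panel.snp_ids), "phenotype_associated"
    ] = True

    truth: TruthTable | None = None
    for branch_id, delta in config.injected_events:
        frequencies, t = inject_event(
            frequencies, pop_order, tree, branch_id, delta, panel.snp_ids, snp_ids
        )
        if truth is None:
            truth = t
        else:
            truth.event_branches.extend(t.event_branches)
            truth.expected_direction.update(t.expected_direction)
            truth.clamped_snps.extend(t.clamped_snps)

    genotypes = simulate_genotypes(
        frequencies,
        pop_order,
        config.n_individuals_per_pop,
        rng_geno,
        snp_ids=snp_ids,
        counted_is_allele1=counted_is_allele1,
        allele_symbols=pairs,
        missing_rate=config.missing_rate,
    )
    return SimulatedCohort(
        config=config,
        tree=tree,
        population_order=pop_order,
        frequencies=frequencies,
        ancestral_frequencies=ancestral,
        genotypes=genotypes,
        annotations=annotations,
        associations=associations,
        panel=panel,
        truth=truth,
    )
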