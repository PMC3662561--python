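"""Branch tests for genetic-risk differentiation beyond drift.

For every branch ``i`` of the population tree, the observed statistic is

    O_i = mean risk of ancestral-set individuals
        - mean risk of descendant-set individuals,

and its null distribution is built by *matched resampling*: the disease
panel H is replaced wholesale, each SNP by one drawn uniformly from the
genome-wide pool of SNPs sharing its global major-allele-frequency bin, its
functional category and the major/minor status of its risk allele.  The
replacement inherits the original SNP's combined likelihood ratios, so only
the allele-frequency structure is randomised — exactly what genetic drift
would shuffle.  All branches are scored against the *same* replaced panel
in each draw, preserving the correlation of risk among related populations;
``K`` draws give the null matrix ``r_{i,k}``.

Empirical p-values count draws at least as extreme as ``O_i`` in the
observed direction (floored at ``1/K``); q-values divide the expected
number of branches reaching significance ``alpha`` under the null by the
observed number.

The model/results split follows the statsmodels convention:
:class:`RiskDifferentiationModel` holds data and configuration,
``fit()`` runs the Monte Carlo and returns
:class:`RiskDifferentiationResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import events as _events
from .risk import cohort_risks
from .robustness import population_outlier_mask
from .tree import Branch, PopulationTree
from .types import DiseasePanel, GenotypeMatrix, PanelSnp

logger = logging.getLogger("riskdrift.differentiation")

DEFAULT_MAF_BIN_WIDTH = 0.02
_CHUNK = 2000  # draws per vectorised chunk


# ----------------------------------------------------------------------
# empirical p and q values (pure array operations)
# ----------------------------------------------------------------------

def branch_empirical_p(
    observed: float, null_row: np.ndarray, alternative: str = "one-sided"
) -> tuple[float, str]:
    """Empirical p-value of one branch against its null row.

    One-sided (default): the fraction of draws at least as extreme as the
    observed deviation *in the observed direction*; two-sided: twice the
    smaller tail, capped at 1.  Either way the p-value is floored at
    ``1/K`` — zero exceedances out of K reports ``1/K``, never 0.

    Returns ``(p, direction)`` where direction says whether risk is
    increased or decreased in the descendant set (the observed deviation is
    ancestral minus descendant mean, so a positive value means decreased
    descendant risk).
    """
    row = np.asarray(null_row, dtype=float)
    k = row.size
    if k == 0:
        raise ValueError("empty null row")
    upper = np.count_nonzero(row >= observed) / k
    lower = np.count_nonzero(row <= observed) / k
    direction = "decreased" if observed >= 0 else "increased"
    if alternative == "one-sided":
        p = upper if observed >= 0 else lower
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(upper, lower))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return max(p, 1.0 / k), direction


def _null_pvalues(null: np.ndarray, alternative: str) -> np.ndarray:
    """P-value of every null draw scored against its own branch row.

    Each column's deviation is treated exactly like an observed one (tail
    chosen by its sign, same flooring), scored against the full row
    including itself — simple and exact under exchangeability.
    """
    b, k = null.shape
    out = np.empty((b, k))
    for i in range(b):
        row = null[i]
        order = np.sort(row)
        upper = (k - np.searchsorted(order, row, side="left")) / k
        lower = np.searchsorted(order, row, side="right") / k
        if alternative == "one-sided":
            p = np.where(row >= 0, upper, lower)
        else:
            p = np.minimum(1.0, 2.0 * np.minimum(upper, lower))
        out[i] = np.maximum(p, 1.0 / k)
    return out


def branch_qvalues(
    observed_p: np.ndarray, null_p: np.ndarray
) -> np.ndarray:
    """Empirical q-values over correlated branches.

    For a branch with p-value ``alpha``: ``N(alpha)`` is the number of
    observed branches at p <= alpha, ``E[N(alpha)]`` the mean number of
    branches per null draw at null p <= alpha; ``q = E[N]/N`` capped at 1.
    ``null_p`` is the per-draw p-value matrix from the same null matrix
    (branches x draws).
    """
    observed_p = np.asarray(observed_p, dtype=float)
    b, k = null_p.shape
    flat = np.sort(null_p.ravel())
    q = np.empty_like(observed_p)
    for i, alpha in enumerate(observed_p):
        n_obs = np.count_nonzero(observed_p <= alpha)  # counts itself, >= 1
        e_null = np.searchsorted(flat, alpha, side="right") / k
        q[i] = min(1.0, e_null / n_obs)
    return q


# ----------------------------------------------------------------------
# observed deviations
# ----------------------------------------------------------------------

def observed_branch_deviations(
    tree: PopulationTree, risks: pd.DataFrame, branches: Sequence[Branch] | None = None
) -> pd.Series:
    """O_i per tested branch from a per-individual risk table.

    Means are individual-weighted: every member of the ancestral
    (descendant) set counts equally regardless of population size.
    ``risks`` is a :func:`riskdrift.risk.cohort_risks` table.  By default
    every branch of the tree is scored (the root has no branch; a branch
    with an empty ancestral set is excluded and logged); the testing layer
    passes its deduplicated branch list explicitly.
    """
    if branches is None:
        branches = tree.branches
    pops = risks["population"].to_numpy()
    vals = risks["risk"].to_numpy(dtype=float)
    out = {}
    for br in branches:
        desc = np.isin(pops, list(br.descendants))
        anc = ~desc
        if not anc.any():
            logger.info("branch %s has an empty ancestral set; excluded", br.id)
            continue
        out[br.id] = vals[anc].mean() - vals[desc].mean()
    return pd.Series(out, name="observed")


# ----------------------------------------------------------------------
# matched resampling null
# ----------------------------------------------------------------------

def maf_bin(global_maf: np.ndarray | float, width: float = DEFAULT_MAF_BIN_WIDTH):
    """Bin index of the global major-allele frequency (1 - MAF)."""
    major = 1.0 - np.asarray(global_maf, dtype=float)
    return np.floor(major / width + 1e-9).astype(int)


@dataclass
class NullMatrix:
    """K draws of all-branch risk deviations under matched random panels.

    ``values[i, k]`` is the deviation of branch ``i`` in draw ``k``; every
    column comes from one shared replaced panel, so rows are correlated by
    construction.  ``draw_snp_ids[k][j]`` records which pool SNP replaced
    panel slot ``j`` in draw ``k`` (enables from-scratch recomputation).
    """

    branch_ids: list[str]
    values: np.ndarray  # (n_branches, draws)
    draws: int
    seed: int | None
    matched_on: dict = field(default_factory=dict)
    draw_indices: np.ndarray | None = None  # (draws, panel size) into pool_snp_ids
    pool_snp_ids: list[str] | None = None

    @property
    def draw_snp_ids(self) -> list[list[str]]:
        if self.draw_indices is None or self.pool_snp_ids is None:
            raise ValueError("draw bookkeeping was not stored")
        return [
            [self.pool_snp_ids[j] for j in row] for row in self.draw_indices
        ]


def draw_null_panel(
    panel: DiseasePanel,
    pools: Mapping[str, Sequence[str]],
    rng: np.random.Generator,
) -> list[str]:
    """One random replacement of the vector H.

    Each panel SNP is replaced by a uniform draw from its matched pool;
    the replaced panel has the same length and order as H.
    """
    out = []
    for snp in panel:
        cand = pools[snp.snp_id]
        if len(cand) == 0:
            raise ValueError(f"empty matched pool for {snp.snp_id}")
        out.append(cand[int(rng.integers(len(cand)))])
    return out


# ----------------------------------------------------------------------
# the model
# ----------------------------------------------------------------------

class RiskDifferentiationModel:
    """Test a disease panel for risk differentiation on a population tree.

    Parameters
    ----------
    genotypes
        Cohort genotype matrix (counted allele = global minor allele).
    panel
        LD-pruned disease panel (the vector H).
    tree
        Rooted population phylogeny whose leaves are the cohort's
        population labels.
    annotations
        Genome-wide SNP annotation table (``snp_id``, ``global_maf``,
        ``functional_category``, ``phenotype_associated``) defining the
        resampling pool.
    maf_bin_width
        Width of the major-allele-frequency bins used for matching.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        panel: DiseasePanel,
        tree: PopulationTree,
        annotations: pd.DataFrame,
        maf_bin_width: float = DEFAULT_MAF_BIN_WIDTH,
    ):
        tree.validate_populations(set(genotypes.population_labels))
        self.genotypes = genotypes
        self.panel = panel
        self.tree = tree
        self.maf_bin_width = float(maf_bin_width)
        ann = annotations.copy()
        if "snp_id" in ann.columns:
            ann = ann.set_index("snp_id")
        in_matrix = ann.index.isin(genotypes.snp_ids)
        if (~in_matrix).any():
            logger.info(
                "%d annotated SNP(s) not genotyped; excluded from the pool",
                int((~in_matrix).sum()),
            )
        self.annotations = ann[in_matrix]
        self._bins = pd.Series(
            maf_bin(self.annotations["global_maf"].to_numpy(), self.maf_bin_width),
            index=self.annotations.index,
        )
        self.population_order = list(tree.leaves)
        self._panel_snps: list[PanelSnp] = [
            s for s in panel if genotypes.has_snp(s.snp_id)
        ]
        if len(self._panel_snps) < len(panel):
            logger.info(
                "%d panel SNP(s) not genotyped; excluded from the test",
                len(panel) - len(self._panel_snps),
            )
        if not self._panel_snps:
            raise ValueError("no panel SNP is genotyped in this cohort")

    # -- matched pools -------------------------------------------------
    def matched_pool(self, snp_id: str, pool: str = "all") -> list[str]:
        """Candidate replacement SNPs for one panel SNP.

        Candidates share the SNP's global major-allele-frequency bin and
        functional category (risk-allele major/minor status is matched by
        construction when the replacement is oriented).  The SNP itself is
        excluded so the observed statistic cannot contaminate its own null.
        ``pool="phenotype-associated"`` restricts candidates to flagged
        SNPs (ascertainment control).
        """
        ann = self.annotations
        if snp_id not in ann.index:
            raise KeyError(f"panel SNP {snp_id} has no pool annotation")
        if pool == "phenotype-associated":
            from .robustness import ascertainment_pool

            ann = ascertainment_pool(ann)
            bins = self._bins[ann.index]
        elif pool == "all":
            bins = self._bins
        else:
            raise ValueError(f"unknown pool {pool!r}")
        target_bin = int(self._bins[snp_id])
        target_cat = self.annotations.loc[snp_id, "functional_category"]
        mask = (
            (bins == target_bin)
            & (ann["functional_category"] == target_cat)
            & (ann.index != snp_id)
        )
        cands = list(ann.index[mask])
        if not cands:
            raise ValueError(
                f"empty matched pool for SNP {snp_id} "
                f"(major-frequency bin {target_bin}, category {target_cat!r})"
            )
        return cands

    # -- internals -----------------------------------------------------
    def _oriented_logl(self) -> np.ndarray:
        """(J, 3) ln L per panel slot, indexed by counted-allele dosage."""
        rows = []
        for snp in self._panel_snps:
            logl = snp.effect.log_l()
            counted = self.genotypes.counted_allele.get(snp.snp_id)
            if counted is not None and counted != snp.risk_allele:
                logl = logl[::-1]  # risk copies = 2 - counted dosage
            rows.append(logl)
        return np.vstack(rows)

    def _partition_weights(
        self, partitions: list[tuple[str, frozenset[str]]], keep_rows: np.ndarray
    ) -> np.ndarray:
        """(n_pops, n_partitions) contrast weights: +1/n_anc and -1/n_desc."""
        pops = np.asarray(self.genotypes.populations)
        sizes = np.array(
            [np.count_nonzero((pops == p) & keep_rows) for p in self.population_order],
            dtype=float,
        )
        w = np.zeros((len(self.population_order), len(partitions)))
        for b, (_, desc) in enumerate(partitions):
            is_desc = np.array([p in desc for p in self.population_order])
            n_desc = sizes[is_desc].sum()
            n_anc = sizes[~is_desc].sum()
            if n_desc == 0 or n_anc == 0:
                raise ValueError("partition with an empty side")
            # applied to per-population risk *sums*: +-1/(set size) turns
            # them into individual-weighted set means
            w[is_desc, b] = -1.0 / n_desc
            w[~is_desc, b] = 1.0 / n_anc
        return w

    def _null_matrix(
        self,
        partitions: list[tuple[str, frozenset[str]]],
        draws: int,
        seed: int | None,
        pool: str,
        keep_rows: np.ndarray,
    ) -> NullMatrix:
        pools = {s.snp_id: self.matched_pool(s.snp_id, pool) for s in self._panel_snps}
        pool_ids = sorted({c for cands in pools.values() for c in cands})
        pool_pos = {s: i for i, s in enumerate(pool_ids)}
        pool_counts = self.genotypes.dosage_counts(
            self.population_order, snp_ids=pool_ids, keep_rows=keep_rows
        ).astype(np.float64)
        a = self._oriented_logl()  # (J, 3)
        w = self._partition_weights(partitions, keep_rows)  # (P, B)
        rng = np.random.default_rng(seed)
        j_slots = len(self._panel_snps)
        idx = np.empty((draws, j_slots), dtype=np.int32)
        for j, snp in enumerate(self._panel_snps):
            cand = np.array([pool_pos[c] for c in pools[snp.snp_id]], dtype=np.int32)
            idx[:, j] = cand[rng.integers(0, len(cand), size=draws)]
        values = np.empty((len(partitions), draws))
        for start in range(0, draws, _CHUNK):
            sl = slice(start, min(start + _CHUNK, draws))
            gathered = pool_counts[idx[sl]]  # (k, J, P, 3)
            popsums = np.einsum("kjpg,jg->kp", gathered, a)
            values[:, sl] = (popsums @ w).T
        return NullMatrix(
            branch_ids=[name for name, _ in partitions],
            values=values,
            draws=draws,
            seed=seed,
            matched_on={
                "maf_bin_width": self.maf_bin_width,
                "functional_category": True,
                "risk_allele_status": True,
                "pool": pool,
            },
            draw_indices=idx,
            pool_snp_ids=pool_ids,
        )

    def build_null_matrix(
        self,
        draws: int = 1000,
        seed: int | None = None,
        pool: str = "all",
    ) -> NullMatrix:
        """Null matrix over the tree's tested branches (K shared draws)."""
        partitions = [(b.id, b.descendants) for b in self.tree.tested_branches()]
        keep = np.ones(self.genotypes.n_individuals, dtype=bool)
        return self._null_matrix(partitions, draws, seed, pool, keep)

    # -- fitting -------------------------------------------------------
    def fit(
        self,
        draws: int = 1000,
        seed: int | None = None,
        alternative: str = "one-sided",
        pool: str = "all",
        remove_outliers: bool = False,
    ) -> "RiskDifferentiationResults":
        """Run the matched-resampling test on every tested branch.

        ``draws`` is the number K of random panels (the study this package
        reproduces used 100,000; desk-scale analyses use 1,000–10,000).
        ``remove_outliers`` drops individuals deviating more than 1.5 IQRs
        from their population's median risk before testing.
        """
        risks = cohort_risks(self.genotypes, self.panel)
        keep_rows = np.ones(self.genotypes.n_individuals, dtype=bool)
        outliers: list[str] = []
        if remove_outliers:
            keep_rows = population_outlier_mask(risks)
            outliers = list(risks.loc[~keep_rows, "individual"])
            risks = risks[keep_rows].reset_index(drop=True)
        branches = self.tree.tested_branches()
        partitions = [(b.id, b.descendants) for b in branches]
        observed = observed_branch_deviations(self.tree, risks, branches)
        null = self._null_matrix(partitions, draws, seed, pool, keep_rows)
        return self._assemble(
            observed, null, risks, alternative, seed, pool, outliers,
            descendants={b.id: b.descendants for b in branches},
        )

    def fit_population(
        self,
        population: str,
        draws: int = 1000,
        seed: int | None = None,
        alternative: str = "one-sided",
        pool: str = "all",
        remove_outliers: bool = False,
    ) -> "RiskDifferentiationResults":
        """Population-vs-rest special case of the branch test.

        The single partition separates one population from all others
        combined; reported deviation, p and q use the same machinery.
        """
        if population not in self.population_order:
            raise KeyError(f"unknown population {population!r}")
        n_members = self.genotypes.populations.count(population)
        if n_members < 2:
            logger.warning(
                "population %s has %d member(s); the test is noisy",
                population,
                n_members,
            )
        risks = cohort_risks(self.genotypes, self.panel)
        keep_rows = np.ones(self.genotypes.n_individuals, dtype=bool)
        outliers: list[str] = []
        if remove_outliers:
            keep_rows = population_outlier_mask(risks)
            outliers = list(risks.loc[~keep_rows, "individual"])
            risks = risks[keep_rows].reset_index(drop=True)
        name = f"{population}-vs-rest"
        desc = frozenset([population])
        pops = risks["population"].to_numpy()
        vals = risks["risk"].to_numpy(dtype=float)
        is_desc = pops == population
        observed = pd.Series(
            {name: vals[~is_desc].mean() - vals[is_desc].mean()}, name="observed"
        )
        null = self._null_matrix([(name, desc)], draws, seed, pool, keep_rows)
        return self._assemble(
            observed, null, risks, alternative, seed, pool, outliers,
            descendants={name: desc},
        )

    def _assemble(
        self,
        observed: pd.Series,
        null: NullMatrix,
        risks: pd.DataFrame,
        alternative: str,
        seed: int | None,
        pool: str,
        outliers: list[str],
        descendants: Mapping[str, frozenset[str]],
    ) -> "RiskDifferentiationResults":
        obs = observed.reindex(null.branch_ids).to_numpy(dtype=float)
        p = np.empty(len(obs))
        direction = []
        for i, o in enumerate(obs):
            p[i], d = branch_empirical_p(o, null.values[i], alternative)
            direction.append(d)
        null_p = _null_pvalues(null.values, alternative)
        q = branch_qvalues(p, null_p)
        table = pd.DataFrame(
            {
                "branch": null.branch_ids,
                "descendant_populations": [
                    ",".join(sorted(descendants[b])) for b in null.branch_ids
                ],
                "observed": obs,
                "direction": direction,
                "p_value": p,
                "q_value": q,
            }
        ).set_index("branch")
        return RiskDifferentiationResults(
            model=self,
            branch_table=table,
            null_matrix=null,
            individual_risks=risks,
            alternative=alternative,
            seed=seed,
            pool=pool,
            removed_outliers=outliers,
        )


@dataclass
class RiskDifferentiationResults:
    """Fitted branch tests: deviations, p- and q-values, and the null.

    ``branch_table`` is indexed by branch id with columns
    ``descendant_populations``, ``observed`` (ancestral minus descendant
    mean risk), ``direction`` (of descendant risk), ``p_value`` and
    ``q_value``.
    """

    model: RiskDifferentiationModel
    branch_table: pd.DataFrame
    null_matrix: NullMatrix
    individual_risks: pd.DataFrame
    alternative: str
    seed: int | None
    pool: str
    removed_outliers: list[str]

    @property
    def population_risks(self) -> pd.Series:
        return self.individual_risks.groupby("population")["risk"].mean()

    @property
    def branch_pvalues(self) -> pd.Series:
        """The vector P consumed by event inference."""
        return self.branch_table["p_value"]

    def infer_events(
        self, max_events: int = 8, alpha: float = 0.05, allow_nested: bool = False
    ) -> "_events.EventInferenceResults":
        """Maximum-likelihood count and location of independent events."""
        return _events.infer_events(
            self.branch_pvalues.to_dict(),
            self.model.tree,
            max_events=max_events,
            alpha=alpha,
            allow_nested=allow_nested,
        )

    def run_summary(self) -> dict:
        """Machine-readable description of this run (for serialisation)."""
        return {
            "disease": self.model.panel.disease,
            "draws": int(self.null_matrix.draws),
            "seed": self.seed,
            "alternative": self.alternative,
            "pool": self.pool,
            "maf_bin_width": self.model.maf_bin_width,
            "panel_snps": list(self.model.panel.snp_ids),
            "removed_outliers": list(self.removed_outliers),
            "n_branches": int(len(self.branch_table)),
            "populations": list(self.model.population_order),
        }

    def summary(self) -> str:
        """Human-readable results table, most significant branches first."""
        t = self.branch_table.sort_values("p_value")
        lines = [
            "Genetic risk differentiation test"
            f" — disease: {self.model.panel.disease}",
            f"draws K = {self.null_matrix.draws}, alternative = {self.alternative},"
            f" pool = {self.pool}, seed = {self.seed}",
            f"panel SNPs = {len(self.model.panel)},"
            f" branches tested = {len(t)}",
            "",
            f"{'branch':<40} {'observed':>10} {'direction':>10} "
            f"{'p':>10} {'q':>10}",
        ]
        for bid, row in t.iterrows():
            label = bid if len(bid) <= 40 else bid[:37] + "..."
            lines.append(
                f"{label:<40} {row['observed']:>10.4f} {row['direction']:>10} "
                f"{row['p_value']:>10.3g} {row['q_value']:>10.3g}"
            )
        return "\n".join(lines)


def population_vs_rest_test(
    genotypes: GenotypeMatrix,
    panel: DiseasePanel,
    tree: PopulationTree,
    annotations: pd.DataFrame,
    population: str,
    draws: int = 1000,
    seed: int | None = None,
    **fit_kwargs,
) -> RiskDifferentiationResults:
    """Convenience wrapper: one population against the rest of the world."""
    model = RiskDifferentiationModel(genotypes, panel, tree, annotations)
    return model.fit_population(population, draws=draws, seed=seed, **fit_kwargs)
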