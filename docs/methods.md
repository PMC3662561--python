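# Methods

This note documents the statistical model behind `riskdrift`, the choices
made where the design was genuinely open, what the simulator does and does
not emulate, and the known limitations. Everything quantitative stated
here is computed by the test suite or by `scripts/acceptance.py`.

## Risk model

The effect of genotype *g* at a biallelic SNP is its likelihood ratio
`LR(g) = P(g|disease)/P(g|no disease)`. Studies reporting the same SNP are
merged by a √(sample-size)-weighted mean,
`L(g) = Σᵢ √Aᵢ LRᵢ(g) / Σᵢ √Aᵢ`. An alternative estimator that averages
the case and control genotype probabilities separately before taking their
ratio is available (`combine_likelihood_ratios(..., method="prob-mean")`);
the weighted mean of ratios is the default. Individual risk is
`r = Σ ln L(g)` over the disease panel. Natural logarithms are used
throughout; the base only rescales every score by a constant.

Missing genotypes contribute nothing (factor 1): a missing call is absent
evidence, not a homozygote, and no imputation is attempted. An individual
with no usable panel genotypes scores 0 with a logged warning.

Panels are LD-pruned greedily in panel order: a SNP is dropped when its
genotype-dosage r² with any already-kept SNP reaches 0.2. r² is computed
on the pooled cohort by default (overridable per population); dosage
r², not haplotype r², because phase is not assumed. Monomorphic SNPs
(undefined r²) are kept and logged. Greedy first-kept-wins pruning is not
unique-optimal, but it is deterministic and order-faithful to how panels
are curated.

Association tables are filtered before panel building: a SNP needs at
least one association with p < 10⁻⁶, detection in ≥ 2 distinct study
populations, and enough information to form genotype likelihood ratios.
Effect sizes can be restricted to a group of study populations (e.g. only
Asian-based studies) to check that a finding is not an artifact of
population-biased effect-size estimates; SNPs left without any qualifying
study drop out of the panel, and counts are logged.

### Genotype orientation

The genotype matrix stores, for every SNP, copies of a single *counted
allele* — by convention the global minor allele. Risk-allele dosage is
resolved at scoring time by comparing a panel SNP's risk allele with its
counted allele. (Orienting the matrix per disease is not possible, since
panel membership depends on the disease.)

## The drift null

For branch *i* of the rooted population tree, the observed statistic is

    O_i = mean(r over ancestral-set individuals)
        − mean(r over descendant-set individuals),

individual-weighted, so every person counts equally regardless of
population size. The root has no branch; the root's two children induce
the same partition, and the one with the lexicographically larger
identifier is suppressed, leaving 2n − 3 tested branches for n
populations.

The null asks: how far would `O_i` wander if the panel were an arbitrary
set of SNPs with the same ascertainment profile? Each draw replaces every
panel SNP by one sampled uniformly from its matched pool — same global
major-allele-frequency bin (width 0.02 by default), same functional
category, same major/minor status for the designated risk allele — and the
replacement inherits the original SNP's `L(g)`. Only allele-frequency
structure is randomised, which is exactly the quantity drift perturbs.
A SNP is excluded from its own matched pool so the observed statistic
cannot contaminate its null. All branches are evaluated on the *same*
replaced panel within a draw, so the branch-by-draw null matrix preserves
the correlation of risk among related populations.

The default bin width of 0.02 keeps frequency tightly matched while
leaving pools populated at desk scale (a 2,000-SNP pool spreads over ~25
bins per category); it is a parameter, and small cohorts may need wider
bins.

### p-values and their calibration

The reported p-value is one-sided in the observed direction — the
fraction of draws at least as extreme as `O_i` on the side the data fell,
floored at 1/K (15 exceedances in 100,000 draws report 1.5×10⁻⁴; zero
report 10⁻⁵, never 0). This matches how direction-specific results are
naturally reported ("only 28 of 100,000 draws showed less risk"), but the
tail is *chosen from the data*: under the null such a p-value has CDF
2α (it is at most 0.5 up to ties), and it is the doubled, two-sided
version (`alternative="two-sided"`) that is uniform. Calibration checks
therefore assert uniformity of the two-sided p; the one-sided default is
the reporting convention, and its q-values account for the doubling
because the null p-values inside the q computation are direction-picked
the same way.

### q-values

For an observed branch at p = α, `N(α)` counts observed branches with
p ≤ α and `E[N(α)]` is the mean, over null draws, of the number of
branches whose own null p (each draw's deviation scored against its full
branch row, including itself — simple and exact under exchangeability)
falls at or below α. The q-value is `E[N(α)]/N(α)`, capped at 1. This is
an empirical FDR over correlated branches, conservative by construction.

## Event inference

An event on branch *z* explains *z* and every branch below it (inherited
differentiation). With `P` the vector of per-branch null probabilities,

    l(events) = Σ over unexplained branches of ln P(branch),

explained branches contributing 0. The best *y*-event set maximises *l*
over all admissible subsets (no event inside another event's subtree —
a nested event explains nothing extra; `allow_nested=True` lifts the
constraint). The search is exhaustive enumeration — exact, and fast for
trees of tens of branches with a handful of events, but combinatorial in
`max_events`. Ties break toward the set explaining fewer branches, then
lexicographically. The event count is chosen stepwise: `2(lₙ − lₙ₋₁)` is
referred to χ²₁, starting at n = 2 and stopping at the first
non-significant improvement (default α = 0.05).

**A structural property users must know.** Because explained branches
contribute 0 and `ln P ≤ 0`, *l* is monotone under explained-set
inclusion: an ancestor never scores worse than a branch nested below it,
and the single-event optimum is always a maximal candidate (in practice a
root-child branch — whichever side of the root holds more aggregate
significance). The one-event model therefore answers "which side of which
split shifted", not "which exact interior branch"; finer localisation
comes from the per-branch q-values and from multi-event models, whose
later steps absorb the contrasts echoed onto the unshifted side (every
branch's ancestral or descendant set contains shifted populations when
the tree is small, so echoes are material at 8 populations and negligible
at 50+). For the same reason the stepwise LRT tends to add events beyond
the injected one; the count it returns should be read as "segments of the
tree with distinguishable risk levels", not as a count of true shifts.

## The simulator

`simulate_cohort` generates: a random (or supplied) rooted binary tree;
ancestral allele frequencies uniform on [0.05, 0.95] (avoids fixation
artifacts and keeps matched-frequency bins populated); Balding–Nichols
drift applied recursively along every branch (child ~ Beta with mean
equal to the parent frequency and variance `F·p(1−p)`, fixed frequencies
propagating unchanged); Hardy–Weinberg genotypes, Binomial(2, f) per
individual, with optional uniform missingness; an annotation pool with
global MAF from the ancestral frequency, functional categories drawn from
an array-like mix (55% intron, 35% unknown, 10% near-gene — rare coding
classes are omitted from the default mix because matched resampling needs
populated category × frequency cells at desk scale; the schema supports
all eight classes), and a phenotype-associated flag at rate 0.07 (panel
SNPs are always flagged); and synthetic association studies per panel
SNP — 1–3 studies from distinct study populations, sample sizes
500–5,000, p-values below 10⁻⁶·⁵, and genotype LRs `OR^g` normalised to
unit Hardy–Weinberg expectation with allelic odds ratios uniform on
[1.1, 1.5] by default (the OR range is a parameter; no canonical
effect-size distribution exists for curated panels).

Injected events shift the risk-allele frequency of every panel SNP by δ
in all populations below a chosen branch, clamped to [0.01, 0.99] with
the clamped SNPs recorded in the truth table. A shift at the root moves
all populations together and is unidentifiable by construction.

All randomness derives from one seed through spawned substreams, so each
stage reruns independently and the whole pipeline is byte-reproducible.

What the simulator does *not* emulate: linkage disequilibrium (SNPs are
independent; LD fixtures for pruning tests are built as explicit
duplicated columns), admixture, ascertainment bias in which SNPs get
discovered, genealogical noise (coalescent variance within populations),
or realistic per-disease effect-size distributions. Passing tests on this
generator show the statistical machinery is correct under the null model
the method itself assumes — tree-structured drift of independent SNPs —
not that real cohorts satisfy those assumptions.

**Drift parameterisation and Fst.** `F` is a *per-branch* coefficient.
Differentiation accumulates multiplicatively down the tree, so the
leaf-level Fst of a hierarchical cohort exceeds F (roughly
`1 − Π(1−F_b)` along a path, further shaped by shared branches). Only
under star-shaped drift (every population one step from the ancestor,
`simulate_star_frequencies`) does multi-population Weir–Cockerham θ
target F itself; that configuration is what the estimator checks use.
This also bounds the power of event recovery at desk scale: with 8
populations, F = 0.05 per branch, a 15-SNP panel and δ = 0.15, the
injected contrast is ~3 null standard deviations, so a minority of
replicates land above q = 0.05 (the acceptance run reports the observed
rate rather than asserting one).

## Robustness procedures

*Outlier removal*: within each population, individuals whose risk deviates
more than 1.5×IQR from the median (numpy linear-interpolation quartiles)
are removed and the test rerun; a zero IQR degenerates to keeping exactly
the median values, with a warning. *Ascertainment control*: the resampling
pool is restricted to phenotype-associated SNPs, with retained/discarded
counts logged; matched pools that empty under the restriction raise.
*Fst comparison*: per-SNP Weir–Cockerham (1984) θ across all populations
(negative estimates preserved; monomorphic SNPs undefined and excluded),
rank-normalised within MAF bins (fraction of same-bin pool SNPs with
strictly lower θ, the SNP itself excluded), converted to upper-tail
p-values, floored away from zero, and combined by Fisher's method
(Stouffer's Z behind a flag). The multi-locus θ is the standard
ratio-of-sums estimator. A coherent shift spread over a panel moves the
set-level branch statistic long before any single SNP's θ becomes
extreme within its frequency bin — the contrast the Fst scan is there to
demonstrate.

## Numerical and engineering choices

Empirical p-values are exact counts (no continuity corrections) with the
1/K floor; q-values are capped at 1. The null engine precomputes
per-population genotype-dosage counts for the whole pool and evaluates
draws as einsum contractions in chunks of 2,000, so K = 100,000 draws on
a 51-population, 15-SNP panel is minutes of work; stored draw indices
allow any column to be recomputed from scratch for verification. Problem
sizes in the test and acceptance runs (8 populations × 30 individuals,
2,000 pool SNPs, 15-SNP panels, K = 2,000, 20–50 replicates) were chosen
so a complete from-scratch verification runs in well under a minute while
keeping Monte-Carlo error small relative to the asserted tolerances.
Results files are written with deterministic float formatting; identical
seed and configuration reproduce byte-identical output.
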