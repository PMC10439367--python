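# Methods

`ghostflow` implements a complete inference pipeline for detecting and
dating **ghost introgression** — gene flow into a sampled lineage from an
extinct or unsampled donor — in reduced-representation SNP data from a
pair of sampled lineages.  The motivating system is a sympatric cryptic
plant lineage (called *TaiB* throughout) coexisting with its described
relative (*TaiA*, itself admixed with an allopatric group *Ryu*): the
question is whether TaiB's genome-wide divergence reflects current gene
flow, past contact, or the legacy of an unsampled ghost lineage.

## Demographic model

Four populations: the two sampled lineages TaiA and TaiB (current
diploid sizes `N_A`, `N_B`), an unsampled ghost, and their common
ancestor.  Backward in time:

1. at `T_m` generations the present-day sizes revert to the larger
   post-split sizes `N_aA`, `N_aB` (forward in time: a bottleneck at
   `T_m`, when inter-lineage gene flow also ceases);
2. between `T_m` and the split `T_div`, TaiA and TaiB exchange migrants
   at forward-time fractions `m_A` (into TaiA) and `m_B` (into TaiB);
3. at `T_div` the pair merges into an ancestor of size
   `N_anc × (N_aA + N_aB)` — `N_anc` is a dimensionless ratio, i.e. the
   ancestor declined `N_anc`-fold into the two daughters;
4. the ghost (size `N_ghost`) splits from the ancestor at `T_divG`.

The nine scenarios differ only in their migration/admixture structure.
Gene-flow scenarios: **CI** (no migration ever), **CG** (migration from
`T_div` to the present), **PC** (primary contact: migration from
`T_div` until `T_m`, then the bottleneck), **SC** (secondary contact:
isolation until `T_m`, migration since).  The T_m size change is attached
to PC (and the ghost scenarios, which extend PC); CI/CG/SC hold
`N_A`/`N_B` constant after the split and use `N_anc × (N_A + N_B)` as
the ancestral size.  Ghost scenarios add the ghost split: **GhPC** (no
ghost gene flow), **GhGeA**/**GhGeB** (bidirectional ghost↔TaiA or
ghost↔TaiB migration from `T_div` until `T_G`, with `m_G` the
ghost→lineage and `m_AG` the lineage→ghost forward fraction), and
**GhHyA**/**GhHyB** (the lineage is founded at `T_div` as a hybrid with
ghost ancestry fraction `h_frac`).

Migration parameters are forward-time fractions of the recipient
replaced per generation; because that equals the backward-time rate at
which a recipient lineage jumps to the source, they enter the
structured coalescent unchanged.  Generation time (30 years) is used
only to convert reported times to years, never inside the simulator.

## Coalescent engine

Every SNP is an independent single-site genealogy (ddRAD loci are short
and effectively unlinked), so no recombination is simulated.  The
default backend is a numba-compiled structured coalescent: exponential
competing risks for within-population coalescence (rate `k(k-1)/(4N)`
per generation for `k` lineages in a diploid population of size `N`) and
per-lineage migration, interleaved with the scheduled demographic events
(size changes, rate switches, splits, admixture pulses).  The identical
event schedule also compiles to an `msprime.Demography`; the test suite
cross-validates the two backends distributionally (two-sample KS on all
22 summary statistics under three scenarios) and against Watterson's
closed-form expectation for segregating sites.  The compiled engine
exists for throughput: building ABC reference tables requires tens of
millions of genealogies, and running the whole per-dataset loop in
compiled code is roughly an order of magnitude faster than per-replicate
tree-sequence construction, which is what makes the full-scale
acceptance experiment fit on a single CPU.

Mutations follow the infinite-sites limit with one SNP per locus: a
polymorphic locus carries a single derived allele placed uniformly along
the genealogy's total branch length (Hudson's fixed-segregating-sites
convention).

## Panel designs and ascertainment

Two SNP-panel designs are provided:

* **Fixed panel** (`design="panel"`): exactly `n_snps` ascertained SNPs,
  each genealogy redrawn until its SNP's pooled minor-allele frequency
  reaches `maf_asc` (default 0.05, ties kept).  Convenient for fixtures
  and limit checks, but the resulting statistics are pure allele
  frequencies, and a dataset of frequencies is invariant to rescaling
  all sizes and times by a common factor — absolute parameters are then
  identified only through prior boundaries.
* **ddRAD emulation** (`design="ddrad"`, the default for reference
  tables): `n_loci` loci are genotyped at a fixed per-locus mutation
  rate `mu_locus`; each locus is polymorphic with probability
  `1 − exp(−mu·L)` for genealogy length `L`, contributes at most one
  SNP, and low-MAF SNPs are dropped.  The SNP yield is therefore
  random and increases with the absolute population-size/time scale —
  exactly the information a real SNP panel carries through its locus
  count.  Defaults `mu_locus = 2.5e-6` (a ~100–150 bp locus at typical
  plant per-base rates) and `n_loci = 2016` were calibrated once so the
  expected yield at the fitted ghost-gene-flow parameters is ~801 SNPs,
  the size of the study-design dataset this generator emulates.

Missingness is optional uniform random masking (`missing_rate`);
structured missingness of real ddRAD data is out of scope, so tests
passing under this generator say nothing about batch or locus-dropout
artefacts.

## Summary statistics

The 22-statistic vector (per group × 2: polymorphic-site count, mean
H_exp with the 2n/(2n−1) correction, mean H_obs, mean per-site
F_IS = 1 − H_obs/H_exp over polymorphic sites, Tajima's D, singleton
fraction, private-site count, mean private-allele frequency; joint:
multilocus Weir–Cockerham F_ST, SD of per-site F_ST, mean absolute
allele-frequency difference, shared-polymorphism count,
fixed-difference count, d_xy) is this package's own choice of
sufficient statistics, covering the divergence, expansion and size
axes that random-forest ABC pipelines for two-population systems
conventionally summarize, and under
the ddRAD design the count-valued entries carry the absolute-scale
signal.  Statistics undefined on an input (no polymorphism, no private
allele) are imputed with 0 and logged.  F_IS uses the heterozygosity
deficit rather than the W–C within-population correlation because
that is what SNP-panel diversity software reports.

## ABC with random forests

Model choice follows the classification-forest scheme of Pudlo et al.
(2016): features are the standardized statistics plus
(number of scenarios − 1) linear-discriminant axes; votes are the
fraction of trees choosing each scenario at the observed point; the
prior error rate is the out-of-bag misclassification rate; the winner's
posterior probability is one minus the local error predicted by a
regression forest trained on out-of-bag error indicators.  Rows are
canonically sorted before fitting so results are invariant to table row
order under a fixed seed.  The hierarchical protocol compares the four
gene-flow scenarios first and the five ghost scenarios (on the winning
backbone) second.

Parameter estimation follows Raynal et al. (2019): one regression
forest per parameter; the posterior is the training-response
distribution weighted by leaf co-membership with the observed point
(Meinshausen's quantile-forest weights); reported are the weighted
mean, median and 2.5/97.5% quantiles, plus the normalized mean absolute
error `mean(|oob − y|/|y|)` of out-of-bag predictions.  Forest defaults:
500 trees; leaf size and `mtry` from out-of-bag tuning (`tune_forest`,
ties to the smaller value).  At reference-table sizes of a few thousand
rows the tuned leaf size is ~5; the study-scale preset (50 nodes, 7
variables) is kept as a documented constant.

Supporting checks: PCA overlap (observed point inside the convex hull
of the simulations on the first two principal axes), and a
goodness-of-fit test whose statistic is the mean Euclidean distance (on
standardized statistics) to the k = 10 nearest simulations, with the
null built from held-out simulated rows excluding self-neighbours and
`p = (1 + #{null ≥ obs}) / (n_rep + 1)` — exchangeability makes this
calibrated by construction, which the test suite verifies empirically.

## Priors

The default priors are reconstructed from the credible intervals
previously reported for this system: for every parameter the printed 95% CI
coincides (to ~3 significant figures) with the 2.5%/97.5% quantiles of
a uniform — log-uniform for migration — distribution on round-number
bounds, and the printed medians sit at the interval midpoints, the
signature of prior-dominated posteriors.  Inverting that arithmetic
gives: `N_A`, `N_B` ~ U[1500, 3000]; `N_aA`, `N_ghost` ~ U[5000, 17000];
`N_aB` ~ U[6000, 17000]; `N_anc` ~ U[0.01, 5]; `T_m` ~ U[3000, 6000];
`T_G` ~ U[1000, 15000]; `T_div` ~ U[2e5, 4e5]; `T_divG` ~ U[3e5, 5e5];
all migration fractions log-uniform on [1e-5, 5e-3]; the hybrid
fraction `h_frac` (unreported) ~ U[0.1, 0.9] and `N_ghost` takes
`N_aA`'s prior (also unreported).  A deliberately broad alternative set
(`broad_priors()`: sizes to 30,000, times to 8e5) is provided for
sensitivity analyses; under it the deep times are essentially
unidentifiable from a frequency-dominated SNP panel, which is worth
knowing before trusting any single-panel estimate of a ghost divergence
time.  Time orderings (`T_m ≤ T_G < T_div < T_divG` where applicable)
are enforced by rejection sampling.

## Divergence and ghost scans

Per-SNP divergence between two groups is Fisher's exact test on the
2×2 allele-count table (two-sided by the point-probability rule, the
convention that sums all tables at most as probable as the observed
one), significant at p < 0.001 with no multiple-testing correction —
matching SNP-wise divergence scanning practice for small panels.  The
three pairwise comparisons are partitioned into seven Venn regions; the
focal lineage's "unique" set (diverged from both its sympatric and
allopatric contrasts) feeds the ghost scan.  Between-group
differentiation reported alongside is the W–C multilocus estimator (a
surrogate for AMOVA-corrected F_ST; the two agree closely for biallelic
SNPs).  Individual structure: Nei's (1972) standard distance on
per-individual frequency vectors (the uncorrected variant; the 1978
small-sample correction targets population samples, not single
individuals), classical neighbour joining, bootstrap over sites with
supports attached to canonical bipartitions; and average-linkage
clustering of the F_ST matrix rows on Euclidean distances.

The ghost scan profiles each candidate SNP in the focal lineage:
private-allele frequency P_F, observed heterozygosity H_o, site-wise
F_IS, and per-site F_ST to each contrast lineage.  Where the focal
group is fixed for a private allele (H_exp = 0, H_o = 0, allele in ≥ 2
copies) F_IS is reported as 1, the complete-deficit convention.  Sites
passing all thresholds (defaults: P_F ≥ 0.5, H_o ≤ 0.5, F_IS ≥ 0.1,
F_ST ≥ 0.15 — bracketing the profile of a strong sweep-like signal;
no field-standard numeric cutoffs exist, so these are explicit
package defaults, CLI-configurable) are chained into clusters when
consecutive passing sites lie within `window_bp` (default 1000 bp) and
clusters with ≥ `min_snps` (default 2) members are reported.
`plant_introgression` writes a synthetic introgressed block (carriers
homozygous for an allele absent elsewhere) as the positive control; the
validation battery requires ≥ 95% recovery of 4-SNP blocks at carrier
fraction 0.8 and < 0.5 false clusters per null replicate.

## Numerical and edge-case conventions

MAF ties at the threshold are kept (matching `--min-maf` semantics of
standard SNP callers); depth/quality masking uses strict `<` cuts;
filtering order is genotype masking → individual missing-rate →
site-level cuts → optional unit-specific all-missing removal, because
masking must precede missing-rate computation.  Whether "unit" means
population or group for that last cut is configurable
(`missing_unit`), since the source pipeline's wording is ambiguous.
Monomorphic sites contribute 0 to heterozygosity means and are excluded
from F_IS; sites monomorphic across both groups are excluded from F_ST;
a genotype matrix with zero SNPs yields the all-imputed statistic
vector rather than an error (small prior draws legitimately produce
SNP-free panels).  All randomness flows from explicit seeds; reference
tables derive per-row seeds from (master seed, scenario index, row
index) so chunked and single-pass builds agree byte for byte.

## Problem sizes

Default analysis sizes are chosen for a single-CPU session: reference
tables of 2,000 rows per scenario for the hierarchical comparison,
10,000 rows for the parameter-recovery experiment in
`scripts/acceptance.py` (the validation battery inside the test suite
re-runs it at 3,000 rows, which the dry runs show already recovers all
five focal parameters inside their credible intervals), 500-tree
forests, 1,000-trial GOF calibration, 100-trial ghost-scan recovery.
Published analyses of this system used 70,000–200,000 simulations;
row counts here are
configurable and the estimator quality (NMAE) is reported with every
run so the cost of the smaller tables is visible rather than assumed.

## Known limitations

* The 22-statistic set is a surrogate; if the original list differed,
  vote shares and error rates will differ in detail.
* The ddRAD emulation fixes the locus count and mutation rate; real
  panels vary locus length, depth and dropout, and the absolute-scale
  anchor inherits any error in `mu_locus` proportionally.
* Under the fitted parameters the ghost-migration fractions imply near
  panmixia among TaiA, TaiB and the ghost during the migration epoch,
  so the migration rates themselves (and `N_anc`, `T_G`) are weakly
  identified — their posteriors track the priors, as the large NMAE
  values make explicit.
* Haplotype/LD-based introgression detection is deliberately absent:
  single-SNP ddRAD loci carry no within-locus haplotype information.
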