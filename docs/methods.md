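# Methods

This note documents the models and procedures implemented in `mixploid`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data generator does and does not emulate.

## Data model

Genotypes are integer alternate-allele dosages in a sites × samples matrix
with per-sample ploidy ∈ {2, 4} and a `MISSING` sentinel; only biallelic
records are represented (multi-allelic VCF records are skipped and
counted; invariant records are kept with alt "." so they can enter
diversity denominators).  Phasing separators `/` and `|` are equivalent —
no statistic here uses phase.  Coordinates are 1-based closed for VCF/GFF
and 0-based half-open for BED and all in-memory window tables, with the
conversion centralized in `io.to_halfopen`/`io.to_onebased`.

## Ploidy inference

Three evidences are computed per sample and combined.

**Allele balance.**  At a heterozygous site, the fraction of reads carrying
the alternate allele concentrates near dosage/ploidy.  Sites are kept when
read depth ≥ 10 and the alt fraction lies strictly inside (0.1, 0.9) (a
hard-bounds stand-in for histogram denoising; both bounds are exposed).
Samples retaining < 20 sites are flagged "insufficient" and skipped.
The retained fractions y are modeled as one-dimensional Gaussian mixtures
with a single shared σ:

- fixed models: means fixed at {1/2} (2x), {1/3, 2/3} (3x),
  {1/4, 1/2, 3/4} (4x), **equal fixed weights**, σ free;
- free model: K = 3 free means, free weights, σ free; EM multi-started
  from every fixed model's means plus random starts.

The call is argmin over d_m = logL_free − logL_fixed(m), ties toward lower
ploidy.  Fixing the weights in the fixed models is deliberate: with free
weights the tetraploid model *nests* the diploid one (put all weight on the
1/2 component), so the likelihood contest could never prefer the diploid
model.  Equal weights are also the expected heterozygous-dosage-class
proportions when site frequencies are roughly uniform.  EM details: shared
σ floored at 0.01 (a standard degeneracy guard against zero-variance
components), convergence when the log-likelihood improves < 1e-8, 500
iterations max; the log-likelihood is non-decreasing by construction, and
because the free model is seeded from each fixed model, d_m ≥ −1e-6 always.
The triploid model participates in the contest for completeness but the
final evidence combination only ever emits 2, 4 or "unsure".

**Heterozygosity.**  The fraction of heterozygous calls among genotyped
sites when everything is called as-if-diploid.  Tetraploids keep dosage
classes 1–3 heterozygous under a diploid caller, so their proportion is
systematically higher.  The 2x/4x threshold `het_hi = 0.51` is the midpoint
of the analytic means of the two groups in the simulator's default world
(diploid outcrossers E[2p(1−p)] ≈ 0.37; tetraploids 1 − 2E[p⁴] ≈ 0.66 for
p ~ Uniform(0.05, 0.95)).  On real data this threshold is
population-dependent and should be inspected (selfing diploids sit far
below it and are unproblematic).

**S-locus copy number.**  Self-incompatibility alleles are so diverse that
the number of distinct S-alleles per individual is bounded by ploidy.
Given per-allele coverages and a control coverage over unlinked single-copy
regions, the per-copy unit is control/ploidy and copies are
round(coverage/unit), minimum 1 per detected allele.  When the rounded
copies do not sum to the ploidy hypothesis the call is flagged and
reconciled by largest-remainder proportional allocation of the ploidy
across alleles — coverage *proportions* cancel the control-coverage noise
and are far more stable than per-allele rounding (at per-copy coverage 25,
plain rounding of a 3:1 tetraploid fails ~25 % of the time; the reconciled
estimate fails < 1 %).  A 3:1 pattern is only trusted as tetraploid
evidence when the diploid hypothesis is simultaneously inconsistent, which
screens out noisy diploid 1:1 profiles.

**Combination.**  ≥3 distinct S-alleles or a validated 3:1 pattern is hard
evidence for 4x: the final call is 4 unless the mixture or heterozygosity
votes diploid, which is a conflict → "unsure".  Otherwise the available
mixture/heterozygosity votes must agree; ≤2 distinct S-alleles weakly
supports 2x but cannot veto two agreeing 4x votes, because low distinct
counts also occur in tetraploids (e.g. 2:2 configurations).  Unavailable
evidence (insufficient allele-balance data, triploid mixture call, missing
S profile) is skipped and agreement of the remainder is required.

## Diversity and differentiation

π and dxy use pixy-style per-site weighting: numerators and denominators
accumulate over genotyped copies only, so missing genotypes reduce
information without biasing the ratio, and fully missing samples change
nothing.  Allele copies are the sampling unit; an autotetraploid's four
copies contribute C(4,2) within-individual pairs to π.  This treats copies
as exchangeable, which is the only option for dosage genotypes and is
consistent with tetrasomic inheritance; it also means "dxy of a population
against itself" is *not* identical to π (within-individual pairs belong to
π only) — documented, not hidden.  Monomorphic genotyped sites enter
denominators whenever the input VCF carries invariant records; with a
SNP-only input the values are "variant-only" and comparable only to other
variant-only values.

Tajima's D is restricted to sites where every sample of the population is
genotyped, because its variance constants assume a fixed copy number n
(= Σ ploidies); windows without segregating complete-data sites return NA,
as does n < 4.  The constants follow the standard formulation
(a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂) and are cross-checked in the tests against
an independent exact-rational implementation.

Nei's standard distance is computed between individuals from per-individual
allele frequencies (dosage/ploidy) over pairwise-shared loci:
I = J_xy/√(J_x J_y), D = −ln I; identical individuals give 0 and
alternately fixed ones give +inf (flagged; UPGMA refuses non-finite
input).  UPGMA uses proportional (size-weighted) averaging with ties broken
by the lexicographically smallest member labels, making the output
invariant to input order; branch lengths are ultrametric (heights = half
the merge distance).  Branch lengths are printed with 12 significant
digits.

## SFS diagnostics

The SFS is tallied over complete-data sites (constant n); unfolded
polarization takes alt as derived (appropriate for simulator output or
ancestral-polarized VCFs — no outgroup inference is attempted), folding
maps class i to min(i, n−i).  The auto/allo statistic E is the observed
proportion of segregating sites in the frequency band [0.5−δ, 0.5+δ]
(δ = 0.05) divided by the neutral expectation Σ_band(1/i)/Σ(1/i) (folded
analog uses weights 1/i + 1/(n−i)).  Allotetraploids mapped to a single
reference carry fixed heterozygosity at diverged subgenome sites — every
individual has dosage 2 — producing E ≫ 1, while autotetraploids under a
neutral-like spectrum give E ≈ 1.  E is a diagnostic ratio, not a test
statistic; thresholds (< 1.3 auto-like, > 2 allo-like in the tests) were
derived from the simulator's stated worlds.

Block-bootstrap replicates resample consecutive 10-kb blocks (including
empty ones) with replacement until the cumulative segregating-site count
reaches the original total, then tally the SFS on the concatenation;
output is a dadi-style single-population text spectrum.

## Topology weighting and introgression windows

For g taxon groups (3 ≤ g ≤ 7) the topology universe is all (2g−5)!!
unrooted leaf-labeled binary trees, enumerated in a deterministic canonical
order (lexicographic on sorted bipartition sets) that is emitted in the
weights header, so "topology k" is reproducible.  The weight of topology t
in a window is the fraction of one-tip-per-group combinations whose induced
unrooted subtree (computed from the tree's bipartitions restricted to the
combination) matches t.  Exact mode enumerates all combinations (guarded at
10⁷; beyond that, sampled mode draws combinations uniformly).  A
combination whose induced subtree is unresolved (polytomy) splits its tally
equally among compatible topologies.  Weighting is invariant to tip order
and re-rooting, since only bipartitions are used.

Introgression windows are windows whose combined weight over a user-chosen
topology set is strictly > 0.5 (the threshold is exposed); adjacent or
overlapping flagged windows merge, single-window gaps are not bridged, and
no smoothing is applied before thresholding.  Genes intersect flagged
intervals by ≥ 1 bp in half-open arithmetic.  Which topologies constitute
"gene flow" is a required user input — it depends on the group roles and
cannot be derived from the data.  ML window-tree estimation is out of
scope: trees arrive as newick from the simulator or any external tool.

## Divergence scan

Per-gene π (within the focal tetraploid population) and dxy (focal vs
contrast diploids) delegate to the diversity module with gene intervals as
windows.  The scan fits ordinary least squares dxy = β₀ + β₁π over genes
with both statistics defined (≥ 10 required; zero π variance degrades to
intercept-only with a warning) and flags genes whose residual exceeds the
empirical `quantile` (default 0.99) of residuals — a one-sided upper flag,
since only *excess* differentiation is a selection candidate.  One
diploid–tetraploid contrast is scanned at a time; two contrasts are two
runs whose gene lists `overlap_report` intersects, adding a one-sided
hypergeometric enrichment p-value as a labeled optional extra.

## Synthetic data: what it emulates, and what a green test establishes

Frequencies follow Balding–Nichols drift: ancestral p per site, child
frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F) down each branch of a lineage
tree (F ∈ (0,1) per branch).  This reproduces the *shapes* the pipeline
must detect — lineage clustering, auto vs allo SFS contrasts, introgression
signals — with analytically verifiable moments, but it is not a coalescent:
no linkage, no recombination map, no shared genealogies between sites.
Two ancestral spectra are available: `uniform` (p ~ Uniform(0.05, 0.95),
the default structured-panel stand-in) and `neutral` (density ∝ 1/x,
truncated at x_min = 0.005), which yields the standard-neutral 1/i sample
spectrum.  The neutral spectrum is the stated world for neutrality-
calibrated checks (Tajima's D centering, the auto E baseline) because the
uniform spectrum carries a built-in intermediate-frequency excess
(E[D] ≈ +0.65 analytically) that has nothing to do with the estimators.

Autotetraploid dosages are Binomial(4, p); allotetraploids draw
Binomial(2, p_A) + Binomial(2, p_B) with a fraction d (default 0.3) of
sites alternately near-fixed between subgenomes (ε = 0.01 leakage rather
than exact fixation, so the peak diagnostic is tested under realistic
noise).  Read counts are depth ~ Poisson(λ), alt ~ Binomial(depth, q) with
q = (dosage/ploidy)(1−e) + (1 − dosage/ploidy)e; defaults λ = 30, e = 0.01
match a typical resequencing panel.  Missing genotypes are injected
uniformly at rate 0.05.  Introgression tracts redraw recipient genotypes
from the donor frequency with probability m per genotype inside the tract.

Window genealogies come in two flavors: a class-mixture mode
(species/introgression/random classes; the emitted tree is reciprocally
monophyletic for the class topology with random within-group resolution and
unit branch lengths) used for mixture-recovery tests, and a tract mode in
which each recipient tip is a donor-derived migrant with probability 0.8
inside planted tracts and 0.1 outside — the window weight then approximates
the introgressed-haplotype frequency, which is what makes a strict 50 %
rule recover tract boundaries without false positives.  Per-window 0/1
class trees cannot do this: any nonzero background class rate would flag
isolated windows with weight 1.

S-locus profiles draw ploidy-many allele copies from a pool of 20
hyper-diverse alleles; coverage per distinct allele ~ Poisson(copies·λ)
and control ~ Poisson(ploidy·λ) with λ = 25 per copy.

Everything is deterministic under a fixed seed, including emitted file
bytes.  A green test therefore establishes correctness of the *estimators
and decision rules* under an idealized independent-sites world with known
truth — it does not establish robustness to linkage, mapping bias,
reference bias against diverged subgenomes, copy-number error in the
S-locus pipeline upstream, or unequal sequencing depth across populations.

## Known limitations

- No FST, LD, or demographic model fitting (the SFS files feed external
  tools); no outgroup-based polarization.
- Tajima's D ignores pixy-style weighting by design (fixed-n constants);
  its complete-data policy means an all-missing sample removes all usable
  sites for that population.
- The allele-balance contest needs tens of heterozygous sites of depth
  ≥ 10; low-coverage herbarium-grade samples will frequently return
  "insufficient" and rely on the other two evidences.
- Exact topology weighting is exponential in the number of groups' tip
  counts; use sampled mode beyond ~10⁷ combinations.
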