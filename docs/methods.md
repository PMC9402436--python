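# Methods

`cnaphase` implements a complete desk-scale analysis of phased copy-number
evolution in p53-deficient cancer: absolute single-cell copy-number calling
from sparse whole-genome-sequencing bin counts, breakpoint-coincidence
clonal phylogenetics, population-level CNA statistics, and a synthetic
generator for the four-phase clonal model (LOH → deletion accumulation →
whole-genome doubling → gains/amplifications) that makes every stage
testable without sequencing data.

## The synthetic clonal-evolution generator

The generator emulates two marker classes of cells. DP cells retain wild-
type p53 and stay flat diploid; with small probability (default 0.1) a DP
background lineage carries one whole-chromosome gain. SP cells descend
from `n_loh_lineages` independent founder lineages, each created by a
contiguous one-copy deletion on a designated "chr11 analog" chromosome.
Founder deletions always span the p53-locus bin (the middle bin of that
chromosome) and have founder-specific boundaries drawn uniformly, so
independent lineages are distinguishable by their breakpoints.

Evolution proceeds in strictly ordered phases:

1. **LOH** — the founder deletion;
2. **Deletion accumulation** — while diploid, each lineage generation adds
   Poisson(`deletions_per_phase`, default 3) one-copy deletions with
   log-uniform spans between 5 bins and a whole chromosome;
3. **Genome doubling** — per founder, with probability `wgd_probability`
   (default 0.4), the terminal diploid lineage is doubled (profile × 2);
4. **Post-doubling gains and losses** — each post-WGD generation adds
   Poisson(4) broad single-copy gains (log-uniform spans with a 20-bin
   minimum, reflecting the arm-scale gains typical of doubled genomes),
   Poisson(2) single-copy losses shed from doubled material (observed
   polyploid DNA content sits below 4n, so doubled genomes must lose
   copies), and Poisson(1) focal amplifications (1–5 bins, +4 to +8
   copies).

Gains and amplifications are gated on doubling by construction; deletions
are the only event class available to diploid SP lineages. Event edges are
resampled if they fall within two bins of an existing breakpoint of the
lineage, which guarantees that every descendant's breakpoint set is a
superset of its ancestor's and keeps breakpoints resolvable after the ±1
bin tolerance merging downstream. Cells sample the terminal diploid
lineage of each founder (post-sweep populations) and, for the polyploid
fraction (default 0.15, within the observed 10–20% range), the post-WGD
generations — splitting polyploid cells across generations is what makes
late gains subclonal.

Read counts are drawn per cell from a gamma–Poisson (negative binomial)
model: expectations proportional to true copy number × a quadratic GC-bias
factor, normalized to a Poisson total around `reads_per_cell_mean`
(default 10⁶). The default dispersion 0.085 gives a per-bin coefficient of
variation ≈ 0.3 at 10⁶ reads over 5,000 bins. Each cell's random stream is
derived by SHA-256 hashing of its id with the root seed, so adding cells
never perturbs existing ones.

What the generator does *not* emulate: amplification-biased WGA artifacts
beyond iid overdispersion, mappability structure (bins are equal-length,
not mappability-scaled), chromothripsis, SNVs/haplotypes, and doublets.
Passing tests therefore demonstrate correctness of the algorithms under a
realistic noise magnitude, not robustness to every artifact of real
sparse-WGS libraries.

## Copy-number calling

**Scaffold.** Equal-length bins per chromosome, largest-remainder
apportionment of the requested bin count across chromosome lengths (mouse
preset: 5,000 bins ≈ 600 kb; human preset: 20,000 bins). This replaces
mappability-scaled bin boundaries; all downstream computation is
bin-indexed, so the substitution does not affect the methods being tested.

**QC.** Cells with fewer than 250,000 total reads are excluded (boundary
inclusive: exactly 250,000 passes).

**GC correction.** Counts are divided by a LOWESS fit (fraction 0.3) of
count against GC fraction, floored at 10⁻⁶ × the mean count, then rescaled
to mean exactly 1. The correction is scale invariant.

**Segmentation.** Circular binary segmentation per chromosome: the maximal
circular-arc mean-shift statistic is compared with its distribution under
within-segment permutations (α = 0.01, up to 1,000 permutations with
sequential early stopping), recursing on accepted splits. Two additions
address known weaknesses of the greedy recursion at low signal-to-noise:
accepted boundaries are refined to the local two-segment least-squares
optimum (±3 bins), and long segments are re-tested in a second pass at a
relaxed level (α = 0.05) where the multiple-comparison burden is smaller.
Segments shorter than 3 bins merge into the neighbour of nearest mean.
Everything is deterministic for a fixed seed.

**Quantal ploidy fit.** The multiplier q mapping mean-1 ratios to absolute
copies is chosen on a grid (1.5–6.0, step 0.05) by a least-squares
criterion on segment means. Three design choices matter, all forced by the
noise model:

- *Core means.* Boundary-localization errors contaminate segment edges, so
  the fit uses the mean over the central third of each segment.
- *SE-normalized, capped residuals.* Each segment's distance from the
  nearest integer state is divided by the standard error of its mean on
  the copy scale; the squared residual is capped at 25 so a single
  mis-segmented segment cannot veto a multiplier. Segments too noisy to
  resolve adjacent integer states anywhere on the grid are excluded from
  the search (they still receive states). On an absolute scale the
  residual noise grows ∝ q², collapsing every doubled genome onto its q/2
  harmonic; on a purely relative scale large q wins by round-to-nearest
  capture of noisy segments. The SE scale is self-calibrated per cell at
  the best-fitting q (median |z| set to its half-normal expectation),
  absorbing correlated normalization error that survives averaging.
- *Smallest adequate q.* A profile explained by states c is explained
  exactly as well by 2c, so data alone cannot separate q from 2q. The fit
  returns the smallest grid q whose error is within a small slack of the
  global minimum; a genuinely doubled genome rejects q/2 through the
  half-integer residuals of its odd-state segments.

Ploidy is the mean integer state; cells at ploidy ≥ 3.0 are labelled
polyploid. Known limitation: a doubled genome with *no* detectable
odd-state segment is mathematically indistinguishable from its diploid
half and is deliberately called diploid (parsimony); at the default noise
this affects a few percent of simulated doubled cells.

**Detection limits.** At per-bin CV 0.3, a ΔCN = 1 step is ~1.7σ per bin
in a diploid cell and ~0.83σ in a tetraploid one, against a max-arc
permutation threshold around 4.3σ. Five-bin events in diploid cells
(aggregate ~4σ) and most short ΔCN = 1 events in doubled cells are
therefore at or below the detection limit; recovery of such breakpoints is
intrinsically partial, which is why the clone machinery works from
breakpoint *coincidence* with tolerance rather than exact profiles.

## Clonal inference

Breakpoints are state changes (|Δ| ≥ 1) at within-chromosome boundaries;
boundaries within ±1 bin across cells union-merge into canonical
boundaries (leftmost representative), which form the Fisher universe of
size N. Pair dissimilarity is the one-sided Fisher exact p-value
(hypergeometric upper tail) for the observed count of shared boundaries —
one-sided because coincidence is the alternative of interest. Cells
without breakpoints have dissimilarity 1 to everything.

Cells are clustered by average linkage with node heights on a log₁₀ scale
of the p-values (a geometric mean; arithmetic averaging of p-values
spanning twenty decades is dominated by the single worst pair and splits
genuine clones). Input order never matters: cells are sorted by id before
linkage.

The null distribution re-deals the pooled multiset of breakpoints among
cells, preserving every cell's breakpoint count (duplicate tokens within a
cell are repaired by swapping between cells), and recomputes all pairwise
dissimilarities. A node at height h is accepted as clonal when its
estimated FDR — the null per-pair rate of dissimilarities ≤ h scaled to
the node's pair count, divided by the node's observed coherent pairs — is
at most t = 0.01. Nodes with fewer than 3 cells are never clone-eligible:
the best pair in any cohort sits near the bottom of the null by selection
alone, and without the size floor random data yields spurious two-cell
"clones". Clones are the maximal accepted nodes.

Each polyploid cell is traced to the diploid cell sharing the most
breakpoints; the link is supported when its Fisher p ≤ t. This operational
definition of a whole-genome-doubling precursor works because doubling
preserves every pre-existing breakpoint.

## Landscape statistics

Events are maximal constant-state runs differing from the reference state
(2 for diploid cells, 4 for polyploid cells); states below the reference
are deletions, above are gains, and a gain is promoted to amplification
when the state reaches twice the reference over at most 10 bins (the
focal-event reading; the boundary constants are configurable). CORE-style
recurrence greedily extracts the interval maximizing the sum over cells of
the best Jaccard overlap with that cell's events, peels off the explained
events, and repeats; significance permutes event positions uniformly
within chromosomes, preserving lengths and per-cell counts, and compares
against the null top-core score. The greedy Jaccard-sum scoring is an
approximation to the published recurrent-core methodology, which is not
fully specified in the source describing it.

Frequency tracks centre each sample's segmented values to mean 1 and
designate a bin gained at ≥ 1.1 and deleted at ≤ 0.9 (thresholds
inclusive). Single-cell homogeneity is the per-bin frequency of the modal
integer state. Bulk homogeneity consumes externally produced segment
tables with cell-fraction and purity columns: cf/purity is clipped at 1.25
(raw values kept in a diagnostic column), and gain and deletion
distributions are contrasted with the two-sample Kolmogorov–Smirnov test.
Event-count comparisons report the two-sided t-test and Mann–Whitney U
(exact enumeration for tie-free samples of ≤ 20, normal approximation with
tie correction otherwise); both are computed by scipy. Small calculators
cover DAPI-based ploidy (2 × ratio of gate medians) and RPKM-based marker
genotyping (LOH-positive when the lost marker falls below 0.2 × the
retained marker).

## Problem sizes and numerical choices

The validation suite runs the full chain at the native mouse scale
(5,000 bins) throughout: once over the default 120-cell cohort (reused by
several checks), once over 200 half-diploid/half-doubled cells for ploidy
recovery, and once over a 100-cell single-founder sweep for the
phase-signature analysis. Reduced scaffolds are avoided deliberately —
below roughly 2,500 bins chromosome-scale segments become too short for
the quantal fit's SE filter and doubled genomes start collapsing onto
their half-ploidy harmonic. Permutation
counts: 1,000 (CBS), 500 (clone null and CORE). All stochastic steps take
explicit seeds and are bit-reproducible; per-cell streams are hash-derived
so cohort composition does not couple cells.

Degenerate inputs are handled explicitly: all-zero cells are flagged and
skipped without aborting a batch, empty inputs return empty results,
constant profiles segment to one segment per chromosome, and ties in the
quantal fit resolve toward smaller multipliers (the conservative, lower-
ploidy reading).

## Known limitations

- Doubled genomes without resolvable odd-state segments are called at
  half their true ploidy (unavoidable under total-copy-number data).
- Breakpoint recall for short and low-contrast events is power-limited at
  the default noise (see *Detection limits*); downstream inference is
  designed to tolerate this, but per-event recall figures should be read
  with the SNR in mind.
- The CORE approximation and the FDR estimator are re-derivations of
  partially specified methods; both are documented above and validated
  against planted ground truth rather than against the original
  implementations.
- Bulk cf/purity homogeneity never re-estimates purity; garbage in,
  garbage out.
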