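# Methods

This note documents the models, estimators and design choices behind
paleomito, and what the simulation-based tests do and do not demonstrate
about real ancient-DNA data.

## Scope and coordinates

The pipeline begins at aligned fragments (SAM records against a single
circular mtDNA reference) and ends at reconstructed genomes, genome
groups and molecular dates. Base calling, read merging and mapping are
upstream of it; haplogroup nomenclature and Bayesian phylogenetics are
outside it. Coordinates are 0-based half-open internally and 1-based in
all on-disk reports, matching mtDNA community (rCRS) convention.

Fragments that span the circular origin are written as a single SAM
record whose alignment extends past the `@SQ` length; the reader maps
reference positions modulo the reference length. The convention is
declared in a `@CO` header line. This keeps records one-to-one with
molecules and standard SAM tooling usable for everything that does not
cross the origin.

## Read simulator

The simulator is the source of ground truth for every test. It emulates:

- a circular reference of configurable length and GC content (default
  16,569 bp, GC 0.44);
- lognormal fragment lengths, median 55 bp with σ=0.35 on the log scale,
  clamped to [20, 150] bp — a typical post-mortem fragmentation profile;
- single-stranded-library deamination: C→T in read orientation at both
  ends, with per-position probability `δ[i] = δ[0]·λ^i` (λ = 0.5, window
  15). Defaults δ5[0] = 0.40 and δ3[0] = 0.35 sit mid-range for
  well-preserved Pleistocene libraries, whose reported terminal rates
  span roughly 33–50% (5′) and 19–48% (3′);
- uniform sequencing error (default 10⁻³ per base, uniform over the
  three alternative bases);
- present-day contamination: fragments drawn from a contaminant genome
  (the reference plus 20 fixed substitutions) with sequencing error but
  no deamination, at a configurable fraction;
- PCR duplicates sharing coordinates and strand with their originals,
  with independent sequencing error re-applied to the post-damage
  molecule;
- mapping qualities sampled from a discrete distribution so the MQ < 25
  filter has real work to do.

Every emitted fragment carries exactly one truth record (origin, injected
damage positions, duplicate set, source genome).

What the simulator does *not* model: indels, base-quality variation,
reference bias in mapping, fragment-length-dependent damage, double-
stranded-library (3′ G→A) chemistry, and non-uniform fragmentation along
the molecule. Tests passing on this substrate therefore demonstrate the
correctness and calibration of the inference chain under its stated
assumptions, not robustness to mapping artefacts or library-chemistry
variation in real data.

## Filters and duplicate removal

Fragments shorter than 35 bp or with MQ below 25 are removed (strict
thresholds: 35 bp / MQ 25 are kept). Filtering precedes duplicate
removal; both steps log counts so the order is auditable. Duplicates are
keyed by (start, end, strand) — the standard key for merged single-end
aDNA fragments — and collapse to a representative carrying the
per-position majority base among copies, ties becoming N. Majority
consensus was chosen over keep-best-quality because the pipeline carries
no base qualities; it is deterministic and uses all copies. Note that two
independent molecules sharing coordinates by chance are indistinguishable
from duplicates under this key; at mtDNA scale this affects a handful of
fragments per ten thousand.

## Damage profile

For each read-orientation position within 15 bp of either end, the
profile reports `substitutions / opportunities`, where an opportunity is
an observation whose template base (reference base, complemented for
minus-strand fragments) is C, and a substitution additionally reads T.
Positions with zero opportunities report NaN, not zero. Intervals are
Wilson 95% — well-behaved at small counts.

## Contamination estimator

A fragment-level two-component mixture exploiting the damage signal.
Assumptions: (1) contaminant fragments carry no deamination; (2) for
endogenous fragments, deamination events at the 5′ and 3′ termini are
independent; (3) sequencing error contributes C→T at ε′ = error_rate/3.

Let r be the endogenous per-opportunity C→T rate in the 5′ terminal
window (default 3 positions). Over all fragments the observed rate is
`p_t ≈ (1−c)r + ε′`; over the subset with ≥1 C→T in the 3′ terminal
window — almost purely endogenous — it is `p_c ≈ r + ε′`. Hence
`ĉ = 1 − (p_t − ε′)/(p_c − ε′)`, clipped to [0, 1], with a nonparametric
bootstrap over fragments for the 95% interval. If `p_c ≤ ε′` the signal
cannot support an estimate and the estimator raises an explicit
undefined-estimate error rather than returning a number.

This estimator is deliberately transparent rather than a damage-pattern
HMM: its assumptions are testable by parameter recovery, which the
acceptance suite does at contaminant fractions 0–0.5 (recovery within
±0.05 at 50,000 fragments, monotone in the true fraction). Its precision
degrades with the size of the conditioning set; the report includes
`n_conditioning` so low-power estimates are flaggable.

## Lineage assignment

Diagnostic positions carry one base state per lineage (H. sapiens,
Neanderthal, Denisovan); a validated table rejects duplicate positions
and rows where all states agree. Each fragment observation at a
diagnostic site votes for the lineage(s) matching its read-orientation
base. Damage-aware exclusion discards an observed read-orientation T
within 7 positions of either read end whenever any lineage state at the
site is C, since deamination could have manufactured that T from the C
state; the 7-position window deliberately reuses the consensus masking
convention so one masking concept serves the whole pipeline. The verdict
requires winning every pairwise contrast at ≥ 0.8 with ≥ 10 informative
observations (both configurable); these thresholds are conservative
stand-ins — the underlying decision rule in published workflows is not
standardised.

## Consensus calling

Per site, observations are dropped if they are read-orientation C→T
(reference C read T on plus strand; reference G read A on minus strand)
within 7 positions of either alignment end. Masking is unconditional: a
genuine terminal T allele at a C reference site is masked too — the rule
is applied literally rather than adjudicated against a provisional
consensus. Masking context is the reference base, not an evolving
consensus; this keeps calling single-pass and deterministic, at the cost
of slightly over-masking where the sample truly differs from the
reference by C→T (a documented divergence risk). After masking and
removal of N observations, the top base is called iff coverage ≥ 5 and
support ≥ 0.80 — the support threshold is inclusive (8/10 passes), and a
tie for the top base yields N.

Mode selection: libraries with a contamination point estimate below 5%
use all fragments; at or above 5%, only fragments with ≥1 terminal C→T
(the estimate exactly at the threshold resolves to the conservative
deaminated-only branch). Deaminated-only calling costs coverage
(roughly the deaminated fraction times total depth) but removes the
undamaged contaminant molecules entirely, which the acceptance suite
shows recovering contaminant-degraded sites at 20% contamination.

## Pairwise comparison and matriline groups

Differences are counted over positions called (non-N) in both genomes;
`n_compared` is reported alongside `n_diff` because a zero over few
positions is uninformative. Zero-difference groups are maximal cliques of
the graph whose edges are pairs with `n_diff = 0` and `n_compared ≥
1,000` (configurable): zero-difference is not transitive when coverage
differs, and cliques are exactly the sets with *no pairwise differences
among them*. Pairs failing only the overlap guard are reported
separately. Group order is deterministic (size, then lexicographic).

## Tip dating

The chain: Jukes–Cantor distances (sites with N in either sequence
excluded; mismatch fraction ≥ 0.75 is an explicit error) → neighbour
joining (vectorised Saitou–Nei with deterministic taxon-order
tie-breaking; negative branch lengths clamped to zero; equivalence with
an independent NJ implementation is asserted in the test suite) →
rooting at the midpoint of the branch separating a user-specified
outgroup (non-monophyletic outgroups are an error) → ordinary least
squares of root-to-tip distance y on tip age t over the calibration
tips: `y = b − r·t`, so the query's age is `t̂ = (b − y_q)/r`. A fitted
rate ≤ 0 refuses inversion with an explicit error. Outgroup tips are
excluded from the regression even when dated: their root-to-tip path
includes the outgroup stem, which is not clock-comparable to the
ingroup.

Uncertainty is a percentile bootstrap over alignment columns, re-running
the entire chain per replicate; replicates that fail (saturated
distances, unresolvable rooting, non-positive rate) are dropped and
counted. The interval is widened, if necessary, to include the point
estimate.

This is a stand-in for Bayesian tip calibration: no coalescent tree
prior, no clock prior, no posterior probabilities. At realistic mtDNA
rates (~2.5×10⁻⁸ substitutions/site/year) a 16.6 kb genome accumulates
only ~0.4 substitutions per kyr, so intervals spanning tens of millennia
are an honest reflection of the information content, and residuals are
correlated through shared ancestry — the least-squares fit ignores that
covariance, which mainly widens realised scatter relative to the nominal
regression picture. Simulation shows the bootstrap interval covers the
truth in ≥ 90% of runs and the rate is recovered within a few percent on
average over seeds.

## Problem sizes used in tests and the acceptance script

Filter/duplicate recovery uses 10,000 fragments (plus 15% duplicates);
damage recovery 20,000 fragments with error off (so the terminal count
is an exact binomial draw); contamination recovery 50,000 fragments per
contaminant fraction, with monotonicity checked at 20,000 over three
seeds; lineage assignment 8,000 fragments per lineage at 60 diagnostic
sites; consensus accuracy ~30× clean coverage and ~60× at 20%
contamination for the mode comparison; tip dating 20 calibration tips
spanning 0–55 kyr BP plus two ~120 kyr outgroups, 16,569 bp alignments,
100 bootstrap replicates, 50 seeds in the test suite (20 in the
acceptance script). These sizes give the statistical checks the
resolution their tolerances require while keeping a full run to a few
minutes on one core.

## Known limitations

- The contamination estimator assumes a fully undamaged contaminant;
  ancient-on-ancient contamination is not identifiable from damage alone.
- Masking against the reference rather than a provisional consensus
  over-masks genuine terminal C→T differences from the reference.
- The duplicate key cannot distinguish true duplicates from coincidental
  coordinate matches.
- Tip dating ignores phylogenetic covariance among calibration tips and
  reports no posterior; it is a calibrated approximation, not a
  replacement for full Bayesian inference.
- No indel handling anywhere in the chain; alignments are treated as
  substitution-only.
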