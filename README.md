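# paleomito

Analysis of ancient mitochondrial DNA from aligned sequencing fragments:
damage-based authentication, contamination estimation, hominin lineage
assignment, damage-masked consensus calling, matriline grouping, and
strict-clock tip dating — together with a ground-truth read simulator so
that every stage is verifiable without access to real ancient data.

## Who this is for

Ancient-DNA practitioners reconstructing mitochondrial genomes from
skeletal or sediment libraries, and methods developers who need a fully
simulated, truth-tracked test bed for aDNA inference chains. The pipeline
starts from aligned fragments (SAM against a circular mtDNA reference, e.g.
the 16,569 bp rCRS) and runs to reconstructed genomes, kinship-relevant
genome groups, and molecular ages.

## The methods at its core

**Authentication.** Post-mortem cytosine deamination is read as C→T in
read orientation, concentrated at fragment termini. The damage profile
reports position-wise frequencies `f_i = s_i / n_i` (substitutions over
template-C opportunities at distance *i* from each read end) with Wilson
95% intervals; single-stranded libraries show the signal at both ends.

**Contamination.** With contaminant molecules undamaged and damage
independent between the two ends of an endogenous fragment, the terminal
C→T rate over all fragments is `p_t ≈ (1−c)·r + ε′` while the same rate
over fragments carrying opposite-end damage is `p_c ≈ r + ε′`
(`ε′ = error_rate/3`). The contaminant fraction is estimated as
`ĉ = 1 − (p_t − ε′)/(p_c − ε′)`, with a fragment bootstrap for the
interval.

**Fragment filters and duplicates.** Fragments shorter than 35 bp or with
mapping quality below 25 are removed; PCR duplicates sharing
(start, end, strand) collapse to a per-position majority representative.

**Lineage assignment.** Observations at diagnostic positions — sites whose
states differ among H. sapiens, Neanderthal and Denisovan mtDNA — are
tallied per lineage; terminal T observations that deamination could have
manufactured from a C state are excluded. The verdict goes to the lineage
winning every pairwise contrast at ≥ 80% with ≥ 10 informative
observations.

**Consensus.** A site is called when ≥ 5 fragments cover it after masking
terminal C→T observations (first/last 7 alignment positions) and the top
base reaches ≥ 80% support; otherwise N. Libraries whose contamination
estimate is ≥ 5% use deaminated fragments only.

**Matrilines.** Pairwise differences are counted over positions called in
both genomes; groups with zero pairwise differences (maximal cliques, with
a minimum-overlap guard) indicate the same individual or maternal
relatives.

**Tip dating.** Jukes–Cantor distances → neighbour joining → rooting on an
archaic outgroup → least-squares regression of root-to-tip distance on tip
age over radiocarbon-dated calibration genomes (`y = b − r·t`), inverted at
the query's distance; uncertainty from a bootstrap over alignment columns.
A transparent approximation to Bayesian tip calibration — no tree prior,
no posterior.

## Worked example

`examples/` contains one short script per capability. For instance:

```bash
$ python examples/02_damage_authentication.py
position   5' C->T    3' C->T
       1     0.340     0.292
       2     0.166     0.142
       3     0.083     0.071
       4     0.045     0.036
       5     0.022     0.019

contamination: 0.171 (95% CI 0.109-0.227; truth 0.15)
terminal damage rate 0.196 over all fragments vs 0.236 among 3186 fragments with opposite-end damage
```

The decaying terminal C→T frequencies are the ancient-DNA signature (the
library was simulated with 15% present-day contamination, which dilutes
the terminal rate from 40% to ~34%); the contamination estimate recovers
the simulated fraction within its interval.

```bash
$ python examples/06_tip_dating.py
estimated age: 39,703 years BP (95% bootstrap CI 16,274-62,703; truth 45,000)
fitted clock rate: 2.265e-08 subs/site/year (simulated 2.5e-08), R^2 = 0.772
```

At a realistic mtDNA substitution rate a 16.6 kb genome carries only tens
of substitutions per 100 kyr, so genuinely wide intervals are expected;
the point estimate and fitted rate bracket the simulated truth.

A full end-to-end run (`examples/07_full_pipeline.py`, or `paleomito run
--config config.yaml` from the shell) writes per-stage artefacts (damage
profile TSV, contamination JSON, lineage assignment JSON, consensus
FASTA/TSV) plus a versioned JSON report.

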