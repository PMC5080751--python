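# Methods

## The genetic model

The package targets species where sex is set by one to three segregating
sex-determination (SD) alleles rather than a fixed sex chromosome.  Two
allele classes are modeled: a dominant male-determining **Y** and a
dominant female-determining **W**, with W epistatic over Y.  Genotypic sex
is a pure function of the carried SD alleles:

    any W  -> female
    else any Y -> male
    else   -> female        (the XX-female default)

This hierarchy reproduces the classic two-locus expectation: a cross
between an XY sire (Y het at locus A) and a ZW dam (W het at locus B)
yields offspring carrying {}, {Y}, {W}, {Y,W} in equal parts, hence a 1:3
male:female ratio.

A single-locus ZW family needs care under the XX-female default: a dam
carrying only a heterozygous W would produce all-female broods (non-W
offspring default to female), which no informative cross shows.  The
simulator therefore lets an SD locus carry a *background* allele filling
the other three parental slots.  With background `Y` a W-carrier dam is
W/Y and the sire Y/Y — the platyfish-style single-locus X/Y/W
configuration — giving 1:1 broods in which the dam's transmissions are
fully informative for W while the sire is structurally uninformative (NI)
at the locus, the pattern real ZW families show.  The default background
`-` keeps the plain heterozygous-carrier semantics used for XY loci and
for the two-locus epistasis expectation above.

**Penetrance** is the probability that phenotypic sex equals genotypic
sex; sex reversal is modeled as an i.i.d. phenotype flip with probability
1 − penetrance, independent of genotype.  This is the simplest mechanism
consistent with the candidate explanations for observed genotype–phenotype
mismatches (mis-phenotyping, marker–locus recombination, true reversal);
it makes no claim about which operates in real data.

## Meiosis

Gametes follow the Haldane model: crossover count per physical chromosome
is Poisson in its map length, crossover positions uniform, no
interference.  Map length is physical length × 1 cM/Mb by default (a
typical teleost genome-wide average; configurable via
`GenomeLayout.morgans_per_bp`).  A chromosome fusion is two reference
linkage groups concatenated into one physical chromosome that recombines
as a single unit, so cross-LG marker pairs near the junction co-segregate
— the signal the fusion detector looks for.  Closed-form checks: markers
*d* Morgans apart recombine at (1 − e^(−2d))/2.

## Founder genotypes

SNP founder allele frequencies are Beta(2, 2) draws (intermediate-biased
but still yielding uninformative markers); SSR founders draw uniformly
from 4–8 equifrequent labels (default).  The *confirmation panel* used by
the recovery studies instead uses 8–12 allele SSRs placed ~1 cM apart
bracketing each SD locus: real microsatellite confirmation panels are
pre-screened for high polymorphism inside a previously mapped interval,
and the anonymous-marker default would understate their informativeness.

## Statistics

- **Fisher's exact test** (two-sided) uses the minimum-likelihood
  convention — the p-value sums hypergeometric point probabilities ≤ that
  of the observed table within relative tolerance 1e-7 — via
  `scipy.stats.fisher_exact`, and is verified exhaustively against an
  independent enumeration for all tables with total ≤ 30.  P-values are
  memoized by table counts; null-scan simulations hit a few hundred
  distinct tables.
- **Transmission tables** require the tested parent heterozygous and the
  transmitted allele deducible per offspring (pseudo-testcross logic);
  markers with fewer than 5 deducible offspring are NI.  When both
  parents are heterozygous for the same two alleles, only homozygous
  offspring are deducible and the deduced sire and dam transmissions
  coincide, so the association cannot be attributed to a parent; the
  *classifier* skips these parent-confounded markers (the intercross
  "hk × hk" class of linkage mapping).  The transmission-table primitive
  itself keeps them (they remain valid for linkage, where phase handles
  the symmetry).
- **Classification** takes the minimum transmission-test p per parent over
  each region's markers, uncorrected, at α = 0.05 — small regions, few
  markers, and real designs replicate calls across families rather than
  correcting within them.  Ties break by more informative offspring, then
  marker id.  Both parents significant emits two calls (a multi-locus
  family); cross-family interpretation (e.g. an XYW locus) belongs to
  `shared_haplotype_check`, because per-family data cannot separate a
  true second allele from occasional sex reversal.
- **Penetrance** anchors to the majority allele→sex mapping at the best
  marker (the only self-consistent direction choice) and equals the
  matching fraction of informative offspring; the mismatch set is the
  sex-reversal candidate list.  Estimates at linked (not causal) markers
  absorb marker–locus recombination into apparent non-penetrance, and
  selecting the minimum-p marker biases the estimate slightly upward;
  at the study conditions (50 families × 20 offspring, markers ≤1 cM from
  the locus) the recovered mean sits within ~0.02 of the true value.
- **Sex ratios**: Pearson χ² with df 1 and *no* continuity correction —
  the uncorrected statistic is the one that matches pooled-count values
  reported for this kind of panel (with Yates' correction the ZW pool
  would give ≈14.6 rather than 15.2).  Welch's t uses the standard
  Welch–Satterthwaite df.  The χ² against 1:1 at n = 100 has exact size
  0.057 at nominal 0.05 (discreteness), which the calibration test checks
  in closed form and by simulation.
- **Two-point LOD**: rf̂ = min(R, N−R)/N (phase-unknown), LOD =
  log10[rf̂^R̃ (1−rf̂)^(N−R̃) / 0.5^N], with the rf̂ = 0 limit N·log10 2.
  Per-family (N, R) are summed across families and parents before the LOD
  (LOD additivity under a shared rf; individual families are
  underpowered).  Verified against numeric maximization of the binomial
  likelihood to 1e-6 for all N ≤ 50.
- **Fusion calls**: LG pairs with best cross-LG LOD > 4; transitive
  chains merge into one group (named by joining LG numbers).  The
  "continuous haplotype" flag marks zero recombinants at the best pair in
  ≥1 family with ≥5 informative meioses — two-point data cannot place the
  junction, so "nearest markers to the junction" is approximated by the
  best-linked pair.

## Anchoring

Window alignments are filtered (unique mapping, <5 suboptimal hits,
identity ≥ 0.90 — the boundary value is kept since only windows *below*
90% are removed).  The suboptimal-hit count is read from an integer PAF
tag (default `s2`); aligners encode this differently, so the tag is a
parameter.  Scaffolds are assigned by majority vote (> 60% of ≥3 windows;
both thresholds configurable — the filters are standard but no assignment
rule is, so the defaults are conservative and logged), ordered by median
target position (ties: minimum target position, then scaffold id), and
oriented by the sign of the Spearman correlation between window index and
target position (single-window scaffolds get "+" with an ambiguity flag).
Offsets are cumulative lengths plus a fixed 1-kb gap: pseudo-coordinates
for ordering, not physical distance — downstream use is rank-based.
An unplaced scaffold whose windows split mostly between two LGs is
flagged as a fusion-junction candidate.

## What the simulator does and does not emulate

It emulates: Mendelian transmission with Haldane recombination, multi-LG
genomes with fusions, SNP/SSR marker panels with realistic informativeness
mixes (including NI markers), incomplete penetrance, ddRAD-style
missingness from Poisson read depth (homozygote depth masking feeds the QC
rule), and window alignments with misassignment noise.  It does not
emulate: crossover interference, segregation distortion, genotyping error
other than missingness (no allelic dropout into *wrong* calls), linkage
disequilibrium among founders, locus-dependent sex reversal, or
sequence-level artifacts (restriction-site dropout, paralogy).  Passing
recovery tests therefore show the *inference logic* is correct under the
stated model, not that real data meet the model.

## Study sizes and evaluation choices

The recovery studies use: 200 families (mixed XY/ZW/none, 16–36 offspring,
penetrance 0.9) for classification; 50 families × 20 offspring at true
penetrance 0.88 for penetrance recovery; 50 replicates of a 3-LG genome
(one 50-cM fused pair, 2 families × 24 offspring, six SSRs per LG) for
fusion detection; 50 random two-LG layouts for anchoring recovery; the
null association scan uses 40 replicates × 50 markers.  Family-level
accuracy scores the dominant (smallest-p) significant call against the
configured truth; because the classifier deliberately emits one call per
significant parent, an XY↔ZW *confusion* is counted only as heterogamety
reversal — the opposite system asserted while the true one is missed
entirely.  At α = 0.05 with uncorrected region minima this event has a
small but nonzero probability per run (it is exactly the failure mode that
among-family replication eliminates in real panels), so the confusion
count is reported rather than assumed zero.

## Known limitations

- Transmission deduction is per-marker; no multi-marker haplotype phasing,
  so isolated genotyping errors at a best marker propagate into penetrance.
- `lg_pair_linkage` enumerates cross-LG marker pairs; for dense RAD-scale
  panels (thousands of markers per LG) it should be fed a thinned map.
- The anchorer reconciles one reference at a time; arbitration between
  discordant references is out of scope.
- Partial-LG translocations (one reference LG split across two physical
  chromosomes) are not modeled and would look like a weak or chained
  fusion signal.
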