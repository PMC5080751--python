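# polysd

Family-based mapping and classification of **polygenic sex determination**
in fish crosses, built around the analysis design used for the cichlid
*Astatotilapia burtoni*: small single-pair families (10–40 offspring)
genotyped at reduced-representation SNPs and microsatellites, with sex set
by one or more dominant sex-determination alleles — male-determining **Y**
and female-determining **W** — interacting epistatically (any W ⇒ female;
else any Y ⇒ male; else female).

It is a library for geneticists mapping sex loci in non-model species with
small outbred families, where genome-wide association is underpowered and
the workhorse tools are exact tests, parental-transmission logic and
two-point linkage.

## What it computes

- **Marker–sex association** (`polysd.assoc`): two-sided Fisher's exact
  test on allele × sex or transmitted-parental-allele × sex 2×2 tables;
  a dominant-model screen for minor alleles at intermediate frequency in
  one sex and absent in the other (the signature of a heterozygous dominant
  SD allele, expected at ~0.25 allelic frequency in the carrier sex); and
  sliding-window summaries (mean −log10 *p* over 10-marker windows).
- **System classification** (`polysd.sysclass`): per family and candidate
  region, the sire's transmissions are tested for Y-type association and
  the dam's for W-type; the minimum *p* per parent at α = 0.05 calls the
  family XY, ZW, both (multi-locus), unknown, or NI (no informative
  markers).  Penetrance = fraction of informative offspring matching the
  majority allele→sex mapping at the best marker; mismatches are flagged
  as sex-reversal candidates, and sex-linked haplotypes are checked for
  consistency across families sharing a parent.
- **Sex-ratio statistics** (`polysd.ratios`): sex ratio *m*/(*m*+*f*),
  Pearson χ² (df = 1, no continuity correction) of pooled counts against
  1:1, and Welch's unequal-variances *t* between system classes.
- **Two-point linkage and fusion detection** (`polysd.linkage`):
  pseudo-testcross recombination fractions rf = min(R, N−R)/N with
  LOD = log₁₀[rf^R (1−rf)^(N−R) / 0.5^N]; linkage-group pairs whose best
  cross-LG marker-pair LOD exceeds 4 are called chromosome fusions, with
  transitive chains merged (e.g. `LG8-24` + `LG16-21` → `LG8-24-16-21`).
- **Scaffold anchoring** (`polysd.anchor`): 5-kb window alignments (PAF)
  filtered to unique hits with <5 suboptimal alignments and ≥90% identity,
  majority-vote scaffold→LG assignment, ordering by median target position,
  orientation by rank correlation, and marker liftover onto
  pseudo-chromosomes.
- **Synthetic data** (`polysd.simulate`): a Mendelian pedigree simulator
  with Haldane meiosis (Poisson crossovers, no interference), chromosome
  fusions that recombine as one unit, SD loci with configurable penetrance
  (sex reversal as an i.i.d. phenotype flip), ddRAD-style Poisson depth
  noise, and window-alignment simulation — all with ground-truth labels
  for parameter-recovery testing.
- **I/O and QC** (`polysd.dataio`): genotype TSV/minimal VCF, pedigree and
  marker-map TSV, PAF; the two-stage genotype QC (homozygous calls below a
  depth floor masked, markers below an offspring call-rate dropped).

## Worked example

```python
from polysd import (Region, SDLocus, SexDeterminationModel, MarkerSpec,
                    classify_family, default_layout, simulate_family)

layout = default_layout(n_lgs=2, markers_per_lg=8)
model = SexDeterminationModel((SDLocus("LG1", 15_000_000, "Y", "sire"),), penetrance=1.0)
matrix, family, truth = simulate_family(layout, model, 24, MarkerSpec(ssr_fraction=1.0), seed=11)

calls = classify_family(matrix, family, [Region("LG1", "LG1"), Region("LG2", "LG2")])
for c in calls:
    if c.system in ("XY", "ZW"):
        print(c.region.name, c.system, c.best_marker, f"p={c.best_p:.2e}",
              f"penetrance={c.penetrance:.2f}")
```

prints

```
LG1 XY LG1_13333332 p=7.40e-07 penetrance=1.00
LG2 XY LG2_9999999 p=3.61e-02 penetrance=0.75
```

The sire's transmissions at the marker nearest the simulated Y locus
separate sons from daughters perfectly (Fisher *p* ≈ 7×10⁻⁷, 24 informative
meioses, penetrance 1), so the family is called XY at LG1.  The marginal
LG2 call (*p* = 0.036, penetrance 0.75) is the kind of isolated,
low-penetrance signal that the uncorrected per-region minimum *p* produces
by chance at α = 0.05 — real panels resolve these by replication across
families (`shared_haplotype_check`), and the strong call dominates.  The
`examples/` directory has one narrative script per capability (simulation,
association scan, classification, sex ratios, fusion detection, scaffold
anchoring); each prints its results with a comment on what they mean.

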