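# cutisol

Solubility-class analysis of insect cuticular proteins (CPs) from
serial-extraction bottom-up proteomics.

## The problem

How cuticular proteins interact with chitin and with each other in the
insect exoskeleton is unresolved. One way in is *serial extraction*:
pulverized cuticle is treated with solvents of increasing strength — PBS,
EDTA, 2 / 4 / 8 M urea, boiling SDS — and the residue that survives
everything is digested on-pellet with trypsin. Peptides identified by
LC-MS/MS in each fraction tell you which proteins solubilize easily,
which only appear in the final pellet (FP), and which peptide regions of
an insoluble protein are never recovered — a hint that residues there
(His, Lys, Tyr, Gln, or the protein's N-terminus) were consumed by
sclerotization cross-links.

`cutisol` takes a protein FASTA, a protein metadata table (CP family,
R&R-Consensus group, chitin-binding-domain intervals, sequence-cluster
membership) and a peptide-evidence table (peptide, proteins, fraction,
replicate, gel slice, spectral count) and computes:

* **Solubility classes** under a replicate rule: a (protein, fraction)
  counts only if at least one peptide was found in ≥ 2 of 3 biological
  replicates; accepted fractions then give `SOLUBLE_ONLY`, `BOTH`,
  `FP_ONLY` or `INSUFFICIENT`, with a flag for "occasional peptide"
  exceptions and a `++` strength mark for proteins with ≥ 3 peptides.
* **Residue-resolution coverage**: merged peptide intervals per protein,
  N-terminal peptide recovery, chitin-binding-domain (pf00379 / pf01607)
  overlap, and a census of HH/KK pairs and QQQQ runs inside vs. outside
  recovered peptides.
* **Sequence properties**: isoelectric point (Bjellqvist pK set, found by
  bisection of the Henderson–Hasselbalch net charge), H/Y/Q/K
  percentages, and counts of AAP[A/V/L], GYR and YLP motifs (overlaps
  counted).
* **Association tests**: Pearson chi-square on class × family tables (no
  continuity correction) and one-/two-way ANOVA F tests, the two-way
  model with Type III sums of squares and a family × solubility
  interaction term.
* **Spectral-count ranking**: final-pellet proteins grouped by shared
  peptides (transitive closure), ranked by NSAF (length-normalized
  spectral-count share), and summarized as the fraction of CPs among the
  top quartile of multi-peptide groups.

A seeded synthetic-data generator (`cutisol.synth`) emulates the study
design — 72 proteins in the observed class/family proportions, three
replicates, class-dependent composition and detection — so the entire
pipeline is testable without downloading anything.

## Worked example

```sh
cutisol simulate --seed 5 --out sim/
cutisol run --fasta sim/proteome.fasta --evidence sim/evidence.tsv \
            --metadata sim/metadata.tsv --out report/
```

prints

```
generated 72 proteins, 1674 observations
wrote 7 report tables to report/
  SOLUBLE_ONLY: 13
  BOTH: 11
  FP_ONLY: 48
  INSUFFICIENT: 0
```

i.e. the planted solubility classes (13 soluble-only, 11 in both soluble
fractions and final pellet, 48 final-pellet-only) are recovered exactly
under noise-free detection. `report/` then contains the classification
table (per-fraction `+`/`(+)` marks), the property table, a per-class
summary (n, mean pI, mean %H/%Y/%Q per class × RR-1/RR-2/other cell,
with a drop-most-extreme companion mean), the association-test battery
(statistic, df, p per hypothesis), residue-coverage reports, and the
NSAF-ranked final-pellet group table with its top-quartile summary.

The same steps are available as library calls; see
`cutisol.pipeline.run_pipeline` and the module docstrings.

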