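# Methods

## The analysis model

The pipeline treats a serial-extraction experiment as a matrix of
peptide observations indexed by (peptide, protein set, fraction,
biological replicate, gel slice) with a spectral count. Fractions are
totally ordered: PBS → EDTA → 2 M urea → 4 M urea → 8 M urea → boiling
SDS, followed by the final pellet (FP), whose peptides come from
on-pellet trypsin digestion. A potassium-tetraborate pre-wash (`KTB`) is
representable in the fraction scheme but excluded from classification
and coverage by default: its purpose is to strip non-cuticular material
before the serial extraction proper, so its peptides say nothing about
CP solubility.

### Replicate rule and solubility classes

A (protein, fraction) pair is **accepted** when at least one peptide of
the protein appears in that fraction in at least `r_required` distinct
replicates (default 2 of 3). The rule is applied at protein level: two
*different* peptides of the same protein in two replicates satisfy it.
The stricter peptide-level reading (one peptide sequence recurring
across replicates) is available via `level="peptide"`; protein-level is
the default because the inclusion wording is "at least one peptide *for
a protein*", i.e. evidence pools at the protein.

Accepted fractions partition proteins into `SOLUBLE_ONLY` (extract
fractions only), `BOTH` (extracts and FP), `FP_ONLY`, and
`INSUFFICIENT` (observed but nothing accepted). Minority-category raw
evidence that fails the replicate rule sets an `exception` flag without
changing the class — these are the parenthesized entries of a solubility
table; they stay counted in their majority class. Proteins with ≥ 3
distinct peptides are marked `multi` (`++`). `INSUFFICIENT` proteins
are reported but excluded from every association test.

EDTA evidence is ordinary extract evidence; no special-casing, because
the fraction is defined by the scheme, not by how much it yielded.

### Counting units and sequence clusters

Paralogous CPs can be identical or near-identical in sequence; their
peptides are then attributed to every member. For contingency tables,
cluster members that have *only* shared peptides are collapsed to one
unit per (cluster, class); members with at least one unique peptide
count individually. Both the collapsed and the per-protein tables are
reported, since the two conventions give different totals and published
counts have used both.

### Coverage and the cross-linking census

Every occurrence of every observed peptide contributes its interval(s);
intervals are merged into maximal covered runs (touching intervals
merge, since coverage is a property of residues, not of individual
peptides). From the merged map we derive: covered fraction; whether any
covered interval starts at residue 1 (`nterm_recovered` — relevant
because the α-amino group is a candidate sclerotization site); the
longest recovered peptide; per-domain overlap for annotated pf00379 /
pf01607 chitin-binding domains; and a residue census. The census finds
maximal runs of histidine and lysine of length ≥ 2 ("pairs or short
clusters") and glutamine runs of length ≥ 4, flagging each run as
recovered iff every residue in it is covered, and every individual
H/K/Y/Q site likewise. Ile/Leu are never collapsed; peptide-to-protein
ambiguity is the caller's responsibility via the `protein_ids` column.

### Tryptic digestion

Cleavage is C-terminal to K/R, suppressed before proline (the default
trypsin rule of the common search engines), up to two missed cleavages.
The zero-missed peptides concatenate back to the input — a property the
tests enforce on random sequences. The "potential first peptide" length
assumes zero missed cleavages; mature-sequence handling is explicit via
the annotated signal-peptide end, and the protein N-terminal Met is not
removed automatically. Peptide masses are monoisotopic sums over the
pyteomics residue-mass table plus water, with carbamidomethyl-C fixed
(+57.02146 Da) and oxidation-M (+15.99491) / deamidation-N/Q (+0.98402)
as additive variable deltas, enumerated to at most three sites per
peptide; masses are bookkeeping here, not search scoring.

### Isoelectric point

The pI is the root of the Henderson–Hasselbalch net-charge function
using the Bjellqvist pK set as deployed by the ExPASy Compute pI tool:
residue-specific N-terminal pKs (default 7.5; A 7.59, M 7.0, S 6.93,
P 8.36, T 6.82, V 7.44, E 7.7), C-terminal 3.55 with residue-specific
values for terminal D (4.55) and E (4.75), and side-chain pKs D 4.05,
E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0. The charge is strictly
decreasing in pH and has opposite signs at pH 0 and 14, so bisection on
[0, 14] always converges; iteration stops when |charge| < 1e-4, which
bounds the pH error well below the 0.01 the comparisons use. X residues
are non-ionizable and ignored.

### Association tests

Chi-square is the plain Pearson statistic, df = (r−1)(c−1), no
continuity correction, with expected counts attached and a warning when
any expected count is below 5. The two-way ANOVA (family group ×
solubility class, with interaction) uses Type III sums of squares under
sum-to-zero contrasts via statsmodels — the decomposition a SAS PROC GLM
user would get on unbalanced data. Degenerate inputs follow explicit
contracts: zero within-group variance with distinct means reports an
infinite F and a p→0 sentinel (the smallest positive double), so the
p ∈ (0, 1] invariant survives. No multiplicity adjustment is applied;
all raw p-values are reported together so users can adjust.

### Spectral counts

Final-pellet proteins sharing any observed peptide are grouped by
transitive closure. Groups are ranked by NSAF — SpC/length renormalized
to sum to one — with ties broken by raw spectral count, then lexical
member id, making the ranking input-order invariant. The exact
normalization of the original commercial software is unpublished; NSAF
is the standard length-normalized convention and only the rank order
feeds the summary. The quartile size is nearest-integer(0.25 · B) with
halves rounded away from zero — the only rule consistent with all three
published (B, C) pairs (73→18, 127→32, 144→36). A group counts as a CP
group if any member is in the CP set.

## The synthetic-data generator

The generator's defaults are the study conditions, chosen once:

* 72 proteins: 13 `SOLUBLE_ONLY` (10 CPR/RR-1, 3 CPR/RR-2), 11 `BOTH`
  (2 RR-1, 4 RR-2, 5 non-CPR), 48 `FP_ONLY` (7 RR-1, 23 RR-2, 18
  non-CPR spread over CPLCG/CPLCP/TWDL/CPF/CPFL/CPLCA/CPLCX) — the
  class and family proportions of the adult-mosquito dataset.
* Lengths uniform on 80–250 aa; residues sampled i.i.d. from
  class-conditional frequency vectors built from per-class targets:
  %H 1.3 / 3.6 / 5.0, %Y 6.5 / 6.0 / 8.0, %Q 7.0 / 6.5 / 4.0, acidic
  pool (D+E) 13 / 8 / 4.5 %, basic pool (K+R) 8 / 9 / 11 % for
  soluble / both / FP respectively. These follow the observed gradients:
  soluble proteins acidic and histidine-poor, final-pellet proteins
  basic and histidine/tyrosine-rich. The remainder is spread over
  neutral residues in A/G/S/P-rich, C/W-poor proportions typical of
  CPs. Composition targets are met by construction of the sampling
  frequencies and verified on the output within sampling error.
* Motif insertion by overwriting non-overlapping windows at per-protein
  Poisson rates: AAP[A/V/L] 0 / 1.0 / 1.5 per protein by class (none in
  soluble proteins, as observed), GYR/YLP at low rates, plus HH pairs
  and QQQQ runs concentrated in the insoluble classes.
* Two sequence clusters of three identical RR-2 final-pellet proteins;
  cluster members therefore share every peptide, exercising the
  shared-peptide and cluster-collapse paths.
* Evidence: ~5 peptides per protein sampled from the true 0–2
  missed-cleavage tryptic digest, restricted to the 6–55 aa detectable
  window (falling back to the longest peptide when sparse cleavage
  leaves nothing in the window — short fragments would be promiscuous
  substring matches). Detection is certain in the planted fractions
  (urea 2/4/8 M for soluble; urea 8 M + SDS + FP for both; FP only for
  FP-only) and zero elsewhere, with an optional per-replicate,
  per-peptide dropout probability; spectral counts are 1 + Poisson(1);
  gel slices A–D for the 8 M urea and SDS gels, `whole` otherwise,
  `none` for the pellet digest.
* One seeded generator drives everything; identical seeds produce
  byte-identical files.

What it does *not* emulate: search-engine scoring and FDR filtering,
modification-induced missed identifications, chimeric spectra, shared
peptides between non-identical paralogs, and abundance-dependent
detection. Passing recovery tests therefore shows that the
classification logic inverts the generative model it defines — not that
real identifications are this clean.

## Problem sizes and numerical choices

The recovery and association checks use the 72-protein cohort over 100
generator seeds (7 200 protein classifications per condition), which
keeps the full suite under a minute of compute while estimating the
agreement rate to well under one percentage point. Report rounding
follows the printed precision of per-class summaries: pI to 2 decimals,
percentages to 1. Per-class summary cells report both the all-n mean
and a drop-most-extreme mean (the value farthest from the cell median,
cells of n ≥ 3 only), because the published convention excludes a
single unidentified outlier; reporting both avoids guessing which
protein it was.

## Known limitations

* The chi-square layout behind a published association p-value can be
  pooled in more than one way; the layout is therefore configuration,
  and the shipped worked example uses the 3 × 3 class × (RR-1, RR-2,
  other) table.
* Type III tests with empty design cells (e.g. no soluble non-CPR
  proteins) are computed as statsmodels returns them; interpret
  interaction terms accordingly.
* The pI model is sequence-only: no structure-based pKa shifts, no
  post-translational modifications.
* Protein-level FDR is out of scope; the evidence table is taken as
  given, and decoy construction (sequence reversal) is provided only so
  users can build target–decoy databases for their own searches.
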