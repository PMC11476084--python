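# Methods

`palb2prev` estimates how common pathogenic germline variants of an
autosomal-dominant cancer-predisposition gene are in sequenced populations,
from per-population allele-count tables of the kind published by gnomAD,
KOVA and KRGDB. The pipeline has four stages: quality filtering,
five-tier variant classification, per-source qualification, and
Hardy–Weinberg carrier-prevalence estimation. This note records the model,
the tunable parameters, the numerical conventions, and what the synthetic
data can and cannot establish.

## Variant identity and normalization

Variants are keyed by a normalized, VCF-style `(chrom, pos, ref, alt)`
tuple: 1-based coordinates, anchor-base indels, shared trailing bases
trimmed before shared leading bases, always keeping at least one base per
allele. All joins between population tables and assertion tables go
through this key; HGVS strings are carried as annotation only, because
HGVS dialects drift between sources.

Reference-free trimming canonicalizes every representation *within the
information the strings carry*: it provably returns the leftmost
parsimonious form among all trimmings of its input (checked exhaustively
against an enumeration oracle for alleles up to length 4). It cannot
reconcile representations that differ by run-extending context (a 1-bp
deletion written at two different offsets inside a homopolymer); that
requires a reference genome, which is out of scope. Multi-allelic sites
must be decomposed before entry; the VCF reader does this.

## Quality filtering

Records carrying any of the gnomAD quality-control filters
`InbreedingCoeff`, `AC0` or `RF` are excluded before classification. The
excluded records are retained in memory (`partition_by_quality`) so reports
can state the exclusion count; they never reach the classifier.

## Five-tier classification

The engine assigns the ACMG/AMP evidence codes computable from population
data, a transcript model and in-silico scores, then combines them with the
2015 combining rules under strength-modified counting (a code counts at its
assigned strength, not its default).

**PVS1 (loss of function).** A reduced ClinGen-SVI decision tree:

* nonsense/frameshift with the premature termination codon (PTC) more than
  50 nt upstream of the last exon–exon junction → nonsense-mediated decay
  (NMD) predicted → very strong; PTC in the last exon or within 50 nt of
  the final junction → strong. Single-exon transcripts never trigger NMD.
  The PTC position is taken from the leading CDS coordinate of the `c.`
  HGVS string; for frameshifts this approximates the true (downstream) PTC
  by the variant position, which is adequate on the toy transcript and
  conservative in the NMD-positive direction only near the 50-nt boundary.
* canonical ±1/2 splice variants → very strong when the SpliceAI Δ score
  supports spliceogenicity (Δ ≥ `spliceai_min`, default 0.2) or is absent;
  otherwise downgraded to strong.
* initiation-codon variants → moderate.
* in-frame exon-skipping rescue analysis is not implemented (out of scope).

**PP3 / BP4 (computational).** Missense variants use REVEL with the
Pejaver calibration tiers, boundaries inclusive on both sides:
pathogenic ≥ 0.644 / 0.773 / 0.932 (supporting / moderate / strong),
benign ≤ 0.290 / 0.183 / 0.016 (supporting / moderate / strong). Scores in
(0.290, 0.644) are uncalibrated and yield no code. The benign very-strong
tier (≤ 0.003) is not used because the 2015 combining table has no benign
very-strong slot. Non-canonical splice-region variants with a SpliceAI
score get PP3 supporting at Δ ≥ 0.2, else BP4 supporting. A variant never
receives both PVS1 and PP3: LoF consequences take the PVS1 branch only.

**PM2 (rarity) and BA1/BS1 (frequency).** Popmax allele frequency is the
maximum `ac/an` over populations with `an > 0`. PM2 is assigned at or
below `pm2_af_max` (default 1e-4) at `pm2_strength` (default supporting,
the ClinGen-style downgrade). On the benign side, BA1 (stand-alone) at
popmax ≥ 0.05 and BS1 (strong) at ≥ 0.005, InterVar-style defaults.
BA1/BS1 are auto-assigned because they are directly computable from the
population counts — without them a population-only engine could never
reach likely benign/benign, and the synthetic truth-recovery tests would
be vacuous. Codes that need external data (PS1–PS4, PM1/PM3–PM6, PP1/PP2/
PP4/PP5, BS2–BS4, BP1–BP3/BP5–BP7) are accepted as pre-annotated inputs
but never auto-assigned.

**Combination.** With `vs/s/m/p` the pathogenic-side counts per strength:

* pathogenic: `vs≥2`, or `vs≥1` with (`s≥1` | `m≥2` | `m≥1 & p≥1` | `p≥2`),
  or `s≥2`, or `s≥1` with (`m≥3` | `m≥2 & p≥2` | `m≥1 & p≥4`);
* likely pathogenic: `vs≥1 & m≥1`, `s≥1 & m≥1`, `s≥1 & p≥2`, `m≥3`,
  `m≥2 & p≥2`, or `m≥1 & p≥4`;
* benign: BA1, or ≥ 2 benign strong; likely benign: any two benign codes.
  The 2015 table has no benign moderate slot, but the Pejaver BP4 tiers
  emit one; counting any two benign codes as likely benign is the natural
  extension and is stated here once and mirrored by the test oracle.
* evidence meeting rules on both sides, or on neither, → uncertain
  significance. Duplicate codes are rejected.

The implementation is verified against an independent rule-row enumeration
oracle for every strength multiset of size ≤ 6, and is monotone: adding
pathogenic evidence to a benign-free set never lowers the class.

## Qualification and prevalence

Three qualifying sets feed the prevalence tables: `acmg` (engine class
pathogenic or likely pathogenic), `clinvar` (asserted Pathogenic or
Likely_pathogenic; Conflicting and VUS excluded), `hgmd` (asserted DM;
DM? excluded).

For a cohort of `n` individuals with `total_ac` qualifying alleles
(summed over the cohort's member populations for pooled cohorts), the
minor-allele frequency is `q = total_ac / 2n` and, assuming Hardy–Weinberg
equilibrium and autosomal-dominant inheritance, the carrier prevalence is
the heterozygote frequency `2pq = 2q(1−q)`. Homozygotes (`q²`) are
excluded, with no small-q approximation. The denominator is always twice
the cohort size, never the per-variant allele number (`an` is kept for QC
only). "One carrier in every N" is `floor(1/2pq)`, rendered `NA` at zero
prevalence; percentages use two decimals, rounding half away from zero.

Confidence intervals are computed for `q` on the allele scale — exact
Clopper–Pearson binomial by default (via `statsmodels`), Wilson score or
Garwood Poisson-exact as alternatives — and mapped to the carrier scale
through `f(q) = 2q(1−q)`, which is monotone for `q ≤ 1/2` (bounds above
1/2 are clamped to the maximum 0.5). With zero counts the lower bound is
exactly 0. The exact CI agrees with a direct binomial tail-sum bisection
oracle to well beyond four significant figures. The CI method is pluggable
because no single standard method reproduces every published interval of
this kind; point estimates are the reproducible quantity.

At the planted carrier frequency 0.002 and cohort size n = 10,000, the
exact coverage of the carrier-scale Clopper–Pearson interval (by binomial
enumeration) is 95.7%; the acceptance study measures empirical coverage
over 2,000 simulated cohorts and checks the 93–97% band.

## Synthetic data

`simulate_cohort_table` draws allele counts `ac ~ Binomial(2n, af)` per
planted variant and cohort, deterministically under a seed. Class-
conditional templates leave a margin between the classes: planted
pathogenic variants are NMD-positive nonsense at AF ~ 5e-4; planted benign
variants are common (AF ~ 9e-3) low-REVEL missense; planted uncertain
variants are rare mid-REVEL missense. The matching classification config
puts the PM2 cutoff at 2e-3 — between the rare and common regimes — at
moderate strength, so PVS1 + PM2 reaches likely pathogenic and BS1 + BP4
reaches likely benign. A configurable `flag_rate` adds excluding QC flags.

The generator emulates allele-count sampling only: independent variants,
no linkage, no genotype-level data, no sequencing error, no relatedness,
and an idealized call rate (`an = 2n`). Passing tests therefore establish
the arithmetic and the engine's logic, not robustness to real-data
artefacts such as joint-calling batch effects or population structure.

`make_paper_fixtures` pins the study this package re-implements: ten
gnomAD-style populations (125,748 exomes, including 1,909 Korean, 76
Japanese and 7,212 other East Asian), KOVA (5,305) and KRGDB (1,722)
tables, ClinVar-style and HGMD-style assertion tables, and pooled cohorts
(East Asian: 9,197; all-Korean: 8,936). Qualifying-allele sums reproduce
every published Total-Alleles cell (e.g. 227/214/277 globally for
ACMG/ClinVar/HGMD), and the individually reported variants are embedded
with their reported counts: c.1592del (46 alleles, Finnish-enriched,
absent in East Asians), c.2167_2168del (16, mostly Latino),
c.2968G>T (top East Asian, absent in Koreans), c.1048C>T (top Korean),
c.1050_1053del (the only East Asian variant shared with other groups).
Only the sums and these named facts are meaningful; per-variant splits the
sources report only in aggregate are fixed synthetic choices, as are the
genomic coordinates (placeholders on a three-exon toy transcript: 3,800 nt,
50-nt 5' UTR, 3,561-nt CDS, last junction at position 3,000). The fixture
classification config uses `pm2_af_max = 2e-3` and PM2 at moderate
strength: the commonest qualifying variant (c.1592del, Finnish AF 1.39e-3)
must still earn PM2 so that PVS1 + PM2 combines to at least likely
pathogenic; with the supporting-strength default, PVS1 + PM2 alone would
remain VUS under the strict 2015 table.

## Numerical conventions and edge cases

* REVEL/SpliceAI/PM2/BA1/BS1 cutoffs are inclusive at the boundary.
* Populations with `an = 0` are ignored in popmax (a variant absent
  everywhere has popmax 0 and earns PM2).
* `one_in_n` uses exact `floor(1/2pq)`. One published reciprocal
  (2 alleles / 1,909 individuals) prints 954 where exact arithmetic gives
  955.0003; the floor rule reproduces all other published reciprocals
  exactly, so the exact value (955) is reported.
* Carrier projection onto a census population multiplies the *rounded*
  percentage (2 dp) and rounds to the nearest thousand — e.g. 0.13% of
  51.8 million → 67,000 — matching how such figures are quoted.
* KRGDB-style tables that publish frequencies instead of counts are
  converted by `ac = round(af × 2n)`.
* Report rows are ordered by cohort-registry order, then source
  (acmg, clinvar, hgmd); reruns are byte-identical.

## Known limitations

Large (> 50 bp) deletions/insertions and CNVs are outside the model, as
are penetrance adjustment, founder-effect modelling, and classification-
uncertainty propagation into the CIs. The PVS1 tree is the reduced form
(no exon-skipping rescue). The engine cannot use case-level evidence, so
variants that are pathogenic on functional or segregation grounds but
common enough to miss PM2 require pre-annotated evidence or the assertion
sources to qualify.
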