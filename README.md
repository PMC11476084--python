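# palb2prev

Population-scale carrier-prevalence estimation for pathogenic germline
variants of an autosomal-dominant cancer-predisposition gene, built around
the PALB2 case: classify every variant in gnomAD-style allele-count tables
into the five ACMG/AMP tiers, cross-reference ClinVar-style and HGMD-style
assertions, and convert the qualifying allele totals into Hardy–Weinberg
carrier frequencies with confidence intervals.

It is aimed at clinical-genetics and population-genetics analysts who want
to answer, from published allele counts alone: *how many people in this
population carry a pathogenic or likely pathogenic allele of this gene?*

## Model

For a cohort of `n` sequenced individuals, a qualifying allele total
`AC` gives the minor (disease) allele frequency

```
q = AC / 2n,    p = 1 − q
```

and, under Hardy–Weinberg equilibrium (`1 = p² + 2pq + q²`) with autosomal-
dominant inheritance, the carrier prevalence is the heterozygote frequency

```
carrier prevalence = 2pq = 2q(1 − q)
```

reported as a percentage and as "one carrier in every `⌊1/2pq⌋`". A 95% CI
is computed for `q` on the allele scale (exact Clopper–Pearson binomial by
default; Wilson and Poisson-exact available) and mapped through the
monotone transform `2q(1−q)`.

Variants qualify through three evidence routes:

* **acmg** — the built-in engine assigns PVS1 (ClinGen-SVI-style
  loss-of-function tree with the NMD 50-nt rule), PP3/BP4 (REVEL at the
  Pejaver calibration tiers; SpliceAI Δ ≥ 0.2), PM2 and BA1/BS1
  (population frequency), and combines them with the 2015 ACMG/AMP rules
  into pathogenic / likely pathogenic / VUS / likely benign / benign;
* **clinvar** — asserted Pathogenic or Likely_pathogenic;
* **hgmd** — asserted DM (disease-causing mutation).

Records flagged `InbreedingCoeff`, `AC0` or `RF` are excluded up front.
See `docs/methods.md` for the full model, parameter defaults and
limitations.

## Worked example

The package ships a synthetic fixture bundle emulating the gnomAD v2.1.1 /
KOVA / KRGDB analysis of PALB2 (125,748 exomes across ten populations plus
two Korean databases; see `docs/methods.md` for what is pinned and what is
placeholder):

```
palb2prev fixtures --out fixtures
palb2prev prevalence \
    --variants fixtures/gnomad_variants.tsv \
    --variants fixtures/kova_variants.tsv \
    --variants fixtures/krgdb_variants.tsv \
    --clinvar fixtures/clinvar_assertions.tsv \
    --hgmd fixtures/hgmd_assertions.tsv \
    --cohorts fixtures/cohorts.yaml \
    --transcript fixtures/transcript.yaml \
    --thresholds fixtures/thresholds.yaml \
    --out report.tsv --pretty
```

which prints (abridged):

```
45 report rows written to report.tsv (3 records excluded by quality filters; CI: exact_binomial)
          cohort  n_individuals  source  total_alleles  prevalence prevalence_pct    ci_pct one_in_n one_in_n_ci
          global         125748    acmg            227    0.001804           0.18 0.16-0.21      554     486-634
          global         125748 clinvar            214    0.001700           0.17 0.15-0.19      588     514-675
          global         125748    hgmd            277    0.002200           0.22 0.19-0.25      454     404-513
      east_asian           9197    acmg              8    0.000869           0.09 0.04-0.17     1150    584-2663
         finnish          10824    acmg             44    0.004057           0.41 0.30-0.54      246     183-338
ashkenazi_jewish           5040    acmg              2    0.000397           0.04 0.00-0.14     2520   698-20808
```

Reading the global acmg row: 227 qualifying alleles among 125,748
individuals give `q = 227/251,496`, a carrier prevalence of
`2q(1−q) = 0.0018` — 0.18% of the population, i.e. one carrier in every
554 people (95% CI 486–634). Finnish cohorts show the highest prevalence
(0.41%, driven by the c.1592del founder frameshift) and Ashkenazi Jewish
cohorts the lowest (0.04%). Pooling the Korean data (2/1,909 gnomAD +
10/5,305 KOVA + 0/1,722 KRGDB = 12 alleles in 8,936 individuals) gives a
Korean carrier prevalence of 0.13% — one in 745, or roughly 67,000
carriers in South Korea's 51.8 million inhabitants
(`project_carriers(0.13, 51_800_000)`).

`palb2prev classify` writes a per-variant audit (evidence codes with
strengths and the resulting tier), and `palb2prev simulate` draws
synthetic cohorts with known ground truth:

```
palb2prev classify --variants fixtures/kova_variants.tsv \
    --transcript fixtures/transcript.yaml --thresholds fixtures/thresholds.yaml \
    --out audit.tsv
# classified 6 variants (0 excluded by quality filters); tiers:
# {'likely_pathogenic': 5, 'uncertain_significance': 1}
```

The same operations are available as a library
(`palb2prev.classify_all`, `palb2prev.carrier_prevalence`,
`palb2prev.prevalence_ci`, `palb2prev.make_paper_fixtures`, ...).

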