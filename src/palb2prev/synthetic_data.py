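"""Synthetic population tables with known ground truth, plus packaged fixtures.

Two generators live here:

* :func:`simulate_cohort_table` draws gnomAD-like allele-count tables from a
  :class:`SimulationConfig`: each planted variant receives a binomial allele
  count ``ac ~ Binomial(2 * n_individuals, af)`` per cohort, with
  class-conditional consequences and in-silico scores chosen so the
  classification engine recovers the planted class (pathogenic variants are
  NMD-positive nonsense/frameshift, benign ones common low-REVEL missense).

* :func:`make_paper_fixtures` builds the fixed fixture bundle that emulates
  the gnomAD v2.1.1 / KOVA / KRGDB PALB2 analysis: per-population
  allele-count tables, ClinVar-style and HGMD-style assertion tables, a
  cohort registry and a classification threshold configuration whose
  qualifying-allele sums reproduce every published Total-Alleles cell.
  Genomic coordinates are synthetic placeholders on a toy transcript; the
  HGVS labels, consequences and count totals are the meaningful part.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .acmg_engine import Strength, ThresholdConfig
from .io_formats import (
    AssertionTable,
    merge_variant_tables,
    write_assertion_table,
    write_cohort_registry,
    write_threshold_config,
    write_transcript_model,
    write_variant_table,
)
from .variant_model import (
    CohortSpec,
    Consequence,
    TranscriptModel,
    VariantKey,
    VariantRecord,
)

__all__ = [
    "SpectrumEntry",
    "SimulationConfig",
    "simulate_cohort_table",
    "simulate_allele_counts",
    "example_config",
    "FixtureBundle",
    "make_paper_fixtures",
    "TOY_TRANSCRIPT",
    "FIXTURE_THRESHOLDS",
]

# ---------------------------------------------------------------------------
# stochastic cohort simulation

#: Three-exon toy transcript: 3800 nt, 50 nt 5'UTR, 3561 nt CDS.  The last
#: exon-exon junction sits at transcript position 3000, so PTCs at CDS
#: positions <= 2899 are NMD-positive.
TOY_TRANSCRIPT = TranscriptModel(
    exon_lengths=(1500, 1500, 800), cds_start_offset=50, cds_end_offset=3611
)

_NMD_SAFE_CDS = (100, 2800)  # PTC positions comfortably NMD-positive
_EXCLUDING_FLAGS = ("AC0", "RF", "InbreedingCoeff")


@dataclass(frozen=True)
class SpectrumEntry:
    """One planted variant: identity, true class, and per-cohort frequency."""

    key: VariantKey
    consequence: Consequence
    true_class: str  # "pathogenic" | "benign" | "uncertain"
    af: Mapping[str, float]  # cohort name -> planted allele frequency
    hgvs_c: str = ""
    hgvs_p: str = ""
    revel: Optional[float] = None
    spliceai: Optional[float] = None

    def __post_init__(self) -> None:
        if self.true_class not in ("pathogenic", "benign", "uncertain"):
            raise ValueError(f"unknown true class {self.true_class!r}")
        for cohort, af in self.af.items():
            if not (0.0 <= af <= 0.01):
                raise ValueError(
                    f"{self.key}: planted AF {af} for {cohort!r} outside the "
                    "rare-variant regime [0, 0.01]"
                )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort table.

    ``thresholds`` is the classification configuration consistent with the
    generative settings: PM2 (moderate) against a 2e-3 popmax cutoff that
    separates the planted rare pathogenic/uncertain regime (AF <= 1e-3)
    from the planted common benign regime (AF ~ 1e-2, which instead earns
    BS1), so that planted classes are recoverable with margin.
    """

    seed: int
    cohorts: Tuple[CohortSpec, ...]
    spectrum: Tuple[SpectrumEntry, ...]
    flag_rate: float = 0.0
    thresholds: ThresholdConfig = ThresholdConfig(
        pm2_af_max=2e-3, pm2_strength=Strength.MODERATE
    )

    def __post_init__(self) -> None:
        if not (0.0 <= self.flag_rate <= 1.0):
            raise ValueError(f"flag_rate {self.flag_rate} outside [0, 1]")


def simulate_cohort_table(
    config: SimulationConfig,
) -> Tuple[List[VariantRecord], pd.DataFrame]:
    """Draw one (variant table, truth table) pair; deterministic under seed."""
    rng = np.random.default_rng(config.seed)
    records: List[VariantRecord] = []
    truth_rows = []
    for entry in config.spectrum:
        counts: Dict[str, Tuple[int, int]] = {}
        for cohort in config.cohorts:
            an = 2 * cohort.n_individuals
            af = entry.af.get(cohort.name, 0.0)
            counts[cohort.name] = (int(rng.binomial(an, af)), an)
        flags = frozenset()
        if config.flag_rate > 0 and rng.random() < config.flag_rate:
            flags = frozenset({_EXCLUDING_FLAGS[int(rng.integers(len(_EXCLUDING_FLAGS)))]})
        records.append(
            VariantRecord(
                key=entry.key,
                consequence=entry.consequence,
                hgvs_c=entry.hgvs_c,
                hgvs_p=entry.hgvs_p,
                filter_flags=flags,
                pop_counts=counts,
                revel=entry.revel,
                spliceai_delta=entry.spliceai,
            )
        )
        row = {
            "variant": str(entry.key),
            "hgvs_c": entry.hgvs_c,
            "true_class": entry.true_class,
            "flagged": bool(flags),
        }
        for cohort in config.cohorts:
            row[f"af_{cohort.name}"] = entry.af.get(cohort.name, 0.0)
            row[f"ac_{cohort.name}"] = counts[cohort.name][0]
        truth_rows.append(row)
    return records, pd.DataFrame(truth_rows)


def example_config(
    seed: int,
    n_individuals: int = 10_000,
    n_pathogenic: int = 5,
    n_benign: int = 3,
    n_uncertain: int = 3,
    pathogenic_af: float = 5e-4,
    benign_af: float = 9e-3,
    uncertain_af: float = 3e-4,
    flag_rate: float = 0.0,
    cohort_name: str = "simulated",
) -> SimulationConfig:
    """A single-cohort config with class-conditional variant templates.

    Pathogenic variants are NMD-positive nonsense (PVS1 very_strong + PM2);
    benign ones are common missense with low REVEL (BS1 + BP4); uncertain
    ones are rare mid-REVEL missense (PM2 alone).
    """
    rng = np.random.default_rng(seed)
    cohort = CohortSpec(cohort_name, n_individuals, source="synthetic")
    entries: List[SpectrumEntry] = []
    pos_pool = rng.choice(
        np.arange(_NMD_SAFE_CDS[0], _NMD_SAFE_CDS[1]),
        size=n_pathogenic + n_benign + n_uncertain,
        replace=False,
    )
    i = 0
    for _ in range(n_pathogenic):
        cds = int(pos_pool[i]); i += 1
        entries.append(
            SpectrumEntry(
                key=VariantKey("16", 23_600_000 + cds, "C", "T"),
                consequence=Consequence.NONSENSE,
                true_class="pathogenic",
                af={cohort_name: pathogenic_af},
                hgvs_c=f"c.{cds}C>T",
            )
        )
    for _ in range(n_benign):
        cds = int(pos_pool[i]); i += 1
        entries.append(
            SpectrumEntry(
                key=VariantKey("16", 23_600_000 + cds, "A", "G"),
                consequence=Consequence.MISSENSE,
                true_class="benign",
                af={cohort_name: benign_af},
                hgvs_c=f"c.{cds}A>G",
                revel=float(rng.uniform(0.02, 0.15)),
            )
        )
    for _ in range(n_uncertain):
        cds = int(pos_pool[i]); i += 1
        entries.append(
            SpectrumEntry(
                key=VariantKey("16", 23_600_000 + cds, "G", "C"),
                consequence=Consequence.MISSENSE,
                true_class="uncertain",
                af={cohort_name: uncertain_af},
                hgvs_c=f"c.{cds}G>C",
                revel=float(rng.uniform(0.35, 0.60)),
            )
        )
    return SimulationConfig(
        seed=seed, cohorts=(cohort,), spectrum=tuple(entries), flag_rate=flag_rate
    )


def simulate_allele_counts(
    carrier_frequency: float,
    n_individuals: int,
    n_replicates: int,
    seed: int,
) -> np.ndarray:
    """Replicate qualifying allele counts for a planted 2pq carrier frequency.

    Solves ``2q(1-q) = c`` for the allele frequency q, then draws
    ``Binomial(2n, q)`` counts — the sampling model behind every cohort cell.
    """
    if not (0.0 <= carrier_frequency < 0.5):
        raise ValueError("carrier frequency must lie in [0, 0.5)")
    q = (1.0 - np.sqrt(1.0 - 2.0 * carrier_frequency)) / 2.0
    rng = np.random.default_rng(seed)
    return rng.binomial(2 * n_individuals, q, size=n_replicates)


# ---------------------------------------------------------------------------
# packaged fixtures reproducing the published count tables

#: Classification configuration used with the fixture tables: PM2 at
#: moderate strength with a popmax cutoff above the rarest-common qualifying
#: variant (the Finnish founder frameshift, AF 1.4e-3), so every planted
#: pathogenic/likely-pathogenic variant earns PVS1 + PM2 and combines to at
#: least likely pathogenic.
FIXTURE_THRESHOLDS = ThresholdConfig(pm2_af_max=2e-3, pm2_strength=Strength.MODERATE)

_GNOMAD_POPS: Tuple[Tuple[str, int], ...] = (
    ("african", 8128),
    ("latino", 17296),
    ("ashkenazi_jewish", 5040),
    ("finnish", 10824),
    ("nfe", 56885),
    ("south_asian", 15308),
    ("other", 3070),
    ("korean", 1909),
    ("japanese", 76),
    ("other_east_asian", 7212),
)
_KOVA_N = 5305
_KRGDB_N = 1722

# Variant catalogue.  Columns: hgvs_c, hgvs_p, consequence, ref, alt,
# revel, spliceai.  Positions are synthetic placeholders derived from the
# catalogue order; allele strings are fabricated but normalization-stable.
_CATALOGUE: Dict[str, Tuple[str, str, str, str, Optional[float], Optional[float]]] = {
    "c.1592del": ("p.(Leu531CysfsTer30)", "frameshift", "CA", "C", None, None),
    "c.2167_2168del": ("p.(Met723ValfsTer21)", "frameshift", "CAT", "C", None, None),
    "c.3113G>A": ("p.(Trp1038Ter)", "nonsense", "G", "A", None, None),
    "c.172_175del": ("p.(Gln60ArgfsTer7)", "frameshift", "GCAGA", "G", None, None),
    "c.509_510del": ("p.(Arg170IlefsTer14)", "frameshift", "TAG", "T", None, None),
    "c.2968G>T": ("p.(Glu990Ter)", "nonsense", "G", "T", None, None),
    "c.1050_1053del": ("p.(Thr351ArgfsTer4)", "frameshift", "CACTG", "C", None, None),
    "c.3549C>A": ("p.(Tyr1183Ter)", "nonsense", "C", "A", None, None),
    "c.3116del": ("p.(Asn1039IlefsTer2)", "frameshift", "TA", "T", None, None),
    "c.2257C>T": ("p.(Arg753Ter)", "nonsense", "C", "T", None, None),
    "c.1240C>T": ("p.(Arg414Ter)", "nonsense", "C", "T", None, None),
    "c.3323del": ("p.(Tyr1108SerfsTer16)", "frameshift", "GT", "G", None, None),
    "c.229del": ("p.(Leu77PhefsTer3)", "frameshift", "AC", "A", None, None),
    "c.2962C>T": ("p.(Gln988Ter)", "nonsense", "C", "T", None, None),
    "c.2871del": ("p.(Phe957LeufsTer4)", "frameshift", "GT", "G", None, None),
    "c.301del": ("p.(Val101TrpfsTer8)", "frameshift", "CG", "C", None, None),
    "c.661A>T": ("p.(Lys221Ter)", "nonsense", "A", "T", None, None),
    "c.2748+1G>A": ("", "canonical_splice", "G", "A", None, 0.91),
    "c.751C>T": ("p.(Gln251Ter)", "nonsense", "C", "T", None, None),
    "c.758dup": ("p.(Ser254IlefsTer3)", "frameshift", "A", "AG", None, None),
    "c.1048C>T": ("p.(Gln350Ter)", "nonsense", "C", "T", None, None),
    "c.3267_3268del": ("p.(Phe1090SerfsTer6)", "frameshift", "TCT", "T", None, None),
    "c.2834+2T>C": ("", "canonical_splice", "T", "C", None, 0.95),
    "c.475C>T": ("p.(Gln159Ter)", "nonsense", "C", "T", None, None),
    # non-qualifying background
    "c.1194G>A": ("p.(=)", "synonymous", "G", "A", None, None),
    "c.212A>G": ("p.(Asn71Ser)", "missense", "A", "G", 0.08, None),
    "c.925A>G": ("p.(Ile309Val)", "missense", "A", "G", 0.50, None),
    "c.1685A>C": ("p.(Gln562Pro)", "missense", "A", "C", 0.35, None),
    "c.2590C>T": ("p.(Pro864Ser)", "missense", "C", "T", 0.50, None),
    "c.2T>C": ("p.(Met1?)", "initiation_codon", "T", "C", None, None),
    # quality-flagged records, excluded before classification
    "c.2515del": ("p.(Leu839Ter)", "frameshift", "CT", "C", None, None),
    "c.3201C>A": ("p.(Tyr1067Ter)", "nonsense", "C", "A", None, None),
    "c.394G>A": ("p.(Val132Met)", "missense", "G", "A", 0.20, None),
    # HGMD-only DM missense (engine: uncertain significance)
    "c.101C>T": ("p.(Thr34Ile)", "missense", "C", "T", 0.50, None),
    "c.508G>A": ("p.(Ala170Thr)", "missense", "G", "A", 0.55, None),
    "c.1210G>C": ("p.(Gly404Arg)", "missense", "G", "C", 0.50, None),
    "c.2258G>A": ("p.(Arg753Gln)", "missense", "G", "A", 0.60, None),
    "c.2429C>T": ("p.(Ser810Leu)", "missense", "C", "T", 0.45, None),
    "c.2816T>G": ("p.(Leu939Trp)", "missense", "T", "G", 0.50, None),
    "c.3299C>T": ("p.(Thr1100Met)", "missense", "C", "T", 0.52, None),
}

# gnomAD per-population nonzero allele counts.  Only sums are published;
# this allocation is fixed and documented, chosen to respect the published
# per-variant facts (c.1592del: 46 alleles, none East Asian; c.2167_2168del:
# 16, mostly Latino; c.2968G>T: top East Asian, absent in Koreans;
# c.1048C>T: top Korean; c.1050_1053del: the only East Asian variant shared
# with other ethnic groups).
_GNOMAD_AC: Dict[str, Dict[str, int]] = {
    "c.1592del": {"finnish": 30, "nfe": 12, "latino": 2, "african": 2},
    "c.2167_2168del": {"latino": 14, "nfe": 2},
    "c.3113G>A": {"nfe": 10, "latino": 2, "african": 1},
    "c.172_175del": {"nfe": 9, "latino": 2, "african": 1},
    "c.509_510del": {"nfe": 8, "latino": 2, "african": 1},
    "c.2968G>T": {"other_east_asian": 3},
    "c.1050_1053del": {"other_east_asian": 2, "nfe": 2},
    "c.3549C>A": {"other_east_asian": 1},
    "c.3116del": {"african": 11},
    "c.2257C>T": {"latino": 6},
    "c.1240C>T": {"ashkenazi_jewish": 1},
    "c.3323del": {"finnish": 14},
    "c.229del": {"nfe": 55},
    "c.2962C>T": {"south_asian": 12},
    "c.2871del": {"other": 8},
    "c.301del": {"latino": 1},
    "c.661A>T": {"ashkenazi_jewish": 1},
    "c.2748+1G>A": {"nfe": 7},
    "c.751C>T": {"south_asian": 3},
    "c.758dup": {"korean": 1},
    "c.1048C>T": {"korean": 1},
    "c.1194G>A": {"nfe": 6000, "african": 500},
    "c.212A>G": {"nfe": 2300, "latino": 400},
    "c.925A>G": {"latino": 2},
    "c.1685A>C": {"nfe": 40},
    "c.2590C>T": {"korean": 1},
    "c.2T>C": {"other_east_asian": 1},
    "c.101C>T": {"african": 1},
    "c.508G>A": {"latino": 11},
    "c.1210G>C": {"ashkenazi_jewish": 1},
    "c.2258G>A": {"nfe": 39},
    "c.2429C>T": {"south_asian": 2},
    "c.2816T>G": {"other": 2},
    "c.3299C>T": {"other_east_asian": 8},
}
_GNOMAD_FLAGS: Dict[str, Tuple[str, ...]] = {
    "c.2515del": ("RF",),
    "c.3201C>A": ("AC0",),
    "c.394G>A": ("InbreedingCoeff",),
}
_GNOMAD_FLAGGED_AC: Dict[str, Dict[str, int]] = {
    "c.2515del": {"nfe": 6},
    "c.3201C>A": {},
    "c.394G>A": {"african": 3},
}

_KOVA_AC: Dict[str, int] = {
    "c.1048C>T": 3,
    "c.475C>T": 3,
    "c.3267_3268del": 2,
    "c.2167_2168del": 1,
    "c.2834+2T>C": 1,
    "c.1194G>A": 400,
}
_KRGDB_AC: Dict[str, int] = {
    "c.1194G>A": 150,
    "c.212A>G": 80,
}

# ClinVar-style assertions (engine-only qualifiers are deliberately absent).
_CLINVAR: Dict[str, str] = {
    "c.1592del": "Pathogenic",
    "c.2167_2168del": "Pathogenic",
    "c.3113G>A": "Pathogenic",
    "c.172_175del": "Pathogenic",
    "c.509_510del": "Pathogenic",
    "c.2968G>T": "Pathogenic",
    "c.1050_1053del": "Likely_pathogenic",
    "c.3549C>A": "Likely_pathogenic",
    "c.3116del": "Pathogenic",
    "c.2257C>T": "Pathogenic",
    "c.1240C>T": "Pathogenic",
    "c.3323del": "Likely_pathogenic",
    "c.229del": "Pathogenic",
    "c.2962C>T": "Likely_pathogenic",
    "c.2871del": "Pathogenic",
    "c.1048C>T": "Pathogenic",
    "c.3267_3268del": "Pathogenic",
    "c.2834+2T>C": "Likely_pathogenic",
    "c.475C>T": "Pathogenic",
    "c.212A>G": "Benign",
    "c.925A>G": "Uncertain_significance",
    "c.1685A>C": "Conflicting",
    "c.1194G>A": "Benign",
}

# HGMD-style assertions; DM? and DP entries exercise the exclusion rules.
_HGMD: Dict[str, str] = {
    "c.1592del": "DM",
    "c.2167_2168del": "DM",
    "c.3113G>A": "DM",
    "c.172_175del": "DM",
    "c.509_510del": "DM",
    "c.2968G>T": "DM",
    "c.1050_1053del": "DM",
    "c.3549C>A": "DM",
    "c.3116del": "DM",
    "c.2257C>T": "DM",
    "c.1240C>T": "DM",
    "c.3323del": "DM",
    "c.229del": "DM",
    "c.2962C>T": "DM",
    "c.2871del": "DM",
    "c.3267_3268del": "DM",
    "c.475C>T": "DM",
    "c.101C>T": "DM",
    "c.508G>A": "DM",
    "c.1210G>C": "DM",
    "c.2258G>A": "DM",
    "c.2429C>T": "DM",
    "c.2816T>G": "DM",
    "c.3299C>T": "DM",
    "c.2590C>T": "DM?",
    "c.925A>G": "DP",
}

_CHROM = "16"
_BASE_POS = 23_600_000


def _fixture_keys() -> Dict[str, VariantKey]:
    from .variant_model import normalize_variant

    keys = {}
    for i, (hgvs_c, (_, _, ref, alt, _, _)) in enumerate(_CATALOGUE.items()):
        keys[hgvs_c] = normalize_variant(_CHROM, _BASE_POS + 10 * (i + 1), ref, alt)
    return keys


@dataclass(frozen=True)
class FixtureBundle:
    """The packaged tables emulating the published population analysis."""

    gnomad: Tuple[VariantRecord, ...]
    kova: Tuple[VariantRecord, ...]
    krgdb: Tuple[VariantRecord, ...]
    clinvar: AssertionTable
    hgmd: AssertionTable
    cohorts: Tuple[CohortSpec, ...]
    transcript: TranscriptModel = TOY_TRANSCRIPT
    thresholds: ThresholdConfig = FIXTURE_THRESHOLDS

    def all_records(self) -> List[VariantRecord]:
        """All three tables merged by normalized key."""
        return merge_variant_tables([self.gnomad, self.kova, self.krgdb])

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_variant_table(self.gnomad, outdir / "gnomad_variants.tsv")
        write_variant_table(self.kova, outdir / "kova_variants.tsv")
        write_variant_table(self.krgdb, outdir / "krgdb_variants.tsv")
        write_assertion_table(self.clinvar, outdir / "clinvar_assertions.tsv")
        write_assertion_table(self.hgmd, outdir / "hgmd_assertions.tsv")
        write_cohort_registry(self.cohorts, outdir / "cohorts.yaml")
        write_threshold_config(self.thresholds, outdir / "thresholds.yaml")
        write_transcript_model(self.transcript, outdir / "transcript.yaml")


def _record(
    hgvs_c: str,
    keys: Mapping[str, VariantKey],
    pop_counts: Mapping[str, Tuple[int, int]],
    flags: Tuple[str, ...] = (),
) -> VariantRecord:
    hgvs_p, cons, _, _, revel, spliceai = _CATALOGUE[hgvs_c]
    return VariantRecord(
        key=keys[hgvs_c],
        consequence=Consequence(cons),
        hgvs_c=hgvs_c,
        hgvs_p=hgvs_p,
        filter_flags=frozenset(flags),
        pop_counts=dict(pop_counts),
        revel=revel,
        spliceai_delta=spliceai,
    )


def make_paper_fixtures() -> FixtureBundle:
    """Build the fixture bundle pinning the published qualifying-allele sums."""
    keys = _fixture_keys()

    gnomad: List[VariantRecord] = []
    for hgvs_c in _CATALOGUE:
        if hgvs_c in _GNOMAD_FLAGS:
            alloc, flags = _GNOMAD_FLAGGED_AC[hgvs_c], _GNOMAD_FLAGS[hgvs_c]
        elif hgvs_c in _GNOMAD_AC:
            alloc, flags = _GNOMAD_AC[hgvs_c], ()
        else:
            continue
        counts = {pop: (alloc.get(pop, 0), 2 * n) for pop, n in _GNOMAD_POPS}
        gnomad.append(_record(hgvs_c, keys, counts, flags))

    kova = [
        _record(h, keys, {"kova": (ac, 2 * _KOVA_N)}) for h, ac in _KOVA_AC.items()
    ]
    krgdb = [
        _record(h, keys, {"krgdb": (ac, 2 * _KRGDB_N)}) for h, ac in _KRGDB_AC.items()
    ]

    clinvar = AssertionTable(
        "clinvar-style", {keys[h]: a for h, a in _CLINVAR.items()}
    )
    hgmd = AssertionTable("hgmd-style", {keys[h]: a for h, a in _HGMD.items()})

    gnomad_pop_names = [p for p, _ in _GNOMAD_POPS]
    cohorts = (
        CohortSpec("global", 125_748, "gnomAD-exomes", tuple(gnomad_pop_names)),
        CohortSpec(
            "east_asian",
            9_197,
            "gnomAD-exomes",
            ("korean", "japanese", "other_east_asian"),
        ),
        CohortSpec("african", 8_128, "gnomAD-exomes"),
        CohortSpec("latino", 17_296, "gnomAD-exomes"),
        CohortSpec("ashkenazi_jewish", 5_040, "gnomAD-exomes"),
        CohortSpec("finnish", 10_824, "gnomAD-exomes"),
        CohortSpec("nfe", 56_885, "gnomAD-exomes"),
        CohortSpec("south_asian", 15_308, "gnomAD-exomes"),
        CohortSpec("other", 3_070, "gnomAD-exomes"),
        CohortSpec("korean", 1_909, "gnomAD-exomes"),
        CohortSpec("japanese", 76, "gnomAD-exomes"),
        CohortSpec("other_east_asian", 7_212, "gnomAD-exomes"),
        CohortSpec("kova", _KOVA_N, "KOVA"),
        CohortSpec("krgdb", _KRGDB_N, "KRGDB"),
        CohortSpec("all_korean", 8_936, "pooled", ("korean", "kova", "krgdb")),
    )
    return FixtureBundle(
        gnomad=tuple(gnomad),
        kova=tuple(kova),
        krgdb=tuple(krgdb),
        clinvar=clinvar,
        hgmd=hgmd,
        cohorts=cohorts,
    )
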