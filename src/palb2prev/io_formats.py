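"""Readers and writers for variant tables, assertion tables and cohort configs.

Two variant-table dialects are supported:

* a canonical TSV dialect with header columns ``chrom, pos, ref, alt,
  hgvs_c, hgvs_p, consequence, filters, revel, spliceai`` followed by
  ``AC_<pop>`` / ``AN_<pop>`` pairs (or ``AF_<pop>`` columns, converted to
  counts via the cohort sizes);
* VCF, read through pysam, with per-alt ``AC_<pop>`` INFO fields and
  multi-allelic rows decomposed into biallelic records.

Quality-filter exclusion follows the gnomAD convention: records flagged
``InbreedingCoeff``, ``AC0`` or ``RF`` never reach classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd
import yaml

from .variant_model import (
    CohortSpec,
    Consequence,
    TranscriptModel,
    VariantKey,
    VariantRecord,
    normalize_variant,
)

__all__ = [
    "DEFAULT_EXCLUDED_FLAGS",
    "CLINVAR_ASSERTIONS",
    "HGMD_ASSERTIONS",
    "AssertionTable",
    "TableFormatError",
    "read_variant_table",
    "write_variant_table",
    "apply_quality_filters",
    "partition_by_quality",
    "read_assertion_table",
    "write_assertion_table",
    "read_cohort_registry",
    "write_cohort_registry",
    "read_threshold_config",
    "write_threshold_config",
    "read_transcript_model",
    "write_transcript_model",
    "merge_variant_tables",
]

#: gnomAD-style quality-control filters excluded from every analysis.
DEFAULT_EXCLUDED_FLAGS = frozenset({"InbreedingCoeff", "AC0", "RF"})

CLINVAR_ASSERTIONS = frozenset(
    {
        "Pathogenic",
        "Likely_pathogenic",
        "Uncertain_significance",
        "Likely_benign",
        "Benign",
        "Conflicting",
    }
)
HGMD_ASSERTIONS = frozenset({"DM", "DM?", "DP", "DFP", "FP", "R"})

_FIXED_COLUMNS = ["chrom", "pos", "ref", "alt", "consequence"]
_OPTIONAL_COLUMNS = ["hgvs_c", "hgvs_p", "filters", "revel", "spliceai"]
_MISSING = {"", ".", "NA", "nan", None}


class TableFormatError(ValueError):
    """A table violates the documented dialect."""


@dataclass(frozen=True)
class AssertionTable:
    """Clinical assertions from one source, keyed by normalized variant."""

    source: str  # "clinvar-style" | "hgmd-style"
    entries: Mapping[VariantKey, str] = field(default_factory=dict)


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and pd.isna(value):
        return True
    return str(value).strip() in {"", ".", "NA", "nan"}


def _population_columns(
    columns: Sequence[str], population_map: Optional[Mapping[str, str]]
) -> Dict[str, Tuple[str, str]]:
    """Map population label -> (kind, column) pairs for AC/AN/AF columns."""
    out: Dict[str, Dict[str, str]] = {}
    for col in columns:
        for prefix in ("AC_", "AN_", "AF_"):
            if col.startswith(prefix):
                label = (population_map or {}).get(col, col[len(prefix):])
                out.setdefault(label, {})[prefix[:2]] = col
    return {k: tuple(sorted(v.items())) for k, v in out.items()}  # type: ignore[return-value]


def read_variant_table(
    path,
    dialect: str = "tsv",
    population_map: Optional[Mapping[str, str]] = None,
    cohort_sizes: Optional[Mapping[str, int]] = None,
) -> List[VariantRecord]:
    """Read a per-population allele-count variant table.

    ``population_map`` renames columns to population labels (e.g.
    ``{"AC_eas": "east_asian"}``); otherwise the suffix after ``AC_`` is the
    label.  ``AF_<pop>`` frequency columns are converted to counts as
    ``ac = round(af * 2 * n_individuals)`` and require ``cohort_sizes``.
    """
    if dialect == "tsv":
        return _read_tsv(path, population_map, cohort_sizes)
    if dialect == "vcf":
        return _read_vcf(path, population_map)
    raise TableFormatError(f"unknown dialect {dialect!r}; expected 'tsv' or 'vcf'")


def _read_tsv(path, population_map, cohort_sizes) -> List[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing mandatory columns: {', '.join(missing)}")
    pops = _population_columns(df.columns, population_map)
    if not pops:
        raise TableFormatError(f"{path}: no AC_/AN_/AF_ population columns found")

    records: List[VariantRecord] = []
    for idx, row in df.iterrows():
        key = normalize_variant(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        counts: Dict[str, Tuple[int, int]] = {}
        for label, cols in pops.items():
            cols = dict(cols)
            if "AC" in cols and "AN" in cols:
                ac, an = int(row[cols["AC"]]), int(row[cols["AN"]])
            elif "AF" in cols:
                if cohort_sizes is None or label not in cohort_sizes:
                    raise TableFormatError(
                        f"{path}: AF column for population {label!r} requires "
                        "cohort_sizes to convert frequencies to counts"
                    )
                an = 2 * int(cohort_sizes[label])
                ac = int(round(float(row[cols["AF"]]) * an))
            else:
                raise TableFormatError(
                    f"{path}: population {label!r} needs AC+AN or AF columns"
                )
            if ac > an:
                raise TableFormatError(
                    f"{path}: row {idx + 1} ({key}): AC {ac} > AN {an} for {label!r}"
                )
            counts[label] = (ac, an)
        flags = frozenset(
            f for f in str(row.get("filters", "")).replace(",", ";").split(";")
            if f and not _is_missing(f) and f != "PASS"
        )
        revel = None if _is_missing(row.get("revel")) else float(row["revel"])
        spliceai = None if _is_missing(row.get("spliceai")) else float(row["spliceai"])
        records.append(
            VariantRecord(
                key=key,
                consequence=Consequence(row["consequence"]),
                hgvs_c="" if _is_missing(row.get("hgvs_c")) else str(row["hgvs_c"]),
                hgvs_p="" if _is_missing(row.get("hgvs_p")) else str(row["hgvs_p"]),
                filter_flags=flags,
                pop_counts=counts,
                revel=revel,
                spliceai_delta=spliceai,
            )
        )
    return records


def _read_vcf(path, population_map) -> List[VariantRecord]:
    import pysam

    records: List[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        header_keys = set(vcf.header.info.keys())
        pop_keys = _population_columns(sorted(header_keys), population_map)
        if not pop_keys:
            raise TableFormatError(f"{path}: no AC_/AN_ INFO fields in VCF header")
        for site in vcf:
            flags = frozenset(f for f in site.filter.keys() if f != "PASS")
            alts = site.alts or ()
            for ai, alt in enumerate(alts):  # decompose multi-allelic sites
                counts: Dict[str, Tuple[int, int]] = {}
                for label, cols in pop_keys.items():
                    cols = dict(cols)
                    if "AC" not in cols or "AN" not in cols:
                        continue
                    ac_val = site.info.get(cols["AC"], 0)
                    ac = int(ac_val[ai]) if isinstance(ac_val, tuple) else int(ac_val)
                    an = int(site.info.get(cols["AN"], 0))
                    if ac > an:
                        raise TableFormatError(
                            f"{path}: {site.chrom}:{site.pos} AC {ac} > AN {an} for {label!r}"
                        )
                    counts[label] = (ac, an)

                def _per_alt(name):
                    # pysam raises on INFO keys absent from the header
                    if name not in header_keys:
                        return None
                    val = site.info.get(name)
                    if val is None:
                        return None
                    if isinstance(val, tuple):
                        val = val[ai]
                    return val

                cons = _per_alt("CONSEQUENCE")
                revel = _per_alt("REVEL")
                spliceai = _per_alt("SPLICEAI")
                records.append(
                    VariantRecord(
                        key=normalize_variant(site.chrom, site.pos, site.ref, alt),
                        consequence=Consequence(cons) if cons else Consequence.OTHER,
                        hgvs_c=_per_alt("HGVSC") or "",
                        hgvs_p=_per_alt("HGVSP") or "",
                        filter_flags=flags,
                        pop_counts=counts,
                        revel=None if revel is None else float(revel),
                        spliceai_delta=None if spliceai is None else float(spliceai),
                    )
                )
    return records


def write_variant_table(records: Sequence[VariantRecord], path) -> None:
    """Write records in the canonical TSV dialect (round-trips with the reader)."""
    pops = sorted({p for r in records for p in r.pop_counts})
    rows = []
    for r in records:
        row = {
            "chrom": r.key.chrom,
            "pos": r.key.pos,
            "ref": r.key.ref,
            "alt": r.key.alt,
            "hgvs_c": r.hgvs_c or ".",
            "hgvs_p": r.hgvs_p or ".",
            "consequence": r.consequence.value,
            "filters": ";".join(sorted(r.filter_flags)) or ".",
            "revel": "." if r.revel is None else repr(r.revel),
            "spliceai": "." if r.spliceai_delta is None else repr(r.spliceai_delta),
        }
        for p in pops:
            ac, an = r.pop_counts.get(p, (0, 0))
            row[f"AC_{p}"] = ac
            row[f"AN_{p}"] = an
        rows.append(row)
    cols = _FIXED_COLUMNS[:4] + ["hgvs_c", "hgvs_p", "consequence", "filters", "revel", "spliceai"]
    cols += [c for p in pops for c in (f"AC_{p}", f"AN_{p}")]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def partition_by_quality(
    records: Sequence[VariantRecord],
    excluded_flags: Iterable[str] = DEFAULT_EXCLUDED_FLAGS,
) -> Tuple[List[VariantRecord], List[VariantRecord]]:
    """Split records into (passing, excluded) by quality-filter flags."""
    excluded_flags = frozenset(excluded_flags)
    passing, excluded = [], []
    for r in records:
        (excluded if r.filter_flags & excluded_flags else passing).append(r)
    return passing, excluded


def apply_quality_filters(
    records: Sequence[VariantRecord],
    excluded_flags: Iterable[str] = DEFAULT_EXCLUDED_FLAGS,
) -> List[VariantRecord]:
    """Records whose flags do not intersect the excluded set (order kept)."""
    return partition_by_quality(records, excluded_flags)[0]


def read_assertion_table(path, source: str) -> AssertionTable:
    """Read a (chrom, pos, ref, alt, assertion) TSV into an AssertionTable.

    Keys are normalized; duplicate rows with identical assertions collapse,
    duplicates with conflicting assertions are rejected (ClinVar-style
    conflicts must be pre-resolved to "Conflicting").
    """
    if source not in ("clinvar-style", "hgmd-style", "clinvar", "hgmd"):
        raise TableFormatError(f"unknown assertion source {source!r}")
    vocab = CLINVAR_ASSERTIONS if "clinvar" in source else HGMD_ASSERTIONS
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("chrom", "pos", "ref", "alt", "assertion") if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing mandatory columns: {', '.join(missing)}")
    entries: Dict[VariantKey, str] = {}
    for _, row in df.iterrows():
        key = normalize_variant(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        assertion = row["assertion"]
        if assertion not in vocab:
            raise TableFormatError(
                f"{path}: assertion {assertion!r} not valid for {source} tables"
            )
        if key in entries and entries[key] != assertion:
            raise TableFormatError(
                f"{path}: conflicting assertions for {key}: "
                f"{entries[key]!r} vs {assertion!r}"
            )
        entries[key] = assertion
    norm = "clinvar-style" if "clinvar" in source else "hgmd-style"
    return AssertionTable(source=norm, entries=entries)


def write_assertion_table(table: AssertionTable, path) -> None:
    rows = [
        {"chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt, "assertion": v}
        for k, v in table.entries.items()
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "assertion"]).to_csv(
        path, sep="\t", index=False
    )


def read_cohort_registry(path) -> List[CohortSpec]:
    """Read a YAML cohort registry (ordered list of cohort mappings).

    A pooled cohort whose members are all themselves registered must have
    ``n_individuals`` equal to the sum over its members.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cohorts = [
        CohortSpec(
            name=c["name"],
            n_individuals=int(c["n_individuals"]),
            source=c.get("source", "synthetic"),
            member_populations=tuple(c["member_populations"])
            if c.get("member_populations")
            else None,
        )
        for c in raw
    ]
    by_name = {c.name: c for c in cohorts}
    for c in cohorts:
        if c.member_populations and all(m in by_name for m in c.member_populations):
            total = sum(by_name[m].n_individuals for m in c.member_populations)
            if total != c.n_individuals:
                raise TableFormatError(
                    f"pooled cohort {c.name!r}: n_individuals {c.n_individuals} "
                    f"!= sum over members {total}"
                )
    return cohorts


def write_cohort_registry(cohorts: Sequence[CohortSpec], path) -> None:
    raw = []
    for c in cohorts:
        entry = {"name": c.name, "n_individuals": c.n_individuals, "source": c.source}
        if c.member_populations:
            entry["member_populations"] = list(c.member_populations)
        raw.append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def read_threshold_config(path):
    """Load a ThresholdConfig from YAML."""
    from .acmg_engine import Strength, ThresholdConfig

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for scalar in ("spliceai_min", "pm2_af_max", "ba1_af_min", "bs1_af_min"):
        if scalar in raw:
            kwargs[scalar] = float(raw[scalar])
    if "pm2_strength" in raw:
        kwargs["pm2_strength"] = Strength(raw["pm2_strength"])
    for tiers in ("revel_pathogenic", "revel_benign"):
        if tiers in raw:
            kwargs[tiers] = tuple(
                (float(cut), Strength(strength)) for cut, strength in raw[tiers]
            )
    return ThresholdConfig(**kwargs)


def write_threshold_config(thresholds, path) -> None:
    raw = {
        "spliceai_min": thresholds.spliceai_min,
        "pm2_af_max": thresholds.pm2_af_max,
        "pm2_strength": thresholds.pm2_strength.value,
        "ba1_af_min": thresholds.ba1_af_min,
        "bs1_af_min": thresholds.bs1_af_min,
        "revel_pathogenic": [[c, s.value] for c, s in thresholds.revel_pathogenic],
        "revel_benign": [[c, s.value] for c, s in thresholds.revel_benign],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def read_transcript_model(path) -> TranscriptModel:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return TranscriptModel(
        exon_lengths=tuple(raw["exon_lengths"]),
        cds_start_offset=int(raw["cds_start_offset"]),
        cds_end_offset=int(raw["cds_end_offset"]),
        strand=raw.get("strand", "+"),
    )


def write_transcript_model(transcript: TranscriptModel, path) -> None:
    raw = {
        "exon_lengths": list(transcript.exon_lengths),
        "cds_start_offset": transcript.cds_start_offset,
        "cds_end_offset": transcript.cds_end_offset,
        "strand": transcript.strand,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def merge_variant_tables(tables: Iterable[Sequence[VariantRecord]]) -> List[VariantRecord]:
    """Merge tables from different databases by normalized key.

    Population counts are unioned (a key may appear in gnomAD and KOVA
    tables with disjoint population labels); annotations take the first
    non-empty value; filter flags are unioned.
    """
    merged: Dict[VariantKey, VariantRecord] = {}
    for table in tables:
        for rec in table:
            if rec.key not in merged:
                merged[rec.key] = VariantRecord(
                    key=rec.key,
                    consequence=rec.consequence,
                    hgvs_c=rec.hgvs_c,
                    hgvs_p=rec.hgvs_p,
                    filter_flags=rec.filter_flags,
                    pop_counts=dict(rec.pop_counts),
                    revel=rec.revel,
                    spliceai_delta=rec.spliceai_delta,
                )
                continue
            base = merged[rec.key]
            counts = dict(base.pop_counts)
            for pop, (ac, an) in rec.pop_counts.items():
                if pop in counts and counts[pop] != (ac, an):
                    raise TableFormatError(
                        f"{rec.key}: conflicting counts for population {pop!r} "
                        f"across tables: {counts[pop]} vs {(ac, an)}"
                    )
                counts[pop] = (ac, an)
            merged[rec.key] = VariantRecord(
                key=base.key,
                consequence=base.consequence,
                hgvs_c=base.hgvs_c or rec.hgvs_c,
                hgvs_p=base.hgvs_p or rec.hgvs_p,
                filter_flags=base.filter_flags | rec.filter_flags,
                pop_counts=counts,
                revel=base.revel if base.revel is not None else rec.revel,
                spliceai_delta=base.spliceai_delta
                if base.spliceai_delta is not None
                else rec.spliceai_delta,
            )
    return list(merged.values())
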