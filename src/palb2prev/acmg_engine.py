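"""ACMG/AMP evidence assignment and five-tier combination.

Implements the evidence codes that are computable from population allele
counts, a transcript model, and in-silico scores:

* PVS1 — loss-of-function, strength-modulated by a reduced ClinGen-SVI
  decision tree (NMD 50-nt rule, canonical-splice spliceogenicity check,
  initiation-codon downgrade);
* PP3 / BP4 — computational evidence, REVEL calibrated to the Pejaver et
  al. tiers for missense, SpliceAI delta for non-canonical splice-region
  variants;
* PM2 — absence / extreme rarity (popmax AF cutoff, configurable strength);
* BA1 / BS1 — frequency-based benign evidence (stand-alone / strong).

Everything else (segregation, functional, de-novo, case-control, ...)
requires data a population database does not carry; such codes are accepted
as pre-annotated inputs to :func:`classify_all` but never auto-assigned.

The combination step implements the 2015 combining table with
strength-modified counting: a code contributes at its *assigned* strength,
not its default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .io_formats import AssertionTable
from .variant_model import (
    LOF_CONSEQUENCES,
    CohortSpec,
    Consequence,
    TranscriptModel,
    VariantKey,
    VariantRecord,
    cds_position_from_hgvs,
)

__all__ = [
    "Strength",
    "FiveTierClass",
    "EvidenceAssignment",
    "ThresholdConfig",
    "PATHOGENIC_CODES",
    "BENIGN_CODES",
    "predict_nmd",
    "assign_pvs1",
    "assign_computational",
    "assign_pm2",
    "assign_frequency_benign",
    "combine_evidence",
    "collect_evidence",
    "classify_all",
    "classify_with_audit",
    "qualify_by_source",
]


class Strength(str, Enum):
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"
    STAND_ALONE = "stand_alone"
    NONE = "none"


class FiveTierClass(str, Enum):
    """The five ACMG/AMP tiers, ordered P > LP > VUS > LB > B for reporting."""

    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    UNCERTAIN_SIGNIFICANCE = "uncertain_significance"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"

    @property
    def ordinal(self) -> int:
        """Pathogenicity rank: benign = 0 ... pathogenic = 4."""
        return _ORDER.index(self)

    def __lt__(self, other):  # total order for reporting
        if isinstance(other, FiveTierClass):
            return self.ordinal < other.ordinal
        return NotImplemented


_ORDER = [
    FiveTierClass.BENIGN,
    FiveTierClass.LIKELY_BENIGN,
    FiveTierClass.UNCERTAIN_SIGNIFICANCE,
    FiveTierClass.LIKELY_PATHOGENIC,
    FiveTierClass.PATHOGENIC,
]

PATHOGENIC_CODES = frozenset(
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
)
BENIGN_CODES = frozenset(
    ["BA1"] + [f"BS{i}" for i in range(1, 5)] + [f"BP{i}" for i in range(1, 8)]
)


@dataclass(frozen=True)
class EvidenceAssignment:
    """One evidence code at an assigned strength, with an audit rationale."""

    code: str
    strength: Strength
    rationale: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "strength", Strength(self.strength))
        if self.code in PATHOGENIC_CODES:
            if self.strength is Strength.STAND_ALONE:
                raise ValueError(f"{self.code} cannot carry stand_alone strength")
        elif self.code in BENIGN_CODES:
            if self.code == "BA1":
                if self.strength not in (Strength.STAND_ALONE, Strength.NONE):
                    raise ValueError("BA1 only carries stand_alone strength")
            elif self.strength is Strength.STAND_ALONE:
                raise ValueError(f"{self.code} cannot carry stand_alone strength")
            elif self.strength is Strength.VERY_STRONG:
                raise ValueError(f"benign code {self.code} cannot be very_strong")
        else:
            raise ValueError(f"unknown evidence code {self.code!r}")


# (cutoff, strength) tiers from the Pejaver et al. REVEL calibration;
# pathogenic side is checked top-down with >=, benign side bottom-up with <=.
_DEFAULT_REVEL_PATHOGENIC = (
    (0.932, Strength.STRONG),
    (0.773, Strength.MODERATE),
    (0.644, Strength.SUPPORTING),
)
_DEFAULT_REVEL_BENIGN = (
    (0.016, Strength.STRONG),
    (0.183, Strength.MODERATE),
    (0.290, Strength.SUPPORTING),
)


@dataclass(frozen=True)
class ThresholdConfig:
    """Calibration knobs for the auto-assigned evidence codes.

    spliceai_min
        SpliceAI delta at or above which a variant is treated as
        spliceogenic (default 0.2).
    revel_pathogenic / revel_benign
        ``(cutoff, strength)`` tiers; a score equal to a cutoff earns that
        tier (boundaries inclusive on both sides).
    pm2_af_max / pm2_strength
        Popmax-AF cutoff (inclusive) and strength for PM2.  The ClinGen-style
        default downgrades PM2 to supporting.
    ba1_af_min / bs1_af_min
        Popmax-AF cutoffs (inclusive) for stand-alone / strong benign
        frequency evidence.
    """

    spliceai_min: float = 0.2
    revel_pathogenic: Tuple[Tuple[float, Strength], ...] = _DEFAULT_REVEL_PATHOGENIC
    revel_benign: Tuple[Tuple[float, Strength], ...] = _DEFAULT_REVEL_BENIGN
    pm2_af_max: float = 1e-4
    pm2_strength: Strength = Strength.SUPPORTING
    ba1_af_min: float = 0.05
    bs1_af_min: float = 0.005

    def __post_init__(self) -> None:
        if not (0.0 < self.spliceai_min < 1.0):
            raise ValueError("spliceai_min must lie in (0, 1)")
        p_cuts = [c for c, _ in self.revel_pathogenic]
        b_cuts = [c for c, _ in self.revel_benign]
        if p_cuts != sorted(p_cuts, reverse=True):
            raise ValueError("pathogenic REVEL cutoffs must increase with strength")
        if b_cuts != sorted(b_cuts):
            raise ValueError("benign REVEL cutoffs must decrease with strength")
        if self.bs1_af_min > self.ba1_af_min:
            raise ValueError("bs1_af_min must not exceed ba1_af_min")


def predict_nmd(transcript: TranscriptModel, ptc_transcript_pos: int) -> bool:
    """Is a premature termination codon predicted to trigger NMD?

    True iff the transcript has at least two exons and the PTC lies more
    than 50 nt upstream of the last exon-exon junction.  PTCs in the last
    exon or within 50 nt of the final junction escape NMD, as do all PTCs
    on single-exon transcripts.
    """
    if not transcript.contains_transcript_pos_in_cds(ptc_transcript_pos):
        raise ValueError(
            f"PTC transcript position {ptc_transcript_pos} is outside the CDS "
            f"({transcript.cds_start_offset + 1}..{transcript.cds_end_offset})"
        )
    junction = transcript.last_junction
    if junction is None:
        return False
    return junction - ptc_transcript_pos > 50


def _ptc_transcript_pos(variant: VariantRecord, transcript: TranscriptModel) -> int:
    cds_pos = cds_position_from_hgvs(variant.hgvs_c)
    if cds_pos is None:
        raise ValueError(
            f"{variant.key}: {variant.consequence.value} consequence requires a "
            "coding HGVS annotation to locate the premature termination codon"
        )
    return transcript.transcript_position_of_cds(cds_pos)


def assign_pvs1(
    variant: VariantRecord,
    transcript: Optional[TranscriptModel],
    thresholds: Optional[ThresholdConfig] = None,
) -> EvidenceAssignment:
    """PVS1 strength from the reduced loss-of-function decision tree.

    * nonsense / frameshift: very_strong when NMD is predicted, strong when
      the PTC escapes NMD;
    * canonical +-1/2 splice: very_strong when SpliceAI supports (or does
      not contradict) spliceogenicity, strong otherwise;
    * initiation codon: moderate;
    * anything else: strength none.
    """
    thresholds = thresholds or ThresholdConfig()
    cons = variant.consequence
    if cons in LOF_CONSEQUENCES:
        if transcript is None:
            raise ValueError(
                f"{variant.key}: transcript model required to evaluate NMD for "
                f"{cons.value} variant"
            )
        nmd = predict_nmd(transcript, _ptc_transcript_pos(variant, transcript))
        if nmd:
            return EvidenceAssignment("PVS1", Strength.VERY_STRONG, "LoF, NMD predicted")
        return EvidenceAssignment("PVS1", Strength.STRONG, "LoF, NMD escape")
    if cons is Consequence.CANONICAL_SPLICE:
        delta = variant.spliceai_delta
        if delta is None or delta >= thresholds.spliceai_min:
            why = "canonical splice" + ("" if delta is None else f", SpliceAI {delta:.2f}")
            return EvidenceAssignment("PVS1", Strength.VERY_STRONG, why)
        return EvidenceAssignment(
            "PVS1", Strength.STRONG, f"canonical splice, SpliceAI {delta:.2f} below cutoff"
        )
    if cons is Consequence.INITIATION_CODON:
        return EvidenceAssignment("PVS1", Strength.MODERATE, "initiation codon")
    return EvidenceAssignment("PVS1", Strength.NONE, "not a LoF consequence")


def assign_computational(
    variant: VariantRecord, thresholds: Optional[ThresholdConfig] = None
) -> EvidenceAssignment:
    """PP3 / BP4 from REVEL (missense) or SpliceAI (splice-region).

    Missense scores in the uncalibrated middle zone yield strength none.
    Loss-of-function and canonical-splice consequences never enter this
    path (they are PVS1 territory).
    """
    thresholds = thresholds or ThresholdConfig()
    cons = variant.consequence
    if cons is Consequence.MISSENSE and variant.revel is not None:
        score = variant.revel
        for cutoff, strength in thresholds.revel_pathogenic:
            if score >= cutoff:
                return EvidenceAssignment("PP3", strength, f"REVEL {score:.3f} >= {cutoff}")
        for cutoff, strength in thresholds.revel_benign:
            if score <= cutoff:
                return EvidenceAssignment("BP4", strength, f"REVEL {score:.3f} <= {cutoff}")
        return EvidenceAssignment("PP3", Strength.NONE, "REVEL in uncalibrated zone")
    if (
        cons not in LOF_CONSEQUENCES
        and cons is not Consequence.CANONICAL_SPLICE
        and variant.spliceai_delta is not None
    ):
        delta = variant.spliceai_delta
        if delta >= thresholds.spliceai_min:
            return EvidenceAssignment(
                "PP3", Strength.SUPPORTING, f"SpliceAI {delta:.2f} >= {thresholds.spliceai_min}"
            )
        return EvidenceAssignment(
            "BP4", Strength.SUPPORTING, f"SpliceAI {delta:.2f} < {thresholds.spliceai_min}"
        )
    return EvidenceAssignment("PP3", Strength.NONE, "no applicable in-silico score")


def assign_pm2(
    variant: VariantRecord,
    cohorts: Optional[Sequence[CohortSpec]] = None,
    thresholds: Optional[ThresholdConfig] = None,
) -> EvidenceAssignment:
    """PM2: absent from / extremely rare in population databases.

    Popmax AF is the maximum ac/an over populations with an > 0 (restricted
    to the given non-pooled cohorts when provided); the cutoff is inclusive.
    """
    thresholds = thresholds or ThresholdConfig()
    pops = None
    if cohorts is not None:
        pops = [c.name for c in cohorts if c.member_populations is None]
    af = variant.popmax_af(pops)
    if af <= thresholds.pm2_af_max:
        return EvidenceAssignment(
            "PM2", thresholds.pm2_strength, f"popmax AF {af:.2e} <= {thresholds.pm2_af_max:.0e}"
        )
    return EvidenceAssignment("PM2", Strength.NONE, f"popmax AF {af:.2e} above cutoff")


def assign_frequency_benign(
    variant: VariantRecord,
    cohorts: Optional[Sequence[CohortSpec]] = None,
    thresholds: Optional[ThresholdConfig] = None,
) -> EvidenceAssignment:
    """BA1 (stand-alone) / BS1 (strong) from popmax allele frequency."""
    thresholds = thresholds or ThresholdConfig()
    pops = None
    if cohorts is not None:
        pops = [c.name for c in cohorts if c.member_populations is None]
    af = variant.popmax_af(pops)
    if af >= thresholds.ba1_af_min:
        return EvidenceAssignment("BA1", Strength.STAND_ALONE, f"popmax AF {af:.3f}")
    if af >= thresholds.bs1_af_min:
        return EvidenceAssignment("BS1", Strength.STRONG, f"popmax AF {af:.3f}")
    return EvidenceAssignment("BS1", Strength.NONE, f"popmax AF {af:.2e} below cutoff")


def combine_evidence(assignments: Iterable[EvidenceAssignment]) -> FiveTierClass:
    """Combine evidence into a five-tier class (2015 combining table).

    Counting is strength-modified: each code contributes at its assigned
    strength.  Pathogenic rows (vs = very_strong, s = strong, m = moderate,
    p = supporting)::

        P:  vs>=2 | vs & (s>=1 | m>=2 | m&p | p>=2) | s>=2
            | s & (m>=3 | m>=2&p>=2 | m>=1&p>=4)
        LP: vs&m | s&(1<=m<=2) | s&p>=2 | m>=3 | m>=2&p>=2 | m>=1&p>=4

    Benign side: BA1 or >= 2 strong -> benign; any two benign codes
    (strong/moderate/supporting) -> likely benign.  Meeting rules on both
    sides, or on neither, yields uncertain significance.
    """
    assignments = list(assignments)
    seen: Set[str] = set()
    for a in assignments:
        if a.code in seen:
            raise ValueError(f"duplicate evidence code {a.code}")
        seen.add(a.code)
    active = [a for a in assignments if a.strength is not Strength.NONE]

    vs = sum(1 for a in active if a.code in PATHOGENIC_CODES and a.strength is Strength.VERY_STRONG)
    s = sum(1 for a in active if a.code in PATHOGENIC_CODES and a.strength is Strength.STRONG)
    m = sum(1 for a in active if a.code in PATHOGENIC_CODES and a.strength is Strength.MODERATE)
    p = sum(1 for a in active if a.code in PATHOGENIC_CODES and a.strength is Strength.SUPPORTING)
    ba = any(a.code == "BA1" and a.strength is Strength.STAND_ALONE for a in active)
    bs = sum(1 for a in active if a.code in BENIGN_CODES and a.strength is Strength.STRONG)
    b_any = sum(
        1
        for a in active
        if a.code in BENIGN_CODES
        and a.strength in (Strength.STRONG, Strength.MODERATE, Strength.SUPPORTING)
    )

    pathogenic = (
        vs >= 2
        or (vs >= 1 and (s >= 1 or m >= 2 or (m >= 1 and p >= 1) or p >= 2))
        or s >= 2
        or (s >= 1 and (m >= 3 or (m >= 2 and p >= 2) or (m >= 1 and p >= 4)))
    )
    likely_pathogenic = (
        (vs >= 1 and m >= 1)
        or (s >= 1 and m >= 1)
        or (s >= 1 and p >= 2)
        or m >= 3
        or (m >= 2 and p >= 2)
        or (m >= 1 and p >= 4)
    )
    benign = ba or bs >= 2
    likely_benign = b_any >= 2

    path_met = pathogenic or likely_pathogenic
    benign_met = benign or likely_benign
    if path_met and benign_met:
        return FiveTierClass.UNCERTAIN_SIGNIFICANCE
    if pathogenic:
        return FiveTierClass.PATHOGENIC
    if likely_pathogenic:
        return FiveTierClass.LIKELY_PATHOGENIC
    if benign:
        return FiveTierClass.BENIGN
    if likely_benign:
        return FiveTierClass.LIKELY_BENIGN
    return FiveTierClass.UNCERTAIN_SIGNIFICANCE


def collect_evidence(
    record: VariantRecord,
    transcript: Optional[TranscriptModel],
    thresholds: Optional[ThresholdConfig] = None,
    extra: Iterable[EvidenceAssignment] = (),
) -> List[EvidenceAssignment]:
    """Auto-assign the computable codes for one record, plus pre-annotated ones.

    PVS1 and the computational path are mutually exclusive: a LoF,
    canonical-splice or initiation-codon consequence takes the PVS1 branch
    and never also receives PP3.
    """
    thresholds = thresholds or ThresholdConfig()
    out: List[EvidenceAssignment] = []
    pvs1 = assign_pvs1(record, transcript, thresholds)
    if pvs1.strength is not Strength.NONE:
        out.append(pvs1)
    else:
        comp = assign_computational(record, thresholds)
        if comp.strength is not Strength.NONE:
            out.append(comp)
    pm2 = assign_pm2(record, None, thresholds)
    if pm2.strength is not Strength.NONE:
        out.append(pm2)
    else:
        freq = assign_frequency_benign(record, None, thresholds)
        if freq.strength is not Strength.NONE:
            out.append(freq)
    for a in extra:
        if a.strength is not Strength.NONE and a.code not in {x.code for x in out}:
            out.append(a)
    return out


def classify_with_audit(
    records: Sequence[VariantRecord],
    transcript: Optional[TranscriptModel],
    thresholds: Optional[ThresholdConfig] = None,
    extra_evidence: Optional[Mapping[VariantKey, Iterable[EvidenceAssignment]]] = None,
) -> List[Tuple[VariantRecord, List[EvidenceAssignment], FiveTierClass]]:
    """Classify every record; returns (record, evidence, class) audit rows."""
    thresholds = thresholds or ThresholdConfig()
    extra_evidence = extra_evidence or {}
    rows = []
    for rec in records:
        evidence = collect_evidence(
            rec, transcript, thresholds, extra_evidence.get(rec.key, ())
        )
        rows.append((rec, evidence, combine_evidence(evidence)))
    return rows


def classify_all(
    records: Sequence[VariantRecord],
    transcript: Optional[TranscriptModel],
    thresholds: Optional[ThresholdConfig] = None,
    extra_evidence: Optional[Mapping[VariantKey, Iterable[EvidenceAssignment]]] = None,
) -> Dict[VariantKey, FiveTierClass]:
    """Deterministic map from variant key to five-tier class."""
    return {
        rec.key: cls
        for rec, _, cls in classify_with_audit(records, transcript, thresholds, extra_evidence)
    }


_QUALIFYING_CLINVAR = {"Pathogenic", "Likely_pathogenic"}
_QUALIFYING_ACMG = {FiveTierClass.PATHOGENIC, FiveTierClass.LIKELY_PATHOGENIC}


def qualify_by_source(
    records: Sequence[VariantRecord],
    classifications: Mapping[VariantKey, FiveTierClass],
    assertions: Optional[AssertionTable],
    source: str,
) -> Set[VariantKey]:
    """Variant keys that qualify for prevalence under one evidence source.

    * ``acmg``: classified pathogenic / likely pathogenic by the engine;
    * ``clinvar``: asserted Pathogenic / Likely_pathogenic (Conflicting and
      Uncertain_significance excluded);
    * ``hgmd``: asserted DM (DM? excluded).
    """
    keys = {r.key for r in records}
    if source == "acmg":
        return {k for k in keys if classifications.get(k) in _QUALIFYING_ACMG}
    if source == "clinvar":
        if assertions is None:
            raise ValueError("clinvar source requires an assertion table")
        return {k for k in keys if assertions.entries.get(k) in _QUALIFYING_CLINVAR}
    if source == "hgmd":
        if assertions is None:
            raise ValueError("hgmd source requires an assertion table")
        return {k for k in keys if assertions.entries.get(k) == "DM"}
    raise ValueError(f"unknown qualification source {source!r}; expected acmg|clinvar|hgmd")
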