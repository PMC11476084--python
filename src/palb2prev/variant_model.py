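"""Core domain types shared by every pipeline stage.

Variant identity is a normalized, VCF-style (1-based, anchor-base) tuple of
``(chrom, pos, ref, alt)``.  All cross-database joins — population tables,
ClinVar-style and HGMD-style assertion tables — go through
:class:`VariantKey` equality, never through HGVS strings, because HGVS
dialects drift between sources.  HGVS annotations are carried along purely
as labels (and, for coding variants, as the source of the CDS coordinate the
NMD rule needs).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence, Tuple

__all__ = [
    "Consequence",
    "LOF_CONSEQUENCES",
    "VariantKey",
    "VariantRecord",
    "CohortSpec",
    "TranscriptModel",
    "normalize_variant",
    "cds_position_from_hgvs",
]

_ALLELE_RE = re.compile(r"^[ACGT]+$")
_HGVS_CDS_RE = re.compile(r"c\.(\d+)")


class Consequence(str, Enum):
    """Molecular consequence of a variant on the canonical transcript."""

    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    CANONICAL_SPLICE = "canonical_splice"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    INITIATION_CODON = "initiation_codon"
    OTHER = "other"


#: Consequences that introduce a premature termination codon and therefore
#: enter the loss-of-function (PVS1) decision tree via the NMD rule.
LOF_CONSEQUENCES = frozenset({Consequence.NONSENSE, Consequence.FRAMESHIFT})


def _check_allele(name: str, allele: str) -> None:
    if not isinstance(allele, str) or not _ALLELE_RE.match(allele):
        raise ValueError(
            f"{name} allele {allele!r} is not a non-empty uppercase A/C/G/T string"
        )


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized identity of a biallelic variant (1-based, VCF-style)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        _check_allele("ref", self.ref)
        _check_allele("alt", self.alt)
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref!r})")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")

    def __str__(self) -> str:  # used in audit logs and error messages
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def normalize_variant(chrom, pos: int, ref: str, alt: str) -> VariantKey:
    """Return the left-aligned, parsimonious :class:`VariantKey`.

    Shared trailing bases are trimmed first, then shared leading bases
    (advancing ``pos``), always retaining at least one base on each side so
    indels keep their anchor base.  The operation is idempotent, and any two
    representations of the same edit that differ only by shared flanking
    bases normalize to the same key.
    """
    chrom = str(chrom)
    _check_allele("ref", ref)
    _check_allele("alt", alt)
    if ref == alt:
        raise ValueError(f"ref and alt are identical ({ref!r}); not a variant")
    if pos < 1:
        raise ValueError(f"pos must be >= 1, got {pos}")
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(chrom, pos, ref, alt)


def cds_position_from_hgvs(hgvs_c: str) -> Optional[int]:
    """Leading CDS coordinate of a coding HGVS string, or None.

    ``"c.1048C>T" -> 1048``; intronic offsets (``c.2834+2T>C``) return the
    last exonic base (2834).  Frameshift PTC positions are approximated by
    the variant position itself — adequate for a toy-transcript NMD call.
    """
    m = _HGVS_CDS_RE.search(hgvs_c or "")
    return int(m.group(1)) if m else None


@dataclass
class VariantRecord:
    """One biallelic variant with per-population allele counts and scores.

    ``pop_counts`` maps a population label to an ``(ac, an)`` pair: the
    alternate-allele count and the total number of called alleles in that
    population.  ``revel`` is only meaningful for missense variants;
    ``spliceai_delta`` is the maximum SpliceAI delta score.
    """

    key: VariantKey
    consequence: Consequence = Consequence.OTHER
    hgvs_c: str = ""
    hgvs_p: str = ""
    filter_flags: frozenset = frozenset()
    pop_counts: Mapping[str, Tuple[int, int]] = field(default_factory=dict)
    revel: Optional[float] = None
    spliceai_delta: Optional[float] = None

    def __post_init__(self) -> None:
        self.consequence = Consequence(self.consequence)
        self.filter_flags = frozenset(self.filter_flags)
        for pop, (ac, an) in self.pop_counts.items():
            if not (0 <= ac <= an):
                raise ValueError(
                    f"{self.key}: population {pop!r} has ac={ac}, an={an}; "
                    "0 <= ac <= an is required"
                )
        if self.revel is not None:
            if self.consequence is not Consequence.MISSENSE:
                raise ValueError(
                    f"{self.key}: REVEL score given for non-missense consequence "
                    f"{self.consequence.value}"
                )
            if not (0.0 <= self.revel <= 1.0):
                raise ValueError(f"{self.key}: REVEL {self.revel} outside [0, 1]")
        if self.spliceai_delta is not None and not (0.0 <= self.spliceai_delta <= 1.0):
            raise ValueError(
                f"{self.key}: SpliceAI delta {self.spliceai_delta} outside [0, 1]"
            )

    def ac(self, population: str) -> int:
        """Alternate allele count in ``population`` (0 if absent)."""
        return self.pop_counts.get(population, (0, 0))[0]

    def popmax_af(self, populations: Optional[Sequence[str]] = None) -> float:
        """Maximum allele frequency across populations with an > 0."""
        pops = populations if populations is not None else self.pop_counts.keys()
        afs = [
            ac / an
            for pop in pops
            for ac, an in [self.pop_counts.get(pop, (0, 0))]
            if an > 0
        ]
        return max(afs, default=0.0)


@dataclass(frozen=True)
class CohortSpec:
    """A named population with its number of sequenced individuals.

    A pooled cohort (e.g. "east_asian" over Korean + Japanese + other East
    Asian, or "all_korean" over three databases) lists the population labels
    it pools in ``member_populations``; its ``n_individuals`` must equal the
    sum over the members when those members are themselves registered.
    """

    name: str
    n_individuals: int
    source: str = "synthetic"
    member_populations: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError(
                f"cohort {self.name!r}: n_individuals must be >= 1, "
                f"got {self.n_individuals}"
            )
        if self.member_populations is not None:
            object.__setattr__(
                self, "member_populations", tuple(self.member_populations)
            )

    @property
    def populations(self) -> Tuple[str, ...]:
        """Population labels whose allele counts this cohort aggregates."""
        return self.member_populations or (self.name,)


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure of the transcript used by the PVS1 / NMD rule.

    Transcript coordinates are 1-based.  ``cds_start_offset`` is the number
    of 5'-UTR bases (so CDS position 1 sits at transcript position
    ``cds_start_offset + 1``); ``cds_end_offset`` is the transcript position
    of the last CDS base.
    """

    exon_lengths: Tuple[int, ...]
    cds_start_offset: int
    cds_end_offset: int
    strand: str = "+"

    def __post_init__(self) -> None:
        object.__setattr__(self, "exon_lengths", tuple(int(x) for x in self.exon_lengths))
        if not self.exon_lengths or any(x < 1 for x in self.exon_lengths):
            raise ValueError("all exon lengths must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.cds_start_offset < self.cds_end_offset <= self.length):
            raise ValueError(
                f"CDS boundaries ({self.cds_start_offset}, {self.cds_end_offset}) "
                f"inconsistent with transcript length {self.length}"
            )

    @property
    def length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def n_exons(self) -> int:
        return len(self.exon_lengths)

    @property
    def last_junction(self) -> Optional[int]:
        """Transcript position of the last exon-exon junction (None if single-exon).

        The junction sits immediately after the last base of the penultimate
        exon.
        """
        if self.n_exons < 2:
            return None
        return sum(self.exon_lengths[:-1])

    def transcript_position_of_cds(self, cds_pos: int) -> int:
        """Map a CDS coordinate (c. position) to a transcript position."""
        tpos = self.cds_start_offset + cds_pos
        if not (self.cds_start_offset < tpos <= self.cds_end_offset):
            raise ValueError(
                f"CDS position {cds_pos} falls outside the CDS "
                f"(1..{self.cds_end_offset - self.cds_start_offset})"
            )
        return tpos

    def contains_transcript_pos_in_cds(self, tpos: int) -> bool:
        return self.cds_start_offset < tpos <= self.cds_end_offset
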