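"""Evidence assignment, five-tier combination, and qualification semantics."""

import itertools

import pytest

from palb2prev.acmg_engine import (
    BENIGN_CODES,
    PATHOGENIC_CODES,
    EvidenceAssignment,
    FiveTierClass,
    Strength,
    ThresholdConfig,
    assign_computational,
    assign_frequency_benign,
    assign_pm2,
    assign_pvs1,
    classify_all,
    classify_with_audit,
    combine_evidence,
    predict_nmd,
    qualify_by_source,
)
from palb2prev.io_formats import AssertionTable
from palb2prev.synthetic_data import TOY_TRANSCRIPT
from palb2prev.variant_model import (
    TranscriptModel,
    VariantKey,
    VariantRecord,
    normalize_variant,
)

P = FiveTierClass.PATHOGENIC
LP = FiveTierClass.LIKELY_PATHOGENIC
VUS = FiveTierClass.UNCERTAIN_SIGNIFICANCE
LB = FiveTierClass.LIKELY_BENIGN
B = FiveTierClass.BENIGN


def _rec(consequence, hgvs_c="", revel=None, spliceai=None, counts=None):
    return VariantRecord(
        key=VariantKey("16", 1000, "C", "T"),
        consequence=consequence,
        hgvs_c=hgvs_c,
        revel=revel,
        spliceai_delta=spliceai,
        pop_counts=counts or {},
    )


# ---------------------------------------------------------------------------
# NMD rule and PVS1 decision tree


class TestPredictNmd:
    def test_ptc_far_upstream_of_last_junction_triggers_nmd(self, two_exon_transcript):
        # junction at 200; PTC at 100 is 100 nt upstream (> 50)
        assert predict_nmd(two_exon_transcript, 100) is True

    def test_ptc_within_50nt_of_last_junction_escapes(self, two_exon_transcript):
        assert predict_nmd(two_exon_transcript, 180) is False  # 20 nt upstream
        assert predict_nmd(two_exon_transcript, 150) is False  # exactly 50 nt

    def test_single_exon_transcript_never_triggers_nmd(self):
        t = TranscriptModel(exon_lengths=(300,), cds_start_offset=0, cds_end_offset=300)
        for pos in (1, 150, 300):
            assert predict_nmd(t, pos) is False

    def test_position_outside_cds_is_rejected(self, two_exon_transcript):
        with pytest.raises(ValueError):
            predict_nmd(two_exon_transcript, 301)


class TestAssignPvs1:
    def test_nmd_positive_nonsense_is_very_strong(self, toy_transcript):
        a = assign_pvs1(_rec("nonsense", hgvs_c="c.1048C>T"), toy_transcript)
        assert (a.code, a.strength) == ("PVS1", Strength.VERY_STRONG)

    def test_nmd_escaping_frameshift_is_strong(self, toy_transcript):
        # CDS 3267 -> transcript 3317, inside the last exon
        a = assign_pvs1(_rec("frameshift", hgvs_c="c.3267_3268del"), toy_transcript)
        assert a.strength is Strength.STRONG

    def test_missense_gets_no_pvs1(self, toy_transcript):
        assert assign_pvs1(_rec("missense", revel=0.9), toy_transcript).strength is Strength.NONE

    def test_canonical_splice_very_strong_when_spliceai_supports(self, toy_transcript):
        a = assign_pvs1(_rec("canonical_splice", spliceai=0.25), toy_transcript)
        assert a.strength is Strength.VERY_STRONG
        # absent score: spliceogenicity not contradicted
        a = assign_pvs1(_rec("canonical_splice"), toy_transcript)
        assert a.strength is Strength.VERY_STRONG

    def test_canonical_splice_downgraded_below_spliceai_cutoff(self, toy_transcript):
        a = assign_pvs1(_rec("canonical_splice", spliceai=0.19), toy_transcript)
        assert a.strength is Strength.STRONG

    def test_initiation_codon_is_moderate(self, toy_transcript):
        a = assign_pvs1(_rec("initiation_codon", hgvs_c="c.2T>C"), toy_transcript)
        assert a.strength is Strength.MODERATE

    def test_lof_without_transcript_is_rejected(self):
        with pytest.raises(ValueError):
            assign_pvs1(_rec("nonsense", hgvs_c="c.100C>T"), None)


# ---------------------------------------------------------------------------
# computational (REVEL / SpliceAI) and frequency evidence


class TestComputationalEvidence:
    @pytest.mark.parametrize(
        "revel, code, strength",
        [
            (0.95, "PP3", Strength.STRONG),
            (0.932, "PP3", Strength.STRONG),  # pathogenic boundary inclusive
            (0.80, "PP3", Strength.MODERATE),
            (0.644, "PP3", Strength.SUPPORTING),
            (0.50, "PP3", Strength.NONE),  # uncalibrated middle zone
            (0.290, "BP4", Strength.SUPPORTING),  # benign boundary inclusive
            (0.10, "BP4", Strength.MODERATE),
            (0.01, "BP4", Strength.STRONG),
        ],
    )
    def test_revel_tier_lookup(self, revel, code, strength):
        a = assign_computational(_rec("missense", revel=revel))
        if strength is Strength.NONE:
            assert a.strength is Strength.NONE
        else:
            assert (a.code, a.strength) == (code, strength)

    def test_splice_region_uses_spliceai_threshold(self):
        a = assign_computational(_rec("other", spliceai=0.25))
        assert (a.code, a.strength) == ("PP3", Strength.SUPPORTING)
        a = assign_computational(_rec("other", spliceai=0.19))
        assert (a.code, a.strength) == ("BP4", Strength.SUPPORTING)

    def test_score_out_of_range_is_rejected(self):
        with pytest.raises(ValueError):
            _rec("missense", revel=1.5)


class TestFrequencyEvidence:
    def test_absent_variant_earns_pm2(self):
        a = assign_pm2(_rec("nonsense", counts={"eas": (0, 1000)}))
        assert (a.code, a.strength) == ("PM2", Strength.SUPPORTING)

    def test_common_variant_gets_no_pm2(self):
        assert assign_pm2(_rec("missense", counts={"eas": (10, 1000)})).strength is Strength.NONE

    def test_pm2_boundary_is_inclusive(self):
        thr = ThresholdConfig(pm2_af_max=1e-3)
        a = assign_pm2(_rec("nonsense", counts={"eas": (1, 1000)}), thresholds=thr)
        assert a.strength is thr.pm2_strength

    def test_ba1_and_bs1_cutoffs(self):
        assert assign_frequency_benign(_rec("missense", counts={"x": (60, 1000)})).code == "BA1"
        a = assign_frequency_benign(_rec("missense", counts={"x": (10, 1000)}))
        assert (a.code, a.strength) == ("BS1", Strength.STRONG)
        assert (
            assign_frequency_benign(_rec("missense", counts={"x": (1, 1000)})).strength
            is Strength.NONE
        )


# ---------------------------------------------------------------------------
# evidence combination: examples, brute-force oracle, monotonicity


def _mk(counts):
    """Build assignments with distinct codes for a strength-count vector.

    counts = (vs, s, m, p, ba, bs, bp) on the pathogenic / benign sides.
    """
    vs, s, m, p, ba, bs, bp = counts
    path_pool = iter(sorted(PATHOGENIC_CODES - {"PVS1"}))
    benign_pool = iter(sorted(BENIGN_CODES - {"BA1"}))
    out = []
    for _ in range(vs):
        out.append(EvidenceAssignment(next(path_pool), Strength.VERY_STRONG))
    for _ in range(s):
        out.append(EvidenceAssignment(next(path_pool), Strength.STRONG))
    for _ in range(m):
        out.append(EvidenceAssignment(next(path_pool), Strength.MODERATE))
    for _ in range(p):
        out.append(EvidenceAssignment(next(path_pool), Strength.SUPPORTING))
    if ba:
        out.append(EvidenceAssignment("BA1", Strength.STAND_ALONE))
    for _ in range(bs):
        out.append(EvidenceAssignment(next(benign_pool), Strength.STRONG))
    for _ in range(bp):
        out.append(EvidenceAssignment(next(benign_pool), Strength.SUPPORTING))
    return out


# Rule rows of the 2015 combining table as minimal requirement vectors
# (vs, s, m, p); a counts vector satisfies a row by componentwise dominance.
_P_ROWS = [
    (2, 0, 0, 0),
    (1, 1, 0, 0), (1, 0, 2, 0), (1, 0, 1, 1), (1, 0, 0, 2),
    (0, 2, 0, 0),
    (0, 1, 3, 0), (0, 1, 2, 2), (0, 1, 1, 4),
]
_LP_ROWS = [
    (1, 0, 1, 0),
    (0, 1, 1, 0), (0, 1, 0, 2),
    (0, 0, 3, 0), (0, 0, 2, 2), (0, 0, 1, 4),
]


def oracle_combine(counts):
    """Enumerate every rule row of the combining table (independent oracle)."""
    vs, s, m, p, ba, bs, bp = counts
    vec = (vs, s, m, p)
    dominates = lambda row: all(v >= r for v, r in zip(vec, row))
    pathogenic = any(dominates(row) for row in _P_ROWS)
    likely_path = any(dominates(row) for row in _LP_ROWS)
    benign = bool(ba) or bs >= 2
    likely_benign = bs + bp >= 2
    if (pathogenic or likely_path) and (benign or likely_benign):
        return VUS
    if pathogenic:
        return P
    if likely_path:
        return LP
    if benign:
        return B
    if likely_benign:
        return LB
    return VUS


def all_strength_vectors(max_total):
    for total in range(max_total + 1):
        for vs in range(total + 1):
            for s in range(total - vs + 1):
                for m in range(total - vs - s + 1):
                    for p in range(total - vs - s - m + 1):
                        rest = total - vs - s - m - p
                        for ba in range(min(rest, 1) + 1):
                            for bs in range(min(rest - ba, 4) + 1):
                                bp = rest - ba - bs
                                if bp <= 6:
                                    yield (vs, s, m, p, ba, bs, bp)


class TestCombineEvidence:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((1, 0, 1, 0, 0, 0, 0), LP),  # PVS1 + one moderate
            ((1, 1, 0, 1, 0, 0, 0), P),  # very strong + strong (+ supporting)
            ((0, 0, 0, 0, 0, 0, 0), VUS),  # no evidence at all
            ((1, 0, 0, 1, 0, 0, 0), VUS),  # VS + single supporting: no row
            ((0, 1, 0, 2, 0, 0, 0), LP),
            ((0, 0, 0, 0, 1, 0, 0), B),  # BA1 stand-alone
            ((0, 0, 0, 0, 0, 1, 1), LB),
            ((1, 0, 1, 0, 0, 1, 1), VUS),  # conflicting evidence
        ],
    )
    def test_combination_examples(self, counts, expected):
        assert combine_evidence(_mk(counts)) is expected

    def test_agrees_with_rule_table_oracle_for_all_multisets_up_to_six(self):
        checked = 0
        for counts in all_strength_vectors(6):
            assert combine_evidence(_mk(counts)) is oracle_combine(counts), counts
            checked += 1
        assert checked > 1000

    def test_adding_pathogenic_evidence_never_lowers_class(self):
        """Monotonicity on benign-free evidence sets of size <= 5."""
        for counts in all_strength_vectors(4):
            vs, s, m, p, ba, bs, bp = counts
            if ba or bs or bp:
                continue
            base = combine_evidence(_mk(counts)).ordinal
            for bump in range(4):  # add one code at each pathogenic strength
                extra = list(counts)
                extra[bump] += 1
                assert combine_evidence(_mk(tuple(extra))).ordinal >= base

    def test_duplicate_codes_are_rejected(self):
        dup = [
            EvidenceAssignment("PM2", Strength.MODERATE),
            EvidenceAssignment("PM2", Strength.SUPPORTING),
        ]
        with pytest.raises(ValueError):
            combine_evidence(dup)

    def test_pathogenic_codes_cannot_be_stand_alone(self):
        with pytest.raises(ValueError):
            EvidenceAssignment("PS1", Strength.STAND_ALONE)
        with pytest.raises(ValueError):
            EvidenceAssignment("BA1", Strength.STRONG)


# ---------------------------------------------------------------------------
# classify_all composition properties


def _catalogue_records():
    nonsense = VariantRecord(
        key=VariantKey("16", 100, "C", "T"),
        consequence="nonsense",
        hgvs_c="c.500C>T",
        pop_counts={"pop": (1, 20000)},
    )
    common_missense = VariantRecord(
        key=VariantKey("16", 200, "A", "G"),
        consequence="missense",
        hgvs_c="c.700A>G",
        revel=0.1,
        pop_counts={"pop": (300, 20000)},
    )
    rare_missense = VariantRecord(
        key=VariantKey("16", 300, "G", "C"),
        consequence="missense",
        hgvs_c="c.900G>C",
        revel=0.5,
        pop_counts={"pop": (2, 20000)},
    )
    return [nonsense, common_missense, rare_missense]


class TestClassifyAll:
    def test_composition_on_mixed_records(self, toy_transcript):
        thr = ThresholdConfig(pm2_af_max=1e-4, pm2_strength=Strength.MODERATE)
        classes = classify_all(_catalogue_records(), toy_transcript, thr)
        nonsense, common, rare = (r.key for r in _catalogue_records())
        assert classes[nonsense] is LP  # PVS1 very strong + PM2 moderate
        assert classes[common] is LB  # BS1 strong + BP4 moderate
        assert classes[rare] is VUS

    def test_empty_input_yields_empty_map(self, toy_transcript):
        assert classify_all([], toy_transcript) == {}

    def test_permutation_invariance(self, toy_transcript):
        recs = _catalogue_records()
        forward = classify_all(recs, toy_transcript)
        backward = classify_all(list(reversed(recs)), toy_transcript)
        assert forward == backward

    def test_pvs1_and_pp3_never_coassigned(self, bundle, kept_records):
        for rec, evidence, _ in classify_with_audit(
            kept_records, bundle.transcript, bundle.thresholds
        ):
            codes = {a.code for a in evidence}
            assert not ({"PVS1", "PP3"} <= codes), rec.key


# ---------------------------------------------------------------------------
# qualification per evidence source


class TestQualifyBySource:
    def _keys(self):
        return [VariantKey("16", i, "A", "G") for i in (10, 20, 30)]

    def _records(self):
        return [
            VariantRecord(key=k, consequence="missense", pop_counts={"x": (1, 100)})
            for k in self._keys()
        ]

    def test_clinvar_filters_to_pathogenic_assertions(self):
        k1, k2, k3 = self._keys()
        table = AssertionTable(
            "clinvar-style",
            {k1: "Pathogenic", k2: "Conflicting", k3: "Likely_benign"},
        )
        got = qualify_by_source(self._records(), {}, table, "clinvar")
        assert got == {k1}

    def test_hgmd_counts_dm_only(self):
        k1, k2, k3 = self._keys()
        table = AssertionTable("hgmd-style", {k1: "DM", k2: "DM?", k3: "DP"})
        assert qualify_by_source(self._records(), {}, table, "hgmd") == {k1}

    def test_acmg_takes_p_and_lp_classes(self):
        k1, k2, k3 = self._keys()
        classes = {k1: LP, k2: VUS, k3: P}
        got = qualify_by_source(self._records(), classes, None, "acmg")
        assert got == {k1, k3}

    def test_unknown_source_rejected(self):
        with pytest.raises(ValueError):
            qualify_by_source([], {}, None, "intervar")
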