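"""Nuclear qualification rules: predicates, collapsing, and cohort runs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paroxscore.models import (
    Category,
    ClinVarCall,
    Consequence,
    GenePanel,
    QualificationThresholds,
)
from paroxscore.qualification import (
    aggregate_clinvar,
    collapse_cosegregating,
    detect_recessive_candidates,
    is_clinical,
    is_coding,
    is_plp,
    is_qualifying,
    is_recorded,
    qualify_cohort,
)

from conftest import make_variant


class TestCodingPredicate:
    @pytest.mark.parametrize(
        "consequence, splice_ada, expected",
        [
            (Consequence.MISSENSE, None, True),
            (Consequence.NONSENSE, None, True),
            (Consequence.FRAMESHIFT, None, True),
            (Consequence.INFRAME_INDEL, None, True),
            (Consequence.INTRONIC, 0.7, True),   # predicted splice site
            (Consequence.INTRONIC, 0.6, False),  # boundary is strict
            (Consequence.INTRONIC, None, False),
            (Consequence.UTR, None, False),
            (Consequence.SYNONYMOUS, None, False),
            (Consequence.INTERGENIC, None, False),
        ],
    )
    def test_examples(self, consequence, splice_ada, expected):
        v = make_variant(consequence=consequence, splice_ada=splice_ada)
        assert is_coding(v) is expected

    def test_splice_rf_also_counts(self):
        assert is_coding(make_variant(consequence=Consequence.SYNONYMOUS, splice_rf=0.61))


class TestRecordedPredicate:
    @pytest.mark.parametrize(
        "af, expected",
        [(0.05, True), (0.10, False), (0.099, True), (0.5, False), (None, True)],
    )
    def test_recording_threshold_strict(self, af, expected):
        assert is_recorded(make_variant(af_nfe=af)) is expected


class TestQualifyingPredicate:
    @pytest.mark.parametrize(
        "af, phylop, mammal, expected",
        [
            (0.001, 2.3, None, True),
            (0.03, 2.3, None, False),    # above the 2% cutoff
            (0.02, 2.3, None, False),    # boundary is strict
            (0.001, 0.2, 95.0, True),    # mammalian-alignment fallback
            (0.001, 0.2, 89.9, False),
            (0.001, 1.5, None, True),    # conservation boundary inclusive
            (0.001, None, None, False),
            (None, 2.3, None, True),     # absent frequency = rare
        ],
    )
    def test_examples(self, af, phylop, mammal, expected):
        v = make_variant(af_nfe=af, phylop=phylop, mammal_match_pct=mammal)
        assert is_qualifying(v) is expected

    def test_noncoding_never_qualifies_without_splice_evidence(self):
        v = make_variant(consequence=Consequence.UTR, af_nfe=0.001, phylop=3.0)
        assert not is_qualifying(v)

    @pytest.mark.parametrize("flag", [True, False])
    def test_repeat_expansion_qualifies_by_flag_only(self, flag):
        v = make_variant(
            consequence=Consequence.REPEAT_EXPANSION,
            af_nfe=None,
            phylop=None,
            coding_equivalent=flag,
        )
        assert is_qualifying(v) is flag

    def test_population_setting_is_honoured(self):
        t = QualificationThresholds(comparison_population="afr")
        v = make_variant(af_nfe=0.5)
        v.allele_freq["afr"] = 0.001
        assert is_qualifying(v, t)


class TestClinVarAggregation:
    @pytest.mark.parametrize(
        "calls, lof, expected",
        [
            ([ClinVarCall.P, ClinVarCall.VUS], False, True),       # half P
            ([ClinVarCall.VUS, ClinVarCall.VUS, ClinVarCall.LP], False, False),
            ([], True, True),                                      # nonsense/frameshift
            ([], False, False),
            ([ClinVarCall.LP], False, True),
            ([ClinVarCall.B, ClinVarCall.LB], False, False),
            ([ClinVarCall.P, ClinVarCall.LP, ClinVarCall.VUS, ClinVarCall.B], False, True),
        ],
    )
    def test_majority_rule(self, calls, lof, expected):
        assert aggregate_clinvar(calls, lof) is expected


class TestClinicalPredicate:
    def test_matching_diagnosis(self, small_panel, phenotype_factory):
        v = make_variant(gene="CACNA1A")
        p = phenotype_factory(diagnoses={"EAx"})
        assert is_clinical(v, p, small_panel)

    def test_no_diagnosis_no_match(self, small_panel, phenotype_factory):
        v = make_variant(gene="CACNA1A")
        assert not is_clinical(v, phenotype_factory(), small_panel)

    def test_cvs_itself_never_matches(self, phenotype_factory):
        panel = GenePanel(name="t", genes=["RYR2"], gene_phenotypes={"RYR2": {"CVS"}})
        p = phenotype_factory(diagnoses={"CVS"})
        assert not is_clinical(make_variant(gene="RYR2"), p, panel)

    def test_pp_matches_periodic_paralysis_gene(self, small_panel, phenotype_factory):
        p = phenotype_factory(diagnoses={"PP"})
        assert is_clinical(make_variant(gene="SCN4A"), p, small_panel)

    def test_gene_absent_from_panel_is_lookup_error(self, small_panel, phenotype_factory):
        with pytest.raises(KeyError):
            is_clinical(make_variant(gene="NOTINPANEL"), phenotype_factory(), small_panel)


class TestCosegregationCollapse:
    def test_grouped_records_form_one_occurrence(self):
        records = [
            make_variant(variant_id=f"p.V{i}", gene="SCN1A", coseg_group="g1")
            for i in range(3)
        ]
        groups = collapse_cosegregating(records)
        assert len(groups) == 1
        assert len(groups[0]) == 3

    def test_ungrouped_records_stay_separate(self):
        records = [
            make_variant(variant_id="p.Asp685Asn", gene="TRAP1"),
            make_variant(variant_id="p.Arg469His", gene="TRAP1"),
        ]
        assert len(collapse_cosegregating(records)) == 2

    def test_empty_input(self):
        assert collapse_cosegregating([]) == []

    def test_mixed_participants_rejected(self):
        records = [make_variant(participant_id="P1"), make_variant(participant_id="P2")]
        with pytest.raises(ValueError):
            collapse_cosegregating(records)


class TestQualifyCohort:
    def test_common_variants_are_not_recorded(self, small_panel, phenotype_factory):
        variants = [make_variant(variant_id=f"v{i}", af_nfe=0.5) for i in range(5)]
        results = qualify_cohort(variants, [phenotype_factory()], small_panel)
        assert all(not r.recorded for r in results)
        assert all(r.category is Category.NOT_RECORDED for r in results)

    def test_single_plp_variant_is_one_key_result(self, small_panel, phenotype_factory):
        v = make_variant(clinvar_calls=[ClinVarCall.P])
        results = qualify_cohort([v], [phenotype_factory()], small_panel)
        assert [r.category for r in results] == [Category.KEY]
        assert results[0].plp and not results[0].clinical

    def test_unknown_participant_is_reported(self, small_panel, phenotype_factory):
        v = make_variant(participant_id="GHOST")
        with pytest.raises(KeyError, match="GHOST"):
            qualify_cohort([v], [phenotype_factory("P1")], small_panel)

    def test_hemizygous_counts_as_single_occurrence(self, small_panel, phenotype_factory):
        from paroxscore.models import Zygosity

        v = make_variant(zygosity=Zygosity.HEMI)
        results = qualify_cohort([v], [phenotype_factory()], small_panel)
        assert len(results) == 1 and results[0].qualifying

    def test_group_is_key_if_any_member_is(self, small_panel, phenotype_factory):
        members = [
            make_variant(variant_id="p.A", coseg_group="g", clinvar_calls=[ClinVarCall.P]),
            make_variant(
                variant_id="c.*1T>C", coseg_group="g", consequence=Consequence.UTR
            ),
        ]
        results = qualify_cohort(members, [phenotype_factory()], small_panel)
        assert len(results) == 1
        assert results[0].category is Category.KEY


class TestRecessiveCandidates:
    def test_two_qualifying_variants_in_one_gene(self, phenotype_factory):
        panel = GenePanel(name="t", genes=["GLS2"])
        variants = [
            make_variant(gene="GLS2", variant_id="p.Arg149Gln"),
            make_variant(gene="GLS2", variant_id="p.Arg107Trp"),
        ]
        results = qualify_cohort(variants, [phenotype_factory()], panel)
        assert detect_recessive_candidates(results) == [("P1", "GLS2", 2)]

    def test_one_variant_per_gene_gives_nothing(self, small_panel, phenotype_factory):
        variants = [make_variant(gene="SCN4A"), make_variant(gene="CACNA1A")]
        results = qualify_cohort(variants, [phenotype_factory()], small_panel)
        assert detect_recessive_candidates(results) == []

    def test_cosegregating_trio_is_not_a_candidate(self, small_panel, phenotype_factory):
        variants = [
            make_variant(variant_id=f"p.V{i}", coseg_group="g1") for i in range(3)
        ]
        results = qualify_cohort(variants, [phenotype_factory()], small_panel)
        assert detect_recessive_candidates(results) == []
        # brute-force check: raw count 3, collapsed occurrence count 1
        assert sum(1 for r in results if r.qualifying) == 1


# -- Properties --------------------------------------------------------------

variant_strategy = st.builds(
    make_variant,
    variant_id=st.text("abcdef", min_size=1, max_size=6),
    consequence=st.sampled_from(list(Consequence)),
    af_nfe=st.one_of(st.none(), st.floats(0, 1)),
    phylop=st.one_of(st.none(), st.floats(-5, 10)),
    mammal_match_pct=st.one_of(st.none(), st.floats(0, 100)),
    splice_ada=st.one_of(st.none(), st.floats(0, 1)),
    clinvar_calls=st.lists(st.sampled_from(list(ClinVarCall)), max_size=5),
    lof_predicted=st.booleans(),
    coding_equivalent=st.booleans(),
)


@settings(max_examples=300, derandomize=True)
@given(v=variant_strategy)
def test_predicate_nesting_holds_for_arbitrary_records(v):
    """key implies qualifying implies recorded on every record."""
    if is_qualifying(v) and v.consequence.value not in (
        "repeat_expansion", "structural_deletion", "structural_duplication",
    ):
        assert is_recorded(v)
    if is_plp(v):
        assert aggregate_clinvar(v.clinvar_calls, v.lof_predicted)


@settings(max_examples=200, derandomize=True)
@given(
    v=variant_strategy,
    tighter_af=st.floats(0.0001, 0.02),
    higher_phylop=st.floats(1.5, 6.0),
)
def test_threshold_monotonicity(v, tighter_af, higher_phylop):
    """Tightening the frequency cutoff or raising the conservation cutoff
    never adds records to the qualifying set."""
    base = QualificationThresholds()
    tight = QualificationThresholds(af_qualify_max=tighter_af, phylop_min=higher_phylop)
    if is_qualifying(v, tight):
        relaxed_af = QualificationThresholds(phylop_min=higher_phylop)
        assert is_qualifying(v, relaxed_af) or v.consequence.value in (
            "repeat_expansion", "structural_deletion", "structural_duplication",
        )
    # and never in the other direction for conservation alone
    if is_qualifying(v, QualificationThresholds(phylop_min=3.0)):
        assert is_qualifying(v, base)


def test_permutation_determinism(small_panel, phenotype_factory):
    rng = np.random.default_rng(7)
    variants = [
        make_variant(
            participant_id=f"P{rng.integers(1, 6)}",
            gene=str(rng.choice(["SCN4A", "CACNA1A"])),
            variant_id=f"v{i}",
            af_nfe=float(rng.uniform(0, 0.2)),
            phylop=float(rng.uniform(-1, 4)),
        )
        for i in range(60)
    ]
    phenos = [phenotype_factory(f"P{i}") for i in range(1, 6)]
    base = qualify_cohort(variants, phenos, small_panel)
    perm = list(variants)
    rng.shuffle(perm)
    shuffled = qualify_cohort(perm, phenos, small_panel)
    key = lambda r: (r.gene, r.participant_id, tuple(sorted(r.variant_ids)), r.category)
    assert sorted(map(key, base)) == sorted(map(key, shuffled))


def test_cohort_matches_per_record_brute_force(small_panel, phenotype_factory):
    """On a cohort without co-segregation groups, qualify_cohort agrees
    with independently re-evaluating the three predicates per record."""
    rng = np.random.default_rng(11)
    variants = []
    for i in range(200):
        variants.append(
            make_variant(
                participant_id=f"P{rng.integers(1, 11)}",
                gene=str(rng.choice(small_panel.genes)),
                variant_id=f"v{i}",
                consequence=Consequence(
                    str(rng.choice(["missense", "intronic", "synonymous", "nonsense"]))
                ),
                af_nfe=float(rng.uniform(0, 0.15)),
                phylop=float(rng.uniform(-2, 5)),
                clinvar_calls=[ClinVarCall.P] if rng.random() < 0.1 else [],
            )
        )
    phenos = [
        phenotype_factory(f"P{i}", diagnoses={"EAx"} if i % 3 == 0 else set())
        for i in range(1, 11)
    ]
    results = qualify_cohort(variants, phenos, small_panel)
    by_key = {(r.gene, r.participant_id, r.variant_ids[0]): r for r in results}
    assert len(by_key) == len(variants)
    pheno_by_id = {p.participant_id: p for p in phenos}
    for v in variants:
        r = by_key[(v.gene, v.participant_id, v.variant_id)]
        rec, qual = is_recorded(v), is_qualifying(v)
        plp = qual and is_plp(v)
        clin = qual and is_clinical(v, pheno_by_id[v.participant_id], small_panel)
        assert (r.recorded, r.qualifying, r.plp, r.clinical) == (rec, qual, plp, clin)
        expected = (
            Category.KEY if qual and (plp or clin)
            else Category.OTHER if qual
            else Category.RECORDED_ONLY if rec
            else Category.NOT_RECORDED
        )
        assert r.category is expected
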