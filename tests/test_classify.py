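import pytest

from minivar import classify as cl
from minivar.errors import DataError, OutOfScopeError, ValidationError
from minivar.records import (
    GenomeSequence,
    MinimotifInstance,
    TranscriptModel,
    VariantRecord,
)


def _variant(pos1, ref, alt, gts=None, contig="c1", ancestral=None):
    return VariantRecord(
        contig, pos1, ref, alt, gts if gts is not None else {"s1": (0, 1)},
        ancestral=ancestral,
    )


# ---------------------------------------------------------------------------
# codon mapping

def test_map_first_residue_plus_strand():
    # CDS starts at genomic 0-based 2 -> residue 1 occupies 1-based 3,4,5
    model = TranscriptModel("t", "p", "c1", "+", [(2, 17)])
    motif = MinimotifInstance("m", "p", 1, 2, "binding", None, "")
    mapping = cl.map_minimotif_to_codons(motif, model)
    assert mapping[0] == (1, (3, 4, 5))
    assert mapping[1] == (2, (6, 7, 8))


def test_map_residue_spanning_exon_junction():
    # split after 5 coding bases: codon 2 takes 2 bases from exon 1, 1 from exon 2
    model = TranscriptModel("t", "p", "c1", "+", [(0, 5), (10, 20)])
    motif = MinimotifInstance("m", "p", 2, 3, "binding", None, "")
    mapping = cl.map_minimotif_to_codons(motif, model)
    assert mapping[0] == (2, (4, 5, 11))
    assert mapping[1] == (3, (12, 13, 14))


def test_map_minus_strand_descending():
    model = TranscriptModel("t", "p", "c1", "-", [(0, 15)])
    motif = MinimotifInstance("m", "p", 1, 2, "binding", None, "")
    mapping = cl.map_minimotif_to_codons(motif, model)
    assert mapping[0] == (1, (15, 14, 13))
    assert mapping[1] == (2, (12, 11, 10))


def test_map_beyond_protein_end_errors():
    model = TranscriptModel("t", "p", "c1", "+", [(0, 9)])  # 3 codons
    motif = MinimotifInstance("m", "p", 3, 4, "binding", None, "")
    with pytest.raises(ValidationError, match="beyond"):
        cl.map_minimotif_to_codons(motif, model)


# ---------------------------------------------------------------------------
# effect classification

@pytest.fixture
def effect_gene():
    # codons: ATG GCT TCA TAC AAA TAA -> M A S Y K
    genome = [GenomeSequence("c1", "ATGGCTTCATACAAATAA")]
    model = TranscriptModel("t", "p", "c1", "+", [(0, 18)])
    return genome, model


@pytest.mark.parametrize(
    "pos1,ref,alt,expected",
    [
        (6, "T", "C", "synonymous"),  # GCT -> GCC (Ala)
        (7, "T", "G", "missense"),    # TCA -> GCA (Ser -> Ala)
        (12, "C", "A", "nonsense"),   # TAC -> TAA
    ],
)
def test_classify_effect_by_codon_translation(effect_gene, pos1, ref, alt, expected):
    genome, model = effect_gene
    assert cl.classify_effect(_variant(pos1, ref, alt), model, genome) == expected


def test_classify_effect_outside_cds(effect_gene):
    genome, model = effect_gene
    genome = [GenomeSequence("c1", genome[0].sequence + "GGGG")]
    with pytest.raises(OutOfScopeError):
        cl.classify_effect(_variant(20, "G", "A"), model, genome)


def test_classify_effect_minus_strand(toy_gene_minus):
    genome, model = toy_gene_minus
    # transcript codon 3 TCA spans genomic 1-based 11,10,9 on the minus strand;
    # transcript T->G at its first base is genomic A->C at 1-based 11
    contig = genome[0].sequence
    assert contig[10] == "A"
    effect = cl.classify_effect(_variant(11, "A", "C"), model, genome)
    assert effect == "missense"  # TCA(S) -> GCA(A)


# ---------------------------------------------------------------------------
# motif hits and the LOFM/DM ancestral-allele grid

def test_degenerate_position_hit():
    motif = MinimotifInstance("m", "p", 5, 10, "phosphorylation", 7, "")
    kind, ser_thr = cl.classify_motif_hit(_variant(1, "A", "G"), motif, 6, "P", "L")
    assert kind == "degenerate" and not ser_thr


def test_phospho_ser_thr_transition_not_lofm():
    motif = MinimotifInstance("m", "p", 5, 10, "phosphorylation", 7, "")
    kind, ser_thr = cl.classify_motif_hit(_variant(1, "A", "G"), motif, 7, "S", "T")
    assert kind == "critical" and ser_thr
    assert cl.assign_lofm_dm(kind, ser_thr, "missense", _variant(1, "A", "G", ancestral="A")) == "neither"


def test_acetylation_critical_hit_is_lofm_candidate():
    motif = MinimotifInstance("m", "p", 5, 10, "acetylation", 7, "")
    kind, ser_thr = cl.classify_motif_hit(_variant(1, "A", "G"), motif, 7, "K", "R")
    assert kind == "critical" and not ser_thr


@pytest.mark.parametrize(
    "ancestral,contig,expected",
    [
        ("A", "c1", "LOFM"),   # ancestral = ref: motif ancestral, alt destroys it
        ("G", "c1", "DM"),     # ancestral = alt: motif residue newly derived
        (None, "c1", "unknown_ancestral"),
        ("A", "chrX", "unknown_ancestral"),  # autosomal-only rule
        ("C", "c1", "unknown_ancestral"),    # ancestral matches neither allele
    ],
)
def test_assign_lofm_dm_grid(ancestral, contig, expected):
    v = _variant(1, "A", "G", contig=contig, ancestral=ancestral)
    assert cl.assign_lofm_dm("critical", False, "missense", v) == expected


def test_lofm_dm_requires_critical_missense():
    v = _variant(1, "A", "G", ancestral="A")
    assert cl.assign_lofm_dm("degenerate", False, "missense", v) == "neither"
    assert cl.assign_lofm_dm("critical", False, "synonymous", v) == "neither"


# ---------------------------------------------------------------------------
# MAF

def _cohort_variant(n_hom_ref, n_het, n_hom_alt, n_missing=0):
    gts = {}
    i = 0
    for count, gt in (
        (n_hom_ref, (0, 0)), (n_het, (0, 1)), (n_hom_alt, (1, 1)),
        (n_missing, None),
    ):
        for _ in range(count):
            gts[f"s{i}"] = gt
            i += 1
    return VariantRecord("c1", 1, "A", "G", gts)


def test_maf_singleton_in_1092_diploids():
    v = _cohort_variant(1091, 1, 0)
    maf, cls_ = cl.compute_maf(v)
    assert cls_ == "singleton"
    assert maf == pytest.approx(1 / 2184)


def test_maf_rare_boundary():
    # 20/2184 = 0.92% < 1% -> rare
    v = _cohort_variant(1072, 20, 0)
    maf, cls_ = cl.compute_maf(v)
    assert cls_ == "rare" and maf == pytest.approx(20 / 2184)


def test_maf_common_boundary():
    # 22/2184 = 1.007% >= 1% -> common
    v = _cohort_variant(1070, 22, 0)
    maf, cls_ = cl.compute_maf(v)
    assert cls_ == "common" and maf == pytest.approx(22 / 2184)


def test_maf_all_missing_errors():
    v = _cohort_variant(0, 0, 0, n_missing=3)
    with pytest.raises(DataError):
        cl.compute_maf(v)


def test_maf_denominator_shrinks_with_missing():
    v = _cohort_variant(3, 1, 0, n_missing=2)
    maf, _ = cl.compute_maf(v)
    assert maf == pytest.approx(1 / 8)


# ---------------------------------------------------------------------------
# cohort-level classification

def test_truth_recovery_on_small_cohort(small_cohort):
    """Classifier output must equal the generator's ground truth exactly."""
    contigs = {g.contig_name: g.sequence for g in small_cohort.genome}
    classified = cl.classify_cohort(
        contigs, small_cohort.models, small_cohort.minimotifs,
        small_cohort.variants.records,
    )
    df = cl.classified_to_frame(classified)
    truth = small_cohort.truth_pairs
    merged = df.merge(
        truth, on=["motif_id", "variant_key"], how="outer",
        suffixes=("", "_truth"), indicator=True,
    )
    assert (merged["_merge"] == "both").all()
    for col in ("motif_position_kind", "ser_thr_transition", "lof_dm"):
        assert (merged[col] == merged[f"{col}_truth"]).all()
    tv = small_cohort.truth_variants.set_index("variant_key")
    for key, group in df.groupby("variant_key"):
        row = tv.loc[key]
        assert (group["effect"] == row["true_effect"]).all()
        assert (group["maf_class"] == row["maf_class"]).all()


def test_summary_partition_invariant(small_cohort, study_classified, study_cohort):
    for cohort, classified in (
        (small_cohort, None), (study_cohort, study_classified),
    ):
        if classified is None:
            contigs = {g.contig_name: g.sequence for g in cohort.genome}
            classified = cl.classify_cohort(
                contigs, cohort.models, cohort.minimotifs, cohort.variants.records
            )
        summary = cl.summarize_by_activity(classified, cohort.minimotifs)
        per_activity = summary[~summary.activity.isin(["total", "distinct_snps"])]
        assert (per_activity.n_critical <= per_activity.n_missense).all()
        assert (per_activity.n_missense <= per_activity.n_with_snp).all()
        assert (per_activity.n_with_snp <= per_activity.n_total).all()


def test_summary_distinct_snp_deduplication(study_classified, study_cohort):
    summary = cl.summarize_by_activity(study_classified, study_cohort.minimotifs)
    distinct = summary[summary.activity == "distinct_snps"].iloc[0]
    per_motif_total = len({(c.motif_id, c.variant_key) for c in study_classified})
    assert distinct.n_with_snp <= per_motif_total
    assert distinct.n_with_snp == len({c.variant_key for c in study_classified})


def test_summary_percentages_follow_counts(small_cohort):
    contigs = {g.contig_name: g.sequence for g in small_cohort.genome}
    classified = cl.classify_cohort(
        contigs, small_cohort.models, small_cohort.minimotifs,
        small_cohort.variants.records,
    )
    summary = cl.summarize_by_activity(classified, small_cohort.minimotifs)
    for row in summary.itertuples(index=False):
        if row.activity == "distinct_snps" or row.n_total == 0:
            continue
        assert row.pct_critical == pytest.approx(100 * row.n_critical / row.n_total)
        assert row.pct_with_snp == pytest.approx(100 * row.n_with_snp / row.n_total)


def test_lofm_dm_exhaustiveness(study_classified):
    """Every critical missense hit with a known autosomal ancestral allele is
    exactly one of LOFM or DM."""
    seen = 0
    for rec in study_classified:
        if (
            rec.motif_position_kind == "critical"
            and rec.effect == "missense"
            and not rec.ser_thr_transition
            and rec.lof_dm != "unknown_ancestral"
        ):
            assert rec.lof_dm in ("LOFM", "DM")
            seen += 1
    assert seen > 0


def test_zero_snp_activity_reports_zero(small_cohort):
    summary = cl.summarize_by_activity([], small_cohort.minimotifs)
    per_activity = summary[~summary.activity.isin(["total", "distinct_snps"])]
    assert (per_activity.n_with_snp == 0).all()
    assert (per_activity.pct_with_snp == 0).all()
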