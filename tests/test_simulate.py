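import hashlib
from pathlib import Path

import numpy as np
import pytest

from minivar.classify import compute_maf
from minivar.errors import SpecError
from minivar.records import MMOD_ACTIVITIES
from minivar.simulate import (
    CohortSpec,
    GERP_RANGE,
    simulate_cohort,
    simulate_minimotifs,
    simulate_reference,
    simulate_scores,
    write_cohort,
)

TINY = dict(n_genes=10, n_minimotifs=40, n_variants=80)


def _digests(directory):
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(Path(directory).iterdir())
    }


def test_fixed_seed_byte_identical_outputs(tmp_path):
    for sub in ("a", "b"):
        write_cohort(simulate_cohort(CohortSpec(seed=7, **TINY)), tmp_path / sub)
    assert _digests(tmp_path / "a") == _digests(tmp_path / "b")


def test_different_seeds_differ(tmp_path):
    a = simulate_cohort(CohortSpec(seed=1, **TINY))
    b = simulate_cohort(CohortSpec(seed=2, **TINY))
    assert [v.key for v in a.variants.records] != [v.key for v in b.variants.records]


def test_reference_translates_cleanly_and_uses_both_strands():
    genome, models, proteome = simulate_reference(CohortSpec(seed=3, **TINY))
    assert len(proteome) == len(models) == 10
    assert {m.strand for m in models} == {"+", "-"}
    for prot in proteome:
        assert "*" not in prot.residues
        assert prot.residues.startswith("M")


def test_reference_exercises_split_codons_and_frames():
    spec = CohortSpec(seed=4, n_genes=40, n_minimotifs=10, n_variants=10)
    _, models, _ = simulate_reference(spec)
    assert any(len(m.exons) > 1 for m in models)
    assert any(m.frame_offset > 0 for m in models)
    # at least one multi-exon gene has a boundary off the codon grid
    assert any(
        len(m.exons) > 1
        and any((e - s) % 3 for s, e in m.exons[:-1])
        for m in models
    )


def test_infeasible_spec_rejected():
    with pytest.raises(SpecError):
        CohortSpec(cds_codons=(1, 1)).validate()


def test_phosphorylation_mmod_residue_is_ser_or_thr():
    spec = CohortSpec(seed=5, activity_mix={"phosphorylation": 1.0}, **TINY)
    _, _, proteome = simulate_reference(spec)
    motifs, _ = simulate_minimotifs(proteome, spec)
    by_id = {p.protein_id: p for p in proteome}
    for m in motifs:
        assert m.activity == "phosphorylation"
        assert by_id[m.protein_id].residues[m.mmod_position - 1] in "ST"
        assert m.start <= m.mmod_position <= m.end


def test_zero_minimotifs():
    spec = CohortSpec(seed=5, n_minimotifs=0, n_genes=5, n_variants=10,
                      fraction_critical=0.0)
    _, _, proteome = simulate_reference(spec)
    motifs, truth = simulate_minimotifs(proteome, spec)
    assert motifs == [] and truth.empty


def test_activity_proportions_within_binomial_error():
    mix = {"phosphorylation": 0.7, "proteolysis": 0.3}
    spec = CohortSpec(seed=6, n_genes=30, n_minimotifs=1000, n_variants=10,
                      activity_mix=mix)
    _, _, proteome = simulate_reference(spec)
    motifs, _ = simulate_minimotifs(proteome, spec)
    n = len(motifs)
    observed = sum(m.activity == "phosphorylation" for m in motifs) / n
    sd = np.sqrt(0.7 * 0.3 / n)
    assert abs(observed - 0.7) < 3 * sd


def test_motif_lengths_within_spec_range(small_cohort):
    lengths = {m.end - m.start + 1 for m in small_cohort.minimotifs}
    assert lengths <= set(range(2, 16))
    assert len(lengths) > 5  # spread over the range, not a single length


def test_mmod_only_on_mmod_activities(small_cohort):
    for m in small_cohort.minimotifs:
        if m.activity in MMOD_ACTIVITIES:
            assert m.mmod_position is not None
        else:
            assert m.mmod_position is None


def test_peptide_matches_reference_proteome(small_cohort):
    by_id = {p.protein_id: p for p in small_cohort.reference_proteome}
    for m in small_cohort.minimotifs:
        assert m.peptide == by_id[m.protein_id].residues[m.start - 1 : m.end]


def test_fraction_critical_zero_plants_no_critical_hits():
    spec = CohortSpec(seed=8, fraction_critical=0.0, **TINY)
    cohort = simulate_cohort(spec)
    assert (cohort.truth_variants.kind != "critical").all()


def test_allele_count_bookkeeping(small_cohort):
    """Alt dosage summed over samples equals called-chromosomes x empirical AF
    exactly, and the truth table's MAF matches a direct recount."""
    truth = small_cohort.truth_variants.set_index("variant_key")
    for v in small_cohort.variants.records:
        nref, nalt = v.allele_counts()
        maf, maf_class = compute_maf(v)
        assert truth.loc[v.key, "maf"] == pytest.approx(maf)
        assert truth.loc[v.key, "maf_class"] == maf_class
        assert nalt == round((nref + nalt) * (nalt / (nref + nalt))) if nref + nalt else True


def test_variants_are_biallelic_snvs_with_unique_positions(small_cohort):
    seen = set()
    for v in small_cohort.variants.records:
        assert len(v.ref) == 1 and len(v.alt) == 1 and v.ref != v.alt
        assert (v.contig, v.position) not in seen
        seen.add((v.contig, v.position))


def test_noncoding_variants_outside_every_exon(small_cohort):
    exonic = {}
    for m in small_cohort.models:
        for s, e in m.exons:
            exonic.setdefault(m.contig, set()).update(range(s, e))
    truth = small_cohort.truth_variants.set_index("variant_key")
    for v in small_cohort.variants.records:
        inside = v.pos0 in exonic.get(v.contig, set())
        if truth.loc[v.key, "kind"] == "noncoding":
            assert not inside
        else:
            assert inside


def test_derived_motif_fraction_plants_dm_truth():
    spec = CohortSpec(seed=9, fraction_derived_motif=0.5, fraction_x_genes=0.0,
                      n_genes=30, n_minimotifs=300, n_variants=500)
    cohort = simulate_cohort(spec)
    crit = cohort.truth_variants[cohort.truth_variants.kind == "critical"]
    assert (crit.lof_dm == "DM").sum() > 0
    assert (crit.lof_dm == "LOFM").sum() > 0


def test_score_clipping_to_observed_gerp_range():
    spec = CohortSpec(seed=10, **TINY)
    spec.score_model = {
        cls: {"gerp": (10.0, 1.0), "slr": ms["slr"], "phylop": ms["phylop"]}
        for cls, ms in spec.score_model.items()
    }
    cohort = simulate_cohort(CohortSpec(seed=10, **TINY))
    scores, _ = simulate_scores(cohort.variants.records, spec)
    assert max(s.gerp for s in scores.values()) <= GERP_RANGE[1]
    assert min(s.gerp for s in scores.values()) >= GERP_RANGE[0]


def test_zero_sd_scores_recover_exact_means():
    spec = CohortSpec(seed=11, **TINY)
    spec.score_model = {
        "negative": {"gerp": (3.0, 0.0), "slr": (-6.0, 0.0), "phylop": (2.0, 0.0)},
        "neutral": {"gerp": (0.5, 0.0), "slr": (0.0, 0.0), "phylop": (0.5, 0.0)},
        "positive": {"gerp": (-2.0, 0.0), "slr": (6.0, 0.0), "phylop": (-0.5, 0.0)},
    }
    cohort = simulate_cohort(CohortSpec(seed=11, **TINY))
    scores, truth = simulate_scores(cohort.variants.records, spec)
    means = {"negative": -6.0, "neutral": 0.0, "positive": 6.0}
    truth = truth.set_index("variant_key")
    for v in cohort.variants.records:
        cls = truth.loc[v.key, "selection_class"]
        assert scores[(v.contig, v.position)].slr == pytest.approx(means[cls])


def test_constrained_class_gerp_tail():
    """With a constrained-class GERP mean of 3 (sd 1), well over half of that
    class's sites exceed the constraint threshold of 2."""
    cohort = simulate_cohort(CohortSpec(seed=12, n_genes=50, n_minimotifs=200,
                                        n_variants=2000))
    truth = cohort.truth_variants.set_index("variant_key")
    gerps = [
        cohort.scores[(v.contig, v.position)].gerp
        for v in cohort.variants.records
        if truth.loc[v.key, "selection_class"] == "negative"
    ]
    assert len(gerps) > 100
    assert np.mean(np.array(gerps) > 2.0) > 0.5


def test_truth_labels_cover_every_variant(small_cohort):
    keys = {v.key for v in small_cohort.variants.records}
    assert set(small_cohort.truth_variants.variant_key) == keys
    assert small_cohort.truth_variants.variant_key.is_unique
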