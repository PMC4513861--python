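import numpy as np
import pytest

from minivar import proteome as pr
from minivar.errors import DataError, ReferenceMismatchError
from minivar.records import AA_INDEX, GenomeSequence, Protein, TranscriptModel, VariantRecord

# independent codon table for hand-translation oracles (kept separate from the
# implementation's Biopython path)
_ORACLE = {}
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for i, a in enumerate(_BASES):
    for j, b in enumerate(_BASES):
        for k, c in enumerate(_BASES):
            _ORACLE[a + b + c] = _AA[16 * i + 4 * j + k]


def oracle_translate(cds: str) -> str:
    out = []
    for i in range(0, len(cds) - 2, 3):
        aa = _ORACLE[cds[i : i + 3]]
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


def test_single_exon_hand_translation():
    genome = [GenomeSequence("c1", "ATGGCTTAA")]
    model = TranscriptModel("t", "p", "c1", "+", [(0, 9)])
    prots = pr.build_reference_proteome(genome, [model])
    assert prots == [Protein("p", "MA")]


def test_minus_strand_equivalence(toy_gene, toy_gene_minus):
    plus = pr.build_reference_proteome(toy_gene[0], [toy_gene[1]])
    minus = pr.build_reference_proteome(toy_gene_minus[0], [toy_gene_minus[1]])
    assert plus[0].residues == minus[0].residues == "MASK"


def test_splice_concatenation_equivalence():
    # exon boundary inside codon 2: ATG|GC TTCA... split after 5 bases
    cds = "ATGGCTTCAAAATAA"
    genome = [GenomeSequence("c1", cds)]
    unsplit = TranscriptModel("t1", "p", "c1", "+", [(0, len(cds))])
    split = TranscriptModel("t2", "p", "c1", "+", [(0, 5), (5, len(cds))])
    a = pr.build_reference_proteome(genome, [unsplit])[0]
    b = pr.build_reference_proteome(genome, [split])[0]
    assert a.residues == b.residues


def test_strand_and_splice_equivalence_on_random_genes(small_cohort):
    """Every simulated gene's protein must match an independent hand
    translation of its spliced CDS, on either strand."""
    contigs = {g.contig_name: g.sequence for g in small_cohort.genome}
    by_id = {p.protein_id: p for p in small_cohort.reference_proteome}
    minus_seen = plus_seen = 0
    for model in small_cohort.models:
        cds = pr.splice_cds(contigs[model.contig], model)
        assert oracle_translate(cds) == by_id[model.protein_id].residues
        if model.strand == "-":
            minus_seen += 1
        else:
            plus_seen += 1
    assert minus_seen and plus_seen


def test_internal_stop_excluded_and_logged(caplog):
    genome = [GenomeSequence("c1", "ATGTAAGCTTAA")]
    model = TranscriptModel("t", "p", "c1", "+", [(0, 12)])
    with caplog.at_level("WARNING"):
        prots = pr.build_reference_proteome(genome, [model])
    assert prots == []
    assert any("internal stop" in r.message for r in caplog.records)


@pytest.mark.parametrize(
    "pred,ref,ok,reason",
    [
        ("M" + "A" * 19, "M" + "A" * 19, True, None),
        # mismatch at residue 3 violates the residues-2-15 rule
        ("MAGAAAAAAAAAAAAAAAAA", "MAAAAAAAAAAAAAAAAAAA", False, "residues_2_15"),
        # equal 2-15 window but different length
        ("M" + "A" * 20, "M" + "A" * 19, False, "length"),
        # 11 scattered mismatches past residue 15 in a 100-mer: 89% identity
        (
            "M" + "A" * 14 + "G" * 11 + "A" * 74,
            "M" + "A" * 99,
            False,
            "identity",
        ),
        # 10 mismatches: exactly 90%, accepted
        (
            "M" + "A" * 14 + "G" * 10 + "A" * 75,
            "M" + "A" * 99,
            True,
            None,
        ),
        # proteins shorter than 15: rule (a) uses the available overlap
        ("MKL", "MKL", True, None),
        ("MKL", "MLL", False, "residues_2_15"),
    ],
)
def test_validate_protein(pred, ref, ok, reason):
    got_ok, got_reason = pr.validate_protein(Protein("q", pred), Protein("r", ref))
    assert (got_ok, got_reason) == (ok, reason)


def _variant(pos1, ref, alt, gt, sample="s1"):
    return VariantRecord("c1", pos1, ref, alt, {sample: gt})


def test_apply_genotypes_hom_ref_identity(toy_gene):
    genome, model = toy_gene
    v = _variant(4, "T", "A", (0, 0))
    h1, h2 = pr.apply_genotypes(genome, [model], [v], "s1")
    assert h1[0].residues == h2[0].residues == "MASK"


def test_apply_genotypes_hom_alt_changes_residue(toy_gene):
    genome, model = toy_gene
    # codon 1 ATG -> TTG: M1L in both haplotypes
    v = _variant(3, "A", "T", (1, 1))
    h1, h2 = pr.apply_genotypes(genome, [model], [v], "s1")
    assert h1[0].residues == h2[0].residues == "LASK"


def test_apply_genotypes_het_synonymous_keeps_reference(toy_gene):
    genome, model = toy_gene
    # codon 2 GCT -> GCC, both Ala
    v = _variant(8, "T", "C", (0, 1))
    h1, h2 = pr.apply_genotypes(genome, [model], [v], "s1")
    assert h1[0].residues == h2[0].residues == "MASK"


def test_apply_genotypes_het_missense_one_haplotype(toy_gene):
    genome, model = toy_gene
    # codon 3 TCA(S) -> GCA(A), het: alt goes to haplotype 2 by convention
    v = _variant(9, "T", "G", (0, 1))
    h1, h2 = pr.apply_genotypes(genome, [model], [v], "s1")
    assert h1[0].residues == "MASK"
    assert h2[0].residues == "MAAK"


def test_apply_genotypes_reference_mismatch(toy_gene):
    genome, model = toy_gene
    v = _variant(3, "G", "T", (1, 1))  # genome has A at position 3
    with pytest.raises(ReferenceMismatchError, match="c1:3"):
        pr.apply_genotypes(genome, [model], [v], "s1")


def test_personal_proteomes_bypass_validation(toy_gene):
    """A variant that would fail reference validation (residue-2 change) must
    not raise: alignment verification is not repeated for personal proteomes."""
    genome, model = toy_gene
    v = _variant(7, "C", "G", (1, 1))  # GCT -> GGT, A2G inside residues 2-15
    h1, h2 = pr.apply_genotypes(genome, [model], [v], "s1")
    assert h1[0].residues == "MGSK"


def test_stop_gain_truncates_and_column_sum_drops(toy_gene):
    genome, model = toy_gene
    ref = pr.build_reference_proteome(genome, [model])
    # codon 3 TCA -> TGA (stop gain) via position 10 C->G
    v = _variant(10, "C", "G", (1, 1))
    haps = pr.apply_genotypes(genome, [model], [v], "s1")
    assert haps[0][0].residues == "MA"
    matrix = pr.compute_match_matrix(ref, [haps])
    sums = matrix.column_sums()
    assert np.allclose(sums[:2], 1.0)
    assert np.allclose(sums[2:], 0.0)  # truncated positions are missing


def test_match_matrix_heterozygote_is_half(toy_gene):
    genome, model = toy_gene
    ref = pr.build_reference_proteome(genome, [model])
    v = _variant(9, "T", "G", (0, 1))  # S3A het
    haps = pr.apply_genotypes(genome, [model], [v], "s1")
    m = pr.compute_match_matrix(ref, [haps])
    assert m.fraction("S", "p1", 3) == 0.5
    assert m.fraction("A", "p1", 3) == 0.5


def test_match_matrix_three_to_one(toy_gene):
    genome, model = toy_gene
    ref = pr.build_reference_proteome(genome, [model])
    gts = {"s1": (0, 0), "s2": (0, 0), "s3": (0, 0), "s4": (1, 1)}
    v = VariantRecord("c1", 9, "T", "A", gts)  # TCA(S) -> ACA(T)
    cohort = [pr.apply_genotypes(genome, [model], [v], s) for s in gts]
    m = pr.compute_match_matrix(ref, cohort)
    assert m.fraction("S", "p1", 3) == 0.75
    assert m.fraction("T", "p1", 3) == 0.25
    assert np.allclose(m.column_sums(), 1.0)


def test_match_matrix_null_cohort_identity(toy_gene):
    genome, model = toy_gene
    ref = pr.build_reference_proteome(genome, [model])
    cohort = [pr.apply_genotypes(genome, [model], [], s) for s in ("a", "b")]
    m = pr.compute_match_matrix(ref, cohort)
    for j, (pid, pos) in enumerate(m.position_index):
        residue = ref[0].residues[pos - 1]
        col = m.values[:, j]
        assert col[AA_INDEX[residue]] == 1.0
        assert col.sum() == 1.0


def test_match_matrix_empty_cohort_errors(toy_gene):
    genome, model = toy_gene
    ref = pr.build_reference_proteome(genome, [model])
    with pytest.raises(DataError):
        pr.compute_match_matrix(ref, [])


def test_match_matrix_sparse_round_trip(tmp_path, toy_gene):
    genome, model = toy_gene
    ref = pr.build_reference_proteome(genome, [model])
    v = _variant(9, "T", "G", (0, 1))
    m = pr.compute_match_matrix(ref, [pr.apply_genotypes(genome, [model], [v], "s1")])
    out = tmp_path / "mm.tsv"
    m.to_sparse_tsv(out, ref)
    lines = out.read_text().strip().split("\n")
    assert lines[0].startswith("protein_id")
    assert len(lines) == 3  # header + the two changed entries at position 3
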