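import numpy as np
import pytest

from minivar.records import GenomeSequence, TranscriptModel
from minivar.simulate import CohortSpec, simulate_cohort


@pytest.fixture
def toy_gene():
    """Single-exon plus-strand gene: ATG GCT TCA AAA TAA -> protein MASK."""
    cds = "ATGGCTTCAAAATAA"
    genome = [GenomeSequence("c1", "GG" + cds + "CC")]
    model = TranscriptModel(
        tx_id="tx1", protein_id="p1", contig="c1", strand="+",
        exons=[(2, 2 + len(cds))],
    )
    return genome, model


@pytest.fixture
def toy_gene_minus():
    """The same CDS on the minus strand (genome stores the reverse complement)."""
    from minivar.proteome import reverse_complement

    cds = "ATGGCTTCAAAATAA"
    block = reverse_complement(cds)
    genome = [GenomeSequence("c1", "GG" + block + "CC")]
    model = TranscriptModel(
        tx_id="tx1", protein_id="p1", contig="c1", strand="-",
        exons=[(2, 2 + len(block))],
    )
    return genome, model


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic study exercised by several module tests."""
    spec = CohortSpec(
        n_genes=30, n_minimotifs=150, n_variants=400,
        n_high_ddaf_sites=1, seed=11,
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def study_cohort():
    """Full-scale study conditions: 200 genes, 2000 motifs, 5000 variants."""
    return simulate_cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def study_classified(study_cohort):
    from minivar.classify import classify_cohort

    contigs = {g.contig_name: g.sequence for g in study_cohort.genome}
    return classify_cohort(
        contigs, study_cohort.models, study_cohort.minimotifs,
        study_cohort.variants.records,
    )


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
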