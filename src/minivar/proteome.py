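"""Reference and personalized proteome construction and the cohort
match-fraction matrix.

The match matrix M[k, j] gives, for amino acid k and proteome position j, the
fraction of the cohort carrying residue k at j. Each person has total weight 1,
split 0.5 per haplotype, so a heterozygote contributes 0.5 to each of its two
residues. The denominator is the fixed cohort size; missing genotypes and
positions beyond a stop-gain truncation contribute nothing, so those columns
sum to less than 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio.Seq import Seq

from .errors import DataError, ReferenceMismatchError, ValidationError
from .records import (
    AA_INDEX,
    AA_ORDER,
    GenomeSequence,
    Protein,
    TranscriptModel,
    VariantRecord,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def genome_dict(genome: Iterable[GenomeSequence]) -> Dict[str, str]:
    return {g.contig_name: g.sequence for g in genome}


def splice_cds(contig_seq: str, model: TranscriptModel) -> str:
    """Coding-strand CDS of a transcript (frame offset applied).

    Exons are concatenated in transcript order; minus-strand exons are
    reverse-complemented individually.
    """
    parts = []
    for s, e in model.exons:
        if s < 0 or e > len(contig_seq):
            raise ValidationError(
                f"{model.tx_id}: exon {s}-{e} outside contig bounds"
            )
        chunk = contig_seq[s:e]
        parts.append(chunk if model.strand == "+" else reverse_complement(chunk))
    return "".join(parts)[model.frame_offset :]


def translate_cds(cds: str) -> Tuple[str, bool]:
    """Translate a CDS with the standard nuclear code, stopping at the first
    stop codon. Returns (residues, internal_stop) where ``internal_stop`` is
    True when a stop occurs before the final codon."""
    full = str(Seq(cds).translate())
    stop = full.find("*")
    if stop == -1:
        return full, False
    return full[:stop], stop < len(full) - 1


def build_reference_proteome(
    genome: Iterable[GenomeSequence] | Mapping[str, str],
    models: Sequence[TranscriptModel],
) -> List[Protein]:
    """Translate every transcript model; models whose CDS contains an internal
    stop codon are flagged invalid, excluded and logged."""
    contigs = genome if isinstance(genome, Mapping) else genome_dict(genome)
    proteins: List[Protein] = []
    for model in models:
        if model.contig not in contigs:
            raise ValidationError(f"{model.tx_id}: unknown contig {model.contig!r}")
        residues, internal_stop = translate_cds(splice_cds(contigs[model.contig], model))
        if internal_stop:
            logger.warning(
                "%s: internal stop codon in reference CDS; protein excluded",
                model.tx_id,
            )
            continue
        proteins.append(Protein(model.protein_id, residues))
    return proteins


def validate_protein(predicted: Protein, reference: Protein) -> Tuple[bool, Optional[str]]:
    """Accept a predicted protein only if (a) residues 2-15 exactly match the
    reference (full available overlap for shorter proteins), (b) the lengths
    are identical and (c) overall positionwise identity is at least 90%."""
    p, r = predicted.residues, reference.residues
    if not p or not r:
        raise DataError("validate_protein requires non-empty sequences")
    window = min(len(p), len(r), 15)
    if p[1:window] != r[1:window]:
        return False, "residues_2_15"
    if len(p) != len(r):
        return False, "length"
    matches = sum(a == b for a, b in zip(p, r))
    if matches / len(r) < 0.90:
        return False, "identity"
    return True, None


def apply_genotypes(
    genome: Iterable[GenomeSequence] | Mapping[str, str],
    models: Sequence[TranscriptModel],
    variants: Iterable[VariantRecord],
    sample_id: str,
) -> Tuple[List[Protein], List[Protein]]:
    """Personal proteome for one sample: substitute the sample's two alleles
    at every SNV into two haplotype genomes and translate.

    Unphased heterozygotes place the alt allele on haplotype 2 (an arbitrary,
    non-contract choice: downstream quantities depend on dosage only). Missing
    genotypes substitute N, translating to an 'X' residue. Alignment
    verification is deliberately NOT repeated for personal proteomes; stop
    gains simply truncate the protein.
    """
    contigs = genome if isinstance(genome, Mapping) else genome_dict(genome)
    hap_seqs: List[Dict[str, bytearray]] = [
        {c: bytearray(s, "ascii") for c, s in contigs.items()} for _ in range(2)
    ]
    for rec in variants:
        if rec.contig not in contigs:
            continue
        ref_base = contigs[rec.contig][rec.pos0]
        if ref_base != rec.ref:
            raise ReferenceMismatchError(
                f"{rec.key}: genome has {ref_base!r} at {rec.contig}:{rec.position}"
            )
        gt = rec.genotypes.get(sample_id)
        if gt is None:
            for hap in hap_seqs:
                hap[rec.contig][rec.pos0] = ord("N")
            continue
        alleles = sorted(gt, key=lambda a: (a is None, a))  # ref first, alt to hap 2
        for hap, allele in zip(hap_seqs, alleles):
            if allele is None:
                hap[rec.contig][rec.pos0] = ord("N")
            elif allele == 1:
                hap[rec.contig][rec.pos0] = ord(rec.alt)
    proteomes: Tuple[List[Protein], List[Protein]] = ([], [])
    for hap_idx in range(2):
        decoded = {c: s.decode("ascii") for c, s in hap_seqs[hap_idx].items()}
        for model in models:
            residues, _ = translate_cds(splice_cds(decoded[model.contig], model))
            proteomes[hap_idx].append(Protein(model.protein_id, residues))
    return proteomes


@dataclass
class MatchMatrix:
    """Amino-acid x proteome-position match-fraction matrix.

    ``values`` has one row per amino acid in :data:`minivar.records.AA_ORDER`
    and one column per reference proteome position; ``position_index[j]`` maps
    column j back to (protein_id, 1-based residue position).
    """

    values: np.ndarray
    n_samples: int
    position_index: List[Tuple[str, int]]

    def column_sums(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def fraction(self, amino_acid: str, protein_id: str, residue_pos: int) -> float:
        j = self.position_index.index((protein_id, residue_pos))
        return float(self.values[AA_INDEX[amino_acid], j])

    def to_sparse_tsv(self, path, reference: Sequence[Protein]) -> None:
        """Write only entries that differ from the reference indicator."""
        ref_res = "".join(p.residues for p in reference)
        with open(path, "w") as fh:
            fh.write("protein_id\tresidue_pos\tamino_acid\tfraction\n")
            for j, (pid, pos) in enumerate(self.position_index):
                col = self.values[:, j]
                ref_aa = ref_res[j]
                for k in np.nonzero(col)[0]:
                    aa = AA_ORDER[k]
                    frac = col[k]
                    if aa == ref_aa and frac == 1.0:
                        continue
                    fh.write(f"{pid}\t{pos}\t{aa}\t{format(frac, '.10g')}\n")

    def to_dense_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("protein_id\tresidue_pos\t" + "\t".join(AA_ORDER) + "\n")
            for j, (pid, pos) in enumerate(self.position_index):
                row = "\t".join(format(v, ".10g") for v in self.values[:, j])
                fh.write(f"{pid}\t{pos}\t{row}\n")


def _residue_indices(residues: str) -> np.ndarray:
    """Map a residue string to AA_ORDER row indices (-1 for non-standard)."""
    lookup = np.full(128, -1, dtype=np.int8)
    for aa, i in AA_INDEX.items():
        lookup[ord(aa)] = i
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    return lookup[arr]


def compute_match_matrix(
    reference_proteome: Sequence[Protein],
    personal_proteomes: Iterable[Tuple[Sequence[Protein], Sequence[Protein]]],
) -> MatchMatrix:
    """Accumulate the match-fraction matrix over an iterable of per-person
    (haplotype 1, haplotype 2) proteomes, each positionally aligned to the
    reference (guaranteed because only substitutions are applied)."""
    position_index: List[Tuple[str, int]] = []
    offsets: Dict[str, int] = {}
    for prot in reference_proteome:
        offsets[prot.protein_id] = len(position_index)
        position_index.extend(
            (prot.protein_id, pos) for pos in range(1, len(prot.residues) + 1)
        )
    n_positions = len(position_index)
    counts = np.zeros((len(AA_ORDER), n_positions), dtype=np.float64)
    n_samples = 0
    for haplotypes in personal_proteomes:
        n_samples += 1
        for hap in haplotypes:
            for prot in hap:
                base = offsets.get(prot.protein_id)
                if base is None:
                    raise DataError(
                        f"personal protein {prot.protein_id!r} absent from reference"
                    )
                idx = _residue_indices(prot.residues)
                valid = idx >= 0
                cols = base + np.nonzero(valid)[0]
                np.add.at(counts, (idx[valid], cols), 0.5)
    if n_samples == 0:
        raise DataError("cannot compute a match matrix for an empty cohort")
    return MatchMatrix(counts / n_samples, n_samples, position_index)


def cohort_match_matrix(
    genome: Iterable[GenomeSequence] | Mapping[str, str],
    models: Sequence[TranscriptModel],
    variants: Sequence[VariantRecord],
    samples: Sequence[str],
) -> MatchMatrix:
    """Convenience driver: apply genotypes sample by sample and accumulate."""
    contigs = genome if isinstance(genome, Mapping) else genome_dict(genome)
    reference = build_reference_proteome(contigs, models)

    def _iter():
        for sample in samples:
            yield apply_genotypes(contigs, models, variants, sample)

    return compute_match_matrix(reference, _iter())
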