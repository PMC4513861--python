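"""Codon-resolved minimotif/variant classification.

Maps each minimotif to genomic codon coordinates, intersects with the SNV
panel and classifies every motif x variant pair:

* effect (synonymous / missense / nonsense by codon translation);
* degenerate vs critical position (critical = the covalently modified
  ``mmod`` residue);
* LOFM vs DM via the ancestral allele: a critical-residue missense whose
  ancestral allele encodes the motif residue destroys an ancestral motif
  (LOFM); one whose ancestral allele encodes the non-motif residue marks a
  motif newly derived in humans (DM). Restricted to autosomal variants with a
  known ancestral allele;
* the Ser<->Thr exception for phosphorylation sites (functionally equivalent
  for dual-specificity kinases, reported separately, never a LOFM);
* minor-allele-frequency class (singleton / rare < 1% / common).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from Bio.Data import CodonTable

from .coords import codon_offset_of_cds_index, residue_of_cds_index
from .errors import DataError, OutOfScopeError, ValidationError
from .proteome import complement_base, genome_dict
from .records import (
    GenomeSequence,
    MinimotifInstance,
    TranscriptModel,
    VariantRecord,
)

logger = logging.getLogger(__name__)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]


def _translate_codon(codon: str) -> str:
    """Single-letter residue, '*' for stop, 'X' for ambiguous."""
    if codon in _STANDARD.stop_codons:
        return "*"
    return _STANDARD.forward_table.get(codon, "X")


# ---------------------------------------------------------------------------
# coordinate mapping

def map_minimotif_to_codons(
    motif: MinimotifInstance, model: TranscriptModel
) -> List[Tuple[int, Tuple[int, int, int]]]:
    """Per-residue genomic codon coordinates (1-based) for a motif.

    Returns [(residue_pos, (g1, g2, g3)), ...] with coordinates in translation
    order: ascending genomically on '+' strand transcripts, descending on '-'.
    Codons may straddle exon junctions, so triples can be discontiguous.
    """
    positions = model.coding_positions()
    n_codons = len(positions) // 3
    if motif.end > n_codons:
        raise ValidationError(
            f"{motif.motif_id}: end {motif.end} beyond the {n_codons} codons of "
            f"{model.tx_id}"
        )
    out = []
    for residue in range(motif.start, motif.end + 1):
        i = (residue - 1) * 3
        triple = tuple(p + 1 for p in positions[i : i + 3])
        out.append((residue, triple))  # type: ignore[arg-type]
    return out


class CodonIndex:
    """Lookup from genomic position to (model, residue, codon offset).

    The terminal stop codon is part of the coding span but maps to residue
    len(protein)+1; callers treating it as out-of-protein must check bounds.
    """

    def __init__(self, models: Sequence[TranscriptModel]):
        self.by_position: Dict[Tuple[str, int], Tuple[TranscriptModel, int]] = {}
        self.by_protein: Dict[str, TranscriptModel] = {}
        for model in models:
            self.by_protein[model.protein_id] = model
            for cds_idx, gpos in enumerate(model.coding_positions()):
                self.by_position[(model.contig, gpos)] = (model, cds_idx)

    def locate(self, variant: VariantRecord) -> Optional[Tuple[TranscriptModel, int]]:
        return self.by_position.get((variant.contig, variant.pos0))


def _ref_alt_codons(
    variant: VariantRecord,
    model: TranscriptModel,
    cds_idx: int,
    contigs: Mapping[str, str],
) -> Tuple[str, str]:
    """Coding-strand reference and alternate codons at a variant."""
    positions = model.coding_positions()
    offset = codon_offset_of_cds_index(cds_idx)
    codon_start = cds_idx - offset
    seq = contigs[model.contig]
    bases = []
    for p in positions[codon_start : codon_start + 3]:
        b = seq[p]
        bases.append(b if model.strand == "+" else complement_base(b))
    ref_codon = "".join(bases)
    alt_base = variant.alt if model.strand == "+" else complement_base(variant.alt)
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
    return ref_codon, alt_codon


def classify_effect(
    variant: VariantRecord,
    model: TranscriptModel,
    genome: Iterable[GenomeSequence] | Mapping[str, str],
    codon_index: Optional[CodonIndex] = None,
) -> str:
    """'synonymous', 'missense' or 'nonsense' by translating ref/alt codons."""
    contigs = genome if isinstance(genome, Mapping) else genome_dict(genome)
    if codon_index is not None:
        hit = codon_index.locate(variant)
        if hit is None or hit[0] is not model:
            hit = None
    else:
        hit = None
    if hit is None:
        try:
            cds_idx = model.coding_positions().index(variant.pos0)
        except ValueError:
            raise OutOfScopeError(
                f"{variant.key}: outside the CDS of {model.tx_id}"
            )
        if variant.contig != model.contig:
            raise OutOfScopeError(f"{variant.key}: contig differs from {model.tx_id}")
    else:
        cds_idx = hit[1]
    ref_codon, alt_codon = _ref_alt_codons(variant, model, cds_idx, contigs)
    ref_aa = _translate_codon(ref_codon)
    alt_aa = _translate_codon(alt_codon)
    if alt_aa == "*" and ref_aa != "*":
        return "nonsense"
    if ref_aa == alt_aa:
        return "synonymous"
    return "missense"


# ---------------------------------------------------------------------------
# classified records

@dataclass
class ClassifiedMinimotifVariant:
    """Joint record for one motif x variant pair."""

    motif_id: str
    variant_key: str
    activity: str
    protein_id: str
    residue_position: int
    ref_residue: str
    alt_residue: str
    effect: str  # synonymous | missense (nonsense folded in, flagged)
    nonsense: bool
    motif_position_kind: str  # degenerate | critical
    ser_thr_transition: bool
    lof_dm: str  # LOFM | DM | neither | unknown_ancestral
    maf: float
    maf_class: str  # singleton | rare | common
    pop_dafs: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ser_thr_transition and (
            self.activity != "phosphorylation" or self.effect != "missense"
        ):
            raise ValidationError(
                f"{self.motif_id}/{self.variant_key}: Ser-Thr transition requires a "
                "phosphorylation missense hit"
            )
        if self.lof_dm in ("LOFM", "DM") and (
            self.motif_position_kind != "critical" or self.ser_thr_transition
        ):
            raise ValidationError(
                f"{self.motif_id}/{self.variant_key}: LOFM/DM requires a critical "
                "non-Ser/Thr hit"
            )


def classify_motif_hit(
    variant: VariantRecord,
    motif: MinimotifInstance,
    residue_position: int,
    ref_residue: str,
    alt_residue: str,
) -> Tuple[str, bool]:
    """(motif_position_kind, ser_thr_transition) for a motif residue hit."""
    critical = (
        motif.mmod_position is not None and residue_position == motif.mmod_position
    )
    kind = "critical" if critical else "degenerate"
    ser_thr = (
        critical
        and motif.activity == "phosphorylation"
        and {ref_residue, alt_residue} == {"S", "T"}
    )
    return kind, ser_thr


def assign_lofm_dm(
    motif_position_kind: str,
    ser_thr_transition: bool,
    effect: str,
    variant: VariantRecord,
) -> str:
    """Classify a critical-residue missense hit as LOFM or DM.

    Restricted to autosomal variants with a known ancestral allele; everything
    else is 'unknown_ancestral'. Non-critical, synonymous or Ser/Thr hits are
    'neither'.
    """
    if motif_position_kind != "critical" or effect != "missense" or ser_thr_transition:
        return "neither"
    if variant.ancestral is None or not variant.autosomal:
        return "unknown_ancestral"
    if variant.ancestral == variant.ref:
        return "LOFM"
    if variant.ancestral == variant.alt:
        return "DM"
    logger.warning(
        "%s: ancestral allele %r equals neither REF nor ALT", variant.key, variant.ancestral
    )
    return "unknown_ancestral"


def compute_maf(variant: VariantRecord, rare_cutoff: float = 0.01) -> Tuple[float, str]:
    """Minor allele frequency over called chromosomes and its class.

    Singleton = minor-allele count exactly 1 (takes precedence over rare);
    rare = MAF strictly below the cutoff (default 1%); common otherwise.
    """
    nref, nalt = variant.allele_counts()
    called = nref + nalt
    if called == 0:
        raise DataError(f"{variant.key}: all genotypes missing")
    minor = min(nref, nalt)
    maf = minor / called
    if minor == 1:
        cls = "singleton"
    elif maf < rare_cutoff:
        cls = "rare"
    else:
        cls = "common"
    return maf, cls


# ---------------------------------------------------------------------------
# cohort driver

def classify_cohort(
    genome: Iterable[GenomeSequence] | Mapping[str, str],
    models: Sequence[TranscriptModel],
    minimotifs: Sequence[MinimotifInstance],
    variants: Sequence[VariantRecord],
    codon_index: Optional[CodonIndex] = None,
    rare_cutoff: float = 0.01,
) -> List[ClassifiedMinimotifVariant]:
    """Classify every motif x variant pair in the cohort.

    A variant overlapping several motifs yields one record per motif
    (motif-instance counting; the distinct-SNP summary row deduplicates).
    Nonsense hits are tallied as missense but flagged.
    """
    contigs = genome if isinstance(genome, Mapping) else genome_dict(genome)
    if codon_index is None:
        codon_index = CodonIndex(models)
    motifs_by_residue: Dict[Tuple[str, int], List[MinimotifInstance]] = {}
    for motif in minimotifs:
        for residue in range(motif.start, motif.end + 1):
            motifs_by_residue.setdefault((motif.protein_id, residue), []).append(motif)
    out: List[ClassifiedMinimotifVariant] = []
    for variant in variants:
        hit = codon_index.locate(variant)
        if hit is None:
            continue
        model, cds_idx = hit
        residue = residue_of_cds_index(cds_idx)
        overlapping = motifs_by_residue.get((model.protein_id, residue))
        if not overlapping:
            continue
        ref_codon, alt_codon = _ref_alt_codons(variant, model, cds_idx, contigs)
        ref_aa = _translate_codon(ref_codon)
        alt_aa = _translate_codon(alt_codon)
        if ref_aa == "*":  # terminal stop codon: not a protein residue
            continue
        nonsense = alt_aa == "*"
        effect = "synonymous" if (ref_aa == alt_aa and not nonsense) else "missense"
        maf, maf_class = compute_maf(variant, rare_cutoff)
        for motif in overlapping:
            kind, ser_thr = classify_motif_hit(variant, motif, residue, ref_aa, alt_aa)
            if effect == "synonymous":
                ser_thr = False
            lof_dm = assign_lofm_dm(kind, ser_thr, effect, variant)
            out.append(
                ClassifiedMinimotifVariant(
                    motif_id=motif.motif_id,
                    variant_key=variant.key,
                    activity=motif.activity,
                    protein_id=motif.protein_id,
                    residue_position=residue,
                    ref_residue=ref_aa,
                    alt_residue=alt_aa,
                    effect=effect,
                    nonsense=nonsense,
                    motif_position_kind=kind,
                    ser_thr_transition=ser_thr,
                    lof_dm=lof_dm,
                    maf=maf,
                    maf_class=maf_class,
                )
            )
    return out


def classified_to_frame(classified: Sequence[ClassifiedMinimotifVariant]) -> pd.DataFrame:
    cols = [
        "motif_id",
        "variant_key",
        "activity",
        "protein_id",
        "residue_position",
        "ref_residue",
        "alt_residue",
        "effect",
        "nonsense",
        "motif_position_kind",
        "ser_thr_transition",
        "lof_dm",
        "maf",
        "maf_class",
    ]
    return pd.DataFrame(
        [[getattr(c, col) for col in cols] for c in classified], columns=cols
    )


# ---------------------------------------------------------------------------
# Table-1-style summary

def summarize_by_activity(
    classified: Sequence[ClassifiedMinimotifVariant],
    minimotifs: Sequence[MinimotifInstance],
) -> pd.DataFrame:
    """Per-activity minimotif tallies.

    Columns: activity, n_critical (motifs with a critical-residue missense
    SNP, Ser-Thr transitions excluded and counted separately), n_ser_thr,
    n_missense (motifs with any missense SNP), n_with_snp (motifs with any
    SNP), n_total, and the corresponding percentages of n_total. A final
    'distinct_snps' row counts deduplicated variants per category.
    """
    totals: Dict[str, int] = {}
    for motif in minimotifs:
        totals[motif.activity] = totals.get(motif.activity, 0) + 1
    critical_motifs: Dict[str, set] = {}
    ser_thr_motifs: Dict[str, set] = {}
    missense_motifs: Dict[str, set] = {}
    any_motifs: Dict[str, set] = {}
    snp_critical: set = set()
    snp_ser_thr: set = set()
    snp_missense: set = set()
    snp_any: set = set()
    for rec in classified:
        a = rec.activity
        any_motifs.setdefault(a, set()).add(rec.motif_id)
        snp_any.add(rec.variant_key)
        if rec.effect == "missense":
            missense_motifs.setdefault(a, set()).add(rec.motif_id)
            snp_missense.add(rec.variant_key)
            if rec.motif_position_kind == "critical":
                if rec.ser_thr_transition:
                    ser_thr_motifs.setdefault(a, set()).add(rec.motif_id)
                    snp_ser_thr.add(rec.variant_key)
                else:
                    critical_motifs.setdefault(a, set()).add(rec.motif_id)
                    snp_critical.add(rec.variant_key)
    rows = []
    activities = sorted(totals)
    for a in activities:
        total = totals[a]
        n_crit = len(critical_motifs.get(a, ()))
        n_st = len(ser_thr_motifs.get(a, ()))
        n_mis = len(missense_motifs.get(a, ()))
        n_any = len(any_motifs.get(a, ()))
        rows.append(
            {
                "activity": a,
                "n_critical": n_crit,
                "n_ser_thr": n_st,
                "n_missense": n_mis,
                "n_with_snp": n_any,
                "n_total": total,
                "pct_critical": 100.0 * n_crit / total if total else 0.0,
                "pct_missense": 100.0 * n_mis / total if total else 0.0,
                "pct_with_snp": 100.0 * n_any / total if total else 0.0,
            }
        )
    grand_total = sum(totals.values())
    sums = {
        "n_critical": sum(r["n_critical"] for r in rows),
        "n_ser_thr": sum(r["n_ser_thr"] for r in rows),
        "n_missense": sum(r["n_missense"] for r in rows),
        "n_with_snp": sum(r["n_with_snp"] for r in rows),
    }
    rows.append(
        {
            "activity": "total",
            **sums,
            "n_total": grand_total,
            "pct_critical": 100.0 * sums["n_critical"] / grand_total if grand_total else 0.0,
            "pct_missense": 100.0 * sums["n_missense"] / grand_total if grand_total else 0.0,
            "pct_with_snp": 100.0 * sums["n_with_snp"] / grand_total if grand_total else 0.0,
        }
    )
    rows.append(
        {
            "activity": "distinct_snps",
            "n_critical": len(snp_critical),
            "n_ser_thr": len(snp_ser_thr),
            "n_missense": len(snp_missense),
            "n_with_snp": len(snp_any),
            "n_total": 0,
            "pct_critical": 0.0,
            "pct_missense": 0.0,
            "pct_with_snp": 0.0,
        }
    )
    return pd.DataFrame(rows)


def summarize_lofm_dm(
    classified: Sequence[ClassifiedMinimotifVariant],
) -> pd.DataFrame:
    """Per-activity DM and LOFM minimotif counts (autosomal, known-ancestral
    critical hits only), with a totals row."""
    dm: Dict[str, set] = {}
    lofm: Dict[str, set] = {}
    acts = set()
    for rec in classified:
        if rec.lof_dm == "DM":
            dm.setdefault(rec.activity, set()).add(rec.motif_id)
            acts.add(rec.activity)
        elif rec.lof_dm == "LOFM":
            lofm.setdefault(rec.activity, set()).add(rec.motif_id)
            acts.add(rec.activity)
    rows = [
        {
            "activity": a,
            "n_dm": len(dm.get(a, ())),
            "n_lofm": len(lofm.get(a, ())),
        }
        for a in sorted(acts)
    ]
    rows.append(
        {
            "activity": "total",
            "n_dm": sum(r["n_dm"] for r in rows),
            "n_lofm": sum(r["n_lofm"] for r in rows),
        }
    )
    return pd.DataFrame(rows)
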