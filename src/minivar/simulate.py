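"""Synthetic study generator.

Produces a complete, fully labelled stand-in for the real study inputs: a
reference genome with multi-exon transcript models on both strands, the
translated proteome, minimotif annotations with critical (mmod) residues, a
diploid genotype panel with a controlled site-frequency spectrum and
population structure, ancestral alleles, class-conditional conservation
scores, a high-confidence mask and a sample panel — plus ground-truth labels
for every downstream classification.

The generator makes no claim of coalescent realism (no linkage, recombination
or phasing structure): allele frequencies are drawn per site from a Beta
minor-allele-frequency distribution skewed toward rare variants, population
structure is frequency jitter around a global value, and genotypes are
binomial per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SpecError
from .io_formats import VariantTable, annotate_mask
from .proteome import build_reference_proteome, complement_base, reverse_complement
from .records import (
    DNA_BASES,
    GenomeSequence,
    MaskTrack,
    MinimotifInstance,
    MMOD_ACTIVITIES,
    PanelRecord,
    Protein,
    ScoreRecord,
    TranscriptModel,
    VariantRecord,
)

logger = logging.getLogger(__name__)

_STOP_CODONS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in DNA_BASES
    for b in DNA_BASES
    for c in DNA_BASES
    if a + b + c not in _STOP_CODONS
)
_CODON_TABLE = {}
from Bio.Seq import Seq as _Seq  # noqa: E402

for _c in _NONSTOP_CODONS:
    _CODON_TABLE[_c] = str(_Seq(_c).translate())
for _c in _STOP_CODONS:
    _CODON_TABLE[_c] = "*"

#: observed GERP range the emitted scores are clipped to
GERP_RANGE = (-12.3, 6.2)


@dataclass(frozen=True)
class PopulationSpec:
    code: str
    continent: str
    n_samples: int
    admixed: bool = False


def default_populations() -> Tuple[PopulationSpec, ...]:
    """Ten populations over three continents, one admixed, echoing the shape
    of the 1000 Genomes phase 1 panel at a desk-scale sample size."""
    return (
        PopulationSpec("YRI", "AFR", 12),
        PopulationSpec("LWK", "AFR", 12),
        PopulationSpec("ASW", "AFR", 12, admixed=True),
        PopulationSpec("CEU", "EUR", 12),
        PopulationSpec("TSI", "EUR", 12),
        PopulationSpec("GBR", "EUR", 12),
        PopulationSpec("FIN", "EUR", 12),
        PopulationSpec("CHB", "ASN", 12),
        PopulationSpec("CHS", "ASN", 12),
        PopulationSpec("JPT", "ASN", 12),
    )


def default_activity_mix() -> Dict[str, float]:
    return {
        "phosphorylation": 0.62,
        "proteolysis": 0.11,
        "ubiquitination": 0.11,
        "acetylation": 0.08,
        "glycosylation": 0.03,
        "binding": 0.05,
    }


def default_score_model() -> Dict[str, Dict[str, Tuple[float, float]]]:
    """Class-conditional (mean, sd) for each score, per selection class."""
    return {
        "negative": {"gerp": (4.0, 1.0), "slr": (-6.0, 1.5), "phylop": (2.0, 1.0)},
        "neutral": {"gerp": (0.5, 1.0), "slr": (0.0, 1.2), "phylop": (0.5, 1.0)},
        "positive": {"gerp": (-2.0, 1.0), "slr": (6.0, 1.5), "phylop": (-0.5, 1.0)},
    }


@dataclass
class CohortSpec:
    """Full specification of a synthetic study."""

    n_genes: int = 200
    exons_per_gene: Tuple[int, int] = (1, 4)
    cds_codons: Tuple[int, int] = (60, 200)
    populations: Tuple[PopulationSpec, ...] = field(default_factory=default_populations)
    n_minimotifs: int = 2000
    activity_mix: Dict[str, float] = field(default_factory=default_activity_mix)
    n_variants: int = 5000
    sfs_shape: Tuple[float, float] = (0.2, 2.0)  # Beta(a, b) minor-AF skew
    #: optional two-point SFS (rare_mass, rare_freq, common_freq) replacing the
    #: Beta draw; keeps planted rare mass away from the 1% boundary so that
    #: recovery experiments are well-posed at finite sample size
    sfs_two_point: Optional[Tuple[float, float, float]] = None
    fraction_critical: float = 0.15
    fraction_derived_motif: float = 0.05
    fraction_noncoding: float = 0.10
    fraction_missing_ancestral: float = 0.05
    fraction_unknown_id: float = 0.02
    fraction_missing_gt: float = 0.01
    fraction_x_genes: float = 0.05
    divergence: float = 0.0  # between-continent frequency sd
    within_jitter: float = 0.01  # within-continent population sd
    n_high_ddaf_sites: int = 0
    ddaf_gap: float = 0.8
    mask_coverage: float = 0.9
    score_model: Dict[str, Dict[str, Tuple[float, float]]] = field(
        default_factory=default_score_model
    )
    slr_mixture: Tuple[float, float, float] = (0.60, 0.38, 0.02)
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return sum(p.n_samples for p in self.populations)

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_minimotifs < 0 or self.n_variants < 0:
            raise SpecError("counts must be positive")
        if self.cds_codons[0] < 2:
            raise SpecError("CDS must be at least 2 codons")
        if self.cds_codons[0] > self.cds_codons[1]:
            raise SpecError("cds_codons range inverted")
        if abs(sum(self.activity_mix.values()) - 1.0) > 1e-9:
            raise SpecError("activity_mix must sum to 1")
        for name in (
            "fraction_critical",
            "fraction_derived_motif",
            "fraction_noncoding",
            "fraction_missing_ancestral",
            "fraction_unknown_id",
            "fraction_missing_gt",
            "fraction_x_genes",
            "mask_coverage",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SpecError(f"{name} must be in [0, 1]")
        if abs(sum(self.slr_mixture) - 1.0) > 1e-9:
            raise SpecError("slr_mixture must sum to 1")
        if self.sfs_two_point is not None:
            mass, rare_f, common_f = self.sfs_two_point
            if not (0.0 <= mass <= 1.0) or not (0 < rare_f < common_f <= 0.5):
                raise SpecError("sfs_two_point must be (mass in [0,1], 0 < rare < common <= 0.5)")
        if not self.populations:
            raise SpecError("at least one population required")

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        d = dict(d)
        if "populations" in d:
            d["populations"] = tuple(
                PopulationSpec(
                    p["code"], p["continent"], int(p["n_samples"]),
                    bool(p.get("admixed", False)),
                )
                for p in d["populations"]
            )
        for key in ("exons_per_gene", "cds_codons", "sfs_shape", "slr_mixture",
                    "sfs_two_point"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "score_model" in d:
            d["score_model"] = {
                cls_: {s: tuple(ms) for s, ms in scores.items()}
                for cls_, scores in d["score_model"].items()
            }
        spec = cls(**d)
        spec.validate()
        return spec


@dataclass
class SyntheticCohort:
    """Everything simulate_cohort produces, with ground truth."""

    spec: CohortSpec
    genome: List[GenomeSequence]
    models: List[TranscriptModel]
    reference_proteome: List[Protein]
    minimotifs: List[MinimotifInstance]
    variants: VariantTable
    panel: List[PanelRecord]
    mask: MaskTrack
    scores: Dict[Tuple[str, int], ScoreRecord]
    truth_variants: pd.DataFrame
    truth_pairs: pd.DataFrame


# ---------------------------------------------------------------------------
# reference genome + transcripts

def simulate_reference(
    spec: CohortSpec, rng: Optional[np.random.Generator] = None
) -> Tuple[List[GenomeSequence], List[TranscriptModel], List[Protein]]:
    """Random genome and transcript models whose CDSs translate cleanly.

    About half the genes land on the minus strand (the genome stores the
    reverse complement); multi-exon genes have exon boundaries at arbitrary
    transcript offsets, so codons straddle junctions; a third of genes carry a
    nonzero frame offset.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    autosomes = ["chr1", "chr2", "chr3"]
    contig_parts: Dict[str, List[str]] = {c: [] for c in autosomes}
    contig_len: Dict[str, int] = {c: 0 for c in autosomes}
    if spec.fraction_x_genes > 0:
        contig_parts["chrX"] = []
        contig_len["chrX"] = 0
    models: List[TranscriptModel] = []
    base_arr = np.array(list("ACGT"))
    for g in range(spec.n_genes):
        if spec.fraction_x_genes > 0 and rng.random() < spec.fraction_x_genes:
            contig = "chrX"
        else:
            contig = autosomes[g % len(autosomes)]
        n_codons = int(rng.integers(spec.cds_codons[0], spec.cds_codons[1] + 1))
        body = rng.choice(len(_NONSTOP_CODONS), size=n_codons - 1)
        cds = "ATG" + "".join(_NONSTOP_CODONS[i] for i in body)
        cds += _STOP_CODONS[int(rng.integers(3))]
        frame = int(rng.choice([0, 0, 1, 2])) if rng.random() < 0.5 else 0
        pad = "".join(rng.choice(base_arr, size=frame)) if frame else ""
        tx_seq = pad + cds
        strand = "-" if rng.random() < 0.5 else "+"
        n_exons = int(
            rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1)
        )
        n_exons = min(n_exons, len(tx_seq) - 1)
        cuts = (
            sorted(rng.choice(np.arange(1, len(tx_seq)), size=n_exons - 1, replace=False))
            if n_exons > 1
            else []
        )
        bounds = [0] + [int(c) for c in cuts] + [len(tx_seq)]
        spacer = "".join(rng.choice(base_arr, size=int(rng.integers(50, 201))))
        offset = contig_len[contig] + len(spacer)
        block = tx_seq if strand == "+" else reverse_complement(tx_seq)
        contig_parts[contig].extend([spacer, block])
        contig_len[contig] = offset + len(block)
        exons: List[Tuple[int, int]] = []
        L = len(tx_seq)
        for lo, hi in zip(bounds, bounds[1:]):
            if strand == "+":
                exons.append((offset + lo, offset + hi))
            else:
                exons.append((offset + L - hi, offset + L - lo))
        models.append(
            TranscriptModel(
                tx_id=f"TX{g:05d}",
                protein_id=f"PROT{g:05d}",
                contig=contig,
                strand=strand,
                exons=exons,
                frame_offset=frame,
            )
        )
    genome = []
    for contig in contig_parts:
        tail = "".join(rng.choice(base_arr, size=int(rng.integers(50, 201))))
        contig_parts[contig].append(tail)
        genome.append(GenomeSequence(contig, "".join(contig_parts[contig])))
    proteome = build_reference_proteome(genome, models)
    if len(proteome) != len(models):
        raise AssertionError("synthetic CDS produced an internal stop codon")
    return genome, models, proteome


# ---------------------------------------------------------------------------
# mask

def simulate_mask(
    genome: Sequence[GenomeSequence], spec: CohortSpec, rng: np.random.Generator
) -> MaskTrack:
    """High-confidence mask: ~mask_coverage of each contig in 200 bp chunks."""
    triples: List[Tuple[str, int, int]] = []
    chunk = 200
    for g in genome:
        for s in range(0, len(g.sequence), chunk):
            if rng.random() < spec.mask_coverage:
                triples.append((g.contig_name, s, min(s + chunk, len(g.sequence))))
    return MaskTrack.from_intervals(triples)


# ---------------------------------------------------------------------------
# minimotifs

def simulate_minimotifs(
    proteome: Sequence[Protein],
    spec: CohortSpec,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[MinimotifInstance], pd.DataFrame]:
    """Place motif instances (length uniform in [2, 15]) on the proteome.

    Activities are multinomial draws from ``activity_mix``; every activity
    with a critical residue gets an mmod position inside the motif, and for
    phosphorylation the mmod residue is guaranteed to be Ser or Thr by
    placing the window around an existing S/T."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(3)[2])
    if spec.n_minimotifs == 0:
        return [], _empty_motif_truth()
    proteins = [p for p in proteome if len(p.residues) >= 2]
    if not proteins:
        raise SpecError("no proteins long enough to host minimotifs")
    lengths = np.array([len(p.residues) for p in proteins], dtype=np.float64)
    weights = lengths / lengths.sum()
    st_positions = {
        p.protein_id: [i + 1 for i, aa in enumerate(p.residues) if aa in "ST"]
        for p in proteins
    }
    activities = sorted(spec.activity_mix)
    probs = np.array([spec.activity_mix[a] for a in activities])
    needs_st = any(
        a == "phosphorylation" and spec.activity_mix[a] > 0 for a in activities
    )
    if needs_st and not any(st_positions.values()):
        raise SpecError("phosphorylation motifs requested but no Ser/Thr residues")
    motifs: List[MinimotifInstance] = []
    rows = []
    for m in range(spec.n_minimotifs):
        activity = activities[int(rng.choice(len(activities), p=probs))]
        length = int(rng.integers(2, 16))
        for _attempt in range(1000):
            pi = int(rng.choice(len(proteins), p=weights))
            prot = proteins[pi]
            plen = len(prot.residues)
            if plen < length:
                continue
            if activity == "phosphorylation":
                st = st_positions[prot.protein_id]
                if not st:
                    continue
                mmod = int(st[int(rng.integers(len(st)))])
                lo = max(1, mmod - length + 1)
                hi = min(mmod, plen - length + 1)
                if lo > hi:
                    continue
                start = int(rng.integers(lo, hi + 1))
            else:
                start = int(rng.integers(1, plen - length + 2))
                if activity in MMOD_ACTIVITIES:
                    mmod = start + int(rng.integers(length))
                else:
                    mmod = None
            end = start + length - 1
            motif = MinimotifInstance(
                motif_id=f"MM{m:06d}",
                protein_id=prot.protein_id,
                start=start,
                end=end,
                activity=activity,
                mmod_position=mmod,
                peptide=prot.residues[start - 1 : end],
            )
            motifs.append(motif)
            rows.append(
                {
                    "motif_id": motif.motif_id,
                    "protein_id": motif.protein_id,
                    "start": start,
                    "end": end,
                    "activity": activity,
                    "mmod_position": -1 if mmod is None else mmod,
                }
            )
            break
        else:
            raise SpecError(
                f"could not place minimotif {m} (activity {activity}, length {length})"
            )
    return motifs, pd.DataFrame(rows)


def _empty_motif_truth() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["motif_id", "protein_id", "start", "end", "activity", "mmod_position"]
    )


# ---------------------------------------------------------------------------
# variants

def _coding_strand_codon(
    contig_seq: str, positions: Sequence[int], strand: str, codon_idx: int
) -> str:
    bases = []
    for p in positions[codon_idx * 3 : codon_idx * 3 + 3]:
        b = contig_seq[p]
        bases.append(b if strand == "+" else complement_base(b))
    return "".join(bases)


def _substitution_options(ref_codon: str) -> List[Tuple[int, str, str]]:
    """All 9 single-base codon changes as (offset, alt coding base, alt aa),
    excluding stop gains."""
    out = []
    for offset in range(3):
        for base in DNA_BASES:
            if base == ref_codon[offset]:
                continue
            alt_codon = ref_codon[:offset] + base + ref_codon[offset + 1 :]
            aa = _CODON_TABLE[alt_codon]
            if aa == "*":
                continue
            out.append((offset, base, aa))
    return out


def simulate_variants(
    genome: Sequence[GenomeSequence],
    models: Sequence[TranscriptModel],
    minimotifs: Sequence[MinimotifInstance],
    spec: CohortSpec,
    rng: Optional[np.random.Generator] = None,
    mask: Optional[MaskTrack] = None,
) -> Tuple[VariantTable, List[PanelRecord], pd.DataFrame, pd.DataFrame]:
    """Plant biallelic SNVs with controlled placement and frequencies.

    Returns (variant table, sample panel, per-variant ground truth,
    per-motif-x-variant ground truth). Placement: ``fraction_critical`` of the
    coding variants on mmod codons (of which ``fraction_derived_motif`` get
    ancestral = alt, i.e. the motif residue is the derived state), the rest on
    random unused codons; ``fraction_noncoding`` land outside every exon.
    Stop gains and stop-codon edits are never planted, so personal proteomes
    stay length-aligned to the reference.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(4)[3])
    contigs = {g.contig_name: g.sequence for g in genome}
    panel: List[PanelRecord] = []
    for pop in spec.populations:
        for i in range(pop.n_samples):
            panel.append(
                PanelRecord(f"{pop.code}{i:04d}", pop.code, pop.continent, pop.admixed)
            )
    samples = [p.sample_id for p in panel]

    model_by_protein = {m.protein_id: m for m in models}
    coding_pos: Dict[str, List[int]] = {
        m.tx_id: m.coding_positions() for m in models
    }
    # registry of plantable codons (terminal stop codon excluded)
    codon_slots: List[Tuple[TranscriptModel, int]] = []
    for m in models:
        n_codons = len(coding_pos[m.tx_id]) // 3
        codon_slots.extend((m, ci) for ci in range(n_codons - 1))
    used_codons: set = set()

    n_noncoding = int(round(spec.n_variants * spec.fraction_noncoding))
    n_coding = spec.n_variants - n_noncoding
    mmod_motifs = [mm for mm in minimotifs if mm.mmod_position is not None]
    n_critical = min(int(round(n_coding * spec.fraction_critical)), len(mmod_motifs))
    if spec.n_high_ddaf_sites > n_critical:
        raise SpecError("n_high_ddaf_sites exceeds the number of critical variants")

    planted: List[dict] = []  # staging records before genotype sampling

    # --- critical (mmod-codon) variants -----------------------------------
    order = rng.permutation(len(mmod_motifs))
    n_planted_critical = 0
    n_high_planted = 0
    want_dm = int(round(n_critical * spec.fraction_derived_motif))
    n_dm_planted = 0
    for oi in order:
        if n_planted_critical >= n_critical:
            break
        motif = mmod_motifs[int(oi)]
        model = model_by_protein[motif.protein_id]
        ci = motif.mmod_position - 1
        key = (model.tx_id, ci)
        if key in used_codons:
            continue
        positions = coding_pos[model.tx_id]
        ref_codon = _coding_strand_codon(contigs[model.contig], positions, model.strand, ci)
        ref_aa = _CODON_TABLE[ref_codon]
        options = [
            (off, base, aa) for off, base, aa in _substitution_options(ref_codon)
            if aa != ref_aa
        ]
        if not options:
            continue
        need_high = n_high_planted < spec.n_high_ddaf_sites
        if need_high:
            # high-ΔDAF sites must be classifiable LOFM/DM: autosomal and,
            # for phosphorylation, not a Ser<->Thr swap
            if model.contig == "chrX":
                continue
            filtered = [
                o for o in options
                if not (
                    motif.activity == "phosphorylation"
                    and {ref_aa, o[2]} == {"S", "T"}
                )
            ]
            if not filtered:
                continue
            options = filtered
        offset, alt_coding, alt_aa = options[int(rng.integers(len(options)))]
        gpos = positions[ci * 3 + offset]
        ref_base = contigs[model.contig][gpos]
        alt_base = alt_coding if model.strand == "+" else complement_base(alt_coding)
        ser_thr = (
            motif.activity == "phosphorylation" and {ref_aa, alt_aa} == {"S", "T"}
        )
        is_dm = False
        if not need_high and not ser_thr and model.contig != "chrX":
            if n_dm_planted < want_dm:
                is_dm = True
                n_dm_planted += 1
        used_codons.add(key)
        planted.append(
            {
                "contig": model.contig,
                "gpos": gpos,
                "ref": ref_base,
                "alt": alt_base,
                "kind": "critical",
                "model": model,
                "codon_idx": ci,
                "ref_aa": ref_aa,
                "alt_aa": alt_aa,
                "effect": "missense",
                "ancestral": alt_base if is_dm else ref_base,
                "high_ddaf": need_high,
            }
        )
        n_planted_critical += 1
        if need_high:
            n_high_planted += 1
    if n_high_planted < spec.n_high_ddaf_sites:
        raise SpecError("could not place all requested high-ΔDAF sites")

    # --- random coding variants -------------------------------------------
    n_random = n_coding - n_planted_critical
    slot_order = rng.permutation(len(codon_slots))
    si = 0
    n_random_planted = 0
    while n_random_planted < n_random and si < len(slot_order):
        model, ci = codon_slots[int(slot_order[si])]
        si += 1
        key = (model.tx_id, ci)
        if key in used_codons:
            continue
        positions = coding_pos[model.tx_id]
        ref_codon = _coding_strand_codon(contigs[model.contig], positions, model.strand, ci)
        options = _substitution_options(ref_codon)
        if not options:
            continue
        offset, alt_coding, alt_aa = options[int(rng.integers(len(options)))]
        ref_aa = _CODON_TABLE[ref_codon]
        gpos = positions[ci * 3 + offset]
        used_codons.add(key)
        planted.append(
            {
                "contig": model.contig,
                "gpos": gpos,
                "ref": contigs[model.contig][gpos],
                "alt": alt_coding if model.strand == "+" else complement_base(alt_coding),
                "kind": "coding",
                "model": model,
                "codon_idx": ci,
                "ref_aa": ref_aa,
                "alt_aa": alt_aa,
                "effect": "synonymous" if ref_aa == alt_aa else "missense",
                "ancestral": None,  # filled below
                "high_ddaf": False,
            }
        )
        n_random_planted += 1
    if n_random_planted < n_random:
        raise SpecError("not enough free codons to plant the requested variants")

    # --- noncoding variants -------------------------------------------------
    exonic: Dict[str, set] = {c: set() for c in contigs}
    for m in models:
        for s, e in m.exons:
            exonic[m.contig].update(range(s, e))
    taken = {(p["contig"], p["gpos"]) for p in planted}
    nc_planted = 0
    contig_names = sorted(contigs)
    clens = np.array([len(contigs[c]) for c in contig_names], dtype=np.float64)
    cprobs = clens / clens.sum()
    attempts = 0
    while nc_planted < n_noncoding and attempts < 100 * max(n_noncoding, 1):
        attempts += 1
        contig = contig_names[int(rng.choice(len(contig_names), p=cprobs))]
        gpos = int(rng.integers(len(contigs[contig])))
        if gpos in exonic[contig] or (contig, gpos) in taken:
            continue
        ref_base = contigs[contig][gpos]
        if ref_base == "N":
            continue
        alt_base = DNA_BASES[int(rng.integers(4))]
        if alt_base == ref_base:
            continue
        taken.add((contig, gpos))
        planted.append(
            {
                "contig": contig,
                "gpos": gpos,
                "ref": ref_base,
                "alt": alt_base,
                "kind": "noncoding",
                "model": None,
                "codon_idx": None,
                "ref_aa": "",
                "alt_aa": "",
                "effect": "none",
                "ancestral": None,
                "high_ddaf": False,
            }
        )
        nc_planted += 1
    if nc_planted < n_noncoding:
        raise SpecError("could not place the requested noncoding variants")

    # ancestral alleles: default ref; a fraction unknown (never for criticals)
    for p in planted:
        if p["kind"] == "critical":
            continue
        if rng.random() < spec.fraction_missing_ancestral:
            p["ancestral"] = None
        else:
            p["ancestral"] = p["ref"]

    planted.sort(key=lambda p: (p["contig"], p["gpos"]))

    # --- frequencies and genotypes -----------------------------------------
    a, b = spec.sfs_shape
    continents = sorted({pop.continent for pop in spec.populations})
    n_by_pop = {pop.code: pop.n_samples for pop in spec.populations}
    pop_order = [pop.code for pop in spec.populations]
    pop_continent = {pop.code: pop.continent for pop in spec.populations}
    high_base = {"AFR": 0.05, "EUR": 0.05 + spec.ddaf_gap, "ASN": spec.ddaf_gap}

    records: List[VariantRecord] = []
    truth_rows: List[dict] = []
    pair_rows: List[dict] = []

    motifs_by_residue: Dict[Tuple[str, int], List[MinimotifInstance]] = {}
    for motif in minimotifs:
        for residue in range(motif.start, motif.end + 1):
            motifs_by_residue.setdefault((motif.protein_id, residue), []).append(motif)

    for p in planted:
        if p["high_ddaf"]:
            pop_freqs = {
                code: float(
                    np.clip(
                        high_base.get(pop_continent[code], 0.05)
                        + rng.normal(0.0, spec.within_jitter),
                        0.0,
                        1.0,
                    )
                )
                for code in pop_order
            }
        else:
            if spec.sfs_two_point is not None:
                mass, rare_f, common_f = spec.sfs_two_point
                q = rare_f if rng.random() < mass else common_f
            else:
                q = float(rng.beta(a, b))
            c_eff = {
                c: (rng.normal(0.0, spec.divergence) if spec.divergence > 0 else 0.0)
                for c in continents
            }
            pop_freqs = {
                code: float(
                    np.clip(
                        q + c_eff[pop_continent[code]]
                        + (rng.normal(0.0, spec.within_jitter) if spec.within_jitter > 0 else 0.0),
                        0.0,
                        1.0,
                    )
                )
                for code in pop_order
            }
        genotypes: Dict[str, Optional[Tuple[int, int]]] = {}
        n_ref = n_alt = 0
        for rec in panel:
            if spec.fraction_missing_gt > 0 and rng.random() < spec.fraction_missing_gt:
                genotypes[rec.sample_id] = None
                continue
            freq = pop_freqs[rec.population]
            a1 = int(rng.random() < freq)
            a2 = int(rng.random() < freq)
            gt = tuple(sorted((a1, a2)))
            genotypes[rec.sample_id] = gt  # type: ignore[assignment]
            n_alt += a1 + a2
            n_ref += 2 - a1 - a2
        known = rng.random() >= spec.fraction_unknown_id
        variant = VariantRecord(
            contig=p["contig"],
            position=p["gpos"] + 1,
            ref=p["ref"],
            alt=p["alt"],
            genotypes=genotypes,
            ancestral=p["ancestral"],
            known=known,
        )
        records.append(variant)

        called = n_ref + n_alt
        minor = min(n_ref, n_alt)
        if called == 0:
            maf, maf_class = 0.0, "rare"
        else:
            maf = minor / called
            maf_class = (
                "singleton" if minor == 1 else "rare" if maf < 0.01 else "common"
            )

        # pair-level truth (direct bookkeeping, includes chance motif overlaps)
        motif_kind = "none"
        lofm_any = ""
        if p["model"] is not None:
            residue = p["codon_idx"] + 1
            for motif in motifs_by_residue.get((p["model"].protein_id, residue), []):
                critical = motif.mmod_position == residue
                kind = "critical" if critical else "degenerate"
                ser_thr = (
                    critical
                    and motif.activity == "phosphorylation"
                    and p["effect"] == "missense"
                    and {p["ref_aa"], p["alt_aa"]} == {"S", "T"}
                )
                if not critical or p["effect"] != "missense" or ser_thr:
                    lofm = "neither"
                elif variant.ancestral is None or not variant.autosomal:
                    lofm = "unknown_ancestral"
                elif variant.ancestral == variant.ref:
                    lofm = "LOFM"
                else:
                    lofm = "DM"
                pair_rows.append(
                    {
                        "motif_id": motif.motif_id,
                        "variant_key": variant.key,
                        "motif_position_kind": kind,
                        "ser_thr_transition": ser_thr,
                        "lof_dm": lofm,
                    }
                )
                if kind == "critical":
                    motif_kind = "critical"
                elif motif_kind == "none":
                    motif_kind = "degenerate"
                if lofm in ("LOFM", "DM") and not lofm_any:
                    lofm_any = lofm
        truth_rows.append(
            {
                "variant_key": variant.key,
                "kind": p["kind"],
                "true_effect": p["effect"],
                "motif_hit": motif_kind,
                "lof_dm": lofm_any,
                "maf": maf,
                "maf_class": maf_class,
                "high_ddaf": p["high_ddaf"],
                **{f"freq_{code}": pop_freqs[code] for code in pop_order},
            }
        )

    table = VariantTable(records, samples)
    if mask is not None:
        annotate_mask(records, mask)
    truth_variants = pd.DataFrame(truth_rows)
    truth_pairs = pd.DataFrame(
        pair_rows,
        columns=[
            "motif_id", "variant_key", "motif_position_kind",
            "ser_thr_transition", "lof_dm",
        ],
    )
    return table, panel, truth_variants, truth_pairs


# ---------------------------------------------------------------------------
# scores

def simulate_scores(
    variants: Sequence[VariantRecord],
    spec: CohortSpec,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Dict[Tuple[str, int], ScoreRecord], pd.DataFrame]:
    """Class-conditional conservation scores per variant site.

    Each variant is assigned a latent selection class from ``slr_mixture``;
    SLR is drawn from a normal truncated to that class's interval (so the
    planted composition is recoverable by thresholding), GERP from the class
    normal clipped to the observed range, PhyloP from the class normal.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(5)[4])
    classes = ("negative", "neutral", "positive")
    bounds = {
        "negative": (-np.inf, -3.0 - 1e-9),
        "neutral": (-3.0 + 1e-9, 3.0 - 1e-9),
        "positive": (3.0 + 1e-9, np.inf),
    }
    probs = np.array(spec.slr_mixture)
    scores: Dict[Tuple[str, int], ScoreRecord] = {}
    rows = []
    for v in variants:
        key = (v.contig, v.position)
        if key in scores:
            continue
        cls = classes[int(rng.choice(3, p=probs))]
        model = spec.score_model[cls]
        g_mean, g_sd = model["gerp"]
        s_mean, s_sd = model["slr"]
        p_mean, p_sd = model["phylop"]
        lo, hi = bounds[cls]
        if s_sd == 0:
            slr = float(np.clip(s_mean, lo, hi))
        else:
            slr = float(
                stats.truncnorm.rvs(
                    (lo - s_mean) / s_sd, (hi - s_mean) / s_sd,
                    loc=s_mean, scale=s_sd, random_state=rng,
                )
            )
        gerp = float(np.clip(rng.normal(g_mean, g_sd) if g_sd > 0 else g_mean, *GERP_RANGE))
        phylop = float(rng.normal(p_mean, p_sd)) if p_sd > 0 else p_mean
        scores[key] = ScoreRecord(v.contig, v.position, gerp=gerp, slr=slr, phylop=phylop)
        rows.append({"variant_key": v.key, "selection_class": cls})
    return scores, pd.DataFrame(rows, columns=["variant_key", "selection_class"])


# ---------------------------------------------------------------------------
# full cohort

def simulate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Run every simulation stage under deterministically derived child seeds
    (stages can be re-run independently with the same streams)."""
    spec.validate()
    children = np.random.SeedSequence(spec.seed).spawn(5)
    rng_ref = np.random.default_rng(children[0])
    rng_mask = np.random.default_rng(children[1])
    rng_motif = np.random.default_rng(children[2])
    rng_var = np.random.default_rng(children[3])
    rng_score = np.random.default_rng(children[4])
    genome, models, proteome = simulate_reference(spec, rng_ref)
    mask = simulate_mask(genome, spec, rng_mask)
    minimotifs, truth_motifs = simulate_minimotifs(proteome, spec, rng_motif)
    variants, panel, truth_variants, truth_pairs = simulate_variants(
        genome, models, minimotifs, spec, rng_var, mask
    )
    scores, truth_classes = simulate_scores(variants.records, spec, rng_score)
    if not truth_variants.empty:
        truth_variants = truth_variants.merge(truth_classes, on="variant_key", how="left")
    return SyntheticCohort(
        spec=spec,
        genome=genome,
        models=models,
        reference_proteome=proteome,
        minimotifs=minimotifs,
        variants=variants,
        panel=panel,
        mask=mask,
        scores=scores,
        truth_variants=truth_variants,
        truth_pairs=truth_pairs,
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> Dict[str, str]:
    """Emit every io_formats dialect plus ground-truth TSVs; returns the file
    map. Fixed seed => byte-identical files."""
    from pathlib import Path

    from . import io_formats as io

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "transcripts": out / "transcripts.tsv",
        "proteome": out / "proteome.fa",
        "minimotifs": out / "minimotifs.tsv",
        "variants": out / "variants.vcf",
        "panel": out / "panel.tsv",
        "mask": out / "mask.bed",
        "scores": out / "scores.tsv",
        "truth_variants": out / "truth_variants.tsv",
        "truth_pairs": out / "truth_pairs.tsv",
    }
    io.write_fasta(cohort.genome, paths["genome"])
    io.write_transcript_models(cohort.models, paths["transcripts"])
    io.write_fasta(cohort.reference_proteome, paths["proteome"])
    io.write_minimotif_table(cohort.minimotifs, paths["minimotifs"])
    io.write_variant_table(cohort.variants, paths["variants"])
    io.write_panel(cohort.panel, paths["panel"])
    io.write_mask(cohort.mask, paths["mask"])
    io.write_score_table(cohort.scores, paths["scores"])
    cohort.truth_variants.to_csv(paths["truth_variants"], sep="\t", index=False)
    cohort.truth_pairs.to_csv(paths["truth_pairs"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
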