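"""Core record types shared across the pipeline.

Coordinate conventions (converted only through :mod:`minivar.coords`):

* genomic intervals — 0-based half-open;
* VCF-style and score-table positions — 1-based;
* protein residue positions — 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .errors import ValidationError

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
DNA_BASES = ("A", "C", "G", "T")

#: canonical row order of amino acids in a MatchMatrix
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

#: activity classes a minimotif may carry
ACTIVITIES = frozenset(
    {
        "acetylation",
        "di-methylation",
        "glycosylation",
        "lipid",
        "mono-methylation",
        "o-glcnac",
        "phosphorylation",
        "proteolysis",
        "tri-methylation",
        "ubiquitination",
        "sumoylation",
        "dephosphorylation",
        "nitration",
        "crotonylation",
        "binding",
        "trafficking",
    }
)

#: activities whose instances designate a critical (covalently modified or
#: cleaved) residue via ``mmod_position``
MMOD_ACTIVITIES = ACTIVITIES - {"binding", "trafficking"}

#: contigs excluded from LOFM/DM assignment (the autosomal-only rule)
NON_AUTOSOMES = frozenset({"X", "chrX", "Y", "chrY", "MT", "chrM", "chrMT"})

CONTINENTS = ("AFR", "EUR", "ASN")


@dataclass
class GenomeSequence:
    """One contig of the (reference or personal) genome."""

    contig_name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"contig {self.contig_name!r}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValidationError(
                f"contig {self.contig_name!r}: characters outside ACGTN: {sorted(bad)}"
            )


@dataclass
class MaskTrack:
    """High-confidence genomic intervals, sorted and disjoint per contig.

    ``intervals`` maps contig -> list of (start, end) 0-based half-open.
    """

    intervals: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)

    @classmethod
    def from_intervals(
        cls, triples: List[Tuple[str, int, int]], warn_on_merge: bool = True
    ) -> "MaskTrack":
        """Build a track from (contig, start, end) triples, merging overlaps."""
        per: Dict[str, List[Tuple[int, int]]] = {}
        for contig, start, end in triples:
            if end <= start:
                raise ValidationError(f"mask interval {contig}:{start}-{end}: end <= start")
            per.setdefault(contig, []).append((start, end))
        merged_any = False
        for contig, ivs in per.items():
            ivs.sort()
            out: List[Tuple[int, int]] = []
            for s, e in ivs:
                if out and s <= out[-1][1]:
                    if s < out[-1][1]:
                        merged_any = True
                    out[-1] = (out[-1][0], max(out[-1][1], e))
                else:
                    out.append((s, e))
            per[contig] = out
        if merged_any and warn_on_merge:
            logger.warning("track contained overlapping intervals; merged on read")
        return cls(per)

    def contains(self, contig: str, pos0: int) -> bool:
        import bisect

        ivs = self.intervals.get(contig)
        if not ivs:
            return False
        i = bisect.bisect_right([s for s, _ in ivs], pos0) - 1
        return i >= 0 and ivs[i][0] <= pos0 < ivs[i][1]

    def as_triples(self) -> List[Tuple[str, int, int]]:
        return [
            (contig, s, e)
            for contig in sorted(self.intervals)
            for s, e in self.intervals[contig]
        ]


@dataclass
class ScoreRecord:
    """Per-site conservation/selection scores; absent scores are ``None``."""

    contig: str
    position: int  # 1-based
    gerp: Optional[float] = None
    slr: Optional[float] = None
    phylop: Optional[float] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"score position {self.position} < 1")
        if self.gerp is None and self.slr is None and self.phylop is None:
            raise ValidationError(
                f"score record {self.contig}:{self.position}: no score present"
            )


@dataclass
class PanelRecord:
    """Sample -> population -> continent assignment."""

    sample_id: str
    population: str
    continent: str  # AFR, EUR, ASN or "other"
    admixed: bool = False


@dataclass
class TranscriptModel:
    """Coding geometry of one transcript.

    ``exons`` are 0-based half-open genomic intervals stored in transcript
    (5'->3') order: ascending genomic coordinates on '+', descending on '-'.
    ``frame_offset`` bases at the transcript 5' end are skipped before the
    first codon.
    """

    tx_id: str
    protein_id: str
    contig: str
    strand: str
    exons: List[Tuple[int, int]]
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.tx_id}: strand must be '+' or '-'")
        if self.frame_offset not in (0, 1, 2):
            raise ValidationError(f"{self.tx_id}: frame_offset must be 0, 1 or 2")
        if not self.exons:
            raise ValidationError(f"{self.tx_id}: no exons")
        for s, e in self.exons:
            if e <= s:
                raise ValidationError(f"{self.tx_id}: exon {s}-{e} has end <= start")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValidationError(f"{self.tx_id}: overlapping exons")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expected:
            raise ValidationError(
                f"{self.tx_id}: exons not sorted 5'->3' in transcript orientation"
            )
        if (self.coding_length) % 3 != 0:
            raise ValidationError(
                f"{self.tx_id}: coding length {self.coding_length} not a multiple of 3 "
                f"after frame offset {self.frame_offset}"
            )

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def coding_length(self) -> int:
        return self.exon_length - self.frame_offset

    def coding_positions(self) -> List[int]:
        """Genomic positions (0-based) of coding bases, in translation order.

        On the minus strand positions descend genomically; the base at each
        position must be complemented to obtain the coding-strand base.
        """
        pos: List[int] = []
        for s, e in self.exons:
            if self.strand == "+":
                pos.extend(range(s, e))
            else:
                pos.extend(range(e - 1, s - 1, -1))
        return pos[self.frame_offset :]


@dataclass
class Protein:
    """A translated protein; personal proteomes may contain 'X' for unknown
    residues and may be truncated by stop-gain variants."""

    protein_id: str
    residues: str


@dataclass
class MinimotifInstance:
    """A short linear motif instance in protein coordinates."""

    motif_id: str
    protein_id: str
    start: int  # 1-based inclusive
    end: int
    activity: str
    mmod_position: Optional[int] = None
    peptide: str = ""

    def __post_init__(self) -> None:
        length = self.end - self.start + 1
        if not (2 <= length <= 15):
            raise ValidationError(
                f"{self.motif_id}: motif length {length} outside [2, 15]"
            )
        if self.activity not in ACTIVITIES:
            raise ValidationError(f"{self.motif_id}: unknown activity {self.activity!r}")
        if self.mmod_position is not None and not (
            self.start <= self.mmod_position <= self.end
        ):
            raise ValidationError(
                f"{self.motif_id}: mmod position {self.mmod_position} outside "
                f"[{self.start}, {self.end}]"
            )
        if self.peptide and len(self.peptide) != length:
            raise ValidationError(
                f"{self.motif_id}: peptide length {len(self.peptide)} != span {length}"
            )


Genotype = Optional[Tuple[Optional[int], Optional[int]]]


@dataclass
class VariantRecord:
    """One biallelic SNV with per-sample diploid genotypes.

    ``genotypes`` maps sample id -> unordered allele pair (0=ref, 1=alt);
    a ``None`` pair is a fully missing call ("./."), a ``None`` allele within
    a pair is a half-call (arises from multi-allelic splitting).
    """

    contig: str
    position: int  # 1-based
    ref: str
    alt: str
    genotypes: Dict[str, Genotype]
    ancestral: Optional[str] = None
    known: bool = True
    masked: bool = False

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValidationError(
                f"{self.key}: REF/ALT must be single bases (biallelic SNV)"
            )
        if self.ref == self.alt:
            raise ValidationError(f"{self.key}: REF == ALT")
        if self.position < 1:
            raise ValidationError(f"{self.key}: non-positive position")

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.position}:{self.ref}>{self.alt}"

    @property
    def pos0(self) -> int:
        return self.position - 1

    def allele_counts(self) -> Tuple[int, int]:
        """(ref allele count, alt allele count) over called alleles."""
        nref = nalt = 0
        for gt in self.genotypes.values():
            if gt is None:
                continue
            for a in gt:
                if a == 0:
                    nref += 1
                elif a == 1:
                    nalt += 1
        return nref, nalt

    @property
    def autosomal(self) -> bool:
        return self.contig not in NON_AUTOSOMES
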