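"""Readers and writers for every on-disk format the pipeline touches.

All dialects are plain-text and loss-free on round trip:

* FASTA (genome, proteomes);
* a minimal tab-separated VCF 4.x subset (GT-only FORMAT, ``AA=`` INFO key);
* BED3 (high-confidence mask);
* TSVs for minimotifs, transcript models, per-site scores, sample panel and
  summary tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .errors import AlphabetError, FormatError, ParseError, ValidationError
from .records import (
    DNA_ALPHABET,
    GenomeSequence,
    Genotype,
    MaskTrack,
    MinimotifInstance,
    PanelRecord,
    Protein,
    ScoreRecord,
    TranscriptModel,
    VariantRecord,
)

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> List[GenomeSequence]:
    """Read a DNA FASTA file; sequences are uppercased and alphabet-checked."""
    records: List[Tuple[str, List[str]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if line[1:].strip() else ""
                if not name:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                records.append((name, []))
            else:
                if not records:
                    raise FormatError(
                        f"{path}: sequence before first header at line {lineno}"
                    )
                body = line.strip().upper()
                bad = set(body) - DNA_ALPHABET
                if bad:
                    raise AlphabetError(
                        f"{path}: line {lineno}: characters outside ACGTN: {sorted(bad)}"
                    )
                records[-1][1].append(body)
    if not records:
        raise FormatError(f"{path}: empty FASTA file")
    out = []
    for name, chunks in records:
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}: record {name!r} has no sequence")
        out.append(GenomeSequence(name, seq))
    return out


def write_fasta(records: Iterable, path, width: int = 60) -> None:
    """Write GenomeSequence/Protein records (or (name, seq) pairs) as FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, GenomeSequence):
                name, seq = rec.contig_name, rec.sequence
            elif isinstance(rec, Protein):
                name, seq = rec.protein_id, rec.residues
            else:
                name, seq = rec
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_protein_fasta(path) -> List[Protein]:
    """Read a protein FASTA (no alphabet restriction beyond non-empty)."""
    proteins: List[Protein] = []
    name: Optional[str] = None
    chunks: List[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    proteins.append(Protein(name, "".join(chunks)))
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line.upper())
    if name is not None:
        proteins.append(Protein(name, "".join(chunks)))
    if not proteins:
        raise FormatError(f"{path}: empty FASTA file")
    return proteins


# ---------------------------------------------------------------------------
# simplified VCF

@dataclass
class VariantTable:
    """Parsed variant panel: biallelic SNV records plus parsing bookkeeping."""

    records: List[VariantRecord]
    samples: List[str]
    dropped: Dict[str, int] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]


def _parse_gt(token: str, sample: str, lineno: int, path) -> Genotype:
    gt = token.split(":", 1)[0]
    sep = "/" if "/" in gt else ("|" if "|" in gt else None)
    if sep is None:
        raise ParseError(
            f"{path}: line {lineno}: malformed GT {gt!r} for sample {sample!r}"
        )
    parts = gt.split(sep)
    if len(parts) != 2:
        raise ParseError(
            f"{path}: line {lineno}: malformed GT {gt!r} for sample {sample!r}"
        )
    alleles: List[Optional[int]] = []
    for p in parts:
        if p == ".":
            alleles.append(None)
        elif p.isdigit():
            alleles.append(int(p))
        else:
            raise ParseError(
                f"{path}: line {lineno}: malformed GT {gt!r} for sample {sample!r}"
            )
    if alleles[0] is None and alleles[1] is None:
        return None
    return (alleles[0], alleles[1])


def read_variant_table(path, dialect: str = "vcf", drop_unknown: bool = False) -> VariantTable:
    """Read the simplified VCF dialect, keeping only biallelic SNVs.

    Indels/structural alleles are dropped (counted); multi-allelic SNV sites
    are split into biallelic records sharing POS. Records whose ID is '.'
    are flagged ``known=False`` (and dropped entirely if ``drop_unknown``).
    Phase separators are accepted but phase is discarded.
    """
    if dialect != "vcf":
        raise FormatError(f"unknown variant dialect {dialect!r}")
    samples: List[str] = []
    records: List[VariantRecord] = []
    dropped = {"non_snv": 0, "unknown_id": 0}
    saw_header = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.lstrip("#").split("\t")
                if len(cols) < 10 or cols[8] != "FORMAT":
                    raise FormatError(f"{path}: line {lineno}: bad #CHROM header")
                samples = cols[9:]
                saw_header = True
                continue
            if not saw_header:
                raise FormatError(f"{path}: line {lineno}: data before #CHROM header")
            fields = line.split("\t")
            if len(fields) != 9 + len(samples):
                raise FormatError(
                    f"{path}: line {lineno}: expected {9 + len(samples)} columns, "
                    f"got {len(fields)}"
                )
            chrom, pos_s, vid, ref, alt_s, _qual, _filt, info, fmt = fields[:9]
            try:
                pos = int(pos_s)
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-integer POS {pos_s!r}")
            if pos < 1:
                raise FormatError(f"{path}: line {lineno}: non-positive POS {pos}")
            if not fmt.split(":")[0] == "GT":
                raise FormatError(f"{path}: line {lineno}: FORMAT must start with GT")
            alts = alt_s.split(",")
            if len(ref) != 1 or any(len(a) != 1 or a == "." for a in alts):
                dropped["non_snv"] += 1
                continue
            known = vid != "."
            if drop_unknown and not known:
                dropped["unknown_id"] += 1
                continue
            ancestral = None
            for kv in info.split(";"):
                if kv.startswith("AA="):
                    aa = kv[3:].upper()
                    if aa in ("A", "C", "G", "T"):
                        ancestral = aa
            raw_gts = [
                _parse_gt(tok, sample, lineno, path)
                for sample, tok in zip(samples, fields[9:])
            ]
            for alt_index, alt in enumerate(alts, start=1):
                genotypes: Dict[str, Genotype] = {}
                for sample, gt in zip(samples, raw_gts):
                    if gt is None:
                        genotypes[sample] = None
                        continue
                    mapped = tuple(
                        (0 if a == 0 else 1 if a == alt_index else None)
                        for a in gt
                    )
                    genotypes[sample] = None if mapped == (None, None) else mapped
                records.append(
                    VariantRecord(
                        contig=chrom,
                        position=pos,
                        ref=ref,
                        alt=alt,
                        genotypes=genotypes,
                        ancestral=ancestral,
                        known=known,
                    )
                )
    if dropped["non_snv"]:
        logger.info("%s: dropped %d non-SNV rows", path, dropped["non_snv"])
    return VariantTable(records, samples, dropped)


def write_variant_table(table: VariantTable, path) -> None:
    """Write records back in the simplified VCF dialect (one row per record;
    multi-allelic sites stay split). Half-calls are written as '.'."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for i, rec in enumerate(table.records):
            info = f"AA={rec.ancestral}" if rec.ancestral else "."
            vid = f"rs{i + 1}" if rec.known else "."
            gts = []
            for sample in table.samples:
                gt = rec.genotypes.get(sample)
                if gt is None:
                    gts.append("./.")
                else:
                    gts.append(
                        "/".join("." if a is None else str(a) for a in gt)
                    )
            fh.write(
                f"{rec.contig}\t{rec.position}\t{vid}\t{rec.ref}\t{rec.alt}"
                f"\t.\tPASS\t{info}\tGT\t" + "\t".join(gts) + "\n"
            )


def annotate_mask(records: Iterable[VariantRecord], mask: MaskTrack) -> None:
    """Set each record's ``masked`` flag from the high-confidence track."""
    for rec in records:
        rec.masked = mask.contains(rec.contig, rec.pos0)


# ---------------------------------------------------------------------------
# score table

SCORE_COLUMNS = ("contig", "pos", "gerp", "slr", "phylop")


def read_score_table(path) -> Dict[Tuple[str, int], ScoreRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out: Dict[Tuple[str, int], ScoreRecord] = {}
    for row in df.itertuples(index=False):
        try:
            pos = int(row.pos)
        except (TypeError, ValueError):
            raise FormatError(f"{path}: non-integer position {row.pos!r}")
        vals = {}
        for col in ("gerp", "slr", "phylop"):
            cell = getattr(row, col)
            if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
                vals[col] = None
            else:
                try:
                    vals[col] = float(cell)
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric {col} cell {cell!r} at {row.contig}:{pos}"
                    )
        key = (str(row.contig), pos)
        if key in out:
            raise FormatError(f"{path}: duplicate score position {key}")
        out[key] = ScoreRecord(str(row.contig), pos, **vals)
    return out


def write_score_table(scores: Mapping[Tuple[str, int], ScoreRecord], path) -> None:
    def fmt(v: Optional[float]) -> str:
        return "" if v is None else format(v, ".6g")

    with open(path, "w") as fh:
        fh.write("\t".join(SCORE_COLUMNS) + "\n")
        for (contig, pos) in sorted(scores):
            rec = scores[(contig, pos)]
            fh.write(
                f"{contig}\t{pos}\t{fmt(rec.gerp)}\t{fmt(rec.slr)}\t{fmt(rec.phylop)}\n"
            )


# ---------------------------------------------------------------------------
# minimotif table

MOTIF_COLUMNS = ("motif_id", "protein_id", "start", "end", "activity", "mmod_pos", "peptide")


def read_minimotif_table(
    path, protein_lengths: Optional[Mapping[str, int]] = None
) -> List[MinimotifInstance]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(MOTIF_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        mmod = int(row.mmod_pos) if row.mmod_pos != "" else None
        motif = MinimotifInstance(
            motif_id=row.motif_id,
            protein_id=row.protein_id,
            start=int(row.start),
            end=int(row.end),
            activity=row.activity,
            mmod_position=mmod,
            peptide=row.peptide,
        )
        if protein_lengths is not None:
            plen = protein_lengths.get(motif.protein_id)
            if plen is None:
                raise ValidationError(
                    f"{motif.motif_id}: unknown protein {motif.protein_id!r}"
                )
            if motif.end > plen:
                raise ValidationError(
                    f"{motif.motif_id}: end {motif.end} beyond protein length {plen}"
                )
        out.append(motif)
    return out


def write_minimotif_table(motifs: Sequence[MinimotifInstance], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(MOTIF_COLUMNS) + "\n")
        for m in motifs:
            mmod = "" if m.mmod_position is None else str(m.mmod_position)
            fh.write(
                f"{m.motif_id}\t{m.protein_id}\t{m.start}\t{m.end}\t{m.activity}"
                f"\t{mmod}\t{m.peptide}\n"
            )


# ---------------------------------------------------------------------------
# transcript models

TX_COLUMNS = ("tx_id", "protein_id", "contig", "strand", "exon_starts", "exon_ends", "frame")


def read_transcript_models(path, contig_lengths: Optional[Mapping[str, int]] = None) -> List[TranscriptModel]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(TX_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    models = []
    for row in df.itertuples(index=False):
        starts = [int(x) for x in row.exon_starts.split(",") if x != ""]
        ends = [int(x) for x in row.exon_ends.split(",") if x != ""]
        if len(starts) != len(ends):
            raise FormatError(f"{path}: {row.tx_id}: exon starts/ends length mismatch")
        model = TranscriptModel(
            tx_id=row.tx_id,
            protein_id=row.protein_id,
            contig=row.contig,
            strand=row.strand,
            exons=list(zip(starts, ends)),
            frame_offset=int(row.frame),
        )
        if contig_lengths is not None:
            clen = contig_lengths.get(model.contig)
            if clen is None:
                raise ValidationError(f"{model.tx_id}: unknown contig {model.contig!r}")
            for s, e in model.exons:
                if s < 0 or e > clen:
                    raise ValidationError(
                        f"{model.tx_id}: exon {s}-{e} outside contig bounds (0, {clen})"
                    )
        models.append(model)
    return models


def write_transcript_models(models: Sequence[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TX_COLUMNS) + "\n")
        for m in models:
            starts = ",".join(str(s) for s, _ in m.exons)
            ends = ",".join(str(e) for _, e in m.exons)
            fh.write(
                f"{m.tx_id}\t{m.protein_id}\t{m.contig}\t{m.strand}\t{starts}\t{ends}"
                f"\t{m.frame_offset}\n"
            )


# ---------------------------------------------------------------------------
# panel

PANEL_COLUMNS = ("sample_id", "population", "continent", "admixed")


def read_panel(path) -> List[PanelRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out: List[PanelRecord] = []
    seen = set()
    for row in df.itertuples(index=False):
        if row.sample_id in seen:
            raise ValidationError(f"{path}: duplicate sample id {row.sample_id!r}")
        seen.add(row.sample_id)
        out.append(
            PanelRecord(
                sample_id=row.sample_id,
                population=row.population,
                continent=row.continent,
                admixed=row.admixed.lower() in ("1", "true", "yes"),
            )
        )
    return out


def write_panel(panel: Sequence[PanelRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PANEL_COLUMNS) + "\n")
        for p in panel:
            fh.write(
                f"{p.sample_id}\t{p.population}\t{p.continent}\t{int(p.admixed)}\n"
            )


# ---------------------------------------------------------------------------
# mask (BED3)

def read_mask(path) -> MaskTrack:
    triples: List[Tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: expected 3 BED columns")
            try:
                triples.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates")
    return MaskTrack.from_intervals(triples)


def write_mask(mask: MaskTrack, path) -> None:
    with open(path, "w") as fh:
        for contig, s, e in mask.as_triples():
            fh.write(f"{contig}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# summary tables

def write_summary_table(table: pd.DataFrame, path) -> None:
    """Write a summary table as TSV (floats at full precision; rendering with
    the report's rounding policy happens in :mod:`minivar.render`)."""
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_summary_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
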