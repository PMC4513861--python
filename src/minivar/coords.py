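"""Centralized coordinate conversions.

Everything internal is 0-based half-open; on-disk VCF/score positions are
1-based; protein residues are 1-based inclusive. All conversions go through
these two helpers so off-by-one conventions live in exactly one place.
"""


def to_zero_based(position_1based: int) -> int:
    """1-based (VCF, score table, protein residue) -> 0-based index."""
    return position_1based - 1


def to_one_based(position_0based: int) -> int:
    """0-based internal index -> 1-based on-disk position."""
    return position_0based + 1


def residue_of_cds_index(cds_index_0based: int) -> int:
    """0-based coding-nucleotide index -> 1-based residue position."""
    return cds_index_0based // 3 + 1


def codon_offset_of_cds_index(cds_index_0based: int) -> int:
    """0-based coding-nucleotide index -> position within its codon (0..2)."""
    return cds_index_0based % 3
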