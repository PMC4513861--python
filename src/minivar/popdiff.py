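"""Derived-allele-frequency geography.

Per-population DAF, continental aggregation (unweighted mean of included
populations, admixed populations excluded under the strict policy), pairwise
ΔDAF within and between continents, and extraction of high-ΔDAF minimotif
alleles among DMs and LOFMs.
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .classify import ClassifiedMinimotifVariant
from .errors import DataError, UndefinedDafError
from .records import CONTINENTS, PanelRecord, VariantRecord

DDAF_THRESHOLD = 0.5


def _derived_is_alt(variant: VariantRecord) -> bool:
    if variant.ancestral is None:
        raise UndefinedDafError(f"{variant.key}: ancestral allele unknown")
    if variant.ancestral == variant.ref:
        return True
    if variant.ancestral == variant.alt:
        return False
    raise UndefinedDafError(
        f"{variant.key}: ancestral {variant.ancestral!r} is neither REF nor ALT"
    )


def population_daf(
    variant: VariantRecord, panel: Sequence[PanelRecord], population: str
) -> float:
    """Derived allele frequency over called chromosomes of one population."""
    derived_alt = _derived_is_alt(variant)
    n_derived = n_called = 0
    for rec in panel:
        if rec.population != population:
            continue
        gt = variant.genotypes.get(rec.sample_id)
        if gt is None:
            continue
        for a in gt:
            if a is None:
                continue
            n_called += 1
            n_derived += (a == 1) == derived_alt
    if n_called == 0:
        raise DataError(
            f"{variant.key}: no called samples in population {population!r}"
        )
    return n_derived / n_called


def continental_daf(
    variant: VariantRecord,
    panel: Sequence[PanelRecord],
    continent: str,
    exclusions: str = "strict",
) -> float:
    """Unweighted mean of the continent's per-population DAFs.

    ``exclusions='strict'`` drops populations flagged admixed from the
    aggregation (they remain available at population level);
    ``'lenient'`` keeps them.
    """
    if exclusions not in ("strict", "lenient"):
        raise DataError(f"unknown exclusion policy {exclusions!r}")
    pops: Dict[str, bool] = {}
    for rec in panel:
        if rec.continent == continent:
            pops[rec.population] = rec.admixed
    included = [
        p for p, admixed in sorted(pops.items())
        if exclusions == "lenient" or not admixed
    ]
    if not included:
        raise DataError(
            f"{variant.key}: no included populations for continent {continent!r}"
        )
    dafs = [population_daf(variant, panel, p) for p in included]
    return sum(dafs) / len(dafs)


def delta_daf(daf_a: float, daf_b: float) -> float:
    """Absolute DAF difference between two units (populations or continents)."""
    return abs(daf_a - daf_b)


def intercontinental_ddaf(
    variant: VariantRecord,
    panel: Sequence[PanelRecord],
    exclusions: str = "strict",
    continents: Sequence[str] = CONTINENTS,
) -> Dict[Tuple[str, str], float]:
    """Pairwise ΔDAF between continental DAFs (AFR/EUR/ASN by default)."""
    dafs = {
        c: continental_daf(variant, panel, c, exclusions) for c in continents
    }
    return {
        (a, b): delta_daf(dafs[a], dafs[b]) for a, b in combinations(continents, 2)
    }


def intracontinental_ddaf(
    variant: VariantRecord, panel: Sequence[PanelRecord], continent: str
) -> Dict[Tuple[str, str], float]:
    """Pairwise ΔDAF between populations of one continent (all populations,
    admixed included: exclusion applies only to continental aggregation)."""
    pops = sorted({r.population for r in panel if r.continent == continent})
    dafs = {p: population_daf(variant, panel, p) for p in pops}
    return {(a, b): delta_daf(dafs[a], dafs[b]) for a, b in combinations(pops, 2)}


def daf_table(
    variants: Iterable[VariantRecord],
    panel: Sequence[PanelRecord],
    exclusions: str = "strict",
) -> pd.DataFrame:
    """Long-format per-population and per-continent DAF table; variants with
    unknown ancestral allele are skipped."""
    rows: List[dict] = []
    pops = sorted({r.population for r in panel})
    for v in variants:
        if v.ancestral is None or v.ancestral not in (v.ref, v.alt):
            continue
        for p in pops:
            rows.append(
                {"variant_key": v.key, "unit": p, "level": "population",
                 "daf": population_daf(v, panel, p)}
            )
        for c in CONTINENTS:
            if any(r.continent == c for r in panel):
                rows.append(
                    {"variant_key": v.key, "unit": c, "level": "continent",
                     "daf": continental_daf(v, panel, c, exclusions)}
                )
    return pd.DataFrame(rows, columns=["variant_key", "unit", "level", "daf"])


def high_ddaf_minimotifs(
    classified: Sequence[ClassifiedMinimotifVariant],
    variants_by_key: Mapping[str, VariantRecord],
    panel: Sequence[PanelRecord],
    threshold: float = DDAF_THRESHOLD,
    exclusions: str = "strict",
) -> pd.DataFrame:
    """Minimotif alleles with maximal intercontinental ΔDAF above threshold.

    Restricted to DMs and LOFMs (critical hits with a known autosomal
    ancestral allele). Rows carry a '+' sign for DMs and '-' for LOFMs and are
    sorted by max ΔDAF descending.
    """
    rows: List[dict] = []
    for rec in classified:
        if rec.lof_dm not in ("DM", "LOFM"):
            continue
        variant = variants_by_key[rec.variant_key]
        pairs = intercontinental_ddaf(variant, panel, exclusions)
        max_pair, max_ddaf = max(pairs.items(), key=lambda kv: (kv[1], kv[0]))
        if max_ddaf <= threshold:
            continue
        rows.append(
            {
                "motif_id": rec.motif_id,
                "protein_id": rec.protein_id,
                "activity": rec.activity,
                "aa_change": f"{rec.ref_residue}{rec.residue_position}{rec.alt_residue}",
                "sign": "+" if rec.lof_dm == "DM" else "-",
                "max_ddaf": max_ddaf,
                "continent_pair": f"{max_pair[0]}-{max_pair[1]}",
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "motif_id", "protein_id", "activity", "aa_change",
            "sign", "max_ddaf", "continent_pair",
        ],
    )
    if not df.empty:
        df = df.sort_values(
            ["max_ddaf", "motif_id", "aa_change"], ascending=[False, True, True]
        ).reset_index(drop=True)
    return df
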