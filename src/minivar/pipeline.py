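"""End-to-end orchestration.

Stages run in dependency order (inputs/simulate -> proteome -> match matrix ->
classify -> selection -> popdiff -> report); every output is a plain-text TSV
(or FASTA) under the run directory, and a manifest records the config hash,
seed and per-stage row counts. Re-running with the same config produces
byte-identical outputs; the pipeline is single-threaded by contract, so a
``threads`` setting never changes results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import classify as cls
from . import io_formats as io
from . import popdiff, selection
from .errors import ConfigError, DataError
from .proteome import build_reference_proteome, cohort_match_matrix
from .records import MaskTrack
from .render import render_lofm_dm, render_summary
from .simulate import CohortSpec, SyntheticCohort, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)

INPUT_KEYS = (
    "genome", "transcripts", "minimotifs", "variants", "panel", "mask", "scores"
)


@dataclass
class PipelineConfig:
    """Everything a run needs: either a simulation spec or input paths, plus
    thresholds, sampling parameters, policies and the seed."""

    simulate: Optional[CohortSpec] = None
    inputs: Optional[Dict[str, str]] = None
    maf_rare_cutoff: float = 0.01
    gerp_threshold: float = 2.0
    slr_neg_threshold: float = -3.0
    slr_pos_threshold: float = 3.0
    ddaf_threshold: float = 0.5
    n_segments: int = 50_000
    segment_length: int = 12
    replicates: int = 5
    admixture_policy: str = "strict"
    drop_unknown: bool = False
    seed: int = 0
    outdir: str = "minivar_run"

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigError("config needs exactly one of 'simulate' or 'inputs'")
        if self.admixture_policy not in ("strict", "lenient"):
            raise ConfigError(f"unknown admixture policy {self.admixture_policy!r}")
        if self.slr_neg_threshold >= self.slr_pos_threshold:
            raise ConfigError("SLR thresholds must satisfy neg < pos")
        for name in ("n_segments", "segment_length", "replicates"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.inputs is not None:
            missing = [k for k in INPUT_KEYS if k not in self.inputs]
            if missing:
                raise ConfigError(f"inputs missing keys {missing}")
            for key in INPUT_KEYS:
                path = Path(self.inputs[key])
                if not path.exists():
                    raise ConfigError(f"input path does not exist: {path}")

    @classmethod
    def from_dict(cls_, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        thresholds = d.pop("thresholds", {})
        sampling = d.pop("sampling", {})
        policies = d.pop("policies", {})
        kwargs: Dict = {}
        if "simulate" in d and d["simulate"] is not None:
            kwargs["simulate"] = CohortSpec.from_dict(d.pop("simulate"))
        else:
            d.pop("simulate", None)
        if "inputs" in d and d["inputs"] is not None:
            kwargs["inputs"] = dict(d.pop("inputs"))
        else:
            d.pop("inputs", None)
        kwargs.update(
            {
                "maf_rare_cutoff": thresholds.get("maf_rare_cutoff", 0.01),
                "gerp_threshold": thresholds.get("gerp", 2.0),
                "slr_neg_threshold": thresholds.get("slr_neg", -3.0),
                "slr_pos_threshold": thresholds.get("slr_pos", 3.0),
                "ddaf_threshold": thresholds.get("ddaf", 0.5),
                "n_segments": sampling.get("n_segments", 50_000),
                "segment_length": sampling.get("segment_length", 12),
                "replicates": sampling.get("replicates", 5),
                "admixture_policy": policies.get("admixture", "strict"),
                "drop_unknown": policies.get("drop_unknown", False),
            }
        )
        for key in ("seed", "outdir"):
            if key in d:
                kwargs[key] = d[key]
        config = cls_(**kwargs)
        config.validate()
        return config

    @classmethod
    def from_yaml(cls_, path) -> "PipelineConfig":
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file does not exist: {p}")
        with open(p) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise ConfigError(f"{p}: config must be a mapping")
        return cls_.from_dict(data)

    def canonical_json(self) -> str:
        d = {
            "simulate": asdict(self.simulate) if self.simulate else None,
            "inputs": self.inputs,
            "thresholds": {
                "maf_rare_cutoff": self.maf_rare_cutoff,
                "gerp": self.gerp_threshold,
                "slr_neg": self.slr_neg_threshold,
                "slr_pos": self.slr_pos_threshold,
                "ddaf": self.ddaf_threshold,
            },
            "sampling": {
                "n_segments": self.n_segments,
                "segment_length": self.segment_length,
                "replicates": self.replicates,
            },
            "policies": {
                "admixture": self.admixture_policy,
                "drop_unknown": self.drop_unknown,
            },
            "seed": self.seed,
        }
        return json.dumps(d, sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _stage_seed(base_seed: int, label: str) -> int:
    """Deterministic per-label child seed below 2^31."""
    return (base_seed * 1_000_003 + zlib.crc32(label.encode())) % (2**31)


@dataclass
class LoadedInputs:
    genome: list
    models: list
    minimotifs: list
    variants: io.VariantTable
    panel: list
    mask: MaskTrack
    scores: dict


def load_inputs(paths: Mapping[str, str], drop_unknown: bool = False) -> LoadedInputs:
    genome = io.read_fasta(paths["genome"])
    contig_lengths = {g.contig_name: len(g.sequence) for g in genome}
    models = io.read_transcript_models(paths["transcripts"], contig_lengths)
    variants = io.read_variant_table(paths["variants"], drop_unknown=drop_unknown)
    panel = io.read_panel(paths["panel"])
    mask = io.read_mask(paths["mask"])
    scores = io.read_score_table(paths["scores"])
    proteome = build_reference_proteome(genome, models)
    plens = {p.protein_id: len(p.residues) for p in proteome}
    minimotifs = io.read_minimotif_table(paths["minimotifs"], plens)
    io.annotate_mask(variants.records, mask)
    return LoadedInputs(genome, models, minimotifs, variants, panel, mask, scores)


def _motif_region(minimotifs, models) -> List[Tuple[str, int, int]]:
    by_protein = {m.protein_id: m for m in models}
    triples = []
    for motif in minimotifs:
        model = by_protein.get(motif.protein_id)
        if model is None:
            continue
        for _residue, coords in cls.map_minimotif_to_codons(motif, model):
            for g in coords:
                triples.append((model.contig, g - 1, g))
    return triples


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute all stages; returns the manifest (also written as JSON)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: List[Dict] = []

    # stage 1: inputs ---------------------------------------------------------
    if config.simulate is not None:
        import dataclasses

        spec = dataclasses.replace(config.simulate, seed=config.seed)
        cohort = simulate_cohort(spec)
        write_cohort(cohort, outdir / "inputs")
        genome, models = cohort.genome, cohort.models
        minimotifs, variants = cohort.minimotifs, cohort.variants
        panel, mask, scores = cohort.panel, cohort.mask, cohort.scores
    else:
        loaded = load_inputs(config.inputs, config.drop_unknown)
        genome, models = loaded.genome, loaded.models
        minimotifs, variants = loaded.minimotifs, loaded.variants
        panel, mask, scores = loaded.panel, loaded.mask, loaded.scores
    contigs = {g.contig_name: g.sequence for g in genome}
    stages.append({"name": "inputs", "rows": len(variants)})

    # stage 2: reference proteome --------------------------------------------
    proteome = build_reference_proteome(contigs, models)
    io.write_fasta(proteome, outdir / "proteome.fa")
    stages.append({"name": "proteome", "rows": len(proteome)})

    # stage 3: match matrix ---------------------------------------------------
    matrix = cohort_match_matrix(contigs, models, variants.records, variants.samples)
    matrix.to_sparse_tsv(outdir / "match_matrix.tsv", proteome)
    stages.append({"name": "match_matrix", "rows": len(matrix.position_index)})

    # stage 4: classification -------------------------------------------------
    codon_index = cls.CodonIndex(models)
    classified = cls.classify_cohort(
        contigs, models, minimotifs, variants.records, codon_index,
        rare_cutoff=config.maf_rare_cutoff,
    )
    frame = cls.classified_to_frame(classified)
    io.write_summary_table(frame, outdir / "classified.tsv")
    summary = cls.summarize_by_activity(classified, minimotifs)
    io.write_summary_table(summary, outdir / "summary_activity.tsv")
    lofm_dm = cls.summarize_lofm_dm(classified)
    io.write_summary_table(lofm_dm, outdir / "summary_lofm_dm.tsv")
    stages.append({"name": "classify", "rows": len(classified)})

    # stage 5: selection ------------------------------------------------------
    region_defs = {
        "minimotif": _motif_region(minimotifs, models),
        "coding": [
            (m.contig, s, e) for m in models for s, e in m.exons
        ],
        "whole_genome": [
            (g.contig_name, 0, len(g.sequence)) for g in genome
        ],
    }
    rate_rows = []
    replicate_sets = {}
    for label, triples in region_defs.items():
        region = selection.RegionSet.from_mask_intersection(label, triples, mask)
        if region.total_length < config.segment_length:
            continue
        reps = selection.sample_substitution_rate(
            region,
            variants.records,
            n_segments=config.n_segments,
            segment_length=config.segment_length,
            replicates=config.replicates,
            seed=_stage_seed(config.seed, label),
        )
        replicate_sets[label] = reps
        for i, r in enumerate(reps.rates):
            rate_rows.append({"region": label, "replicate": i, "rate": r})
    io.write_summary_table(pd.DataFrame(rate_rows), outdir / "substitution_rates.tsv")
    cmp_rows = []
    if "minimotif" in replicate_sets:
        for label, reps in replicate_sets.items():
            if label == "minimotif":
                continue
            result = selection.compare_rates(replicate_sets["minimotif"], reps)
            cmp_rows.append(
                {
                    "region_a": "minimotif",
                    "region_b": label,
                    "mean_a": result.mean_a,
                    "mean_b": result.mean_b,
                    "p_value": result.p_value,
                }
            )
    io.write_summary_table(pd.DataFrame(cmp_rows), outdir / "rate_comparisons.tsv")

    # per-variant selection calls and per-stratum compositions
    motif_variant_keys = sorted({c.variant_key for c in classified})
    by_key = {v.key: v for v in variants.records}
    sel_rows = []
    strata: Dict[str, List[str]] = {"minimotif": motif_variant_keys}
    for c in classified:
        strata.setdefault(f"activity:{c.activity}", []).append(c.variant_key)
    for label, keys in strata.items():
        keys = sorted(set(keys))
        slrs, gerps, mafs = [], [], []
        for k in keys:
            v = by_key[k]
            sc = scores.get((v.contig, v.position))
            slrs.append(sc.slr if sc else None)
            gerps.append(sc.gerp if sc else None)
            mafs.append(cls.compute_maf(v, config.maf_rare_cutoff)[1])
        try:
            comp = selection.selection_composition(
                slrs, config.slr_neg_threshold, config.slr_pos_threshold
            )
        except DataError:
            continue
        try:
            cons = selection.constrained_fraction(gerps, config.gerp_threshold)
        except DataError:
            cons = float("nan")
        sel_rows.append(
            {
                "stratum": label,
                "n_variants": len(keys),
                "rare_variant_fraction": selection.rare_variant_fraction(mafs),
                "gerp_constrained_fraction": cons,
                "slr_negative": comp["negative"],
                "slr_neutral": comp["neutral"],
                "slr_positive": comp["positive"],
            }
        )
    io.write_summary_table(pd.DataFrame(sel_rows), outdir / "selection_composition.tsv")
    stages.append({"name": "selection", "rows": len(sel_rows) + len(rate_rows)})

    # stage 6: population differentiation -------------------------------------
    motif_variants = [by_key[k] for k in motif_variant_keys]
    daf = popdiff.daf_table(motif_variants, panel, config.admixture_policy)
    io.write_summary_table(daf, outdir / "daf.tsv")
    high = popdiff.high_ddaf_minimotifs(
        classified, by_key, panel,
        threshold=config.ddaf_threshold, exclusions=config.admixture_policy,
    )
    io.write_summary_table(high, outdir / "high_ddaf.tsv")
    stages.append({"name": "popdiff", "rows": len(daf)})

    # stage 7: report ---------------------------------------------------------
    report = (
        "Minimotif variability report\n"
        "============================\n\n"
        "Per-activity minimotif summary\n------------------------------\n"
        + render_summary(summary)
        + "\nDM / LOFM minimotifs (autosomal, known ancestral allele)\n"
        "--------------------------------------------------------\n"
        + render_lofm_dm(lofm_dm)
    )
    (outdir / "report.txt").write_text(report)
    stages.append({"name": "report", "rows": len(summary)})

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": stages,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
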