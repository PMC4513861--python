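"""Selection metrics over region classes.

* substitution rate: fixed-length (default 12 bp) segments drawn uniformly
  with replacement from a masked region class, replicated; the per-replicate
  rate is variant sites covered (with segment multiplicity) per sampled base,
  an unbiased estimator of the region's per-bp variant density;
* replicate comparison by a two-sided Welch t-test;
* rare-variant fraction (singletons + MAF < 1%);
* GERP constraint calls (> 2 constrained; exactly 0 omitted);
* SLR three-way selection classes (< -3 negative, > +3 positive, else
  neutral drift / weak selection; thresholds configurable);
* PhyloP summarized descriptively (median), never thresholded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import DataError
from .records import MaskTrack, VariantRecord

GERP_NEG_THRESHOLD = 2.0
SLR_NEG_THRESHOLD = -3.0
SLR_POS_THRESHOLD = 3.0


@dataclass
class RegionSet:
    """A labelled set of genomic intervals (0-based half-open), already
    intersected with the high-confidence mask."""

    label: str
    intervals: List[Tuple[str, int, int]]

    @classmethod
    def from_mask_intersection(
        cls, label: str, intervals: Iterable[Tuple[str, int, int]], mask: MaskTrack
    ) -> "RegionSet":
        track = MaskTrack.from_intervals(list(intervals), warn_on_merge=False)
        out: List[Tuple[str, int, int]] = []
        for contig, ivs in track.intervals.items():
            mask_ivs = mask.intervals.get(contig, [])
            mi = 0
            for s, e in ivs:
                for ms, me in mask_ivs:
                    lo, hi = max(s, ms), min(e, me)
                    if lo < hi:
                        out.append((contig, lo, hi))
        out.sort()
        return cls(label, out)

    @property
    def total_length(self) -> int:
        return sum(e - s for _, s, e in self.intervals)


@dataclass
class RateReplicates:
    label: str
    rates: List[float]
    n_segments: int
    segment_length: int
    seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.rates))


def sample_substitution_rate(
    regions: RegionSet,
    variants: Iterable[VariantRecord],
    n_segments: int = 50_000,
    segment_length: int = 12,
    replicates: int = 5,
    seed: int = 0,
) -> RateReplicates:
    """Replicated segment-sampling substitution-rate estimate for a region set.

    Segment start positions are drawn uniformly with replacement from all
    placements fully inside one interval; each replicate's rate is the number
    of distinct variant sites covered, counted once per covering segment,
    divided by (n_segments * segment_length).
    """
    sites: Dict[str, np.ndarray] = {}
    per_contig: Dict[str, set] = {}
    for v in variants:
        per_contig.setdefault(v.contig, set()).add(v.pos0)
    for contig, posset in per_contig.items():
        sites[contig] = np.array(sorted(posset), dtype=np.int64)
    placements = []  # (contig, first valid start, n valid starts)
    for contig, s, e in regions.intervals:
        n = (e - s) - segment_length + 1
        if n > 0:
            placements.append((contig, s, n))
    if not placements:
        raise DataError(
            f"region set {regions.label!r}: no interval of length >= {segment_length}"
        )
    weights = np.array([n for _, _, n in placements], dtype=np.int64)
    cum = np.cumsum(weights)
    total = int(cum[-1])
    base_starts = np.array([s for _, s, _ in placements], dtype=np.int64)
    cum_before = np.concatenate(([0], cum[:-1]))
    contig_of = np.array(
        [sorted(sites).index(c) if c in sites else -1 for c, _, _ in placements],
        dtype=np.int64,
    )
    contig_order = sorted(sites)
    rng = np.random.default_rng(seed)
    rates = []
    for _ in range(replicates):
        draws = rng.integers(0, total, size=n_segments)
        iv_idx = np.searchsorted(cum, draws, side="right")
        starts = base_starts[iv_idx] + (draws - cum_before[iv_idx])
        count = 0
        seg_contigs = contig_of[iv_idx]
        for ci, contig in enumerate(contig_order):
            sel = starts[seg_contigs == ci]
            if sel.size == 0:
                continue
            arr = sites[contig]
            count += int(
                (
                    np.searchsorted(arr, sel + segment_length, side="left")
                    - np.searchsorted(arr, sel, side="left")
                ).sum()
            )
        rates.append(count / (n_segments * segment_length))
    return RateReplicates(regions.label, rates, n_segments, segment_length, seed)


@dataclass
class RateComparison:
    p_value: float
    mean_a: float
    mean_b: float


def compare_rates(a: RateReplicates, b: RateReplicates) -> RateComparison:
    """Two-sided Welch t-test on the replicate rates of two region classes."""
    xa = np.asarray(a.rates, dtype=np.float64)
    xb = np.asarray(b.rates, dtype=np.float64)
    if len(xa) < 2 or len(xb) < 2:
        raise DataError("compare_rates needs at least two replicates per side")
    if xa.var(ddof=1) == 0.0 and xb.var(ddof=1) == 0.0:
        p = 1.0 if xa.mean() == xb.mean() else 0.0
    else:
        p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
    return RateComparison(p, float(xa.mean()), float(xb.mean()))


def rare_variant_fraction(maf_classes: Sequence[str]) -> float:
    """Fraction of variants that are singletons or rare (MAF < 1%)."""
    if len(maf_classes) == 0:
        raise DataError("rare_variant_fraction of an empty variant set")
    rare = sum(1 for c in maf_classes if c in ("singleton", "rare"))
    return rare / len(maf_classes)


def classify_gerp(score: Optional[float], threshold: float = GERP_NEG_THRESHOLD) -> str:
    """'constrained' above the threshold, 'omitted' at exactly 0, 'absent'
    when unscored, otherwise 'unconstrained'."""
    if score is None:
        return "absent"
    if score == 0.0:
        return "omitted"
    if score > threshold:
        return "constrained"
    return "unconstrained"


def classify_slr(
    score: Optional[float],
    neg_threshold: float = SLR_NEG_THRESHOLD,
    pos_threshold: float = SLR_POS_THRESHOLD,
) -> str:
    """Three-way selection class from an SLR statistic; boundary values are
    neutral (strict inequalities on both sides)."""
    if neg_threshold >= pos_threshold:
        raise DataError("SLR thresholds must satisfy neg < pos")
    if score is None:
        return "absent"
    if score < neg_threshold:
        return "negative"
    if score > pos_threshold:
        return "positive"
    return "neutral"


def constrained_fraction(
    gerp_scores: Iterable[Optional[float]], threshold: float = GERP_NEG_THRESHOLD
) -> float:
    """Fraction of GERP-scored sites called constrained; 'omitted' (exactly 0)
    and absent scores are excluded from numerator and denominator."""
    n_con = n_tot = 0
    for s in gerp_scores:
        cls = classify_gerp(s, threshold)
        if cls in ("constrained", "unconstrained"):
            n_tot += 1
            n_con += cls == "constrained"
    if n_tot == 0:
        raise DataError("no usable GERP scores")
    return n_con / n_tot


def selection_composition(
    slr_scores: Iterable[Optional[float]],
    neg_threshold: float = SLR_NEG_THRESHOLD,
    pos_threshold: float = SLR_POS_THRESHOLD,
) -> Dict[str, float]:
    """Fractions of scored variants under negative selection, neutral drift
    and positive selection (summing to 1 over present scores)."""
    counts = {"negative": 0, "neutral": 0, "positive": 0}
    for s in slr_scores:
        cls = classify_slr(s, neg_threshold, pos_threshold)
        if cls != "absent":
            counts[cls] += 1
    total = sum(counts.values())
    if total == 0:
        raise DataError("no scored variants for selection composition")
    return {k: v / total for k, v in counts.items()}


def phylop_summary(phylop_scores: Iterable[Optional[float]]) -> Dict[str, float]:
    """Descriptive summary (median, mean, n) of present PhyloP scores."""
    vals = np.array([s for s in phylop_scores if s is not None], dtype=np.float64)
    if vals.size == 0:
        raise DataError("no PhyloP scores")
    return {
        "median": float(np.median(vals)),
        "mean": float(vals.mean()),
        "n": int(vals.size),
    }
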