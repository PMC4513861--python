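"""Report rendering: percentage and count formatting.

Percentages are printed at a fixed number of significant figures (default 3,
round-half-even), with trailing zeros kept ("0.50"); zero counts print "0".
Counts in the human-readable report are grouped with thin spaces ("18 542");
machine TSVs never group.
"""

from __future__ import annotations

from decimal import ROUND_HALF_EVEN, Decimal
from typing import Optional

import pandas as pd


def format_sigfig(value: float, sigfigs: int = 3) -> str:
    """Round-half-even to ``sigfigs`` significant figures, plain notation."""
    if value == 0:
        return "0"
    d = Decimal(repr(value))
    exponent = d.adjusted() - sigfigs + 1
    q = d.quantize(Decimal(1).scaleb(exponent), rounding=ROUND_HALF_EVEN)
    return format(q, "f")


def format_percent(count: int, total: int, sigfigs: int = 3) -> str:
    """Percentage 100*count/total at the report's significant-figure policy."""
    if count == 0 or total == 0:
        return "0"
    d = (Decimal(count) * 100) / Decimal(total)
    exponent = d.adjusted() - sigfigs + 1
    q = d.quantize(Decimal(1).scaleb(exponent), rounding=ROUND_HALF_EVEN)
    return format(q, "f")


def format_count(n: int, human: bool = False) -> str:
    if not human:
        return str(n)
    return f"{n:,}".replace(",", " ")


def render_summary(summary: pd.DataFrame, sigfigs: int = 3, human: bool = True) -> str:
    """Render a per-activity summary (from classify.summarize_by_activity)
    as an aligned text table. The totals row equals the column sums of the
    printed per-activity counts."""
    header = [
        "Activity", "Critical", "%", "Ser-Thr", "Missense", "%",
        "With SNP", "%", "Total",
    ]
    lines = []
    for row in summary.itertuples(index=False):
        total = int(row.n_total)
        if row.activity == "distinct_snps":
            lines.append(
                [
                    "Distinct SNPs",
                    format_count(int(row.n_critical), human), "-",
                    format_count(int(row.n_ser_thr), human),
                    format_count(int(row.n_missense), human), "-",
                    format_count(int(row.n_with_snp), human), "-", "-",
                ]
            )
            continue
        lines.append(
            [
                row.activity.capitalize() if row.activity != "total" else "Total",
                format_count(int(row.n_critical), human),
                format_percent(int(row.n_critical), total, sigfigs),
                format_count(int(row.n_ser_thr), human),
                format_count(int(row.n_missense), human),
                format_percent(int(row.n_missense), total, sigfigs),
                format_count(int(row.n_with_snp), human),
                format_percent(int(row.n_with_snp), total, sigfigs),
                format_count(total, human),
            ]
        )
    widths = [
        max(len(header[i]), *(len(l[i]) for l in lines)) for i in range(len(header))
    ]
    fmt = "  ".join("{:<%d}" % w for w in widths)
    out = [fmt.format(*header)]
    out.extend(fmt.format(*l) for l in lines)
    return "\n".join(out) + "\n"


def render_lofm_dm(summary: pd.DataFrame, human: bool = True) -> str:
    """Render the per-activity DM/LOFM count table with its totals row."""
    header = ["Activity", "DMs", "LOFMs"]
    lines = [
        [
            row.activity.capitalize() if row.activity != "total" else "Total",
            format_count(int(row.n_dm), human),
            format_count(int(row.n_lofm), human),
        ]
        for row in summary.itertuples(index=False)
    ]
    widths = [
        max(len(header[i]), *(len(l[i]) for l in lines)) if lines else len(header[i])
        for i in range(len(header))
    ]
    fmt = "  ".join("{:<%d}" % w for w in widths)
    out = [fmt.format(*header)]
    out.extend(fmt.format(*l) for l in lines)
    return "\n".join(out) + "\n"
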