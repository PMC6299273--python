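"""Nucleotide composition and strand-skew statistics.

AT skew = (A - T)/(A + T) and GC skew = (G - C)/(G + C), computed per region
(whole genome, each PCG, the rRNAs, the control region).  Ambiguous bases
(``N``) are excluded from all counts.  Internal values keep full precision;
rounding to the conventional printed precision (1 decimal for percentages,
3 for skews) happens only in reports.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .genome import FeatureKind, GenomeRecord

__all__ = [
    "CompositionSummary",
    "base_composition",
    "skew",
    "composition_table",
    "composition_from_percentages",
]


@dataclass(frozen=True)
class CompositionSummary:
    region: str
    a_pct: float
    c_pct: float
    g_pct: float
    t_pct: float

    @property
    def at_pct(self) -> float:
        return self.a_pct + self.t_pct

    @property
    def gc_pct(self) -> float:
        return self.g_pct + self.c_pct

    @property
    def at_skew(self) -> float:
        return skew(self.a_pct, self.t_pct)

    @property
    def gc_skew(self) -> float:
        return skew(self.g_pct, self.c_pct)

    def rounded(self) -> dict[str, float]:
        """Report row at printed precision (half-up rounding)."""
        return {
            "region": self.region,
            "A_pct": _round_half_up(self.a_pct, 1),
            "C_pct": _round_half_up(self.c_pct, 1),
            "G_pct": _round_half_up(self.g_pct, 1),
            "T_pct": _round_half_up(self.t_pct, 1),
            "AT_pct": _round_half_up(self.at_pct, 1),
            "GC_pct": _round_half_up(self.gc_pct, 1),
            "AT_skew": _round_half_up(self.at_skew, 3),
            "GC_skew": _round_half_up(self.gc_skew, 3),
        }


def _round_half_up(x: float, ndigits: int) -> float:
    if math.isnan(x):
        return x
    factor = 10**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def base_composition(seq: str, region: str = "sequence") -> CompositionSummary:
    """Percent A/C/G/T over the counted (non-``N``) bases of a sequence."""
    counts = Counter(seq.upper())
    total = sum(counts[b] for b in "ACGT")
    if total == 0:
        raise ValueError(f"{region}: no unambiguous bases to count")
    return CompositionSummary(
        region=region,
        a_pct=100 * counts["A"] / total,
        c_pct=100 * counts["C"] / total,
        g_pct=100 * counts["G"] / total,
        t_pct=100 * counts["T"] / total,
    )


def skew(pct_x: float, pct_y: float) -> float:
    """(x - y)/(x + y); NaN when x + y = 0 (flagged-missing value)."""
    if pct_x + pct_y == 0:
        return math.nan
    return (pct_x - pct_y) / (pct_x + pct_y)


def composition_from_percentages(
    region: str, a: float, c: float, g: float, t: float
) -> CompositionSummary:
    """Build a summary directly from (possibly published) percentages, e.g.
    to recompute skews from a printed composition table."""
    return CompositionSummary(region, a, c, g, t)


def composition_table(
    record: GenomeRecord,
    regions: list[str] | None = None,
    *,
    coding_strand: bool = False,
) -> pd.DataFrame:
    """One composition row per region: the whole genome plus each PCG, rRNA
    and control-region feature (or an explicit ``regions`` selection).

    By default per-gene regions are counted on the plus strand as the
    genomic coordinates define them; ``coding_strand=True`` switches to the
    transcribed strand of each gene.
    """
    from .genome import extract_gene_sequence, reverse_complement

    rows: list[CompositionSummary] = []
    wanted: list[str]
    if regions is None:
        wanted = ["whole_mitogenome"] + [
            f.name
            for f in record.features
            if f.kind in (FeatureKind.PCG, FeatureKind.RRNA,
                          FeatureKind.CONTROL_REGION)
        ]
    else:
        wanted = list(regions)
    for name in wanted:
        if name == "whole_mitogenome":
            rows.append(base_composition(record.sequence, name))
            continue
        feat = record.get_feature(name)  # KeyError for unknown region
        seq = extract_gene_sequence(record, feat)
        if not coding_strand and feat.strand == "-":
            seq = reverse_complement(seq)
        rows.append(base_composition(seq, name))
    return pd.DataFrame([r.rounded() for r in rows])
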