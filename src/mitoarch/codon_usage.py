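"""Codon counting, relative synonymous codon usage (RSCU) and per-family
chi-square comparisons between species.

Under the invertebrate mitochondrial code the 62 sense codons partition into
22 synonymous families, all two- or four-fold degenerate (the six-codon
amino acids of the standard code split: Leu1 = CUN vs Leu2 = UUR, Ser1 = AGN
vs Ser2 = UCN; Ile is two-fold because AUA encodes Met).  RSCU follows the
standard definition: a codon's count divided by the mean count within its
family, i.e. ``RSCU(c) = k * n_c / sum(n_family)`` with ``k`` the family
degeneracy; RSCU > 1 marks a preferentially used codon.

Species comparisons run one chi-square test per codon family: observed
counts are the focal species' counts and expected counts distribute the
focal family total according to the pooled two-species codon proportions.
Multiple testing is corrected by the sequential Bonferroni (Holm step-down)
procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import chi2_contingency

from .genome import (
    FeatureKind,
    GeneticCode,
    GenomeRecord,
    INVERTEBRATE_MITO,
    codons_of,
)

__all__ = [
    "CODON_FAMILIES",
    "CodonCountTable",
    "FamilyChiSquare",
    "codon_counts",
    "rscu",
    "rscu_table",
    "family_chisq",
    "compare_codon_usage",
    "sequential_bonferroni",
    "start_stop_usage",
]


def _build_families(code: GeneticCode) -> dict[str, str]:
    """codon -> family label for the 62 sense codons.

    Families group synonymous codons; the split six-codon amino acids keep
    the conventional 1/2 suffixes tied to their tRNA isoacceptors.
    """
    groups: dict[str, list[str]] = {}
    for codon in code.sense_codons:
        aa = code.amino_acid(codon)
        groups.setdefault(aa, []).append(codon)
    fam: dict[str, str] = {}
    for aa, codons in groups.items():
        if aa == "L":  # CUN (Leu1) vs UUA/UUG (Leu2)
            for c in codons:
                fam[c] = "Leu1" if c.startswith("CT") else "Leu2"
        elif aa == "S":  # AGN (Ser1) vs UCN (Ser2)
            for c in codons:
                fam[c] = "Ser1" if c.startswith("AG") else "Ser2"
        else:
            label = {
                "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe",
                "G": "Gly", "H": "His", "I": "Ile", "K": "Lys", "M": "Met",
                "N": "Asn", "P": "Pro", "Q": "Gln", "R": "Arg", "T": "Thr",
                "V": "Val", "W": "Trp", "Y": "Tyr",
            }[aa]
            for c in codons:
                fam[c] = label
    return fam


#: codon -> family label under NCBI table 5 (22 families, 62 codons).
CODON_FAMILIES: dict[str, str] = _build_families(INVERTEBRATE_MITO)


@dataclass
class CodonCountTable:
    """Sense-codon counts for one species (stop codons excluded)."""

    species: str
    counts: dict[str, int]
    family_map: dict[str, str] = field(default_factory=lambda: CODON_FAMILIES)

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(self.family_map)
        if unknown:
            raise ValueError(f"non-sense codons in counts: {sorted(unknown)}")
        self.counts = {c: self.counts.get(c, 0) for c in self.family_map}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def families(self) -> list[str]:
        seen: list[str] = []
        for fam in self.family_map.values():
            if fam not in seen:
                seen.append(fam)
        return seen

    def family_codons(self, family: str) -> list[str]:
        return [c for c, f in self.family_map.items() if f == family]

    def family_total(self, family: str) -> int:
        return sum(self.counts[c] for c in self.family_codons(family))


def codon_counts(
    cds_set: dict[str, str] | list[str],
    code: GeneticCode = INVERTEBRATE_MITO,
    *,
    species: str = "focal",
) -> CodonCountTable:
    """Count sense codons over a set of in-frame CDS sequences.

    Terminal stop codons (full, or abbreviated codons completed by
    polyadenylation) are excluded; an internal stop is an error naming the
    offending gene.
    """
    if not cds_set:
        raise ValueError("empty CDS set")
    items = (
        cds_set.items() if isinstance(cds_set, dict)
        else ((f"cds{i}", s) for i, s in enumerate(cds_set))
    )
    counts: dict[str, int] = {}
    for name, cds in items:
        codons = codons_of(cds)
        for i, codon in enumerate(codons):
            if code.is_stop(codon):
                if i == len(codons) - 1:
                    continue  # terminal stop
                raise ValueError(
                    f"{name}: internal stop codon {codon} at codon {i}"
                )
            if "N" in codon:
                continue
            counts[codon] = counts.get(codon, 0) + 1
    return CodonCountTable(species=species, counts=counts)


def rscu(table: CodonCountTable) -> dict[str, float]:
    """RSCU per codon: ``k * n_c / family_total`` (NaN for empty families)."""
    out: dict[str, float] = {}
    for family in table.families():
        codons = table.family_codons(family)
        total = sum(table.counts[c] for c in codons)
        k = len(codons)
        for c in codons:
            out[c] = k * table.counts[c] / total if total > 0 else float("nan")
    return out


def rscu_table(table: CodonCountTable) -> pd.DataFrame:
    """Tidy RSCU report: codon, family, count, RSCU (3 decimals kept full)."""
    values = rscu(table)
    rows = [
        {
            "codon": c,
            "family": table.family_map[c],
            "count": table.counts[c],
            "rscu": values[c],
        }
        for c in table.family_map
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["family", "codon"])
        .reset_index(drop=True)
    )


@dataclass(frozen=True)
class FamilyChiSquare:
    family: str
    chi2: float
    df: int
    p_value: float
    low_expected: bool  # any expected count < 5
    testable: bool = True


def family_chisq(
    focal: CodonCountTable,
    other: CodonCountTable,
    family: str,
    *,
    contingency: bool = False,
) -> FamilyChiSquare:
    """One-family goodness-of-fit test of the focal species' codon usage
    against equal usage in the two species.

    Observed: focal counts.  Expected: focal family total distributed by the
    pooled (focal + other) codon proportions within the family.  With
    ``contingency=True`` the full 2 x k species-by-codon contingency
    chi-square is computed instead.
    """
    if focal.family_map != other.family_map:
        raise ValueError("count tables use different family maps")
    codons = focal.family_codons(family)
    if not codons:
        raise KeyError(f"unknown family {family!r}")
    obs = [focal.counts[c] for c in codons]
    other_obs = [other.counts[c] for c in codons]
    pooled = [a + b for a, b in zip(obs, other_obs)]
    pooled_total = sum(pooled)
    focal_total = sum(obs)
    df = len(codons) - 1
    if pooled_total == 0 or focal_total == 0:
        return FamilyChiSquare(family, 0.0, df, 1.0, False, testable=False)
    if contingency:
        if sum(other_obs) == 0:
            return FamilyChiSquare(family, 0.0, df, 1.0, False, testable=False)
        keep = [k for k, p in enumerate(pooled) if p > 0]
        table = [[obs[k] for k in keep], [other_obs[k] for k in keep]]
        df_c = len(keep) - 1
        if df_c < 1:
            return FamilyChiSquare(family, 0.0, df, 1.0, False, testable=False)
        chi2, p, _, expected = chi2_contingency(table, correction=False)
        return FamilyChiSquare(
            family, float(chi2), df_c, float(p),
            low_expected=bool((expected < 5).any()),
        )
    expected = [focal_total * p / pooled_total for p in pooled]
    chi2 = sum(
        (o - e) ** 2 / e for o, e in zip(obs, expected) if e > 0
    )
    p = float(chi2_dist.sf(chi2, df))
    return FamilyChiSquare(
        family, chi2, df, p, low_expected=any(0 < e < 5 for e in expected)
    )


def sequential_bonferroni(
    p_values: list[float], alpha: float = 0.05
) -> list[bool]:
    """Holm step-down decisions, in the original test order.

    Sort p ascending and reject p_(i) while p_(i) <= alpha/(m - i + 1),
    stopping at the first failure.
    """
    m = len(p_values)
    if m == 0:
        return []
    if any(not (0 <= p <= 1) for p in p_values):
        raise ValueError("p-values must lie in [0, 1]")
    order = sorted(range(m), key=lambda i: p_values[i])
    decisions = [False] * m
    for rank, idx in enumerate(order, start=1):
        if p_values[idx] <= alpha / (m - rank + 1):
            decisions[idx] = True
        else:
            break
    return decisions


def compare_codon_usage(
    focal: CodonCountTable,
    other: CodonCountTable,
    *,
    alpha: float = 0.05,
    contingency: bool = False,
) -> pd.DataFrame:
    """All per-family chi-square tests between two species with Holm
    correction over the testable families.

    Reports every family; untestable families (pooled total zero) carry
    ``testable=False`` and do not enter the correction.
    """
    results = [
        family_chisq(focal, other, fam, contingency=contingency)
        for fam in focal.families()
    ]
    testable = [r for r in results if r.testable]
    decisions = sequential_bonferroni([r.p_value for r in testable], alpha)
    holm = dict(zip((r.family for r in testable), decisions))
    df = pd.DataFrame(
        {
            "family": [r.family for r in results],
            "chi2": [r.chi2 for r in results],
            "df": [r.df for r in results],
            "p_value": [r.p_value for r in results],
            "significant_raw": [r.testable and r.p_value <= alpha for r in results],
            "holm_reject": [holm.get(r.family, False) for r in results],
            "low_expected": [r.low_expected for r in results],
            "testable": [r.testable for r in results],
        }
    )
    df.attrs["n_families"] = len(results)
    df.attrs["n_testable"] = len(testable)
    return df


def start_stop_usage(record: GenomeRecord) -> pd.DataFrame:
    """Tally of annotated start and stop codons over the PCGs.

    Abbreviated stops count under their completed codon (``TA-``/``T--`` ->
    TAA); PCGs lacking an annotation are reported as ``missing``.
    Percentages are rounded to the nearest integer.
    """
    starts: dict[str, int] = {}
    stops: dict[str, int] = {}
    for f in record.iter_features(FeatureKind.PCG):
        s = f.start_codon or "missing"
        starts[s] = starts.get(s, 0) + 1
        t = f.stop_codon or "missing"
        if t != "missing" and "-" in t:
            t = t.replace("-", "") + "A" * t.count("-")
        stops[t] = stops.get(t, 0) + 1
    rows = []
    n_pcg = sum(starts.values())
    for role, tally in (("start", starts), ("stop", stops)):
        for codon, count in sorted(tally.items(), key=lambda kv: -kv[1]):
            rows.append(
                {
                    "role": role,
                    "codon": codon,
                    "count": count,
                    "percent": round(100 * count / n_pcg),
                }
            )
    return pd.DataFrame(rows)
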