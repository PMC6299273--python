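"""Rule-based curation of mitogenome annotations and gene-geometry statistics.

Automated mitogenome annotators routinely misplace protein-coding gene (PCG)
boundaries: 5' ends are shifted when several in-frame start codons are
plausible, 3' ends when abbreviated stop codons (completed to TAA by
polyadenylation of the transcript) are overlooked, and low-confidence
duplicate gene calls survive.  This module implements a conservative,
rule-driven curation pass:

1. a PCG begins at the first eligible in-frame start codon nearest to the
   preceding gene without overlapping it, subject to a plausible protein
   length when reference genomes are supplied;
2. two same-strand PCGs may not overlap in the same reading frame (both are
   translated from one polycistronic transcript), overlaps in different
   frames or across strands are legal;
3. a PCG ends at the first in-frame full stop codon, or with an abbreviated
   ``TA-``/``T--`` stop immediately before the downstream tRNA;
4. duplicated gene calls are resolved by annotation quality score;
5-6. tRNA and rRNA boundaries are taken as predicted upstream and never
   extended to flanking genes;
7. curated boundaries are compared (report-only) against reference genomes.

Unresolvable genes are flagged and left unchanged, never deleted.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace

from .genome import (
    FeatureKind,
    GeneFeature,
    GenomeRecord,
    GeneticCode,
    INVERTEBRATE_MITO,
    reverse_complement,
)

__all__ = [
    "AdjacencyReport",
    "CurationDiff",
    "CurationResult",
    "DEFAULT_START_CODONS",
    "compute_gene_geometry",
    "geometry_summary",
    "select_start_codon",
    "resolve_stop_codon",
    "check_pcg_overlap_legality",
    "deduplicate_candidates",
    "curate_record",
    "reference_length_ranges",
]

#: Eligible PCG start codons, most common mitochondrial initiators first.
DEFAULT_START_CODONS = ("ATG", "ATA", "ATT", "ATC", "GTG")

#: Default half-width of the search window: candidate starts are considered
#: from the upstream gene boundary up to this many nt into the annotated gene.
DEFAULT_WINDOW_INTO_GENE = 90


@dataclass(frozen=True)
class AdjacencyReport:
    """Spacing between two genes adjacent on the circle.

    ``gap`` counts intergenic nucleotides: negative = overlap, 0 = abutting,
    positive = spacer.
    """

    upstream: str
    downstream: str
    gap: int


@dataclass(frozen=True)
class CurationDiff:
    """One curation change: which gene, which field, old/new, and the rule
    (1-7) that motivated it."""

    gene: str
    field: str  # start / end / start_codon / stop_codon / removed_duplicate
    old: object
    new: object
    rule: int

    def __post_init__(self) -> None:
        if self.rule not in range(1, 8):
            raise ValueError(f"rule must be 1..7, got {self.rule}")
        if self.old == self.new:
            raise ValueError("diff with old == new")


@dataclass
class CurationResult:
    record: GenomeRecord
    diffs: list[CurationDiff] = field(default_factory=list)
    violations: list[str] = field(default_factory=list)
    unresolved: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    reference_report: dict[str, dict[str, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry


def compute_gene_geometry(
    record: GenomeRecord, *, include_control_region: bool = True
) -> list[AdjacencyReport]:
    """Gap (spacer/overlap) between every pair of genes adjacent on the circle.

    For a circular record the wrap-around junction (last feature back to the
    first) is included, so the number of reports equals the number of
    features considered.
    """
    feats = [
        f
        for f in record.features
        if include_control_region or f.kind != FeatureKind.CONTROL_REGION
    ]
    if len(feats) < 2:
        raise ValueError("need at least two features for geometry")
    n = len(record.sequence)
    reports: list[AdjacencyReport] = []
    for i, up in enumerate(feats):
        if i == len(feats) - 1:
            if not record.circular:
                break
            down = feats[0]
            up_end = up.end if up.spans_origin() else up.end - n
            gap = down.start - up_end - 1
        else:
            down = feats[i + 1]
            gap = down.start - up.end - 1
        reports.append(AdjacencyReport(up.name, down.name, gap))
    return reports


def geometry_summary(reports: list[AdjacencyReport]) -> dict[str, int]:
    """Counts used in genome-organisation tables: number and total length of
    intergenic spacers, and number of overlapping adjacent pairs."""
    spacers = [r.gap for r in reports if r.gap > 0]
    overlaps = [r.gap for r in reports if r.gap < 0]
    return {
        "n_spacers": len(spacers),
        "total_spacer_bp": sum(spacers),
        "n_overlaps": len(overlaps),
        "max_overlap": -min(overlaps) if overlaps else 0,
    }


# ---------------------------------------------------------------------------
# coordinate helpers (all 1-based genomic; arithmetic on the circle)


def _circular_slice(seq: str, start1: int, length: int) -> str:
    """length nt starting at 1-based position start1, wrapping the origin."""
    n = len(seq)
    i = (start1 - 1) % n
    if i + length <= n:
        return seq[i : i + length]
    return seq[i:] + seq[: (i + length) % n]


def _coding_codon_at(record: GenomeRecord, feature_strand: str, pos1: int) -> str:
    """The codon whose coding-strand first base is at genomic pos1."""
    if feature_strand == "+":
        return _circular_slice(record.sequence, pos1, 3)
    # minus strand: coding 5'->3' runs toward smaller genomic coordinates
    raw = _circular_slice(record.sequence, pos1 - 2, 3)
    return reverse_complement(raw)


def _upstream_boundary(record: GenomeRecord, gene: GeneFeature) -> int:
    """Genomic coordinate of the transcriptionally-upstream neighbour's edge
    closest to ``gene`` (the position a non-overlapping start must clear)."""
    feats = [f for f in record.features if f is not gene and f.name != gene.name]
    if not feats:
        raise ValueError(f"{gene.name}: no upstream neighbour")
    n = len(record.sequence)
    if gene.strand == "+":
        # nearest feature end strictly "left" of gene.start on the circle
        best = min(feats, key=lambda f: (gene.start - f.end - 1) % n)
        return best.end
    best = min(feats, key=lambda f: (f.start - gene.end - 1) % n)
    return best.start


def _downstream_boundary(record: GenomeRecord, gene: GeneFeature) -> int:
    """Genomic coordinate of the transcriptionally-downstream neighbour's
    near edge (first position the CDS must not reach)."""
    feats = [f for f in record.features if f is not gene and f.name != gene.name]
    if not feats:
        raise ValueError(f"{gene.name}: no downstream neighbour")
    n = len(record.sequence)
    if gene.strand == "+":
        best = min(feats, key=lambda f: (f.start - gene.end - 1) % n)
        return best.start
    best = min(feats, key=lambda f: (gene.start - f.end - 1) % n)
    return best.end


def _shift_coding_start(gene: GeneFeature, pos1: int) -> GeneFeature:
    if gene.strand == "+":
        return replace(gene, start=pos1)
    return replace(gene, end=pos1)


def _coding_start(gene: GeneFeature) -> int:
    return gene.start if gene.strand == "+" else gene.end


def _coding_end(gene: GeneFeature) -> int:
    return gene.end if gene.strand == "+" else gene.start


# ---------------------------------------------------------------------------
# rule 1: start-codon selection


def reference_length_ranges(
    references: list[GenomeRecord], *, tolerance: float = 0.10
) -> dict[str, tuple[float, float]]:
    """Plausible protein-length windows (+-10% of the reference mean, in
    amino acids) per gene name, derived from reference annotations."""
    lengths: dict[str, list[float]] = defaultdict(list)
    for ref in references:
        for f in ref.pcgs():
            aa_len = f.length(len(ref.sequence)) / 3 - 1
            lengths[f.name].append(aa_len)
    out = {}
    for name, vals in lengths.items():
        mean = sum(vals) / len(vals)
        out[name] = (mean * (1 - tolerance), mean * (1 + tolerance))
    return out


def _candidate_start_positions(
    record: GenomeRecord, gene: GeneFeature, window_into_gene: int
) -> list[int]:
    """In-frame genomic positions for a candidate coding start, ordered from
    nearest-to-the-upstream-gene inwards."""
    n = len(record.sequence)
    boundary = _upstream_boundary(record, gene)
    cur = _coding_start(gene)
    if gene.strand == "+":
        span = (cur - boundary - 1) % n  # nt between upstream end and start
        first_offset = -(span - span % 3)  # most-upstream in-frame position
    else:
        span = (boundary - cur - 1) % n
        first_offset = -(span - span % 3)
    positions = []
    offset = first_offset
    while offset <= window_into_gene:
        if gene.strand == "+":
            positions.append((cur + offset - 1) % n + 1)
        else:
            positions.append((cur - offset - 1) % n + 1)
        offset += 3
    return positions


def select_start_codon(
    record: GenomeRecord,
    gene: GeneFeature,
    *,
    candidate_starts: tuple[str, ...] = DEFAULT_START_CODONS,
    reference_lengths: dict[str, tuple[float, float]] | None = None,
    window_into_gene: int = DEFAULT_WINDOW_INTO_GENE,
    code: GeneticCode = INVERTEBRATE_MITO,
) -> tuple[GeneFeature, CurationDiff | None, bool]:
    """Rule 1: place the 5' end at the first eligible in-frame start codon.

    Candidates are scanned from the upstream gene boundary inwards (never
    overlapping the upstream gene); a candidate is eligible when its codon is
    in ``candidate_starts``, the resulting ORF has no internal stop, and the
    protein length falls inside the gene's reference range (when given).

    Returns ``(feature, diff-or-None, unresolved)``; an unresolved gene is
    returned unchanged.
    """
    if gene.kind != FeatureKind.PCG:
        raise ValueError(f"{gene.name} is not a PCG")
    ref_range = (reference_lengths or {}).get(gene.name)
    for pos in _candidate_start_positions(record, gene, window_into_gene):
        codon = _coding_codon_at(record, gene.strand, pos)
        if codon not in candidate_starts:
            continue
        trial = _shift_coding_start(gene, pos)
        # the ORF is delimited by its own first in-frame stop (rule 3), not
        # by the possibly mis-annotated current 3' end
        scan = _scan_for_stop(record, trial, code)
        if scan is None:
            continue
        n_codons = scan[2]
        if ref_range is not None and not (
            ref_range[0] <= n_codons <= ref_range[1]
        ):
            continue
        if pos == _coding_start(gene):
            if gene.start_codon != codon:  # refresh a stale annotation
                diff = CurationDiff(
                    gene.name, "start_codon", gene.start_codon, codon, rule=1
                )
                return replace(gene, start_codon=codon), diff, False
            return gene, None, False
        diff = CurationDiff(
            gene.name,
            "start" if gene.strand == "+" else "end",
            _coding_start(gene),
            pos,
            rule=1,
        )
        trial = replace(trial, start_codon=codon)
        return trial, diff, False
    return gene, None, True


# ---------------------------------------------------------------------------
# rule 3: stop-codon resolution


def resolve_stop_codon(
    record: GenomeRecord,
    gene: GeneFeature,
    *,
    code: GeneticCode = INVERTEBRATE_MITO,
) -> tuple[GeneFeature, CurationDiff | None, bool]:
    """Rule 3: place the 3' end at the first in-frame full stop codon, or at
    an abbreviated ``TA-``/``T--`` immediately before the downstream gene.

    Scans codon by codon from the (already fixed) start.  Returns
    ``(feature, diff-or-None, unresolved)``.
    """
    if gene.kind != FeatureKind.PCG:
        raise ValueError(f"{gene.name} is not a PCG")
    scan = _scan_for_stop(record, gene, code)
    if scan is None:
        return gene, None, True
    end_pos, stop_codon, _ = scan
    new = replace(_set_coding_end(gene, end_pos), stop_codon=stop_codon)
    return _finish_stop(gene, new)


def _scan_for_stop(
    record: GenomeRecord, gene: GeneFeature, code: GeneticCode
) -> tuple[int, str, int] | None:
    """Scan codons from the gene's coding start up to the downstream gene.

    Returns ``(coding-end genomic position, stop codon, protein length in
    codons)`` for the first in-frame full stop, or for an abbreviated
    ``TA-``/``T--`` stop flush against the downstream gene; None if neither
    exists.
    """
    n = len(record.sequence)
    start = _coding_start(gene)
    boundary = _downstream_boundary(record, gene)
    if gene.strand == "+":
        room = (boundary - start) % n  # nt from start up to downstream gene
    else:
        room = (start - boundary) % n
    n_full = room // 3
    remainder = room % 3

    def codon_pos(i: int) -> int:  # genomic position of codon i's first base
        if gene.strand == "+":
            return (start + 3 * i - 1) % n + 1
        return (start - 3 * i - 1) % n + 1

    for i in range(1, n_full):
        codon = _coding_codon_at(record, gene.strand, codon_pos(i))
        if code.is_stop(codon):
            end_pos = (
                (codon_pos(i) + 2 - 1) % n + 1
                if gene.strand == "+"
                else (codon_pos(i) - 2 - 1) % n + 1
            )
            return end_pos, codon, i
    # no full stop before the downstream gene: try an abbreviated stop
    if remainder in (1, 2):
        tail_first = codon_pos(n_full)
        tail = _coding_codon_at(record, gene.strand, tail_first)[:remainder]
        abbrev = {"T": "T--", "TA": "TA-"}.get(tail)
        if abbrev is not None:
            if gene.strand == "+":
                end_pos = (tail_first + remainder - 1 - 1) % n + 1
            else:
                end_pos = (tail_first - remainder + 1 - 1) % n + 1
            return end_pos, abbrev, n_full
    return None


def _set_coding_end(gene: GeneFeature, pos1: int) -> GeneFeature:
    if gene.strand == "+":
        return replace(gene, end=pos1)
    return replace(gene, start=pos1)


def _finish_stop(
    old: GeneFeature, new: GeneFeature
) -> tuple[GeneFeature, CurationDiff | None, bool]:
    if _coding_end(new) == _coding_end(old):
        if new.stop_codon == old.stop_codon:
            return old, None, False
        diff = CurationDiff(
            old.name, "stop_codon", old.stop_codon, new.stop_codon, rule=3
        )
        return new, diff, False
    fieldname = "end" if old.strand == "+" else "start"
    diff = CurationDiff(
        old.name, fieldname, _coding_end(old), _coding_end(new), rule=3
    )
    return new, diff, False


# ---------------------------------------------------------------------------
# rule 2: overlap legality


def check_pcg_overlap_legality(record: GenomeRecord) -> list[str]:
    """Rule 2 violations: same-strand PCG pairs overlapping in the same
    reading frame.  Overlaps across strands or in different frames pass."""
    n = len(record.sequence)
    pcgs = record.pcgs()
    violations = []
    for i, a in enumerate(pcgs):
        for b in pcgs[i + 1 :]:
            if not _overlap_on_circle(a, b, n):
                continue
            if a.strand != b.strand:
                continue
            if a.strand == "+":
                same_frame = (a.start - b.start) % 3 == 0
            else:
                same_frame = (a.end - b.end) % 3 == 0
            if same_frame:
                violations.append(
                    f"{a.name} and {b.name} overlap on strand {a.strand} "
                    f"in the same reading frame"
                )
    return violations


def _overlap_on_circle(a: GeneFeature, b: GeneFeature, n: int) -> bool:
    def intervals(f: GeneFeature):
        if f.spans_origin():
            return [(f.start, n), (1, f.end)]
        return [(f.start, f.end)]

    for s1, e1 in intervals(a):
        for s2, e2 in intervals(b):
            if s1 <= e2 and s2 <= e1:
                return True
    return False


# ---------------------------------------------------------------------------
# rule 4: duplicate resolution


def deduplicate_candidates(
    features: list[GeneFeature],
) -> tuple[list[GeneFeature], list[CurationDiff], list[str]]:
    """Rule 4: among candidates sharing a gene name keep the highest-quality
    one; ties keep the earliest by start coordinate with a warning."""
    by_name: dict[str, list[GeneFeature]] = defaultdict(list)
    for f in features:
        by_name[f.name].append(f)
    kept: list[GeneFeature] = []
    diffs: list[CurationDiff] = []
    warnings: list[str] = []
    for name, group in by_name.items():
        if len(group) == 1:
            kept.append(group[0])
            continue
        best_q = max(f.quality or 0.0 for f in group)
        winners = [f for f in group if (f.quality or 0.0) == best_q]
        winner = min(winners, key=lambda f: f.start)
        if len(winners) > 1:
            warnings.append(
                f"{name}: quality tie at {best_q}; kept candidate at "
                f"{winner.start}"
            )
        kept.append(winner)
        for f in group:
            if f is winner:
                continue
            diffs.append(
                CurationDiff(
                    name,
                    "removed_duplicate",
                    f"{f.start}..{f.end} (q={f.quality})",
                    None,
                    rule=4,
                )
            )
    kept.sort(key=lambda f: (f.start, f.end, f.name))
    return kept, diffs, warnings


# ---------------------------------------------------------------------------
# full pass


def curate_record(
    record: GenomeRecord,
    references: list[GenomeRecord] | None = None,
    *,
    candidate_starts: tuple[str, ...] = DEFAULT_START_CODONS,
    window_into_gene: int = DEFAULT_WINDOW_INTO_GENE,
    code: GeneticCode = INVERTEBRATE_MITO,
) -> CurationResult:
    """Apply the full curation pass: duplicate resolution (rule 4), start
    selection (rule 1), stop resolution (rule 3) and overlap-legality checks
    (rule 2), in that order.  tRNA/rRNA boundaries are never touched (rules
    5-6); reference genomes, when given, contribute plausible protein-length
    windows and a per-gene length-delta report (rule 7), never auto-applied
    changes.
    """
    work = record.copy()
    kept, diffs, warnings = deduplicate_candidates(work.features)
    work.features = kept
    work._normalize_features()

    ref_lengths = (
        reference_length_ranges(references) if references else None
    )
    unresolved: list[str] = []
    for gene in list(work.pcgs()):
        new, diff, failed = select_start_codon(
            work,
            gene,
            candidate_starts=candidate_starts,
            reference_lengths=ref_lengths,
            window_into_gene=window_into_gene,
            code=code,
        )
        if failed:
            unresolved.append(f"{gene.name}: no eligible start codon")
            continue
        if diff is not None:
            work.replace_feature(gene, new)
            diffs.append(diff)
            if diff.field != "start_codon" and new.start_codon != gene.start_codon:
                diffs.append(
                    CurationDiff(
                        gene.name, "start_codon", gene.start_codon,
                        new.start_codon, rule=1,
                    )
                )
            gene = new
        new, diff, failed = resolve_stop_codon(work, gene, code=code)
        if failed:
            unresolved.append(f"{gene.name}: no full or abbreviated stop")
            continue
        if diff is not None:
            work.replace_feature(gene, new)
            diffs.append(diff)
            if diff.field != "stop_codon" and new.stop_codon != gene.stop_codon:
                diffs.append(
                    CurationDiff(
                        gene.name, "stop_codon", gene.stop_codon,
                        new.stop_codon, rule=3,
                    )
                )

    violations = check_pcg_overlap_legality(work)

    reference_report: dict[str, dict[str, float]] = {}
    if references:
        n = len(work.sequence)
        for gene in work.pcgs():
            ref_lens = [
                f.length(len(r.sequence))
                for r in references
                for f in r.pcgs()
                if f.name == gene.name
            ]
            if ref_lens:
                mean_ref = sum(ref_lens) / len(ref_lens)
                reference_report[gene.name] = {
                    "length": gene.length(n),
                    "reference_mean_length": mean_ref,
                    "delta": gene.length(n) - mean_ref,
                }

    return CurationResult(
        record=work,
        diffs=diffs,
        violations=violations,
        unresolved=unresolved,
        warnings=warnings,
        reference_report=reference_report,
    )
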