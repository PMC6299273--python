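"""Synthetic-data generators for every pipeline stage.

Each generator is a pure function of its configuration and seed, so all
analysis stages can be exercised end-to-end with known ground truth and no
external downloads:

* annotated circular genomes with controlled gene layouts, spacer lengths
  and injected annotation errors (shifted starts/stops, duplicated genes,
  illegal overlaps) for the curation stage;
* codon alignments evolved under the Goldman-Yang model with
  branch-specific omega for the selection stage;
* gene orders scrambled by a known number of inversions/transpositions for
  the rearrangement-distance stage;
* clock-like trees with designated rate-accelerated lineages (plus optional
  Jukes-Cantor alignments) for the branch-length test.

Intergenic spacers are drawn from a C/G-only alphabet.  Every eligible
start codon contains A or T, so spacers can never harbour a spurious
upstream in-frame start; generated true annotations are therefore exact
fixed points of the curation rules by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .codon_model import CodonAlignment, CodonModel, PhyloTree
from .genome import (
    FeatureKind,
    GeneFeature,
    GenomeRecord,
    GeneticCode,
    INVERTEBRATE_MITO,
)
from .gene_order import GeneOrder

__all__ = [
    "LayoutGene",
    "SyntheticGenomeConfig",
    "SyntheticGenome",
    "make_annotated_genome",
    "simulate_codon_alignment",
    "scramble_gene_order",
    "make_clock_tree",
    "simulate_nucleotide_alignment",
]


# ---------------------------------------------------------------------------
# annotated genomes


@dataclass(frozen=True)
class LayoutGene:
    """One gene slot in a synthetic genome layout.

    ``length`` is in nucleotides; for PCGs it must be a codon multiple
    (start + interior + full stop).
    """

    name: str
    kind: FeatureKind
    strand: str = "+"
    length: int = 69

    def __post_init__(self) -> None:
        if self.kind == FeatureKind.PCG and self.length % 3:
            raise ValueError(f"{self.name}: PCG length must be a codon multiple")


def _default_layout() -> list[LayoutGene]:
    return [
        LayoutGene("cox1", FeatureKind.PCG, "+", 450),
        LayoutGene("trnD(gtc)", FeatureKind.TRNA, "+", 68),
        LayoutGene("atp6", FeatureKind.PCG, "+", 300),
        LayoutGene("trnM(cat)", FeatureKind.TRNA, "-", 66),
        LayoutGene("rrnS", FeatureKind.RRNA, "+", 500),
        LayoutGene("nad1", FeatureKind.PCG, "-", 360),
        LayoutGene("trnP(tgg)", FeatureKind.TRNA, "+", 67),
        LayoutGene("cob", FeatureKind.PCG, "+", 390),
        LayoutGene("trnS1(gct)", FeatureKind.TRNA, "+", 68),
        LayoutGene("nad2", FeatureKind.PCG, "+", 330),
    ]


@dataclass
class SyntheticGenomeConfig:
    """Layout and corruption switches for :func:`make_annotated_genome`.

    ``spacers`` gives one intergenic length per junction, the last being the
    wrap-around junction back to the first gene; it is cycled if shorter
    than the number of junctions.  Corruption probabilities apply per
    eligible gene.
    """

    seed: int
    genes: list[LayoutGene] = field(default_factory=_default_layout)
    spacers: list[int] = field(default_factory=lambda: [11, 5, 78, 2, 0, 31, 7, 1, 13, 24])
    p_start_shift: float = 0.0
    p_stop_shift: float = 0.0
    p_duplicate: float = 0.0
    p_illegal_overlap: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.p_start_shift, self.p_stop_shift, self.p_duplicate,
                  self.p_illegal_overlap):
            if not 0 <= p <= 1:
                raise ValueError("corruption probabilities must lie in [0,1]")
        if any(s < 0 for s in self.spacers):
            raise ValueError("spacers must be non-negative")
        if not self.genes:
            raise ValueError("layout needs at least one gene")


@dataclass
class SyntheticGenome:
    truth: GenomeRecord
    corrupted: GenomeRecord
    corruption_log: list[dict]


_SPACER_BASES = np.array(list("CG"))
_ALL_BASES = np.array(list("ACGT"))


def _random_pcg(
    rng: np.random.Generator, n_nt: int, code: GeneticCode
) -> str:
    """ATG + random sense codons (no in-frame stop) + TAA/TAG."""
    n_codons = n_nt // 3
    if n_codons < 3:
        raise ValueError("PCG too short")
    sense = [c for c in code.sense_codons]
    interior = rng.choice(len(sense), size=n_codons - 2)
    stop = "TAA" if rng.random() < 0.77 else "TAG"
    return "ATG" + "".join(sense[i] for i in interior) + stop


def make_annotated_genome(config: SyntheticGenomeConfig) -> SyntheticGenome:
    """Generate a circular genome whose true annotation satisfies every
    curation rule, plus a copy corrupted per the configured switches.

    The corruption log records, per event, the gene, the corrupted field
    and the true value, so curation output can be checked exactly.
    """
    rng = np.random.default_rng(config.seed)
    code = INVERTEBRATE_MITO
    n_junctions = len(config.genes)
    spacers = [
        config.spacers[i % len(config.spacers)] for i in range(n_junctions)
    ]

    parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 1
    for gene, spacer_after in zip(config.genes, spacers):
        if gene.kind == FeatureKind.PCG:
            coding = _random_pcg(rng, gene.length, code)
            seq = coding if gene.strand == "+" else _revcomp(coding)
            start_codon, stop_codon = coding[:3], coding[-3:]
        else:
            seq = "".join(rng.choice(_ALL_BASES, size=gene.length))
            start_codon = stop_codon = None
        features.append(
            GeneFeature(
                name=gene.name,
                kind=gene.kind,
                strand=gene.strand,
                start=pos,
                end=pos + gene.length - 1,
                start_codon=start_codon,
                stop_codon=stop_codon,
                quality=0.9,
            )
        )
        parts.append(seq)
        parts.append("".join(rng.choice(_SPACER_BASES, size=spacer_after)))
        pos += gene.length + spacer_after

    sequence = "".join(parts)
    truth = GenomeRecord(
        id=f"synthetic-{config.seed}",
        sequence=sequence,
        circular=True,
        features=features,
    )

    corrupted = truth.copy()
    log: list[dict] = []
    pcgs = [f for f in corrupted.features if f.kind == FeatureKind.PCG]
    for feat in pcgs:
        if rng.random() < config.p_start_shift:
            shift = 3 * int(rng.integers(1, 5))
            if feat.length() - shift >= 60:
                if feat.strand == "+":
                    new = replace(feat, start=feat.start + shift)
                else:
                    new = replace(feat, end=feat.end - shift)
                new = replace(new, start_codon=None)
                corrupted.replace_feature(feat, new)
                log.append(
                    {"gene": feat.name, "field": "start", "true": feat.start
                     if feat.strand == "+" else feat.end, "shift": shift}
                )
                feat = new
        if rng.random() < config.p_stop_shift:
            shift = 3 * int(rng.integers(1, 4))
            if feat.strand == "+" and feat.end + shift <= len(sequence):
                new = replace(feat, end=feat.end + shift, stop_codon=None)
            elif feat.strand == "-" and feat.start - shift >= 1:
                new = replace(feat, start=feat.start - shift, stop_codon=None)
            else:
                continue
            corrupted.replace_feature(feat, new)
            log.append(
                {"gene": feat.name, "field": "end", "true": feat.end
                 if feat.strand == "+" else feat.start, "shift": shift}
            )

    trnas = [f for f in corrupted.features if f.kind == FeatureKind.TRNA]
    for feat in trnas:
        if rng.random() < config.p_duplicate:
            offset = int(rng.integers(50, max(51, len(sequence) - feat.length())))
            dup_start = (feat.start + offset - 1) % len(sequence) + 1
            dup_end = dup_start + feat.length() - 1
            if dup_end > len(sequence):
                continue
            dup = replace(feat, start=dup_start, end=dup_end, quality=0.3)
            corrupted.features.append(dup)
            corrupted._normalize_features()
            log.append(
                {"gene": feat.name, "field": "duplicate", "true": None,
                 "at": dup_start}
            )

    if config.p_illegal_overlap > 0:
        plus_pcgs = [
            f for f in corrupted.features
            if f.kind == FeatureKind.PCG and f.strand == "+"
        ]
        for up, down in zip(plus_pcgs, plus_pcgs[1:]):
            if rng.random() >= config.p_illegal_overlap:
                continue
            # pull the downstream start into the upstream gene, keeping the
            # two genes frame-congruent so the overlap is illegal (rule 2)
            new_start = up.end - 5
            new_start -= (new_start - up.start) % 3
            if new_start <= up.start:
                continue
            new = replace(down, start=new_start, start_codon=None)
            corrupted.replace_feature(down, new)
            log.append(
                {"gene": down.name, "field": "illegal_overlap",
                 "true": down.start, "at": new_start}
            )
            break

    return SyntheticGenome(truth=truth, corrupted=corrupted, corruption_log=log)


def _revcomp(s: str) -> str:
    from .genome import reverse_complement

    return reverse_complement(s)


# ---------------------------------------------------------------------------
# codon alignments


def simulate_codon_alignment(
    tree: dendropy.Tree | PhyloTree,
    *,
    omega: float | dict[str, float] = 0.2,
    kappa: float = 2.0,
    pi: np.ndarray | None = None,
    n_codons: int = 500,
    seed: int = 0,
    model: CodonModel | None = None,
) -> CodonAlignment:
    """Evolve a codon alignment down a tree under the Goldman-Yang model.

    Root states are drawn from ``pi``; each branch uses the exact
    matrix-exponential transition probabilities for its length and its
    omega (a single value, or a map keyed by branch id as used in model
    fitting).  Deterministic for a fixed seed.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be positive")
    model = model or CodonModel()
    ptree = tree if isinstance(tree, PhyloTree) else PhyloTree(tree)
    if pi is None:
        pi = np.full(model.n, 1.0 / model.n)
    pi = np.asarray(pi, dtype=float)
    rng = np.random.default_rng(seed)

    states: dict[int, np.ndarray] = {
        ptree.root: rng.choice(model.n, size=n_codons, p=pi / pi.sum())
    }
    eigs: dict[float, tuple] = {}
    for node in reversed(ptree.postorder):  # preorder: parents first
        if node not in states:
            continue
        for child in ptree.children[node]:
            bk = ptree.branch_of_child[child]
            branch = ptree.branches[bk]
            om = omega[branch.id] if isinstance(omega, dict) else float(omega)
            if om not in eigs:
                eigs[om] = model.eigensystem(kappa, om, pi)
            P = CodonModel.transition_matrix_from_eig(eigs[om], branch.length)
            cum = np.cumsum(P, axis=1)
            u = rng.random(n_codons)
            child_states = (cum[states[node]] > u[:, None]).argmax(axis=1)
            states[child] = child_states
    seqs = {
        name: "".join(model.codons[s] for s in states[node])
        for node, name in ptree.leaf_name.items()
    }
    return CodonAlignment(seqs)


# ---------------------------------------------------------------------------
# gene orders


def scramble_gene_order(
    order: GeneOrder,
    n_inversions: int,
    n_transpositions: int = 0,
    *,
    seed: int = 0,
) -> tuple[GeneOrder, list[dict]]:
    """Apply random segment inversions (sign-flipping) and transpositions
    to a circular gene order; returns the scrambled order and an event log.

    Inverted segments never cover the full circle minus one gene (which
    would be a mere reflection); each inversion introduces at most 2 and
    each transposition at most 3 breakpoints.
    """
    if len(order) < 3:
        raise ValueError("need at least 3 genes")
    rng = np.random.default_rng(seed)
    genes = list(order.genes)
    signs = list(order.signs)
    log: list[dict] = []
    n = len(genes)
    for _ in range(n_inversions):
        i = int(rng.integers(1, n - 1))
        j = int(rng.integers(i, min(n - 1, i + n - 3)))
        genes[i : j + 1] = genes[i : j + 1][::-1]
        signs[i : j + 1] = [-s for s in signs[i : j + 1][::-1]]
        log.append({"event": "inversion", "segment": (i, j)})
    for _ in range(n_transpositions):
        i = int(rng.integers(1, n - 1))
        j = int(rng.integers(i, n - 1))
        seg_g = genes[i : j + 1]
        seg_s = signs[i : j + 1]
        rest_g = genes[:i] + genes[j + 1 :]
        rest_s = signs[:i] + signs[j + 1 :]
        k = int(rng.integers(1, len(rest_g) + 1))
        genes = rest_g[:k] + seg_g + rest_g[k:]
        signs = rest_s[:k] + seg_s + rest_s[k:]
        log.append({"event": "transposition", "segment": (i, j), "to": k})
    scrambled = replace(order, genes=tuple(genes), signs=tuple(signs))
    return scrambled, log


# ---------------------------------------------------------------------------
# clock trees


def make_clock_tree(
    n_taxa: int,
    depth: float = 1.0,
    rate_multipliers: dict[str, float] | None = None,
    *,
    seed: int = 0,
) -> dendropy.Tree:
    """Ultrametric random-join tree of the given depth; each listed taxon's
    root-to-tip path is then scaled to ``depth * factor`` by adjusting its
    pendant edge (factors > 0; a factor of 1 leaves the clock intact).

    Taxa are labelled ``t1 .. tN``.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rate_multipliers = rate_multipliers or {}
    if any(f <= 0 for f in rate_multipliers.values()):
        raise ValueError("rate multipliers must be positive")
    rng = np.random.default_rng(seed)
    taxa = [f"t{i + 1}" for i in range(n_taxa)]
    ns = dendropy.TaxonNamespace(taxa)
    nodes = []
    for label in taxa:
        nd = dendropy.Node(taxon=ns.get_taxon(label))
        nd.age_ = 0.0
        nodes.append(nd)
    heights = np.sort(rng.uniform(0.05, 1.0, size=n_taxa - 1)) * depth
    heights[-1] = depth
    for h in heights:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = dendropy.Node()
        parent.age_ = float(h)
        for child in (a, b):
            parent.add_child(child)
            child.edge.length = parent.age_ - child.age_
        nodes = [nd for nd in nodes if nd is not a and nd is not b]
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=nodes[0])
    tree.is_rooted = True
    for leaf in tree.leaf_node_iter():
        factor = rate_multipliers.get(leaf.taxon.label, 1.0)
        if factor != 1.0:
            extra = depth * (factor - 1.0)
            new_len = leaf.edge.length + extra
            if new_len <= 0:
                raise ValueError(
                    f"{leaf.taxon.label}: factor {factor} would give a "
                    "negative pendant edge"
                )
            leaf.edge.length = new_len
    return tree


_JC_BASES = np.array(list("ACGT"))


def simulate_nucleotide_alignment(
    tree: dendropy.Tree, n_sites: int, *, seed: int = 0
) -> dict[str, str]:
    """Jukes-Cantor alignment on a rooted tree (branch lengths in
    substitutions/site); used to give the BLT bootstrap something real to
    resample."""
    rng = np.random.default_rng(seed)
    states: dict[int, np.ndarray] = {}
    order = list(tree.preorder_node_iter())
    states[id(tree.seed_node)] = rng.integers(0, 4, size=n_sites)
    out: dict[str, str] = {}
    for nd in order:
        if nd is tree.seed_node:
            pass
        else:
            t = nd.edge.length or 0.0
            p_same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
            parent_states = states[id(nd.parent_node)]
            u = rng.random(n_sites)
            changed = u > p_same
            new = parent_states.copy()
            shifts = rng.integers(1, 4, size=int(changed.sum()))
            new[changed] = (new[changed] + shifts) % 4
            states[id(nd)] = new
        if nd.is_leaf():
            out[nd.taxon.label] = "".join(_JC_BASES[states[id(nd)]])
    return out
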