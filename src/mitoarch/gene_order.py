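"""Signed gene-order representation and rearrangement distance measures.

Mitogenome gene orders are circular signed permutations (sign = coding
strand).  Two similarity measures are provided:

* **breakpoints** — adjacencies of one order absent from the other; an
  adjacency (x, y) is matched by (x, y) or by its reading in the opposite
  orientation (-y, -x).  Fewer breakpoints = more similar.
* **common intervals** — gene subsets that form a contiguous block (any
  internal arrangement, signs ignored) in both orders, counted over block
  sizes 2..n on the orders linearized at a shared anchor gene.  More common
  intervals = more similar.

Orders are canonicalized before comparison: rotated so the anchor gene
(default ``cox1``) comes first with positive sign, reflecting the circle if
the anchor is on the minus strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GeneOrder",
    "GeneOrderComparison",
    "canonicalize",
    "breakpoint_count",
    "common_intervals_count",
    "common_intervals_bruteforce",
    "pairwise_matrix",
    "read_gene_orders",
]


@dataclass(frozen=True)
class GeneOrder:
    """A circular (or linear) signed gene order for one taxon."""

    taxon: str
    genes: tuple[str, ...]
    signs: tuple[int, ...]
    circular: bool = True
    anchor: str = "cox1"

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.signs):
            raise ValueError("genes and signs differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"{self.taxon}: duplicate gene symbols")
        if any(s not in (-1, 1) for s in self.signs):
            raise ValueError("signs must be +1/-1")

    @classmethod
    def from_symbols(
        cls, taxon: str, symbols: list[str], *, circular: bool = True,
        anchor: str = "cox1",
    ) -> "GeneOrder":
        """Parse signed symbols like ``['cox1', '-trnM', '+cox2']``."""
        genes, signs = [], []
        for sym in symbols:
            sym = sym.strip()
            if sym.startswith("-"):
                genes.append(sym[1:])
                signs.append(-1)
            else:
                genes.append(sym.lstrip("+"))
                signs.append(1)
        return cls(taxon, tuple(genes), tuple(signs), circular, anchor)

    def __len__(self) -> int:
        return len(self.genes)

    def signed(self) -> list[tuple[str, int]]:
        return list(zip(self.genes, self.signs))

    def symbols(self) -> list[str]:
        return [("-" if s < 0 else "") + g for g, s in self.signed()]


def canonicalize(order: GeneOrder, anchor: str | None = None) -> GeneOrder:
    """Rotate a circular order so the anchor gene is first with positive
    sign; if the anchor is on the minus strand the circle is read in the
    opposite orientation (reverse and negate) first.  Linear orders are
    returned unchanged apart from validation."""
    anchor = anchor or order.anchor
    if anchor not in order.genes:
        raise ValueError(f"anchor gene {anchor!r} absent from {order.taxon}")
    if not order.circular:
        return order
    genes, signs = list(order.genes), list(order.signs)
    i = genes.index(anchor)
    if signs[i] < 0:
        genes = genes[::-1]
        signs = [-s for s in signs[::-1]]
        i = genes.index(anchor)
    genes = genes[i:] + genes[:i]
    signs = signs[i:] + signs[:i]
    return replace(
        order, genes=tuple(genes), signs=tuple(signs), anchor=anchor
    )


def _check_same_gene_set(a: GeneOrder, b: GeneOrder) -> None:
    if set(a.genes) != set(b.genes):
        diff = sorted(set(a.genes) ^ set(b.genes))
        raise ValueError(f"gene sets differ; symmetric difference: {diff}")


def _adjacencies(order: GeneOrder) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    items = order.signed()
    pairs = list(zip(items, items[1:]))
    if order.circular:
        pairs.append((items[-1], items[0]))
    return pairs


def breakpoint_count(a: GeneOrder, b: GeneOrder) -> int:
    """Adjacencies of ``a`` with no orientation-consistent counterpart in
    ``b``.  Zero for identical orders and for an order and its reverse
    complement (the same circular genome read from the other strand)."""
    _check_same_gene_set(a, b)
    a = canonicalize(a) if a.circular else a
    b = canonicalize(b) if b.circular else b
    b_adj = set()
    for (gx, sx), (gy, sy) in _adjacencies(b):
        b_adj.add(((gx, sx), (gy, sy)))
        b_adj.add(((gy, -sy), (gx, -sx)))  # read in the opposite orientation
    breakpoints = 0
    for adj in _adjacencies(a):
        if adj not in b_adj:
            breakpoints += 1
    return breakpoints


def common_intervals_count(a: GeneOrder, b: GeneOrder) -> int:
    """Number of gene subsets of size 2..n contiguous in both orders
    (signs ignored), counted on the anchor-linearized orders.

    O(n^2): for every interval of ``a`` track the min/max of the genes'
    positions in ``b``; the subset is a common interval iff that span equals
    the interval length.
    """
    _check_same_gene_set(a, b)
    a = canonicalize(a) if a.circular else a
    b = canonicalize(b) if b.circular else b
    pos_b = {g: i for i, g in enumerate(b.genes)}
    n = len(a)
    count = 0
    for i in range(n):
        lo = hi = pos_b[a.genes[i]]
        for j in range(i + 1, n):
            p = pos_b[a.genes[j]]
            lo, hi = min(lo, p), max(hi, p)
            if hi - lo == j - i:
                count += 1
    return count


def common_intervals_bruteforce(a: GeneOrder, b: GeneOrder) -> int:
    """O(n^3) reference implementation: enumerate every interval of ``a``
    as a set and scan ``b`` for a contiguous window with the same set."""
    _check_same_gene_set(a, b)
    a = canonicalize(a) if a.circular else a
    b = canonicalize(b) if b.circular else b
    n = len(a)
    b_genes = list(b.genes)
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            target = set(a.genes[i : j + 1])
            size = j - i + 1
            for k in range(n - size + 1):
                if set(b_genes[k : k + size]) == target:
                    count += 1
                    break
    return count


@dataclass(frozen=True)
class GeneOrderComparison:
    taxon_a: str
    taxon_b: str
    breakpoints: int
    common_intervals: int


@dataclass
class PairwiseResult:
    breakpoints: pd.DataFrame
    common_intervals: pd.DataFrame
    ranking: pd.DataFrame | None = None


def pairwise_matrix(
    orders: list[GeneOrder], *, reference: str | None = None
) -> PairwiseResult:
    """Symmetric breakpoint and common-interval matrices over a set of
    orders, plus a similarity ranking against a designated reference taxon
    (fewest breakpoints first, most common intervals as tie-break)."""
    if len(orders) < 2:
        raise ValueError("need at least two gene orders")
    taxa = [o.taxon for o in orders]
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon ids")
    n = len(orders)
    bp = np.zeros((n, n), dtype=int)
    ci = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            bp[i, j] = bp[j, i] = breakpoint_count(orders[i], orders[j])
            ci[i, j] = ci[j, i] = common_intervals_count(orders[i], orders[j])
        ci[i, i] = len(orders[i]) * (len(orders[i]) - 1) // 2
    bp_df = pd.DataFrame(bp, index=taxa, columns=taxa)
    ci_df = pd.DataFrame(ci, index=taxa, columns=taxa)
    ranking = None
    if reference is not None:
        if reference not in taxa:
            raise ValueError(f"reference {reference!r} not among taxa")
        rows = [
            {
                "taxon": t,
                "breakpoints": int(bp_df.loc[reference, t]),
                "common_intervals": int(ci_df.loc[reference, t]),
            }
            for t in taxa
            if t != reference
        ]
        ranking = (
            pd.DataFrame(rows)
            .sort_values(
                ["breakpoints", "common_intervals"], ascending=[True, False]
            )
            .reset_index(drop=True)
        )
    return PairwiseResult(bp_df, ci_df, ranking)


def read_gene_orders(
    path, *, circular: bool = True, anchor: str = "cox1"
) -> list[GeneOrder]:
    """Read a plain-text gene-order file: one taxon per line, taxon id then
    tab/space-separated signed gene symbols."""
    orders = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"malformed gene-order line: {line!r}")
            orders.append(
                GeneOrder.from_symbols(
                    parts[0], parts[1:], circular=circular, anchor=anchor
                )
            )
    return orders
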