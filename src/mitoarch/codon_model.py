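"""Goldman-Yang codon substitution model over the 62 sense codons of the
invertebrate mitochondrial code.

The instantaneous rate from codon i to codon j is zero unless the codons
differ at exactly one position, and otherwise proportional to

    pi_j                synonymous transversion
    kappa * pi_j        synonymous transition
    omega * pi_j        non-synonymous transversion
    omega * kappa * pi_j  non-synonymous transition

with the diagonal set so rows sum to zero and the matrix scaled to one
expected substitution per codon per unit branch length at stationarity.
Branch models let omega differ among branches of the phylogeny while kappa,
the codon frequencies pi and the topology are shared.

Likelihoods are computed by Felsenstein pruning; transition probabilities
P(t) = exp(Qt) come from the eigendecomposition of the reversible generator
symmetrized by pi^(1/2), with a scipy scaling-and-squaring fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .genome import GeneticCode, INVERTEBRATE_MITO, codons_of

__all__ = [
    "CodonModel",
    "CodonAlignment",
    "PhyloTree",
    "BranchModelSpec",
    "BranchModelFit",
    "f3x4_frequencies",
    "log_likelihood",
    "fit_branch_model",
]

_PURINES = {"A", "G"}


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


class CodonModel:
    """Rate-matrix factory for a fixed genetic code.

    Single-nucleotide-step codon pairs and their substitution classes are
    precomputed once; :meth:`rate_matrix` then assembles Q for any
    (kappa, omega, pi).
    """

    def __init__(self, code: GeneticCode = INVERTEBRATE_MITO):
        self.code = code
        self.codons = list(code.sense_codons)
        self.index = {c: i for i, c in enumerate(self.codons)}
        self.n = len(self.codons)
        pairs_i, pairs_j, is_ts, is_syn = [], [], [], []
        for i, ci in enumerate(self.codons):
            for j, cj in enumerate(self.codons):
                if i == j:
                    continue
                diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
                if len(diffs) != 1:
                    continue
                pairs_i.append(i)
                pairs_j.append(j)
                is_ts.append(_is_transition(*diffs[0]))
                is_syn.append(code.amino_acid(ci) == code.amino_acid(cj))
        self._pi_idx = np.array(pairs_i)
        self._pj_idx = np.array(pairs_j)
        self._is_ts = np.array(is_ts)
        self._is_syn = np.array(is_syn)

    def rate_matrix(
        self, kappa: float, omega: float, pi: np.ndarray, *, scale: bool = True
    ) -> np.ndarray:
        """Generator Q, scaled (by default) to mean rate 1 at stationarity."""
        if kappa <= 0 or omega < 0:
            raise ValueError("kappa must be > 0 and omega >= 0")
        pi = np.asarray(pi, dtype=float)
        if pi.shape != (self.n,) or abs(pi.sum() - 1) > 1e-8 or (pi < 0).any():
            raise ValueError("pi must be a probability vector over sense codons")
        rates = pi[self._pj_idx].copy()
        rates[self._is_ts] *= kappa
        rates[~self._is_syn] *= omega
        Q = np.zeros((self.n, self.n))
        Q[self._pi_idx, self._pj_idx] = rates
        np.fill_diagonal(Q, -Q.sum(axis=1))
        if scale:
            mean_rate = -(pi * np.diag(Q)).sum()
            if mean_rate > 0:
                Q /= mean_rate
        return Q

    def eigensystem(self, kappa: float, omega: float, pi: np.ndarray):
        """Spectral decomposition of Q via the pi^(1/2) symmetrization.

        Returns (A, lam, B) with P(t) = A @ diag(exp(lam t)) @ B.
        """
        Q = self.rate_matrix(kappa, omega, pi)
        sqrt_pi = np.sqrt(np.maximum(pi, 1e-300))
        S = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        S = (S + S.T) / 2  # enforce symmetry against round-off
        lam, V = np.linalg.eigh(S)
        A = V / sqrt_pi[:, None]
        B = V.T * sqrt_pi[None, :]
        return A, lam, B

    @staticmethod
    def transition_matrix_from_eig(eig, t: float) -> np.ndarray:
        A, lam, B = eig
        P = (A * np.exp(lam * t)) @ B
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_matrix(
        self, kappa: float, omega: float, pi: np.ndarray, t: float
    ) -> np.ndarray:
        """P(t) = exp(Qt); eigendecomposition with expm fallback."""
        try:
            eig = self.eigensystem(kappa, omega, pi)
            P = self.transition_matrix_from_eig(eig, t)
            if not np.all(np.isfinite(P)):
                raise np.linalg.LinAlgError
            return P
        except np.linalg.LinAlgError:
            return expm(self.rate_matrix(kappa, omega, pi) * t)


# ---------------------------------------------------------------------------
# alignments


@dataclass
class CodonAlignment:
    """In-frame codon alignment: equal-length rows over sense codons.

    Gap- or ambiguity-containing codon columns are removed alignment-wide at
    construction (complete deletion); stop-codon columns are an error.
    """

    sequences: dict[str, str]
    code: GeneticCode = field(default_factory=lambda: INVERTEBRATE_MITO)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        (length,) = lengths
        if length == 0 or length % 3:
            raise ValueError(f"alignment length {length} is not a codon multiple")
        rows = {
            name: codons_of(seq.upper().replace("U", "T"))
            for name, seq in self.sequences.items()
        }
        n_codons = length // 3
        keep = []
        for k in range(n_codons):
            column = [rows[name][k] for name in rows]
            if any(set(c) - set("ACGT") for c in column):
                continue
            for c in column:
                if self.code.is_stop(c):
                    raise ValueError(f"stop codon {c} in alignment column {k}")
            keep.append(k)
        if not keep:
            raise ValueError("no complete codon columns left after filtering")
        self.columns: dict[str, list[str]] = {
            name: [rows[name][k] for k in keep] for name in rows
        }

    @property
    def taxa(self) -> list[str]:
        return list(self.columns)

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.columns.values())))

    def pattern_matrix(self, model: CodonModel) -> tuple[np.ndarray, np.ndarray]:
        """(patterns, weights): unique codon-index columns and their counts."""
        idx = np.array(
            [[model.index[c] for c in self.columns[t]] for t in self.taxa]
        )
        patterns, counts = np.unique(idx, axis=1, return_counts=True)
        return patterns, counts.astype(float)


def f3x4_frequencies(aln: CodonAlignment, model: CodonModel) -> np.ndarray:
    """Codon frequencies from position-specific nucleotide frequencies
    (the CODEML F3x4 convention), restricted to sense codons."""
    freq = np.zeros((3, 4))
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for codons in aln.columns.values():
        for c in codons:
            for pos, b in enumerate(c):
                freq[pos, base_idx[b]] += 1
    freq += 0.1  # guard against unobserved bases
    freq /= freq.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freq[0, base_idx[c[0]]] * freq[1, base_idx[c[1]]] * freq[2, base_idx[c[2]]]
            for c in model.codons
        ]
    )
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# tree wrapper


@dataclass
class Branch:
    id: str
    parent: int  # node index
    child: int
    length: float


class PhyloTree:
    """Minimal fixed-topology tree for pruning: postorder node list with one
    branch per non-root node.  Built from a dendropy tree (derooted to a
    basal multifurcation, the convention for unrooted reversible-model
    fits)."""

    def __init__(self, tree: dendropy.Tree, *, deroot: bool = True):
        work = tree.clone(depth=1)
        if deroot and len(work.seed_node.child_nodes()) == 2:
            work.deroot()
        nodes = list(work.postorder_node_iter())
        self.node_index = {id(nd): i for i, nd in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.root = self.node_index[id(work.seed_node)]
        self.children: list[list[int]] = [[] for _ in nodes]
        self.branches: list[Branch] = []
        self.leaf_name: dict[int, str] = {}
        leaf_count = 0
        for i, nd in enumerate(nodes):
            if nd.is_leaf():
                self.leaf_name[i] = nd.taxon.label
                leaf_count += 1
            if nd.parent_node is not None:
                parent = self.node_index[id(nd.parent_node)]
                self.children[parent].append(i)
                bid = (
                    nd.taxon.label
                    if nd.is_leaf()
                    else (nd.label or f"node{i}")
                )
                self.branches.append(
                    Branch(
                        id=bid,
                        parent=parent,
                        child=i,
                        length=nd.edge.length if nd.edge.length is not None else 0.1,
                    )
                )
        self.n_leaves = leaf_count
        self.postorder = list(range(self.n_nodes))  # nodes already postorder
        self.branch_of_child = {b.child: k for k, b in enumerate(self.branches)}

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    def branch_ids(self) -> list[str]:
        return [b.id for b in self.branches]


# ---------------------------------------------------------------------------
# likelihood


def _pruning_loglik(
    model: CodonModel,
    tree: PhyloTree,
    patterns: np.ndarray,
    weights: np.ndarray,
    taxa: list[str],
    pi: np.ndarray,
    kappa: float,
    branch_lengths: np.ndarray,
    branch_omegas: np.ndarray,
) -> float:
    taxon_row = {t: r for r, t in enumerate(taxa)}
    eigs: dict[float, tuple] = {}
    n_pat = patterns.shape[1]
    partials: list[np.ndarray | None] = [None] * tree.n_nodes
    log_scale = np.zeros(n_pat)
    for node in tree.postorder:
        kids = tree.children[node]
        if not kids:  # leaf
            continue
        acc = np.ones((model.n, n_pat))
        for child in kids:
            bk = tree.branch_of_child[child]
            om = branch_omegas[bk]
            if om not in eigs:
                eigs[om] = model.eigensystem(kappa, om, pi)
            P = CodonModel.transition_matrix_from_eig(
                eigs[om], branch_lengths[bk]
            )
            if child in tree.leaf_name:
                states = patterns[taxon_row[tree.leaf_name[child]]]
                acc *= P[:, states]
            else:
                acc *= P @ partials[child]
        scale = acc.max(axis=0)
        scale[scale == 0] = 1.0
        acc /= scale
        log_scale += np.log(scale)
        partials[node] = acc
    root_partial = partials[tree.root]
    site_lik = pi @ root_partial
    if np.any(site_lik <= 0) or not np.all(np.isfinite(site_lik)):
        bad = int(np.argmin(site_lik))
        raise FloatingPointError(f"non-finite likelihood at site pattern {bad}")
    return float(weights @ (np.log(site_lik) + log_scale))


def log_likelihood(
    aln: CodonAlignment,
    tree: dendropy.Tree | PhyloTree,
    *,
    kappa: float,
    pi: np.ndarray | None = None,
    omega: float | dict[str, float] = 1.0,
    model: CodonModel | None = None,
) -> float:
    """Log-likelihood of a codon alignment on a tree with fixed parameters.

    ``omega`` is a single value for all branches or a map branch-id -> omega
    (branch ids are leaf labels / internal node labels of the derooted tree).
    Branch lengths are taken from the tree, in expected substitutions per
    codon.
    """
    model = model or CodonModel(aln.code)
    ptree = tree if isinstance(tree, PhyloTree) else PhyloTree(tree)
    missing = set(aln.taxa) - set(ptree.leaf_name.values())
    if missing:
        raise ValueError(f"alignment taxa missing from tree: {sorted(missing)}")
    if pi is None:
        pi = f3x4_frequencies(aln, model)
    patterns, weights = aln.pattern_matrix(model)
    lengths = np.array([b.length for b in ptree.branches])
    if isinstance(omega, dict):
        omegas = np.array([omega[b.id] for b in ptree.branches])
    else:
        omegas = np.full(ptree.n_branches, float(omega))
    return _pruning_loglik(
        model, ptree, patterns, weights, aln.taxa, pi, kappa, lengths, omegas
    )


# ---------------------------------------------------------------------------
# branch-model fitting


@dataclass(frozen=True)
class BranchModelSpec:
    """Which branches share an omega: ``one_ratio`` (all), ``free_ratios``
    (one per branch) or ``two_ratios`` (a named foreground branch vs the
    background)."""

    variant: str
    foreground: str | None = None

    def __post_init__(self) -> None:
        if self.variant not in ("one_ratio", "free_ratios", "two_ratios"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "two_ratios" and not self.foreground:
            raise ValueError("two_ratios requires a foreground branch id")
        if self.variant != "two_ratios" and self.foreground:
            raise ValueError("foreground is only meaningful for two_ratios")


@dataclass
class BranchModelFit:
    spec: BranchModelSpec
    log_likelihood: float
    kappa: float
    omega_by_branch: dict[str, float]
    branch_lengths: dict[str, float]
    parameter_count: int
    converged: bool
    pi: np.ndarray

    @property
    def omegas(self) -> list[float]:
        seen: list[float] = []
        for v in self.omega_by_branch.values():
            if v not in seen:
                seen.append(v)
        return seen


_OMEGA_MAX = 999.0
_T_MAX = 50.0


def _omega_groups(ptree: PhyloTree, spec: BranchModelSpec) -> list[int]:
    """Per-branch index into the omega parameter vector."""
    if spec.variant == "one_ratio":
        return [0] * ptree.n_branches
    if spec.variant == "free_ratios":
        return list(range(ptree.n_branches))
    ids = ptree.branch_ids()
    if spec.foreground not in ids:
        raise ValueError(
            f"foreground {spec.foreground!r} not a branch id; have {ids}"
        )
    return [1 if bid == spec.foreground else 0 for bid in ids]


def fit_branch_model(
    aln: CodonAlignment,
    tree: dendropy.Tree | PhyloTree,
    spec: BranchModelSpec,
    *,
    model: CodonModel | None = None,
    pi: np.ndarray | None = None,
    n_restarts: int = 3,
    seed: int = 0,
    init: BranchModelFit | None = None,
) -> BranchModelFit:
    """Maximize the likelihood over kappa, branch lengths and the omega
    parameters the spec allows.

    Bounded quasi-Newton (L-BFGS-B) on log-transformed parameters with
    seeded random restarts; when ``init`` (a fit of a nested model) is
    given its optimum seeds the first start, which guarantees the nesting
    inequality between successive fits.
    """
    model = model or CodonModel(aln.code)
    ptree = tree if isinstance(tree, PhyloTree) else PhyloTree(tree)
    if pi is None:
        pi = f3x4_frequencies(aln, model)
    patterns, weights = aln.pattern_matrix(model)
    groups = _omega_groups(ptree, spec)
    n_omega = max(groups) + 1
    n_branch = ptree.n_branches
    groups_arr = np.array(groups)

    def unpack(x: np.ndarray):
        kappa = np.exp(x[0])
        lengths = np.exp(x[1 : 1 + n_branch])
        omegas = np.exp(x[1 + n_branch :])
        return kappa, lengths, omegas

    def objective(x: np.ndarray) -> float:
        kappa, lengths, omegas = unpack(x)
        try:
            ll = _pruning_loglik(
                model, ptree, patterns, weights, aln.taxa, pi,
                kappa, lengths, omegas[groups_arr],
            )
        except FloatingPointError:
            return 1e12
        return -ll

    bounds = (
        [(np.log(0.05), np.log(100.0))]
        + [(np.log(1e-6), np.log(_T_MAX))] * n_branch
        + [(np.log(1e-4), np.log(_OMEGA_MAX))] * n_omega
    )

    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = []
    base_lengths = np.maximum([b.length for b in ptree.branches], 1e-3)
    if init is not None:
        init_omegas = np.empty(n_omega)
        for k, b in enumerate(ptree.branches):
            init_omegas[groups[k]] = init.omega_by_branch[b.id]
        starts.append(
            np.concatenate(
                [
                    [np.log(init.kappa)],
                    np.log(
                        np.maximum(
                            [init.branch_lengths[b.id] for b in ptree.branches],
                            1e-6,
                        )
                    ),
                    np.log(np.maximum(init_omegas, 1e-4)),
                ]
            )
        )
    starts.append(
        np.concatenate(
            [[np.log(2.0)], np.log(base_lengths), np.full(n_omega, np.log(0.4))]
        )
    )
    while len(starts) < n_restarts + (init is not None):
        jitter = rng.normal(0, 0.7, size=1 + n_branch + n_omega)
        starts.append(starts[-1 if init is None else 1] + jitter)

    best = None
    converged = False
    for x0 in starts:
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-10, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    kappa, lengths, omegas = unpack(best.x)
    ids = ptree.branch_ids()
    return BranchModelFit(
        spec=spec,
        log_likelihood=-float(best.fun),
        kappa=float(kappa),
        omega_by_branch={
            bid: float(omegas[groups[k]]) for k, bid in enumerate(ids)
        },
        branch_lengths={bid: float(lengths[k]) for k, bid in enumerate(ids)},
        parameter_count=1 + n_branch + n_omega,
        converged=converged,
        pi=pi,
    )
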