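"""Protein divergence and selection inference on mitochondrial PCGs.

The maximum-likelihood branch models live in :mod:`mitoarch.codon_model`;
this module adds the descriptive statistics around them: per-gene protein
divergence against a panel of related species, the likelihood-ratio test
between nested branch models, and a Nei-Gojobori-style counting estimate of
dN/dS that serves as an independent sanity check on the ML fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from scipy.stats import chi2 as chi2_dist

from .codon_model import (  # noqa: F401  (public re-exports)
    BranchModelFit,
    BranchModelSpec,
    CodonAlignment,
    CodonModel,
    fit_branch_model,
    log_likelihood,
)
from .genome import GeneticCode, INVERTEBRATE_MITO, codons_of

__all__ = [
    "protein_divergence",
    "likelihood_ratio_test",
    "LRTResult",
    "ng86_pairwise",
    "NG86Result",
    "BranchModelSpec",
    "BranchModelFit",
    "CodonAlignment",
    "fit_branch_model",
    "log_likelihood",
]


def protein_divergence(
    aligned: dict[str, str],
    focal: str,
    *,
    count_gaps: bool = False,
) -> tuple[int, float]:
    """Number and proportion of focal residues differing from *any* other
    sequence at the same site.

    Gap characters only count as differences when ``count_gaps`` is set.
    """
    if focal not in aligned:
        raise KeyError(f"focal taxon {focal!r} not in alignment")
    lengths = {len(s) for s in aligned.values()}
    if len(lengths) != 1:
        raise ValueError(f"aligned sequences have unequal lengths {sorted(lengths)}")
    focal_seq = aligned[focal]
    others = [s for name, s in aligned.items() if name != focal]
    if not others:
        raise ValueError("need at least one non-focal sequence")
    n_diff = 0
    for i, res in enumerate(focal_seq):
        for other in others:
            a, b = res, other[i]
            if "-" in (a, b):
                if count_gaps and a != b:
                    n_diff += 1
                    break
                continue
            if a != b:
                n_diff += 1
                break
    return n_diff, n_diff / len(focal_seq)


# ---------------------------------------------------------------------------
# likelihood-ratio test


@dataclass(frozen=True)
class LRTResult:
    statistic: float  # 2 * (l_alt - l_null), clamped at 0
    df: int
    p_value: float
    significant: bool  # at the stated alpha
    alpha: float = 0.05
    warning: str | None = None


def likelihood_ratio_test(
    null_fit: BranchModelFit,
    alt_fit: BranchModelFit,
    *,
    alpha: float = 0.05,
    tolerance: float = 1e-6,
) -> LRTResult:
    """Chi-square LRT between nested branch-model fits.

    With df = 1 the 5% significance cutoff on the statistic is 3.84.  A
    statistic materially below zero signals optimizer failure on the
    alternative model and is reported as a warning.
    """
    df = alt_fit.parameter_count - null_fit.parameter_count
    if df < 1:
        raise ValueError("alternative model must have more parameters than null")
    raw = 2.0 * (alt_fit.log_likelihood - null_fit.log_likelihood)
    warning = None
    if raw < -tolerance:
        warning = (
            f"negative LRT statistic {raw:.6g}: alternative fit did not reach "
            "the null optimum; re-fit with more restarts"
        )
    stat = max(raw, 0.0)
    p = float(chi2_dist.sf(stat, df))
    return LRTResult(stat, df, p, significant=p <= alpha, alpha=alpha,
                     warning=warning)


# ---------------------------------------------------------------------------
# Nei-Gojobori counting (independent of the ML machinery)


@dataclass(frozen=True)
class NG86Result:
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    dS: float
    dN: float
    omega: float  # NaN when dS == 0


def _codon_site_counts(codon: str, code: GeneticCode) -> tuple[float, float]:
    """(synonymous, non-synonymous) site counts of one codon; mutations to
    stop codons are excluded from the possible-change count."""
    syn = 0.0
    for pos in range(3):
        n_valid = 0
        n_syn = 0
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if code.is_stop(mutant):
                continue
            n_valid += 1
            if code.amino_acid(mutant) == code.amino_acid(codon):
                n_syn += 1
        if n_valid:
            syn += n_syn / n_valid
    return syn, 3.0 - syn


def _pathway_diffs(a: str, b: str, code: GeneticCode) -> tuple[float, float]:
    """Synonymous/non-synonymous differences between two codons, averaged
    over all substitution orderings that avoid stop codons."""
    positions = [i for i in range(3) if a[i] != b[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in permutations(positions):
        cur = a
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if code.is_stop(nxt):
                ok = False
                break
            if code.amino_acid(cur) == code.amino_acid(nxt):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            paths.append((syn, nonsyn))
    if not paths:  # all pathways hit a stop; count every change non-synonymous
        return 0.0, float(len(positions))
    s = sum(p[0] for p in paths) / len(paths)
    n = sum(p[1] for p in paths) / len(paths)
    return s, n


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1 - 4 * p / 3)


def ng86_pairwise(
    seq_a: str,
    seq_b: str,
    code: GeneticCode = INVERTEBRATE_MITO,
) -> NG86Result:
    """Counting-method dN/dS between two equal-length in-frame CDSs, with
    Jukes-Cantor multiple-hit correction."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    codons_a = codons_of(seq_a)
    codons_b = codons_of(seq_b)
    S = N = Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        if set(ca + cb) - set("ACGT"):
            continue
        if code.is_stop(ca) or code.is_stop(cb):
            continue
        sa, na = _codon_site_counts(ca, code)
        sb, nb = _codon_site_counts(cb, code)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = _pathway_diffs(ca, cb, code)
        Sd += sd
        Nd += nd
    if S == 0 or N == 0:
        raise ValueError("no countable codons")
    pS, pN = Sd / S, Nd / N
    dS, dN = _jukes_cantor(pS), _jukes_cantor(pN)
    omega = dN / dS if dS > 0 else math.nan
    return NG86Result(S, N, Sd, Nd, dS, dN, omega)
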