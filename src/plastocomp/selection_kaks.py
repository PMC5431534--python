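"""Terminal-branch Ka/Ks estimation by the Nei-Gojobori (1986) counting
method with Fitch-parsimony ancestral reconstruction.

Selection on a protein-coding gene is summarized by omega = Ka/Ks, the rate
of nonsynonymous substitutions per nonsynonymous site over synonymous
substitutions per synonymous site.  For each terminal branch the tip sequence
is compared against its most recent reconstructed ancestor: per-codon
synonymous/nonsynonymous site fractions are averaged over the pair, observed
differences are apportioned by averaging over all minimal mutational pathways
(pathways through stop codons excluded), and multiple hits are corrected with
the Jukes-Cantor formula d = -3/4 ln(1 - 4p/3).

The genetic code defaults to NCBI translation table 11 (plastid/bacterial).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Optional

import dendropy
import numpy as np
import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "KaKsEstimate",
    "KaKsSaturationError",
    "codon_table",
    "syn_nonsyn_sites",
    "pathway_counts",
    "ng86_pairwise",
    "fitch_ancestral",
    "terminal_branch_kaks",
]

_NUCS = "ACGT"


class KaKsSaturationError(ValueError):
    """Raised when a difference proportion reaches 3/4 and the Jukes-Cantor
    correction is undefined; carries the raw proportions."""

    def __init__(self, pn: float, ps: float):
        super().__init__(
            f"Jukes-Cantor correction undefined (pN={pn:.4f}, pS={ps:.4f})"
        )
        self.pn = pn
        self.ps = ps


@lru_cache(maxsize=None)
def codon_table(code: int = 11) -> dict[str, str]:
    """Codon -> amino acid map (stops as '*') for an NCBI translation table."""
    table = CodonTable.unambiguous_dna_by_id[code]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


@lru_cache(maxsize=None)
def syn_nonsyn_sites(codon: str, code: int = 11) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    At each position the synonymous fraction is the share of the three
    possible changes that preserve the amino acid; changes creating a stop
    codon count as nonsynonymous, so S + N = 3 exactly.
    """
    table = codon_table(code)
    aa = table[codon]
    s = 0.0
    for pos in range(3):
        for alt in _NUCS:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if table[mutant] == aa and table[mutant] != "*":
                s += 1 / 3
    return s, 3.0 - s


@lru_cache(maxsize=None)
def pathway_counts(
    a: str, b: str, code: int = 11
) -> Optional[tuple[float, float]]:
    """(synonymous, nonsynonymous) difference counts between two codons.

    Counts are averaged with equal weight over all orderings of the single-
    nucleotide steps from ``a`` to ``b``; any ordering passing through a stop
    codon is excluded.  Returns ``None`` when every pathway is blocked (the
    codon pair is then excluded from the comparison).
    """
    table = codon_table(code)
    diffs = [i for i in range(3) if a[i] != b[i]]
    if not diffs:
        return 0.0, 0.0
    tot_s = tot_n = 0.0
    valid = 0
    for order in itertools.permutations(diffs):
        cur = a
        s = n = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if table[nxt] == "*" and nxt != b:
                ok = False
                break
            if table[nxt] == table[cur]:
                s += 1
            else:
                n += 1
            cur = nxt
        if ok:
            valid += 1
            tot_s += s
            tot_n += n
    if valid == 0:
        return None
    return tot_s / valid, tot_n / valid


@dataclass
class KaKsEstimate:
    """NG86 estimate for one sequence pair (or one terminal branch)."""

    Ka: float
    Ks: float
    omega: Optional[float]       # None when Ka = Ks = 0; inf when Ks = 0 < Ka
    Na: float
    Ns: float
    S_sites: float
    N_sites: float
    n_codons: int
    n_excluded: int = 0


def _jc_correct(p: float) -> float:
    if p == 0:
        return 0.0
    return -0.75 * math.log(1 - 4 * p / 3)


def ng86_pairwise(a: str, b: str, code: int = 11) -> KaKsEstimate:
    """Nei-Gojobori (1986) Ka and Ks between two aligned coding sequences.

    Codons containing gaps or ambiguous bases in either sequence are excluded
    pairwise, as are codon pairs whose every mutational pathway crosses a
    stop.  Site counts are the average of the two sequences over the compared
    codons; S + N = 3L.  Jukes-Cantor correction is applied to both
    proportions; a proportion >= 3/4 raises :class:`KaKsSaturationError`.
    """
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    if len(a) % 3:
        raise ValueError("alignment length must be divisible by 3")
    table = codon_table(code)
    S = N = Na = Ns = 0.0
    n_codons = n_excluded = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if any(ch not in _NUCS for ch in ca + cb):
            n_excluded += 1
            continue
        if table[ca] == "*" or table[cb] == "*":
            n_excluded += 1
            continue
        counts = pathway_counts(ca, cb, code)
        if counts is None:
            n_excluded += 1
            continue
        sa, na = syn_nonsyn_sites(ca, code)
        sb, nb = syn_nonsyn_sites(cb, code)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        Ns += counts[0]
        Na += counts[1]
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no comparable codons")
    ps = Ns / S if S > 0 else 0.0
    pn = Na / N if N > 0 else 0.0
    if ps >= 0.75 or pn >= 0.75:
        raise KaKsSaturationError(pn, ps)
    Ks = _jc_correct(ps)
    Ka = _jc_correct(pn)
    if Ks > 0:
        omega: Optional[float] = Ka / Ks
    elif Ka > 0:
        omega = math.inf
    else:
        omega = None
    return KaKsEstimate(Ka=Ka, Ks=Ks, omega=omega, Na=Na, Ns=Ns,
                        S_sites=S, N_sites=N, n_codons=n_codons,
                        n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# Fitch parsimony ancestral reconstruction
# ---------------------------------------------------------------------------

def _ensure_node_labels(tree: dendropy.Tree) -> None:
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if not node.label:
            k += 1
            node.label = f"anc{k}"


def fitch_ancestral(
    tree: dendropy.Tree, alignment: Mapping[str, str]
) -> tuple[dict[str, str], int]:
    """Fitch-parsimony ancestral sequences at the internal nodes of a rooted
    tree.

    Per site, the bottom-up pass intersects (else unions) the child state
    sets; the top-down pass assigns the root the alphabetically first state
    of its set and each child its parent's state when compatible, otherwise
    its own alphabetically first state.  Characters outside A/C/G/T are
    wildcards.  Returns ``(ancestor sequences keyed by node label, parsimony
    score)``; unlabeled internal nodes get labels ``anc1``, ``anc2``, ... in
    preorder (assigned on the tree in place).
    """
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing = [t for t in labels if t not in alignment]
    if missing:
        raise KeyError(f"tips missing from alignment: {missing[:5]}")
    length = len(alignment[labels[0]])
    if any(len(alignment[t]) != length for t in labels):
        raise ValueError("aligned sequences must have equal length")
    _ensure_node_labels(tree)

    full = frozenset(_NUCS)
    sets: dict[int, list[frozenset]] = {}
    score = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            seq = alignment[node.taxon.label].upper()
            sets[id(node)] = [
                frozenset(ch) if ch in _NUCS else full for ch in seq
            ]
            continue
        child_sets = [sets[id(c)] for c in node.child_nodes()]
        merged: list[frozenset] = []
        for site in range(length):
            inter = frozenset.intersection(*(cs[site] for cs in child_sets))
            if inter:
                merged.append(inter)
            else:
                union = frozenset.union(*(cs[site] for cs in child_sets))
                merged.append(union)
                score += 1
        sets[id(node)] = merged

    assigned: dict[int, str] = {}
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        own = sets[id(node)]
        if node.parent_node is None:
            seq = "".join(min(s) for s in own)
        else:
            parent_seq = assigned[id(node.parent_node)]
            seq = "".join(
                p if p in s else min(s) for p, s in zip(parent_seq, own)
            )
        assigned[id(node)] = seq
        out[node.label] = seq
    return out, score


def terminal_branch_kaks(
    tree: dendropy.Tree,
    alignment: Mapping[str, str],
    code: int = 11,
    gene: str = "",
) -> pd.DataFrame:
    """Per-tip Ka/Ks against the most recent reconstructed ancestor.

    For each tip the parent node's Fitch-reconstructed sequence is the
    comparison partner; rows with saturated divergence are reported with NaN
    estimates.  Returns a frame with columns gene, tip, Ka, Ks, omega, Na,
    Ns, S, N (omega NaN when undefined, inf when Ks = 0 < Ka).
    """
    ancestors, _ = fitch_ancestral(tree, alignment)
    rows = []
    for leaf in tree.leaf_node_iter():
        tip = leaf.taxon.label
        parent_seq = ancestors[leaf.parent_node.label]
        row = {"gene": gene, "tip": tip}
        try:
            est = ng86_pairwise(alignment[tip], parent_seq, code)
            row.update(
                Ka=est.Ka, Ks=est.Ks,
                omega=(float("nan") if est.omega is None else est.omega),
                Na=est.Na, Ns=est.Ns, S=est.S_sites, N=est.N_sites,
            )
        except KaKsSaturationError:
            row.update(Ka=float("nan"), Ks=float("nan"), omega=float("nan"),
                       Na=float("nan"), Ns=float("nan"),
                       S=float("nan"), N=float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def mean_omega(kaks: pd.DataFrame, cap: Optional[float] = None) -> float:
    """Average omega over tips with a defined estimate.

    Infinite values (Ks = 0 with Ka > 0) are excluded by default or clipped
    to ``cap`` when given; returns NaN when no tip has a defined omega.
    """
    w = kaks["omega"].to_numpy(float)
    w = w[~np.isnan(w)]
    if cap is not None:
        w = np.minimum(w, cap)
    else:
        w = w[np.isfinite(w)]
    return float(w.mean()) if w.size else float("nan")
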