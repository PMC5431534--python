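"""Synthetic inputs with recorded ground truth: Yule trees, Brownian-motion
traits, quadripartite plastomes, and codon alignments with controlled omega.

Every generator is deterministic given its parameters and seed, and emits the
quantities needed to verify downstream modules (true partition boundaries,
true sequence characteristics, true per-branch substitution counts).
Defaults mirror the ranges observed in seed-plant plastomes: total lengths
around 155 kb (spanning roughly 70-218 kb), one IR copy near 25 kb, 110-165
gene features drawn from the 126-gene catalogue, GC content near 0.37.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

from .catalogue import CATALOGUE
from .genome_model import (
    AnnotatedGenome,
    GeneFeature,
    GenomeFeatures,
    QuadripartitePartition,
    compute_features,
    revcomp,
)
from .selection_kaks import codon_table

__all__ = [
    "simulate_tree",
    "CorrelatedTraitSpec",
    "simulate_correlated_traits",
    "PlastomeSpec",
    "simulate_plastome",
    "default_gene_lengths",
    "CodonAlignment",
    "simulate_codon_evolution",
]


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, model: str = "yule", seed: int = 0) -> dendropy.Tree:
    """A random ultrametric Yule (pure-birth) tree rescaled to unit depth.

    Tips are labelled ``t1 .. tn``.  The same seed yields the identical
    Newick string.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if model != "yule":
        raise ValueError(f"unknown tree model {model!r}")
    rng = random.Random(seed)

    # forward pure-birth construction: grow from 1 lineage, split a uniformly
    # chosen active lineage after Exp(k) waiting times, stop at n_tips, then
    # extend all open branches to the present.
    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    active = [tree.seed_node]
    birth_times = {id(tree.seed_node): 0.0}
    t = 0.0
    t_root_split = None
    while len(active) < n_tips:
        k = len(active)
        t += rng.expovariate(k)
        if t_root_split is None:
            t_root_split = t
        node = active.pop(rng.randrange(k))
        node.edge.length = t - birth_times[id(node)] if node.parent_node else 0.0
        birth_times[id(node)] = t  # split time
        for _ in range(2):
            child = node.new_child()
            birth_times[id(child)] = t
            active.append(child)
    t += rng.expovariate(len(active))
    for i, node in enumerate(active):
        node.edge.length = t - birth_times[id(node)]
    depth = t - t_root_split  # crown age: the root stem carries no length
    for node in tree.preorder_node_iter():
        if node.edge.length is not None and depth > 0:
            node.edge.length /= depth
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        taxon = taxon_namespace.new_taxon(f"t{i}")
        leaf.taxon = taxon
    return tree


# ---------------------------------------------------------------------------
# correlated BM traits
# ---------------------------------------------------------------------------

@dataclass
class CorrelatedTraitSpec:
    """Two traits co-evolving under Brownian motion with a known slope.

    x evolves as BM with rate ``sigma2_x``; y = beta * x + e with e an
    independent BM residual of rate ``sigma2_resid``.  Both traits are BM on
    the tree and the expected contrasts-regression slope of y on x is beta.
    The default residual rate is small relative to the signal so that the
    contrasts SMA slope (a ratio of standard deviations) also recovers beta.
    """

    beta: float = 1.1
    sigma2_x: float = 1.0
    sigma2_resid: float = 0.05
    root_x: float = 0.0
    root_y: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma2_x < 0 or self.sigma2_resid < 0:
            raise ValueError("BM rates must be nonnegative")


def simulate_correlated_traits(
    tree: dendropy.Tree, spec: CorrelatedTraitSpec
) -> pd.DataFrame:
    """Tip table with columns ``x`` and ``y`` simulated branchwise."""
    rng = np.random.default_rng(spec.seed)
    vals: dict[int, tuple[float, float]] = {}
    rows = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            px, pe = spec.root_x, 0.0
        else:
            px, pe = vals[id(node.parent_node)]
        bl = node.edge.length or 0.0
        x = px + (rng.normal(0.0, math.sqrt(spec.sigma2_x * bl)) if bl > 0 and spec.sigma2_x > 0 else 0.0)
        e = pe + (rng.normal(0.0, math.sqrt(spec.sigma2_resid * bl)) if bl > 0 and spec.sigma2_resid > 0 else 0.0)
        if node.is_leaf():
            rows[node.taxon.label] = {
                "x": x,
                "y": spec.root_y + spec.beta * (x - spec.root_x) + e,
            }
        else:
            vals[id(node)] = (x, e)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "id"
    return df


# ---------------------------------------------------------------------------
# plastomes
# ---------------------------------------------------------------------------

#: typical single-copy lengths (bp) for catalogue genes, used when a spec
#: does not provide explicit lengths
def default_gene_lengths() -> dict[str, int]:
    lengths = {}
    for name, entry in CATALOGUE.items():
        if entry.subcategory == "transfer RNA":
            lengths[name] = 75
        elif entry.subcategory == "ribosomal RNA":
            lengths[name] = {"rrn4.5": 103, "rrn5": 121, "rrn16": 1491,
                             "rrn23": 2810}.get(name, 1500)
        elif name == "ycf1":
            lengths[name] = 5100
        elif name == "ycf2":
            lengths[name] = 6800
        elif name in ("rpoB", "rpoC1", "rpoC2"):
            lengths[name] = 3200
        elif name.startswith("orf"):
            lengths[name] = 3 * int(name[3:].rstrip("abcdefgh") or 100)
        else:
            lengths[name] = 900
    return lengths


@dataclass
class PlastomeSpec:
    """Blueprint for one synthetic quadripartite plastome.

    ``genes_lsc`` / ``genes_ssc`` / ``genes_ir`` name the catalogue genes
    placed in each region (IR genes appear once per repeat copy); lengths come
    from ``gene_lengths`` (default typical values).  Intergenic spacers are
    exponential with mean ``spacer_mean``; regions are padded to their target
    length.  ``ir_len = 0`` produces a genome without an inverted repeat.
    """

    lsc_len: int = 86_000
    ssc_len: int = 18_000
    ir_len: int = 25_000
    genes_lsc: list[str] = field(default_factory=list)
    genes_ssc: list[str] = field(default_factory=list)
    genes_ir: list[str] = field(default_factory=list)
    gene_lengths: dict[str, int] = field(default_factory=dict)
    spacer_mean: float = 300.0
    gc_target: float = 0.37
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lsc_len <= 0 or self.ssc_len <= 0 or self.ir_len < 0:
            raise ValueError("region lengths must be positive (ir_len >= 0)")
        if not 0 < self.gc_target < 1:
            raise ValueError("gc_target must be a fraction in (0, 1)")

    @classmethod
    def random(cls, seed: int = 0, scale: float = 1.0) -> "PlastomeSpec":
        """A randomized spec in seed-plant ranges, optionally scaled down."""
        rng = random.Random(seed)
        lengths = default_gene_lengths()
        # per-species length variation: RNA genes are nearly invariant,
        # category-III (ycf/orf/potential) genes vary most
        sd_by_cat = {"I": 0.04, "II": 0.02, "III": 0.20}
        for g in lengths:
            entry = CATALOGUE.get(g)
            sd = sd_by_cat[entry.category] if entry else 0.2
            lengths[g] = max(36, round(lengths[g] * rng.lognormvariate(0.0, sd)))
        # a conserved core present in every synthetic species, plus a random
        # complement of the catalogue
        core = ["atpA", "accD", "ycf1", "atpI", "ndhE", "rbcL", "rps8",
                "matK", "psbA", "rrn16"]
        names = sorted(set(CATALOGUE) - set(core))
        n_extra = rng.randint(45, 70)
        sample = core + rng.sample(names, n_extra)
        ir_genes = [g for g in sample if lengths[g] > 1000][:4]
        rest = [g for g in sample if g not in ir_genes]
        n_ssc = max(2, len(rest) // 8)
        genes_ssc = rest[:n_ssc]
        genes_lsc = rest[n_ssc:]
        lsc = int(rng.gauss(86_000, 6_000) * scale)
        ssc = int(rng.gauss(18_000, 2_500) * scale)
        ir = int(rng.gauss(25_000, 3_000) * scale)
        lsc = max(lsc, sum(lengths[g] for g in genes_lsc) + 100 * len(genes_lsc))
        ssc = max(ssc, sum(lengths[g] for g in genes_ssc) + 100 * len(genes_ssc))
        ir = max(ir, sum(lengths[g] for g in ir_genes) + 100 * (len(ir_genes) + 1))
        return cls(
            lsc_len=lsc, ssc_len=ssc, ir_len=ir,
            genes_lsc=genes_lsc, genes_ssc=genes_ssc, genes_ir=ir_genes,
            gene_lengths=lengths,
            gc_target=rng.uniform(0.34, 0.40),
            seed=seed,
        )


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs)) if n else ""


def _fill_region(
    rng: np.random.Generator,
    region_len: int,
    genes: list[str],
    lengths: dict[str, int],
    gc: float,
    spacer_mean: float,
    feature_class,
) -> tuple[str, list[tuple[str, int, int]]]:
    """Lay genes with spacers into a region; returns (sequence, placements)."""
    total_genes = sum(lengths[g] for g in genes)
    slack = region_len - total_genes
    if slack < len(genes) + 1:
        raise ValueError(
            f"genes do not fit: {total_genes} bp of genes in {region_len} bp region"
        )
    n_gaps = len(genes) + 1
    raw = rng.exponential(spacer_mean, n_gaps) + 1.0
    gaps = np.floor(raw * (slack / raw.sum())).astype(int)
    gaps = np.maximum(gaps, 1)
    while gaps.sum() > slack:
        gaps[np.argmax(gaps)] -= 1
    gaps[-1] += slack - gaps.sum()
    parts: list[str] = []
    placements: list[tuple[str, int, int]] = []
    pos = 0
    for g, gap in zip(genes, gaps[:-1]):
        parts.append(_random_seq(rng, int(gap), gc))
        pos += int(gap)
        glen = lengths[g]
        parts.append(_random_seq(rng, glen, gc))
        placements.append((g, pos, pos + glen))
        pos += glen
    parts.append(_random_seq(rng, int(gaps[-1]), gc))
    pos += int(gaps[-1])
    assert pos == region_len
    return "".join(parts), placements


def _feature_class_of(name: str) -> str:
    low = name.lower()
    if low.startswith("trn"):
        return "tRNA"
    if low.startswith("rrn"):
        return "rRNA"
    return "protein"


def simulate_plastome(
    spec: PlastomeSpec, genome_id: str = "synth"
) -> tuple[AnnotatedGenome, GenomeFeatures]:
    """Generate one annotated plastome and its true characteristics.

    The sequence is ``LSC + IRb + SSC + IRa`` with IRa the reverse complement
    of IRb; genes are placed without overlap at recorded coordinates, and IR
    genes are annotated in both repeat copies (strand flipped in IRa).  The
    returned :class:`GenomeFeatures` is computed from the construction
    bookkeeping, independent of :func:`compute_features`.
    """
    rng = np.random.default_rng(spec.seed)
    lengths = dict(spec.gene_lengths) or default_gene_lengths()

    lsc_seq, lsc_genes = _fill_region(
        rng, spec.lsc_len, spec.genes_lsc, lengths, spec.gc_target,
        spec.spacer_mean, None)
    ssc_seq, ssc_genes = _fill_region(
        rng, spec.ssc_len, spec.genes_ssc, lengths, spec.gc_target,
        spec.spacer_mean, None)
    if spec.ir_len > 0:
        irb_seq, irb_genes = _fill_region(
            rng, spec.ir_len, spec.genes_ir, lengths, spec.gc_target,
            spec.spacer_mean, None)
        # the SSC endpoints flank the two IR copies; if they happen to be
        # reverse complements the repeat would extend one base past its true
        # boundary, so break the coincidence (both bases lie in spacers)
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        if ssc_seq[0] == comp[ssc_seq[-1]]:
            repl = next(b for b in "ACGT"
                        if b != ssc_seq[0] and b != comp[ssc_seq[-1]])
            ssc_seq = repl + ssc_seq[1:]
    else:
        if spec.genes_ir:
            raise ValueError("genes_ir given but ir_len is 0")
        irb_seq, irb_genes = "", []

    lsc0 = 0
    irb0 = spec.lsc_len
    ssc0 = irb0 + spec.ir_len
    ira0 = ssc0 + spec.ssc_len
    tl = ira0 + spec.ir_len
    sequence = lsc_seq + irb_seq + ssc_seq + (revcomp(irb_seq) if irb_seq else "")

    features: list[GeneFeature] = []
    strand_choice = ["+", "-"]
    for name, s, e in lsc_genes:
        features.append(GeneFeature(name, strand_choice[int(rng.integers(2))],
                                    [(lsc0 + s, lsc0 + e)], _feature_class_of(name)))
    for name, s, e in ssc_genes:
        features.append(GeneFeature(name, strand_choice[int(rng.integers(2))],
                                    [(ssc0 + s, ssc0 + e)], _feature_class_of(name)))
    for name, s, e in irb_genes:
        features.append(GeneFeature(name, "+", [(irb0 + s, irb0 + e)],
                                    _feature_class_of(name)))
        # mirrored copy in IRa, reverse-complement coordinates, strand flipped
        features.append(GeneFeature(
            name, "-",
            [(ira0 + spec.ir_len - e, ira0 + spec.ir_len - s)],
            _feature_class_of(name)))
    features.sort(key=lambda f: f.start)

    partition = None
    if spec.ir_len > 0:
        partition = QuadripartitePartition(
            lsc=(lsc0, irb0), irb=(irb0, ssc0), ssc=(ssc0, ira0),
            ira=(ira0, tl))
    genome = AnnotatedGenome(genome_id, sequence, features, partition)

    grl = sum(f.length for f in features)   # placement is overlap-free
    gcc = (sequence.count("G") + sequence.count("C")) / tl
    truth = GenomeFeatures(
        TL=tl,
        IRL=spec.ir_len,
        LSCL=spec.lsc_len if spec.ir_len else None,
        SSCL=spec.ssc_len if spec.ir_len else None,
        GRL=grl,
        IGRL=tl - grl,
        GCC=gcc,
        GN=len(features),
    )
    return genome, truth


# ---------------------------------------------------------------------------
# codon evolution
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """A simulated codon alignment with full ground truth."""

    tip_seqs: dict[str, str]
    ancestor_seqs: dict[str, str]
    branch_events: pd.DataFrame   # child, n_syn, n_nonsyn (accepted events)
    omega: float
    kappa: float
    seed: int

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.tip_seqs.values()))) // 3


def simulate_codon_evolution(
    tree: dendropy.Tree,
    n_codons: int,
    omega: float,
    kappa: float = 1.0,
    seed: int = 0,
    code: int = 11,
    proposal_rate: float = 1.0,
) -> CodonAlignment:
    """Evolve a stop-free coding sequence along a tree with controlled omega.

    Mutation-selection scheme: along a branch of length t, point mutations
    are proposed at Poisson(3 * L * t * proposal_rate) sites, with transition
    : transversion weight kappa : 1.  Proposals creating stop codons are
    rejected.  A nonsynonymous proposal is accepted with probability
    min(1, omega); a synonymous one with min(1, 1/omega) (omega > 1
    suppresses synonymous fixation instead), so the realized rate ratio
    tracks omega.  Accepted counts per branch are recorded as ground truth.
    """
    if omega < 0:
        raise ValueError("omega must be nonnegative")
    if n_codons < 1:
        raise ValueError("need at least one codon")
    table = codon_table(code)
    sense = sorted(c for c, aa in table.items() if aa != "*")
    rng = np.random.default_rng(seed)

    root = "".join(rng.choice(sense, size=n_codons))
    _ensure_labels(tree)

    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    p_nonsyn = min(1.0, omega)
    p_syn = min(1.0, 1.0 / omega) if omega > 0 else 1.0

    seqs: dict[int, str] = {}
    anc: dict[str, str] = {}
    tips: dict[str, str] = {}
    events = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            seq = root
            n_syn = n_nonsyn = 0
        else:
            seq = seqs[id(node.parent_node)]
            bl = node.edge.length or 0.0
            n_prop = rng.poisson(3 * n_codons * bl * proposal_rate)
            chars = list(seq)
            n_syn = n_nonsyn = 0
            for _ in range(n_prop):
                site = int(rng.integers(3 * n_codons))
                cur = chars[site]
                alts = [b for b in "ACGT" if b != cur]
                weights = np.array(
                    [kappa if transitions[cur] == b else 1.0 for b in alts]
                )
                alt = alts[int(rng.choice(3, p=weights / weights.sum()))]
                c0 = 3 * (site // 3)
                old_codon = "".join(chars[c0 : c0 + 3])
                new_codon = (old_codon[: site - c0] + alt
                             + old_codon[site - c0 + 1 :])
                if table[new_codon] == "*":
                    continue
                if table[new_codon] == table[old_codon]:
                    if rng.random() < p_syn:
                        chars[site] = alt
                        n_syn += 1
                else:
                    if rng.random() < p_nonsyn:
                        chars[site] = alt
                        n_nonsyn += 1
            seq = "".join(chars)
        seqs[id(node)] = seq
        if node.is_leaf():
            tips[node.taxon.label] = seq
            label = node.taxon.label
        else:
            anc[node.label] = seq
            label = node.label
        if node.parent_node is not None:
            events.append({"child": label, "n_syn": n_syn, "n_nonsyn": n_nonsyn})

    return CodonAlignment(
        tip_seqs=tips,
        ancestor_seqs=anc,
        branch_events=pd.DataFrame(events),
        omega=omega,
        kappa=kappa,
        seed=seed,
    )


def _ensure_labels(tree: dendropy.Tree) -> None:
    k = 0
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and not node.label:
            k += 1
            node.label = f"anc{k}"
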