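"""Plastome model: annotated genomes, quadripartite structure and the eight
sequence characteristics.

The chloroplast genome of seed plants is a circular molecule with a
quadripartite architecture — a large single-copy region (LSC) and a small
single-copy region (SSC) separated by two identical inverted repeats (IRa,
IRb).  This module defines the in-memory representation of an annotated
plastome, the annotation-standardization rules applied before any comparative
analysis, inverted-repeat detection, and the computation of the eight
per-species characteristics:

======  =====================================================
TL      total genome length (bp)
IRL     length of ONE inverted-repeat copy (bp; 0 if absent)
LSCL    large single-copy length (bp; missing if no IR)
SSCL    small single-copy length (bp; missing if no IR)
GRL     gene-region length: union of all gene segments (bp)
IGRL    intergenic-region length, TL - GRL (bp)
GCC     GC content, (#G + #C) / (#A + #C + #G + #T)
GN      number of gene features after standardization
======  =====================================================

Coordinates are 0-based half-open throughout; conversion to/from the 1-based
inclusive conventions of GenBank and GFF3 happens at I/O time only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .catalogue import is_catalogue_gene, normalize_gene_name

__all__ = [
    "GeneFeature",
    "QuadripartitePartition",
    "AnnotatedGenome",
    "GenomeFeatures",
    "StandardizationIssue",
    "standardize_annotations",
    "detect_inverted_repeat",
    "compute_features",
    "features_table",
    "coefficient_of_variation",
    "revcomp",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMP)[::-1]


@dataclass
class GeneFeature:
    """A standardized gene annotation.

    ``segments`` are 0-based half-open intervals on the genome; a gene with
    more than one exon (or a merged successive annotation, e.g. *clpP*) has
    multiple segments.  ``feature_class`` is one of ``protein``, ``tRNA``,
    ``rRNA``.
    """

    name: str
    strand: str
    segments: list[tuple[int, int]]
    feature_class: str = "protein"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.segments:
            raise ValueError(f"gene {self.name}: segments must be non-empty")
        for s, e in self.segments:
            if not s < e:
                raise ValueError(f"gene {self.name}: empty interval ({s}, {e})")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.segments)

    @property
    def end(self) -> int:
        return max(e for _, e in self.segments)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.segments)


@dataclass
class QuadripartitePartition:
    """The LSC / IRb / SSC / IRa tiling of a circular plastome.

    Each interval is (start, end) with 0 <= start < genome length; ``end`` may
    exceed the genome length to denote wrapping past the origin.  The four
    intervals tile the circle; IRa and IRb have equal length and IRa is the
    reverse complement of IRb (up to the detection identity threshold).
    """

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]

    @staticmethod
    def _length(iv: tuple[int, int]) -> int:
        return iv[1] - iv[0]

    @property
    def lsc_len(self) -> int:
        return self._length(self.lsc)

    @property
    def ssc_len(self) -> int:
        return self._length(self.ssc)

    @property
    def ir_len(self) -> int:
        return self._length(self.ira)

    def validate(self, genome_length: int) -> None:
        if self._length(self.ira) != self._length(self.irb):
            raise ValueError("IRa and IRb lengths differ")
        total = sum(self._length(iv) for iv in (self.lsc, self.irb, self.ssc, self.ira))
        if total != genome_length:
            raise ValueError(
                f"partition does not tile the circle: {total} != {genome_length}"
            )


@dataclass
class AnnotatedGenome:
    """A circular plastome sequence with standardized gene features."""

    id: str
    sequence: str
    genes: list[GeneFeature] = field(default_factory=list)
    partition: Optional[QuadripartitePartition] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.id}: empty sequence")
        n = len(self.sequence)
        for g in self.genes:
            if g.end > n:
                raise ValueError(
                    f"genome {self.id}: gene {g.name} extends to {g.end} > {n}"
                )


@dataclass
class GenomeFeatures:
    """The eight per-species sequence characteristics."""

    TL: int
    IRL: int
    LSCL: Optional[int]
    SSCL: Optional[int]
    GRL: int
    IGRL: int
    GCC: float
    GN: int

    def as_dict(self) -> dict:
        return {
            "TL": self.TL,
            "IRL": self.IRL,
            "LSCL": self.LSCL if self.LSCL is not None else float("nan"),
            "SSCL": self.SSCL if self.SSCL is not None else float("nan"),
            "GRL": self.GRL,
            "IGRL": self.IGRL,
            "GCC": self.GCC,
            "GN": self.GN,
        }


@dataclass
class StandardizationIssue:
    """A conflict the standardizer refuses to resolve silently."""

    genome_id: str
    kind: str
    genes: tuple[str, ...]
    detail: str


# ---------------------------------------------------------------------------
# annotation standardization
# ---------------------------------------------------------------------------

def _overlap(a: GeneFeature, b: GeneFeature) -> int:
    """Total overlap in bp between the segment spans of two features."""
    total = 0
    for s1, e1 in a.segments:
        for s2, e2 in b.segments:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def standardize_annotations(
    genomes: Sequence[AnnotatedGenome],
    *,
    max_merge_gap: int = 5000,
    overlap_tolerance: int = 30,
    drop_singletons: bool = True,
    with_report: bool = False,
):
    """Apply the annotation-standardization rules to a set of genomes.

    Rules, in order:

    1. Gene names are normalized to canonical catalogue spelling.
    2. Successive features with the same name, strand and class (separated by
       at most ``max_merge_gap`` bp — multi-exon genes annotated as several
       records, e.g. *clpP*, *rpl2*) are merged into one multi-segment
       feature.  Distant same-name copies (IR duplicates) are NOT merged.
    3. Overlapping differently-named features are collapsed: a catalogue gene
       wins over an ``orf*`` annotation (e.g. *orf188* overlapping *ndhA* is
       dropped).  Same-strand overlap of two catalogue genes beyond
       ``overlap_tolerance`` bp is flagged in the report, never merged.
    4. When more than one genome is given and ``drop_singletons`` is true,
       genes present in exactly one genome of the set are removed.

    Returns the standardized genomes (inputs untouched); with
    ``with_report=True`` returns ``(genomes, issues)``.
    """
    issues: list[StandardizationIssue] = []
    out: list[AnnotatedGenome] = []

    for genome in genomes:
        feats = [
            replace(
                f,
                name=normalize_gene_name(f.name),
                segments=sorted(f.segments),
            )
            for f in genome.genes
        ]
        feats.sort(key=lambda f: (f.start, f.end, f.name))

        # rule 2: merge successive same-name records
        merged: list[GeneFeature] = []
        for f in feats:
            if (
                merged
                and merged[-1].name == f.name
                and merged[-1].strand == f.strand
                and merged[-1].feature_class == f.feature_class
                and f.start - merged[-1].end <= max_merge_gap
            ):
                merged[-1] = replace(
                    merged[-1], segments=sorted(merged[-1].segments + f.segments)
                )
            else:
                merged.append(replace(f))

        # rule 3: resolve overlaps between differently-named features
        drop: set[int] = set()
        for i in range(len(merged)):
            for j in range(i + 1, len(merged)):
                a, b = merged[i], merged[j]
                if b.start >= a.end:
                    break
                if a.name == b.name:
                    continue
                ov = _overlap(a, b)
                if ov == 0:
                    continue
                a_cat, b_cat = is_catalogue_gene(a.name), is_catalogue_gene(b.name)
                a_orf = a.name.startswith("orf")
                b_orf = b.name.startswith("orf")
                if a_cat and b_orf:
                    drop.add(j)
                elif b_cat and a_orf:
                    drop.add(i)
                elif a_cat and b_cat and a.strand == b.strand and ov > overlap_tolerance:
                    issues.append(
                        StandardizationIssue(
                            genome.id,
                            "catalogue-overlap",
                            (a.name, b.name),
                            f"{ov} bp same-strand overlap exceeds tolerance "
                            f"{overlap_tolerance}",
                        )
                    )
        kept = [f for k, f in enumerate(merged) if k not in drop]
        out.append(AnnotatedGenome(genome.id, genome.sequence, kept, genome.partition))

    # rule 4: remove genes annotated in exactly one genome of the set
    if drop_singletons and len(out) > 1:
        presence: dict[str, int] = {}
        for g in out:
            for name in {f.name for f in g.genes}:
                presence[name] = presence.get(name, 0) + 1
        singles = {n for n, c in presence.items() if c == 1}
        if singles:
            out = [
                AnnotatedGenome(
                    g.id,
                    g.sequence,
                    [f for f in g.genes if f.name not in singles],
                    g.partition,
                )
                for g in out
            ]

    return (out, issues) if with_report else out


# ---------------------------------------------------------------------------
# inverted-repeat detection
# ---------------------------------------------------------------------------

def _extend_match(
    s: str, rc: str, i: int, j: int, k: int, min_identity: float
) -> tuple[int, int, int]:
    """Extend an exact k-mer seed s[i:i+k] == rc[j:j+k] in both directions.

    Mismatches are bridged greedily as long as overall identity stays at or
    above ``min_identity``; the returned window is trimmed to end on matches.
    Returns (i_start, j_start, length).
    """
    n = len(s)
    # exact extension helpers
    def exact_right(ii: int, jj: int) -> int:
        m = 0
        while ii + m < n and jj + m < n and s[ii + m] == rc[jj + m]:
            m += 1
        return m

    def exact_left(ii: int, jj: int) -> int:
        m = 0
        while ii - m - 1 >= 0 and jj - m - 1 >= 0 and s[ii - m - 1] == rc[jj - m - 1]:
            m += 1
        return m

    left = exact_left(i, j)
    right = exact_right(i, j)  # includes the seed
    i0, j0 = i - left, j - left
    length = left + right
    mismatches = 0
    # greedily bridge single mismatches on the right, then on the left
    while True:
        ii, jj = i0 + length, j0 + length
        if ii + 1 >= n or jj + 1 >= n:
            break
        ext = exact_right(ii + 1, jj + 1)
        if ext == 0:
            break
        new_len = length + 1 + ext
        if (new_len - (mismatches + 1)) / new_len < min_identity:
            break
        mismatches += 1
        length = new_len
    while True:
        if i0 - 2 < 0 or j0 - 2 < 0:
            break
        ext = exact_left(i0 - 1, j0 - 1)
        if ext == 0:
            break
        new_len = length + 1 + ext
        if (new_len - (mismatches + 1)) / new_len < min_identity:
            break
        mismatches += 1
        i0 -= 1 + ext
        j0 -= 1 + ext
        length = new_len
    return i0, j0, length


def detect_inverted_repeat(
    genome: AnnotatedGenome,
    min_len: int = 1000,
    min_identity: float = 0.90,
) -> Optional[QuadripartitePartition]:
    """Locate the longest pair of reverse-complement repeats and derive the
    quadripartite partition.

    Seed-and-extend: exact k-mer anchors between the sequence and its reverse
    complement are extended (bridging mismatches while identity stays >=
    ``min_identity``); candidate pairs shorter than ``min_len`` or with
    overlapping copies are discarded.  The longer single-copy region between
    the two repeat copies is labelled LSC, and the repeat copy immediately
    downstream of the LSC is labelled IRb.  Ties on repeat length are broken
    by the lowest start coordinate.  Returns ``None`` when no qualifying pair
    exists.

    Both repeat copies must lie within the given linearization; an IR copy
    spanning the sequence origin is not detected (re-linearize first).
    """
    s = genome.sequence.upper()
    n = len(s)
    if n < 2 * min_len:
        return None
    rc = revcomp(s)
    k = min(24, min_len)

    index: dict[str, list[int]] = {}
    for j in range(0, n - k + 1):
        index.setdefault(rc[j : j + k], []).append(j)

    step = max(1, (min_len - k + 1) // 2)
    candidates: dict[tuple[int, int, int, int], int] = {}
    for i in range(0, n - k + 1, step):
        hits = index.get(s[i : i + k])
        if not hits:
            continue
        for j in hits:
            i0, j0, length = _extend_match(s, rc, i, j, k, min_identity)
            if length < min_len:
                continue
            a = (i0, i0 + length)
            b = (n - (j0 + length), n - j0)
            if a == b:
                continue  # palindromic self-match
            first, second = (a, b) if a[0] <= b[0] else (b, a)
            if second[0] < first[1]:
                continue  # copies overlap
            candidates[(first[0], first[1], second[0], second[1])] = length

    if not candidates:
        return None

    best = max(candidates, key=lambda key: (candidates[key], -key[0]))
    f0, f1, s0, s1 = best

    def canon(iv: tuple[int, int]) -> tuple[int, int]:
        # normalize so 0 <= start < n (end > n means the interval wraps)
        return (iv[0] - n, iv[1] - n) if iv[0] >= n else iv

    gap1 = (f1, s0)                # between copy 1 and copy 2
    gap2 = canon((s1, f0 + n))     # wraps the origin
    if gap1[1] - gap1[0] >= gap2[1] - gap2[0]:
        lsc, irb, ssc, ira = gap1, (s0, s1), gap2, (f0, f1)
    else:
        lsc, irb, ssc, ira = gap2, (f0, f1), gap1, (s0, s1)
    part = QuadripartitePartition(lsc=lsc, irb=irb, ssc=ssc, ira=ira)
    part.validate(n)
    return part


# ---------------------------------------------------------------------------
# sequence characteristics
# ---------------------------------------------------------------------------

def _union_length(segments: Iterable[tuple[int, int]]) -> int:
    ivs = sorted(segments)
    total = 0
    cur_s, cur_e = None, None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def compute_features(genome: AnnotatedGenome) -> GenomeFeatures:
    """Compute the eight sequence characteristics of a standardized genome.

    GRL is the length of the union of all gene segments (bases in overlapping
    or trans-spliced segments counted once; IR-duplicated genes contribute
    both copies).  GN counts gene features per occurrence, so IR duplicates
    count twice.  GCC ignores N bases in the denominator.
    """
    seq = genome.sequence.upper()
    tl = len(seq)
    if tl == 0:
        raise ValueError("empty sequence")
    for g in genome.genes:
        if g.end > tl or g.start < 0:
            raise ValueError(f"gene {g.name} out of range")

    counts = {b: seq.count(b) for b in "ACGT"}
    acgt = sum(counts.values())
    if acgt == 0:
        raise ValueError("sequence contains no A/C/G/T bases")
    gcc = (counts["G"] + counts["C"]) / acgt

    grl = _union_length(seg for g in genome.genes for seg in g.segments)
    igrl = tl - grl
    gn = len(genome.genes)

    if genome.partition is not None:
        p = genome.partition
        p.validate(tl)
        irl, lscl, sscl = p.ir_len, p.lsc_len, p.ssc_len
        assert lscl + sscl + 2 * irl == tl
    else:
        irl, lscl, sscl = 0, None, None

    return GenomeFeatures(TL=tl, IRL=irl, LSCL=lscl, SSCL=sscl,
                          GRL=grl, IGRL=igrl, GCC=gcc, GN=gn)


def features_table(genomes: Sequence[AnnotatedGenome]) -> pd.DataFrame:
    """Per-genome characteristics as a DataFrame indexed by genome id."""
    rows = {g.id: compute_features(g).as_dict() for g in genomes}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "id"
    return df


def coefficient_of_variation(values) -> float:
    """Sample standard deviation divided by the mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("coefficient of variation requires n >= 2")
    m = x.mean()
    if m == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    sd = x.std(ddof=1)
    return float(sd / m)
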