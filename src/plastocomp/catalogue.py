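"""Reference catalogue of the 126 chloroplast genes used throughout the package.

The catalogue divides the plastid gene complement of seed plants into three
broad categories — (I) the photosynthetic apparatus, (II) RNA genes and the
genetic apparatus, (III) potential genes — and 13 subcategories.  Category and
subcategory membership follows standard plastid nomenclature (psa/psb/pet/atp/
ndh gene families, trn/rrn/rpo/rps/rpl, ycf/orf).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "GeneCatalogueEntry",
    "CATALOGUE",
    "SUBCATEGORY_COUNTS",
    "classify_gene",
    "normalize_gene_name",
    "is_catalogue_gene",
]


@dataclass(frozen=True)
class GeneCatalogueEntry:
    """One gene of the reference catalogue."""

    name: str
    category: str      # "I", "II" or "III"
    subcategory: str


# subcategory labels
PSA = "photosystem I"
PSB = "photosystem II"
PET = "cytochrome b6f"
ATP = "ATP synthase"
RBC = "RuBisCo"
NDH = "NAD(P)H dehydrogenase"
TRN = "transfer RNA"
RRN = "ribosomal RNA"
RPO = "RNA polymerase"
RPS = "ribosomal subunit"
YCF = "ycf"
ORF = "open reading frame"
POT = "potential protein-coding"

_RAW: list[tuple[str, str, str]] = []

# Category I — photosynthetic apparatus (46 genes)
_RAW += [(g, "I", PSA) for g in ["psaA", "psaB", "psaC", "psaI", "psaJ", "psaM"]]
_RAW += [(g, "I", PSB) for g in [
    "psbA", "psbB", "psbC", "psbD", "psbE", "psbF", "psbH", "psbI",
    "psbJ", "psbK", "psbL", "psbM", "psbN", "psbT", "psbZ"]]
_RAW += [(g, "I", PET) for g in ["petA", "petB", "petD", "petG", "petL", "petM", "petN"]]
_RAW += [(g, "I", ATP) for g in ["atpA", "atpB", "atpE", "atpF", "atpH", "atpI"]]
_RAW += [("rbcL", "I", RBC)]
_RAW += [(g, "I", NDH) for g in [
    "ndhA", "ndhB", "ndhC", "ndhD", "ndhE", "ndhF", "ndhG", "ndhH",
    "ndhI", "ndhJ", "ndhK"]]

# Category II — RNA genes and genetic apparatus (60 genes)
_RAW += [(g, "II", TRN) for g in [
    "trnA-UGC", "trnC-GCA", "trnD-GUC", "trnE-UUC", "trnF-GAA", "trnfM-CAU",
    "trnG-GCC", "trnG-UCC", "trnH-GUG", "trnI-CAU", "trnI-GAU", "trnK-UUU",
    "trnL-CAA", "trnL-UAA", "trnL-UAG", "trnM-CAU", "trnN-GUU", "trnP-UGG",
    "trnQ-UUG", "trnR-ACG", "trnR-CCG", "trnR-UCU", "trnS-GCU", "trnS-GGA",
    "trnS-UGA", "trnT-GGU", "trnT-UGU", "trnV-GAC", "trnV-UAC", "trnW-CCA",
    "trnY-GUA"]]
_RAW += [(g, "II", RRN) for g in ["rrn4.5", "rrn5", "rrn16", "rrn23"]]
_RAW += [(g, "II", RPO) for g in ["rpoA", "rpoB", "rpoC1", "rpoC2"]]
_RAW += [(g, "II", RPS) for g in [
    "rps2", "rps3", "rps4", "rps7", "rps8", "rps11", "rps12", "rps14",
    "rps15", "rps16", "rps18", "rps19",
    "rpl2", "rpl14", "rpl16", "rpl20", "rpl22", "rpl23", "rpl32", "rpl33",
    "rpl36"]]

# Category III — potential genes (20 genes)
_RAW += [(g, "III", YCF) for g in [
    "ycf1", "ycf2", "ycf3", "ycf4", "ycf12", "ycf15", "ycf66", "ycf68"]]
_RAW += [(g, "III", ORF) for g in ["orf42", "orf56"]]
_RAW += [(g, "III", POT) for g in [
    "matK", "clpP", "accD", "ccsA", "cemA", "infA", "chlB", "chlL",
    "chlN", "cysA"]]

CATALOGUE: dict[str, GeneCatalogueEntry] = {
    name: GeneCatalogueEntry(name, cat, sub) for name, cat, sub in _RAW
}
assert len(CATALOGUE) == 126

#: number of genes per (category, subcategory)
SUBCATEGORY_COUNTS: dict[tuple[str, str], int] = {}
for _e in CATALOGUE.values():
    key = (_e.category, _e.subcategory)
    SUBCATEGORY_COUNTS[key] = SUBCATEGORY_COUNTS.get(key, 0) + 1

_LOOKUP = {name.lower(): name for name in CATALOGUE}

_ORF_RE = re.compile(r"^orf\d+[a-z]?$")
_YCF_RE = re.compile(r"^ycf\d+[a-z]?$")


def normalize_gene_name(name: str) -> str:
    """Return the canonical spelling of a gene symbol.

    Case-insensitive lookup against the catalogue; underscores and spaces in
    tRNA anticodon suffixes are normalized to hyphens (``trnH_GUG`` ->
    ``trnH-GUG``).  Names not in the catalogue (orfNNN, novel ycfs) are
    returned lower-cased.
    """
    key = name.strip().replace("_", "-").replace(" ", "-").lower()
    if key in _LOOKUP:
        return _LOOKUP[key]
    return key


def is_catalogue_gene(name: str) -> bool:
    return normalize_gene_name(name) in CATALOGUE


def classify_gene(name: str) -> GeneCatalogueEntry:
    """Map a gene symbol to its catalogue entry.

    Unknown symbols matching the ``orfNNN`` / ``ycfNN`` patterns are placed in
    category III ("open reading frame" / "ycf" subcategories); any other
    unknown symbol raises ``KeyError``.
    """
    canonical = normalize_gene_name(name)
    if canonical in CATALOGUE:
        return CATALOGUE[canonical]
    if _ORF_RE.match(canonical):
        return GeneCatalogueEntry(canonical, "III", ORF)
    if _YCF_RE.match(canonical):
        return GeneCatalogueEntry(canonical, "III", YCF)
    raise KeyError(f"unrecognized gene symbol: {name!r}")
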