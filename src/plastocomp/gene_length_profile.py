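"""Species x gene length matrix, standardized contrasts (SC), PCA and
gene contributions to genome-size variation.

The standardized contrast of a gene length is its column z-score: the
difference between a species' gene length and the across-species mean of that
gene, divided by the across-species standard deviation.  Genes lost in a
species are missing cells and are propagated as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .catalogue import is_catalogue_gene
from .genome_model import AnnotatedGenome

__all__ = [
    "build_gene_length_matrix",
    "standardized_contrasts",
    "sc_cv",
    "PCAResult",
    "pca_decomposition",
    "gene_contribution",
]


def build_gene_length_matrix(
    genomes: Sequence[AnnotatedGenome], catalogue_only: bool = True
) -> pd.DataFrame:
    """Species x gene matrix of gene lengths in bp.

    A gene's length is the summed segment length of one copy; when a gene is
    IR-duplicated the longest copy is recorded.  Columns are restricted to
    catalogue genes unless ``catalogue_only`` is false; absent genes are NaN.
    """
    rows: dict[str, dict[str, float]] = {}
    for g in genomes:
        row: dict[str, float] = {}
        for feat in g.genes:
            if catalogue_only and not is_catalogue_gene(feat.name):
                continue
            row[feat.name] = max(row.get(feat.name, 0), feat.length)
        rows[g.id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "id"
    return df.sort_index(axis=1)


def standardized_contrasts(m: pd.DataFrame, min_present: int = 3) -> pd.DataFrame:
    """Column-wise z-scores of the gene-length matrix.

    ``SC[i, j] = (len[i, j] - mean_j) / sd_j`` with the mean and sample sd
    taken over the species in which gene j is present; missing cells stay
    missing.  Columns with fewer than ``min_present`` present cells or zero
    variance are dropped with a warning.
    """
    keep: dict[str, pd.Series] = {}
    dropped: list[str] = []
    for col in m.columns:
        v = m[col].dropna()
        if len(v) < min_present or v.std(ddof=1) == 0:
            dropped.append(col)
            continue
        keep[col] = (m[col] - v.mean()) / v.std(ddof=1)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} degenerate gene column(s): "
            + ", ".join(dropped[:8])
        )
    if not keep:
        raise ValueError("all gene columns are degenerate")
    return pd.DataFrame(keep, index=m.index)


def sc_cv(raw: pd.DataFrame) -> pd.DataFrame:
    """Per-gene coefficient of variation of gene length.

    Returns a frame indexed by gene with columns ``cv`` (sd/mean over present
    cells) and ``n_present``.
    """
    out = {}
    for col in raw.columns:
        v = raw[col].dropna()
        if len(v) < 2 or v.mean() == 0:
            cv = float("nan")
        else:
            cv = float(v.std(ddof=1) / v.mean())
        out[col] = {"cv": cv, "n_present": int(len(v))}
    df = pd.DataFrame.from_dict(out, orient="index")
    df.index.name = "gene"
    return df


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    loadings: pd.DataFrame       # gene x component
    scores: pd.DataFrame         # species x component
    variance_fractions: np.ndarray


def pca_decomposition(
    sc: pd.DataFrame, impute: str = "mean", max_missing: float = 0.5
) -> PCAResult:
    """Principal component analysis of the SC matrix.

    Columns with more than ``max_missing`` missing cells are dropped with a
    warning; remaining missing cells are imputed by the column mean (which is
    ~0 after standardization).  Components come from the eigendecomposition
    of the sample covariance matrix, ordered by decreasing eigenvalue, each
    oriented so its largest-magnitude loading is positive.
    """
    frac_missing = sc.isna().mean()
    bad = list(frac_missing[frac_missing > max_missing].index)
    if bad:
        warnings.warn(f"dropped {len(bad)} mostly-missing gene column(s)")
        sc = sc.drop(columns=bad)
    if sc.shape[0] < 3 or sc.shape[1] < 2:
        raise ValueError("PCA needs >= 3 species and >= 2 genes")
    if impute == "mean":
        filled = sc.fillna(sc.mean())
    elif impute == "zero":
        filled = sc.fillna(0.0)
    else:
        raise ValueError(f"unknown impute strategy {impute!r}")

    X = filled.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    cov = np.cov(Xc, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-magnitude loading positive
    for c in range(eigvec.shape[1]):
        col = eigvec[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            eigvec[:, c] = -col
    comp = [f"PC{i + 1}" for i in range(eigvec.shape[1])]
    loadings = pd.DataFrame(eigvec, index=filled.columns, columns=comp)
    scores = pd.DataFrame(Xc @ eigvec, index=filled.index, columns=comp)
    total = eigval.sum()
    fractions = eigval / total if total > 0 else eigval
    return PCAResult(eigenvalues=eigval, loadings=loadings, scores=scores,
                     variance_fractions=fractions)


def gene_contribution(
    sc: pd.DataFrame,
    genome_size,
    genes: Sequence[str],
    max_condition: float = 1e8,
) -> float:
    """Fraction of genome-size variation attributable to selected genes.

    The coefficient of determination (R^2) of the ordinary least-squares
    regression of genome size on the selected genes' SC columns, over
    complete cases.  Raises on collinear predictors (design-matrix condition
    number above ``max_condition``).
    """
    missing = [g for g in genes if g not in sc.columns]
    if missing:
        raise KeyError(f"genes not in SC matrix: {missing}")
    y = pd.Series(genome_size)
    df = sc[list(genes)].copy()
    df["_y"] = y.reindex(df.index)
    df = df.dropna()
    k = len(genes)
    if len(df) < k + 2:
        raise ValueError(f"need >= {k + 2} complete cases for {k} genes")
    X = np.column_stack([np.ones(len(df)), df[list(genes)].to_numpy(float)])
    cond = np.linalg.cond(X)
    if cond > max_condition:
        raise ValueError(
            f"selected SC columns are collinear (condition number {cond:.3g})"
        )
    yv = df["_y"].to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("genome size has zero variance")
    return float(1 - np.sum(resid ** 2) / ss_tot)
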