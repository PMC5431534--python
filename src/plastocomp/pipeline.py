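"""End-to-end orchestration: genomes -> characteristics -> association
statistics -> gene-length profile -> Ka/Ks, with a reproducible manifest.

A run is described by a :class:`RunConfig` (loadable from YAML); every
stochastic stage draws from the single run seed.  Stage failures are recorded
in the manifest and do not abort the remaining stages.
"""

from __future__ import annotations

import glob
import hashlib
import json
import math
import os
import platform
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .comparative_stats import (
    blomberg_K,
    mc_phylo_anova,
    pic_contrasts,
    sma_fit,
)
from .gene_length_profile import (
    build_gene_length_matrix,
    gene_contribution,
    pca_decomposition,
    sc_cv,
    standardized_contrasts,
)
from .genome_model import (
    detect_inverted_repeat,
    features_table,
    standardize_annotations,
)
from .io import read_fasta_gff3, read_genbank, read_tree
from .selection_kaks import mean_omega, terminal_branch_kaks

__all__ = ["RunConfig", "run_pipeline", "DEFAULT_LOG10_COLUMNS"]

#: length-like characteristics are log10-transformed before association
#: statistics; GCC (a fraction) stays on its natural scale
DEFAULT_LOG10_COLUMNS = ("TL", "IRL", "LSCL", "SSCL", "GRL", "IGRL", "GN")

CHARACTERISTICS = ("IRL", "LSCL", "SSCL", "GRL", "IGRL", "GCC", "GN")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str
    genomes: Optional[str] = None          # dir of .gb/.gbk or fasta+gff pairs
    genome_format: str = "genbank"         # "genbank" | "fasta-gff3"
    tree: Optional[str] = None             # Newick path
    alignments: Optional[str] = None       # dir of per-gene FASTA alignments
    response: str = "TL"
    n_sim: int = 1000
    seed: Optional[int] = None
    log10_columns: tuple = DEFAULT_LOG10_COLUMNS
    contribution_genes: tuple = ("atpA", "accD", "ycf1")
    ir_min_len: int = 1000
    ir_min_identity: float = 0.90
    run_stats: bool = True
    run_profile: bool = True
    run_kaks: bool = True

    def __post_init__(self) -> None:
        if self.run_stats and self.n_sim < 100:
            raise ValueError("n_sim must be >= 100 for the Monte-Carlo ANOVA")
        if self.run_stats and self.seed is None:
            raise ValueError("a seed is mandatory for stochastic stages")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_genomes(config: RunConfig) -> list:
    if config.genome_format == "genbank":
        paths = sorted(
            glob.glob(os.path.join(config.genomes, "*.gb"))
            + glob.glob(os.path.join(config.genomes, "*.gbk"))
        )
        return [read_genbank(p) for p in paths]
    if config.genome_format == "fasta-gff3":
        fastas = sorted(glob.glob(os.path.join(config.genomes, "*.fasta")))
        out = []
        for f in fastas:
            stem = os.path.splitext(f)[0]
            out.append(read_fasta_gff3(f, stem + ".gff3"))
        return out
    raise ValueError(f"unknown genome format {config.genome_format!r}")


def _transform(df: pd.DataFrame, log10_columns) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if col in log10_columns:
            with np.errstate(divide="ignore"):
                out[col] = np.log10(out[col].where(out[col] > 0))
    return out


def run_pipeline(config: RunConfig, genomes=None, tree=None) -> dict:
    """Execute the configured stages and write the report bundle.

    ``genomes`` (list of AnnotatedGenome) and ``tree`` (dendropy Tree) may be
    passed directly instead of paths.  Returns the manifest dictionary; all
    tables are written under ``config.out_dir``.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "plastocomp_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": asdict(config),
        "config_digest": config.digest(),
        "stages": {},
    }

    def stage(name):
        def wrap(fn):
            try:
                result = fn()
                manifest["stages"][name] = {"status": "ok", **(result or {})}
            except Exception as err:   # stage isolation is deliberate
                manifest["stages"][name] = {"status": "failed",
                                            "error": f"{type(err).__name__}: {err}"}
            return None
        return wrap

    # --- genomes and characteristics ------------------------------------
    if genomes is None and config.genomes:
        genomes = _load_genomes(config)
    if genomes is None:
        raise ValueError("no genomes given (config.genomes or genomes=)")
    if tree is None and config.tree:
        tree = read_tree(config.tree)

    genomes, issues = standardize_annotations(genomes, with_report=True)
    manifest["standardization_issues"] = [asdict(i) for i in issues]

    n_no_ir = 0
    for g in genomes:
        if g.partition is None:
            g.partition = detect_inverted_repeat(
                g, config.ir_min_len, config.ir_min_identity
            )
            if g.partition is None:
                n_no_ir += 1
    feats = features_table(genomes)
    feats.to_csv(os.path.join(config.out_dir, "features.csv"))
    manifest["stages"]["features"] = {
        "status": "ok", "n_genomes": len(genomes), "n_without_ir": n_no_ir,
    }

    # --- association statistics -----------------------------------------
    if config.run_stats and tree is not None:
        @stage("stats")
        def _():
            tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
            missing = sorted(set(feats.index) - tips)
            if missing:
                raise ValueError(f"genomes absent from tree: {missing[:5]}")
            tdf = _transform(feats, config.log10_columns)
            resp = tdf[config.response]
            rows = []
            rng_seed = int(config.seed)
            for i, char in enumerate(CHARACTERISTICS):
                if char == config.response:
                    continue
                pair = pd.concat([resp, tdf[char]], axis=1).dropna()
                if len(pair) < 4:
                    continue
                x, y = pair[config.response], pair[char]
                cross = sma_fit(x, y)
                sub = tree.clone(depth=1)
                keep = set(pair.index)
                sub.retain_taxa_with_labels(list(keep))
                cx = pic_contrasts(sub, x.to_dict()).contrasts
                cy = pic_contrasts(sub, y.to_dict()).contrasts
                phylo = sma_fit(cx, cy, through_origin=True)
                k = blomberg_K(sub, y.to_dict()).K
                mc = mc_phylo_anova(sub, y.to_dict(), x.to_dict(),
                                    n_sim=config.n_sim,
                                    seed=rng_seed + i)
                rows.append({
                    "characteristic": char, "n": len(pair),
                    "cross_r2": cross.r2, "cross_slope": cross.slope,
                    "cross_ci_lo": cross.ci_lo, "cross_ci_hi": cross.ci_hi,
                    "pic_r2": phylo.r2, "pic_slope": phylo.slope,
                    "pic_ci_lo": phylo.ci_lo, "pic_ci_hi": phylo.ci_hi,
                    "K": k, "F_observed": mc.F_observed, "C": mc.C,
                    "p": mc.p,
                })
            table = pd.DataFrame(rows)
            table.to_csv(os.path.join(config.out_dir, "association_stats.csv"),
                         index=False)
            return {"n_characteristics": len(rows)}
    elif config.run_stats:
        manifest["stages"]["stats"] = {
            "status": "skipped", "reason": "no tree given",
        }

    # --- gene-length profile --------------------------------------------
    if config.run_profile:
        @stage("profile")
        def _():
            glm = build_gene_length_matrix(genomes)
            sc = standardized_contrasts(glm)
            sc.to_csv(os.path.join(config.out_dir, "sc_matrix.csv"))
            cv = sc_cv(glm)
            cv.to_csv(os.path.join(config.out_dir, "gene_cv.csv"))
            pca = pca_decomposition(sc)
            pca.loadings.to_csv(os.path.join(config.out_dir, "pca_loadings.csv"))
            pd.DataFrame({
                "eigenvalue": pca.eigenvalues,
                "variance_fraction": pca.variance_fractions,
            }).to_csv(os.path.join(config.out_dir, "pca_eigenvalues.csv"),
                      index=False)
            result: dict = {"n_genes": sc.shape[1]}
            sel = [g for g in config.contribution_genes if g in sc.columns]
            if len(sel) == len(config.contribution_genes):
                r2 = gene_contribution(sc, feats["TL"], sel)
                result["contribution_genes"] = ",".join(sel)
                result["contribution_r2"] = r2
            return result

    # --- Ka/Ks ------------------------------------------------------------
    if config.run_kaks and config.alignments and tree is not None:
        @stage("kaks")
        def _():
            from Bio import SeqIO

            frames = []
            for path in sorted(glob.glob(os.path.join(config.alignments, "*.fasta"))):
                gene = os.path.splitext(os.path.basename(path))[0]
                aln = {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
                sub = tree.clone(depth=1)
                sub.retain_taxa_with_labels(list(aln))
                frames.append(terminal_branch_kaks(sub, aln, gene=gene))
            if not frames:
                raise ValueError("no alignments found")
            kaks = pd.concat(frames, ignore_index=True)
            kaks.to_csv(os.path.join(config.out_dir, "kaks.csv"), index=False)
            summary = (
                kaks.groupby("gene")
                .apply(mean_omega, include_groups=False)
                .rename("mean_omega")
            )
            summary.to_csv(os.path.join(config.out_dir, "kaks_summary.csv"))
            return {"n_genes": kaks["gene"].nunique()}

    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
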