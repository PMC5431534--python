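# Methods

This note documents the models and procedures implemented in `plastocomp`,
the defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical conventions.

## Sequence characteristics

All coordinates are 0-based half-open in memory; GenBank and GFF3 (both
1-based inclusive) are converted at I/O time only. The plastome is treated as
circular; a FASTA/GenBank record is an arbitrary linearization.

The eight characteristics of an annotated genome are:

| symbol | definition | units |
|---|---|---|
| TL | sequence length | bp |
| IRL | length of **one** inverted-repeat copy (0 if absent) | bp |
| LSCL | large single-copy length (missing if no IR) | bp |
| SSCL | small single-copy length (missing if no IR) | bp |
| GRL | length of the union of all gene segments | bp |
| IGRL | TL − GRL | bp |
| GCC | (G+C)/(A+C+G+T); N bases excluded | fraction |
| GN | number of standardized gene features | count |

Conventions that the data themselves do not force, fixed here:

* **IRL counts one copy**, so TL = LSCL + SSCL + 2·IRL holds exactly whenever
  a partition is present (this identity is asserted, not assumed).
* **GRL is a union**: bases covered by overlapping or trans-spliced segments
  count once; both IR copies of a duplicated gene contribute.
* **GN counts features per occurrence**, so IR-duplicated genes count twice.
  Counting unique symbols instead is possible by deduplicating
  `AnnotatedGenome.genes` by name before `compute_features`; per-occurrence
  counting is the default because observed gene numbers in grasses exceed the
  unique-symbol count of the catalogue.
* Genomes without an IR record LSCL/SSCL as missing (not 0) and are excluded
  pairwise from statistics involving those columns.

### Annotation standardization

Applied before any counting, in order: (1) symbols are normalized to the
bundled catalogue's spelling (case, hyphenation of tRNA anticodons);
(2) successive same-name, same-strand records separated by at most
`max_merge_gap` (default 5 000 bp) are merged into one multi-segment feature
— this joins multi-exon annotations (clpP, rpl2) without merging IR
duplicates, which lie at least an SSC apart in real plastomes; (3) an `orf*`
annotation overlapping a catalogue gene is dropped in favour of the gene;
same-strand overlap of two catalogue genes beyond `overlap_tolerance`
(default 30 bp) is flagged in a report and never silently merged; (4) genes
annotated in exactly one genome of a multi-genome input set are removed (the
rule is skipped for single-genome inputs, where it would delete everything).

### The 126-gene catalogue

The bundled catalogue lists 126 genes in three categories and 13
subcategories (photosynthetic apparatus: 6 psa, 15 psb, 7 pet, 6 atp, rbcL,
11 ndh; RNA/genetic apparatus: 31 trn, 4 rrn, 4 rpo, 21 rps/rpl; potential:
8 ycf, 2 orf, 10 others such as matK, clpP, accD). Membership follows
standard plastid nomenclature; unknown symbols matching `orfNNN`/`ycfNN`
classify as category III, anything else is an error.

### Inverted-repeat detection

Seed-and-extend between the sequence and its reverse complement: exact
24-mers anchor candidate matches, extension bridges isolated mismatches while
the running identity stays at or above `min_identity` (default 0.90), and
candidate pairs shorter than `min_len` (default 1 000 bp) or with overlapping
copies are discarded. The longest pair wins, ties broken by lowest start
coordinate. The longer gap between the copies is labelled LSC; the copy
immediately downstream of the LSC is IRb. Intervals may wrap the origin
(end > TL); an IR copy that itself spans the sequence origin is not detected
— re-linearize first. Real analyses normally take IR boundaries from the
deposited annotation; the detector serves synthetic and unannotated inputs.

## Association statistics

Length-like characteristics (TL, IRL, LSCL, SSCL, GRL, IGRL, GN) are
log10-transformed by default before regression — size relationships in these
data are linear on a log scale — while GCC, already a fraction, is left
untransformed. A raw-scale flag exists throughout.

* **SMA (model II) regression.** slope = sign(r)·sd(y)/sd(x), r² is the
  squared Pearson correlation, and the 95% CI uses the pivot
  slope·(√(B+1) ± √B), B = F(0.95; 1, df)(1−r²)/df, df = n−2. The
  through-origin variant (used for contrast pairs, which have no defined
  origin offset) replaces central by uncentered moments and uses df = n−1.
* **Common slope across groups.** Under a shared slope b, each group's SMA
  residual scores (y − bx) are uncorrelated with its axis scores (y + bx);
  the common slope minimizes −Σ(nᵢ−2.5)·ln(1−rᵢ²(b)) and the minimized sum is
  referred to χ² with g−1 degrees of freedom. Simulation (seeded, 300
  replicates) puts the size of the test at ≈ 5% at α = 0.05.
* **Independent contrasts.** Felsenstein pruning: contrast
  (xL−xR)/√(vL+vR), node value the branch-length-weighted average, parent
  branch lengthened by vL·vR/(vL+vR); n−1 contrasts for n tips. Polytomies
  are resolved with zero-length internal branches first; a zero-length cherry
  is jittered by 1e-8 of tree depth (configurable) rather than erroring.
  The "phylogenetic" SMA column is SMA fitted to contrast pairs through the
  origin — the standard contrasts-regression convention.
* **K statistic.** With V the BM covariance of the tree (Vᵢⱼ = shared
  root-to-MRCA path length) and â the GLS mean, K is the ratio of the
  observed (x−â)ᵀ(x−â) / (x−â)ᵀV⁻¹(x−â) to its BM expectation
  (tr V − n/𝟙ᵀV⁻¹𝟙)/(n−1). K = 1 exactly on an equal-branch star tree for any
  data (V ∝ I), and averages ≈ 1 for traits simulated under BM; K < 1 means
  trait similarity is decoupled from relatedness. One K is computed per trait
  column, as the statistic is a property of a single trait.
* **Monte-Carlo phylogenetic ANOVA.** The observed cross-species regression
  F of y on x is compared with F statistics from `n_sim` replicate datasets
  in which *both* traits are re-simulated independently under BM on the study
  tree (association removed, phylogeny kept; a flag re-simulates y only). BM
  rates are estimated from the observed traits by the mean squared
  standardized contrast — though, because F is scale-invariant, the null
  distribution depends only on the tree, which is why the test is accurately
  sized. C is the ⌈0.95·n_sim⌉-th order statistic of the simulated F values;
  p is the plain exceedance fraction #{F_sim ≥ F_obs}/n_sim (a
  (k+1)/(n+1) flag exists). n_sim < 100 is rejected.

Missing trait values are handled by pairwise-complete deletion, with the tree
pruned to the retained tips for each analysis. All stochastic routines take
one integer seed and are bit-reproducible; the pipeline derives per-stage
seeds deterministically from the run seed.

## Gene-length profile

The species × gene matrix records the single-copy length (the longest copy
for IR-duplicated genes). SC is the column z-score over present cells —
the per-gene reading of "standardized contrast", the only one under which a
species at the gene's average sits exactly at SC = 0. Columns with < 3
present cells or zero variance are dropped with a warning. PCA
eigendecomposes the sample covariance of the SC matrix after mean-imputation
of missing cells (≈ 0 post-standardization; columns over 50% missing are
dropped), with a deterministic sign convention (largest-magnitude loading
positive). The "contribution" of a gene set to genome size is the R² of the
OLS regression of genome size on the selected SC columns — an explicit
operationalization chosen over reading loadings off the PCA, because it is a
defined variance fraction; collinear selections are rejected with the
condition number reported. It is monotone nondecreasing in the gene set.

## Terminal-branch Ka/Ks

The quantity of interest is the per-gene selection pressure on the most
recent divergences: ω between each modern sequence and its most recent
reconstructed ancestor, averaged over tips. Ancestors are reconstructed by
nucleotide Fitch parsimony (intersection-else-union sets bottom-up; top-down
assignment keeps the parent state when compatible, otherwise the
alphabetically first state — a deterministic tie-break). Ka and Ks come from
the Nei–Gojobori (1986) counting estimator: per-codon synonymous site
fractions (changes to stops count as nonsynonymous, so S + N = 3L exactly),
differences apportioned by equal-weight averaging over all stop-free
orderings of the mutational steps, Jukes–Cantor correction
d = −¾·ln(1−4p/3). A proportion ≥ 3/4 raises a saturation error carrying the
raw proportions — note a single codon pair with one synonymous difference
saturates by construction (p = 1/S ≥ 1), so per-codon examples must be read
as counts (Na, Ns), not as corrected rates. Codons with gaps or ambiguity
codes, and codon pairs whose every pathway is blocked by a stop, are excluded
pairwise. ω is undefined (reported missing) when Ka = Ks = 0, +∞ when
Ks = 0 < Ka; infinities are excluded from per-gene averages by default or
capped via a flag. Genetic code: NCBI table 11, configurable.

This counting estimator deliberately replaces a free-ratio maximum-likelihood
codon model: it estimates the same observable (per-branch ω) with orders of
magnitude less computation, at the cost of ignoring transition/transversion
and codon-frequency bias. Simulation shows the estimator recovers ω within a
few percent on average under the package's own codon generator (κ = 1) and
preserves ω rank order across genes (Spearman ≥ 0.9 in the test suite).

## Synthetic-data generators

* **Trees**: forward pure-birth (Yule) construction, rescaled to unit crown
  depth, tips `t1..tn`. Depth is measured from the first split (the root
  stem carries no length).
* **Correlated traits**: x ~ BM(σ²ₓ), y = βx + e with e an independent BM
  residual of rate σ²ᵣ, co-simulated branchwise, so both marginals are BM and
  the expected contrasts-regression slope is β. Defaults β = 1.1, σ²ₓ = 1,
  σ²ᵣ = 0.05: the residual is kept small relative to the signal because the
  SMA slope estimates √(β² + σ²ᵣ/σ²ₓ), i.e. SMA recovers β only in the
  strong-signal regime (with these defaults the inflation is ≈ 2%).
* **Plastomes**: LSC + IRb + SSC + IRa with IRa the exact reverse complement
  of IRb; genes placed without overlap at recorded coordinates, exponential
  spacers (mean 300 bp), IR genes annotated in both copies with flipped
  strand; per-species gene lengths jittered log-normally (RNA genes nearly
  invariant, category-III genes most variable) around typical plastid values;
  randomized specs cover LSC ≈ 86 kb, SSC ≈ 18 kb, IR ≈ 25 kb, GC ∈
  [0.34, 0.40], with a conserved 10-gene core present in every species.
  The generator breaks the one-base coincidence in which the two SSC
  endpoint bases are reverse complements, so the true IR boundary is also
  the maximal-repeat boundary and detection at identity 1.0 must recover it
  exactly. What it does **not** emulate: annotation errors, IR boundary
  shifts (ycf1 spanning the SSC/IRa junction), gene order rearrangements,
  pseudogenes, or sequence homology between species — so passing tests
  demonstrate bookkeeping correctness and statistical calibration, not
  robustness to dirty annotations.
* **Codon alignments**: stop-free root; per-branch Poisson(3L·t) point
  proposals with ts/tv weight κ; proposals creating stops rejected;
  nonsynonymous proposals accepted with min(1, ω), synonymous with
  min(1, 1/ω), so the realized nonsynonymous/synonymous rate ratio tracks ω
  for ω on either side of 1. Accepted events are logged per branch as ground
  truth. This acceptance–rejection scheme is a deliberate simplification of
  a full codon model; its role is recovery and rank testing of the counting
  estimator, not rate realism.

## Problem sizes used in the test suite

Calibration tests run at sizes chosen to make Monte-Carlo error small
relative to the asserted bands: K calibration uses 500 BM replicates on a
100-tip tree; the ANOVA type-I check uses 500 outer replicates × 200 null
simulations on a 30-tip tree (the C threshold at n_sim = 200 has exact
exceedance probability 11/201 ≈ 0.055, so the [0.03, 0.07] band is centred);
slope recovery uses 100 replicates of 200 tips; ω recovery averages 10
replicates of 16-tip trees at 1 000 codons with terminal branches of ≈ 0.06
proposals per site — long enough for stable counts, short enough that the
Jukes–Cantor correction stays accurate.

## Known limitations

* IR detection assumes both repeat copies lie inside the given
  linearization and reports at most one pair.
* Fitch reconstruction ignores branch lengths; on very long or very short
  internal branches a likelihood reconstruction would differ.
* The SMA common-slope test uses the large-sample χ² reference; very small
  groups (n < 10) will be anticonservative.
* No OU or rate-shift models of trait evolution; the Monte-Carlo null is
  strictly Brownian.
* The pipeline's gene-length and Ka/Ks stages assume standardized
  single-copy gene symbols; paralog families beyond the IR duplication are
  out of scope.
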