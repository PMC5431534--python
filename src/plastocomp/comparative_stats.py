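"""Cross-species and phylogenetically corrected association statistics.

Species trait values are not independent draws: close relatives inherit
similar values from common ancestors.  This module implements the statistics
used to relate plastome sequence characteristics to genome size both across
species and with the phylogeny taken into account:

* standardized major axis (SMA, model II) regression with the likelihood-ratio
  test of a common slope across groups;
* Felsenstein's phylogenetically independent contrasts (PIC);
* Brownian-motion (BM) trait simulation on a tree;
* a Blomberg-type K statistic of phylogenetic signal (K = 1 under pure BM);
* a Monte-Carlo phylogenetic ANOVA: the observed regression F statistic is
  compared with F statistics from traits re-simulated under BM on the study
  tree; C is the simulated 95th percentile and p the exceedance fraction;
* Welch group t-tests.

Trees are dendropy ``Tree`` objects; tip labels must match trait-table ids.
All stochastic routines take explicit integer seeds and are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SMAFit",
    "CommonSlopeResult",
    "ContrastSet",
    "KStatistic",
    "MCAnovaResult",
    "BMParams",
    "tip_labels",
    "vcv_matrix",
    "sma_fit",
    "sma_common_slope_test",
    "pic_contrasts",
    "pic_rate",
    "bm_simulate",
    "blomberg_K",
    "mc_phylo_anova",
    "group_ttest",
    "regression_F",
]


# ---------------------------------------------------------------------------
# tree utilities
# ---------------------------------------------------------------------------

def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Tip labels in the tree's leaf-iteration order."""
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def tree_depth(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip path length."""
    return max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())


def vcv_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance structure of a rooted tree.

    V[i, j] is the shared root-to-MRCA path length of tips i and j (the depth
    of their most recent common ancestor); V[i, i] is the tip's depth.
    Returns (labels, V) with labels in leaf-iteration order.
    """
    labels = tip_labels(tree)
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    V = np.zeros((n, n))

    depth: dict[int, float] = {}
    tipsets: dict[int, list[int]] = {}
    for node in tree.preorder_node_iter():
        bl = node.edge.length or 0.0
        depth[id(node)] = bl if node.parent_node is None else depth[id(node.parent_node)] + bl

    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = idx[node.taxon.label]
            tipsets[id(node)] = [i]
            V[i, i] = depth[id(node)]
            continue
        child_sets = [tipsets.pop(id(c)) for c in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                for i in child_sets[a]:
                    for j in child_sets[b]:
                        V[i, j] = V[j, i] = d
        tipsets[id(node)] = [i for cs in child_sets for i in cs]
    return labels, V


def _trait_vector(trait, labels: Sequence[str]) -> np.ndarray:
    """Align a mapping/Series of tip values to the given label order."""
    if isinstance(trait, pd.Series):
        trait = trait.to_dict()
    if isinstance(trait, Mapping):
        missing = [lab for lab in labels if lab not in trait]
        if missing:
            raise KeyError(f"trait values missing for tips: {missing[:5]}")
        return np.array([float(trait[lab]) for lab in labels])
    x = np.asarray(trait, dtype=float)
    if x.shape != (len(labels),):
        raise ValueError("trait vector length does not match number of tips")
    return x


# ---------------------------------------------------------------------------
# SMA regression
# ---------------------------------------------------------------------------

@dataclass
class SMAFit:
    """Standardized-major-axis (model II) line fit."""

    slope: float
    intercept: Optional[float]
    r2: float
    ci_lo: float
    ci_hi: float
    n: int


def sma_fit(x, y, through_origin: bool = False, alpha: float = 0.05) -> SMAFit:
    """Fit a standardized major axis to paired data.

    The SMA slope is ``sign(r) * sd(y) / sd(x)``; the through-origin variant
    (used for independent-contrast pairs) replaces centered by uncentered
    second moments and has no intercept.  The 95% CI uses the standard pivot
    ``slope * (sqrt(B + 1) +/- sqrt(B))`` with
    ``B = F(1 - alpha; 1, df) * (1 - r^2) / df`` and df = n - 2 (n - 1 through
    the origin).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("SMA requires at least 3 complete cases")

    if through_origin:
        sxx, syy, sxy = float(x @ x), float(y @ y), float(x @ y)
        df = n - 1
    else:
        xc, yc = x - x.mean(), y - y.mean()
        sxx, syy, sxy = float(xc @ xc), float(yc @ yc), float(xc @ yc)
        df = n - 2
    if sxx == 0 or syy == 0:
        raise ValueError("SMA undefined: zero variance in x or y")

    r2 = sxy * sxy / (sxx * syy)
    sign = 1.0 if sxy >= 0 else -1.0
    slope = sign * math.sqrt(syy / sxx)
    intercept = None if through_origin else float(y.mean() - slope * x.mean())

    B = stats.f.ppf(1 - alpha, 1, df) * (1 - r2) / df
    lo = slope * (math.sqrt(B + 1) - math.sqrt(B))
    hi = slope * (math.sqrt(B + 1) + math.sqrt(B))
    ci_lo, ci_hi = (lo, hi) if lo <= hi else (hi, lo)
    return SMAFit(slope=float(slope), intercept=intercept, r2=float(r2),
                  ci_lo=float(ci_lo), ci_hi=float(ci_hi), n=n)


@dataclass
class CommonSlopeResult:
    common_slope: float
    lr_stat: float
    df: int
    p: float
    group_slopes: list[float]


def _residual_axis_corr2(b: float, groups) -> list[float]:
    """Squared correlation between SMA residual and axis scores per group."""
    out = []
    for x, y in groups:
        r = y - b * x
        f = y + b * x
        rc, fc = r - r.mean(), f - f.mean()
        denom = float((rc @ rc) * (fc @ fc))
        out.append(0.0 if denom == 0 else float((rc @ fc) ** 2 / denom))
    return out


def sma_common_slope_test(
    groups: Sequence[tuple], max_iter: int = 200
) -> CommonSlopeResult:
    """Likelihood-ratio test of a common SMA slope across groups.

    Under a shared slope b, the correlation between each group's SMA residual
    scores (y - b x) and axis scores (y + b x) is zero.  The common slope
    minimizes the summed Bartlett-corrected log-likelihood term
    ``-(n_i - 2.5) * log(1 - r_i^2(b))``; the minimized sum is the LR
    statistic, compared with chi-square on (g - 1) degrees of freedom.
    A single group returns its SMA slope with LR = 0, p = 1.
    """
    cleaned = []
    slopes = []
    for gx, gy in groups:
        gx = np.asarray(gx, dtype=float)
        gy = np.asarray(gy, dtype=float)
        ok = np.isfinite(gx) & np.isfinite(gy)
        gx, gy = gx[ok], gy[ok]
        if gx.size < 3:
            raise ValueError("each group needs n >= 3")
        cleaned.append((gx, gy))
        slopes.append(sma_fit(gx, gy).slope)
    g = len(cleaned)
    if g == 1:
        return CommonSlopeResult(slopes[0], 0.0, 0, 1.0, slopes)

    weights = [x.size - 2.5 for x, _ in cleaned]

    def objective(b: float) -> float:
        r2s = _residual_axis_corr2(b, cleaned)
        return -sum(w * math.log(max(1 - r2, 1e-300))
                    for w, r2 in zip(weights, r2s))

    # bracket around the group slopes (sign taken from them)
    lo = min(slopes)
    hi = max(slopes)
    span = max(abs(hi - lo), 1e-6 * max(abs(lo), abs(hi), 1.0))
    res = optimize.minimize_scalar(
        objective,
        bounds=(lo - 2 * span, hi + 2 * span),
        method="bounded",
        options={"maxiter": max_iter, "xatol": 1e-12},
    )
    if not res.success:
        raise RuntimeError(f"common-slope estimation failed: {res.message}")
    b_hat = float(res.x)
    lr = float(res.fun)
    p = float(stats.chi2.sf(lr, g - 1))
    return CommonSlopeResult(b_hat, lr, g - 1, p, slopes)


# ---------------------------------------------------------------------------
# independent contrasts
# ---------------------------------------------------------------------------

@dataclass
class ContrastSet:
    """Standardized independent contrasts (one per internal node)."""

    contrasts: np.ndarray
    node_labels: list[str]

    def __len__(self) -> int:
        return self.contrasts.size


def _prepare_bifurcating(tree: dendropy.Tree) -> dendropy.Tree:
    work = tree.clone(depth=1)
    if any(len(nd.child_nodes()) > 2 for nd in work.preorder_internal_node_iter()):
        work.resolve_polytomies(limit=2, update_bipartitions=False)
        for nd in work.preorder_node_iter():
            if nd.edge.length is None:
                nd.edge.length = 0.0
    return work


def pic_contrasts(
    tree: dendropy.Tree,
    trait,
    zero_branch_eps: Optional[float] = None,
) -> ContrastSet:
    """Felsenstein's phylogenetically independent contrasts.

    Pruning pass: at each internal node with children (L, R) carrying working
    values (xL, xR) and branch lengths (vL, vR), the standardized contrast is
    ``(xL - xR) / sqrt(vL + vR)``; the node takes the weighted average value
    and its parent branch is lengthened by ``vL * vR / (vL + vR)``.
    Polytomies are resolved with zero-length internal branches first; a
    zero-length cherry (vL + vR = 0) is jittered by ``zero_branch_eps``
    (default 1e-8 of tree depth).  Returns n - 1 contrasts for n tips, in
    postorder.
    """
    labels = tip_labels(tree)
    x = _trait_vector(trait, labels)
    values = dict(zip(labels, x))
    work = _prepare_bifurcating(tree)

    if zero_branch_eps is None:
        zero_branch_eps = 1e-8 * max(tree_depth(work), 1.0)

    node_val: dict[int, float] = {}
    node_bl: dict[int, float] = {}
    contrasts: list[float] = []
    node_names: list[str] = []
    counter = 0
    for node in work.postorder_node_iter():
        if node.is_leaf():
            node_val[id(node)] = values[node.taxon.label]
            node_bl[id(node)] = node.edge.length or 0.0
            continue
        left, right = node.child_nodes()
        xl, xr = node_val.pop(id(left)), node_val.pop(id(right))
        vl, vr = node_bl.pop(id(left)), node_bl.pop(id(right))
        if vl + vr == 0:
            if zero_branch_eps <= 0:
                raise ValueError("zero-length cherry: contrast undefined")
            vl = vr = zero_branch_eps
        contrasts.append((xl - xr) / math.sqrt(vl + vr))
        counter += 1
        node_names.append(node.label or f"node{counter}")
        node_val[id(node)] = (xl / vl + xr / vr) / (1 / vl + 1 / vr)
        node_bl[id(node)] = (node.edge.length or 0.0) + vl * vr / (vl + vr)
    return ContrastSet(np.array(contrasts), node_names)


def pic_rate(tree: dendropy.Tree, trait) -> float:
    """BM rate estimate: mean squared standardized contrast."""
    c = pic_contrasts(tree, trait).contrasts
    return float(np.mean(c * c))


# ---------------------------------------------------------------------------
# Brownian-motion simulation
# ---------------------------------------------------------------------------

@dataclass
class BMParams:
    """Brownian-motion parameters: variance per unit branch length and root state."""

    sigma2: float = 1.0
    root_value: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be nonnegative")


def bm_simulate(
    tree: dendropy.Tree, params: BMParams, n_reps: int = 1
) -> pd.DataFrame:
    """Simulate trait evolution under Brownian motion on a tree.

    Each branch adds an independent Gaussian increment with variance
    ``sigma2 * branch_length``; replicates are vectorized, so the returned
    frame is (n_reps x n_tips) with tip labels as columns.  Tip covariance is
    ``sigma2 * V`` with V the shared-path-length matrix.
    """
    rng = np.random.default_rng(params.seed)
    vals: dict[int, np.ndarray] = {}
    tips: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            base = np.full(n_reps, float(params.root_value))
            bl = node.edge.length or 0.0
        else:
            base = vals[id(node.parent_node)]
            bl = node.edge.length or 0.0
        if params.sigma2 * bl > 0:
            v = base + rng.normal(0.0, math.sqrt(params.sigma2 * bl), n_reps)
        else:
            v = base.copy()
        if node.is_leaf():
            tips[node.taxon.label] = v
        else:
            vals[id(node)] = v
    labels = tip_labels(tree)
    return pd.DataFrame({lab: tips[lab] for lab in labels})


# ---------------------------------------------------------------------------
# phylogenetic signal K
# ---------------------------------------------------------------------------

@dataclass
class KStatistic:
    K: float
    mse0_over_mse_observed: float
    mse0_over_mse_expected: float


def blomberg_K(tree: dendropy.Tree, trait) -> KStatistic:
    """Blomberg-type K statistic of phylogenetic signal.

    With V the BM covariance structure of the tree and a-hat the GLS
    (phylogenetically corrected) mean, K is the ratio of the observed
    MSE0/MSE — ``(x-a)'(x-a) / (x-a)'V^-1(x-a)`` — to its Brownian-motion
    expectation ``(tr V - n / 1'V^-1 1) / (n - 1)``.  K equals 1 for data
    evolved under pure BM on the tree, and is below 1 when trait similarity
    is decoupled from relatedness.
    """
    labels, V = vcv_matrix(tree)
    x = _trait_vector(trait, labels)
    n = x.size
    if n < 3:
        raise ValueError("K requires at least 3 tips")
    one = np.ones(n)
    try:
        Vinv_one = np.linalg.solve(V, one)
        Vinv_x = np.linalg.solve(V, x)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "singular phylogenetic covariance matrix; consider jittering "
            "zero-length branches"
        ) from err
    denom_a = float(one @ Vinv_one)
    a_hat = float(one @ Vinv_x) / denom_a
    d = x - a_hat
    num = float(d @ d)
    den = float(d @ np.linalg.solve(V, d))
    if den == 0:
        raise ValueError("degenerate trait vector: zero phylogenetic MSE")
    observed = num / den
    expected = (float(np.trace(V)) - n / denom_a) / (n - 1)
    return KStatistic(K=observed / expected,
                      mse0_over_mse_observed=observed,
                      mse0_over_mse_expected=expected)


# ---------------------------------------------------------------------------
# Monte-Carlo phylogenetic ANOVA
# ---------------------------------------------------------------------------

@dataclass
class MCAnovaResult:
    F_observed: float
    F_simulated: np.ndarray
    C: float
    p: float
    n_sim: int
    seed: int


def regression_F(x: np.ndarray, y: np.ndarray) -> float:
    """ANOVA F statistic of the least-squares regression of y on x."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    xc, yc = x - x.mean(), y - y.mean()
    sxx, syy, sxy = float(xc @ xc), float(yc @ yc), float(xc @ yc)
    if sxx == 0 or syy == 0:
        raise ValueError("zero variance")
    r2 = sxy * sxy / (sxx * syy)
    if r2 >= 1.0:
        return math.inf
    return (n - 2) * r2 / (1 - r2)


def mc_phylo_anova(
    tree: dendropy.Tree,
    y,
    x,
    n_sim: int = 1000,
    seed: int = 0,
    simulate_x: bool = True,
    plus_one: bool = False,
) -> MCAnovaResult:
    """Monte-Carlo phylogenetic ANOVA of the y-on-x association.

    The observed cross-species regression F statistic is compared with F
    statistics computed from ``n_sim`` replicate datasets in which the traits
    are re-simulated under independent Brownian motion on the study tree (no
    association, phylogeny preserved).  BM rates are estimated from the
    observed traits by the mean squared standardized contrast.  The critical
    value C is the ceil(0.95 * n_sim)-th order statistic of the simulated F
    values; the association is declared non-random when F_observed > C.  p is
    the fraction of simulated F >= observed (``plus_one`` switches to the
    (k+1)/(n+1) convention).  With ``simulate_x=False`` only y is
    re-simulated and x held fixed.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    labels, V = vcv_matrix(tree)
    xv = _trait_vector(x, labels)
    yv = _trait_vector(y, labels)
    F_obs = regression_F(xv, yv)

    rate_x = pic_rate(tree, dict(zip(labels, xv)))
    rate_y = pic_rate(tree, dict(zip(labels, yv)))
    if rate_x == 0 or rate_y == 0:
        raise ValueError("zero BM rate estimate; traits carry no variation")

    L = np.linalg.cholesky(V + 1e-12 * np.eye(len(labels)))
    rng = np.random.default_rng(seed)
    n = len(labels)
    ys = math.sqrt(rate_y) * (L @ rng.standard_normal((n, n_sim)))
    if simulate_x:
        xs = math.sqrt(rate_x) * (L @ rng.standard_normal((n, n_sim)))
    else:
        xs = np.tile(xv[:, None], (1, n_sim))

    xc = xs - xs.mean(axis=0)
    yc = ys - ys.mean(axis=0)
    sxx = np.einsum("ij,ij->j", xc, xc)
    syy = np.einsum("ij,ij->j", yc, yc)
    sxy = np.einsum("ij,ij->j", xc, yc)
    r2 = sxy * sxy / (sxx * syy)
    with np.errstate(divide="ignore"):
        F_sim = (n - 2) * r2 / (1 - r2)

    order = np.sort(F_sim)
    C = float(order[math.ceil(0.95 * n_sim) - 1])
    k = int(np.sum(F_sim >= F_obs))
    p = (k + 1) / (n_sim + 1) if plus_one else k / n_sim
    return MCAnovaResult(F_observed=float(F_obs), F_simulated=F_sim, C=C,
                         p=float(p), n_sim=n_sim, seed=seed)


def group_ttest(a, b) -> tuple[float, float]:
    """Welch's unequal-variance t-test (two-sided)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
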