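"""Mixed-effects inference on pair-structured ISC data.

The central model treats each Fisher-z pairwise correlation as one
observation with *crossed* subject random effects:

    z_ij = x_ij' b + xi_i + xi_j + eps_ij,
    xi_k ~ N(0, tau^2) i.i.d. over subjects,  eps_ij ~ N(0, sigma^2),

so both members of a pair contribute their own random effect — the
correlation structure that makes naive tests on the n(n−1)/2 pair values
anti-conservative. The one-group model has a single intercept b0 (population
ISC); the two-group model parameterizes the fixed effects by pair type
(both-low, both-high, mixed), giving population ISC levels G11, G22, G12 and
their three pairwise contrasts.

Estimation is restricted maximum likelihood: the restricted likelihood is
profiled down to the variance ratio lambda = tau^2/sigma^2 using a single
eigendecomposition of the pair-incidence Gram matrix Z Z' (which depends only
on n and is cached), then optimized over log lambda by bracketed scalar
search. A vectorized variant evaluates many units at once on a shared lambda
grid, which is what the permutation-based cluster calibration uses.

Also here: the median split on trait scores, Benjamini–Hochberg FDR,
cluster-extent correction on 3-D grids (with permutation calibration), and
the median-ISC vs trait-rank Spearman post-hoc.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations as _iter_permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LMEFit",
    "CorrectedMap",
    "ClusterResult",
    "median_split",
    "fit_one_group_lme",
    "fit_two_group_lme",
    "fit_lme_map",
    "voxelwise_fdr",
    "find_clusters",
    "cluster_correct",
    "permutation_cluster_extent",
    "calibrate_extent",
    "isc_rank_posthoc",
    "spearman_test",
    "pair_type_design",
]

_TINY = 1e-300

TWO_GROUP_CONTRASTS = {
    "G11-G22": np.array([1.0, -1.0, 0.0]),
    "G11-G12": np.array([1.0, 0.0, -1.0]),
    "G22-G12": np.array([0.0, 1.0, -1.0]),
}


# ---------------------------------------------------------------------------
# pair bookkeeping
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _pair_structure(n: int):
    """Upper-triangle pair indices, incidence Gram eigendecomposition.

    Z is the n(n−1)/2 × n incidence matrix with a 1 in the two columns of
    each pair's subjects; V0 = I + lambda Z Z' is diagonalized once per n.
    Returned arrays must not be mutated.
    """
    iu, ju = np.triu_indices(n, 1)
    m = len(iu)
    Z = np.zeros((m, n))
    Z[np.arange(m), iu] = 1.0
    Z[np.arange(m), ju] = 1.0
    evals, evecs = np.linalg.eigh(Z @ Z.T)
    return iu, ju, evals, evecs


def _pair_vector(zmat: np.ndarray) -> np.ndarray:
    zmat = np.asarray(zmat, dtype=float)
    n = zmat.shape[0]
    iu, ju, _, _ = _pair_structure(n)
    return zmat[iu, ju]


def pair_type_design(labels: Sequence) -> tuple[np.ndarray, tuple]:
    """Cell-means design over pair types for a two-group sample.

    Returns (X, (g1, g2)) where X has columns [both-g1, both-g2, mixed] so
    the fixed effects are directly G11, G22, G12. Raises if either
    within-group cell is empty (a group of size 1 has no within pairs).
    """
    labels = np.asarray(labels)
    levels = sorted(np.unique(labels).tolist())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels}")
    if set(levels) == {"low", "high"}:
        levels = ["low", "high"]
    g1, g2 = levels
    n = len(labels)
    iu, ju, _, _ = _pair_structure(n)
    li, lj = labels[iu], labels[ju]
    X = np.column_stack(
        [
            (li == g1) & (lj == g1),
            (li == g2) & (lj == g2),
            li != lj,
        ]
    ).astype(float)
    for k, cell in enumerate((f"within-{g1} (G11)", f"within-{g2} (G22)")):
        if X[:, k].sum() == 0:
            raise ValueError(f"empty pair cell {cell}: group has fewer than 2 subjects")
    return X, (g1, g2)


# ---------------------------------------------------------------------------
# REML core
# ---------------------------------------------------------------------------

def _profiled_crit(loglam, Yt, Xt, evals, n_minus_p):
    """−2 restricted log-likelihood, profiled over b and sigma^2 (constants
    dropped), as a function of log lambda."""
    lam = math.exp(loglam)
    w = 1.0 / (1.0 + lam * evals)
    Xw = Xt * w[:, None]
    A = Xw.T @ Xt
    beta = np.linalg.solve(A, Xw.T @ Yt)
    r = Yt - Xt @ beta
    rss = float(np.dot(w * r, r))
    sigma2 = rss / n_minus_p
    _, logdet_a = np.linalg.slogdet(A)
    crit = float(np.log1p(lam * evals).sum()) + logdet_a \
        + n_minus_p * math.log(max(sigma2, _TINY))
    return crit, beta, A, sigma2


def _fit_crossed_reml(y: np.ndarray, X: np.ndarray, n_subjects: int,
                      loglam_bounds=(-20.0, 8.0), grid_size: int = 41):
    """Profiled-REML fit of the crossed random-effects model on pair data.

    Returns (beta, cov_beta, tau2, sigma2, converged). The scalar search is
    a coarse log-lambda grid (plus the tau^2 = 0 boundary) followed by
    bracketed refinement to ~1e-12 in log lambda.
    """
    N, p = X.shape
    if N <= p:
        raise ValueError("more fixed effects than pair observations")
    _, _, evals, evecs = _pair_structure(n_subjects)
    Yt = evecs.T @ y
    Xt = evecs.T @ X
    nmp = N - p

    # saturated/degenerate data: residuals vanish for every lambda
    beta0, res0, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss0 = float(((y - X @ beta0) ** 2).sum())
    scale = max(1.0, float(np.dot(y, y)) / N)
    if rss0 < 1e-12 * scale:
        A = Xt.T @ Xt
        return beta0, np.zeros((p, p)), 0.0, 0.0, True

    grid = np.linspace(loglam_bounds[0], loglam_bounds[1], grid_size)
    crits = np.array([_profiled_crit(g, Yt, Xt, evals, nmp)[0] for g in grid])
    k = int(np.argmin(crits))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid_size - 1)]
    res = optimize.minimize_scalar(
        lambda g: _profiled_crit(g, Yt, Xt, evals, nmp)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    loglam = float(res.x)
    crit, beta, A, sigma2 = _profiled_crit(loglam, Yt, Xt, evals, nmp)

    # tau^2 = 0 boundary (lambda -> 0): compare against the interior optimum
    crit0, beta_0, A_0, sigma2_0 = _profiled_crit(-800.0, Yt, Xt, evals, nmp)
    lam = math.exp(loglam)
    if crit0 <= crit or loglam <= loglam_bounds[0] + 1e-9:
        lam, beta, A, sigma2, crit = 0.0, beta_0, A_0, sigma2_0, crit0

    tau2 = lam * sigma2
    cov = sigma2 * np.linalg.inv(A)
    converged = bool(np.isfinite(crit))
    return beta, cov, tau2, sigma2, converged


@dataclass
class LMEFit:
    """Result of a crossed random-effects fit on one unit's pair data."""

    fixed_effects: dict
    se: dict
    tau2: float
    sigma2: float
    contrasts: pd.DataFrame
    n_subjects: int
    df: float
    converged: bool
    unit_id: str | None = None
    groups: tuple | None = None


def _wald_row(name, est, se, df):
    if se > 0:
        t = est / se
        p = 2.0 * stats.t.sf(abs(t), df)
    elif est == 0:
        t, p = 0.0, 1.0
    else:
        t, p = math.copysign(np.inf, est), 0.0
    return {"contrast": name, "estimate": est, "se": se, "t": t, "df": df, "p": p}


def _check_pairs(y):
    if not np.all(np.isfinite(y)):
        raise ValueError("pair z-values must be finite")


def fit_one_group_lme(zmat: np.ndarray, unit_id: str | None = None,
                      constrain_tau_zero: bool = False) -> LMEFit:
    """One-group population ISC: z_ij = b0 + xi_i + xi_j + eps_ij by REML.

    Returns the intercept estimate with a Wald t test of b0 = 0 at
    df = n_subjects − 1. With ``constrain_tau_zero`` the subject effects are
    dropped and the fit reduces to the ordinary mean of the pair values
    (GLS = OLS), a useful numerical cross-check.
    """
    zmat = np.asarray(zmat, dtype=float)
    n = zmat.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    y = _pair_vector(zmat)
    _check_pairs(y)
    X = np.ones((len(y), 1))
    if constrain_tau_zero:
        beta = np.array([y.mean()])
        sigma2 = float(((y - y.mean()) ** 2).sum() / (len(y) - 1))
        cov = np.array([[sigma2 / len(y)]])
        tau2, converged = 0.0, True
    else:
        beta, cov, tau2, sigma2, converged = _fit_crossed_reml(y, X, n)
    df = n - 1
    se = math.sqrt(max(cov[0, 0], 0.0))
    contrasts = pd.DataFrame([_wald_row("b0", float(beta[0]), se, df)])
    return LMEFit(
        fixed_effects={"b0": float(beta[0])},
        se={"b0": se},
        tau2=tau2,
        sigma2=sigma2,
        contrasts=contrasts,
        n_subjects=n,
        df=df,
        converged=converged,
        unit_id=unit_id,
    )


def fit_two_group_lme(zmat: np.ndarray, labels: Sequence,
                      unit_id: str | None = None) -> LMEFit:
    """Two-group population ISC with pair-type fixed effects G11, G22, G12.

    ``labels`` assigns each subject (in matrix order) to one of two groups;
    when the labels are {"low", "high"}, group 1 is "low". Returns all three
    pairwise contrasts with Wald t tests at df = n_subjects − 3.
    """
    zmat = np.asarray(zmat, dtype=float)
    n = zmat.shape[0]
    labels = np.asarray(labels)
    if len(labels) != n:
        raise ValueError("one group label per subject is required")
    y = _pair_vector(zmat)
    _check_pairs(y)
    X, (g1, g2) = pair_type_design(labels)
    beta, cov, tau2, sigma2, converged = _fit_crossed_reml(y, X, n)
    df = n - X.shape[1]
    names = ["G11", "G22", "G12"]
    fixed = dict(zip(names, map(float, beta)))
    se = {nm: math.sqrt(max(cov[k, k], 0.0)) for k, nm in enumerate(names)}
    rows = []
    for cname, c in TWO_GROUP_CONTRASTS.items():
        est = float(c @ beta)
        cse = math.sqrt(max(float(c @ cov @ c), 0.0))
        rows.append(_wald_row(cname, est, cse, df))
    return LMEFit(
        fixed_effects=fixed,
        se=se,
        tau2=tau2,
        sigma2=sigma2,
        contrasts=pd.DataFrame(rows),
        n_subjects=n,
        df=df,
        converged=converged,
        unit_id=unit_id,
        groups=(g1, g2),
    )


# ---------------------------------------------------------------------------
# vectorized multi-unit fit (lambda grid shared across units)
# ---------------------------------------------------------------------------

def _default_lam_grid() -> np.ndarray:
    return np.concatenate([[0.0], np.logspace(-4, 2, 41)])


def _fit_map_pairs(Y: np.ndarray, X: np.ndarray, n_subjects: int,
                   contrast_vectors: dict, df: float,
                   lam_grid: np.ndarray | None = None,
                   Yt: np.ndarray | None = None) -> dict:
    """Fit all columns of Y (pairs × units) at once on a lambda grid.

    Per-unit lambda is the grid argmin of the profiled REML criterion —
    coarser than the scalar-search fit but identical across permutations,
    which is what exchangeability-based calibration requires.
    """
    N, p = X.shape
    V = Y.shape[1]
    nmp = N - p
    _, _, evals, evecs = _pair_structure(n_subjects)
    if Yt is None:
        Yt = evecs.T @ Y
    Xt = evecs.T @ X
    if lam_grid is None:
        lam_grid = _default_lam_grid()
    L = len(lam_grid)

    crit = np.empty((L, V))
    betas = np.empty((L, p, V))
    sig2 = np.empty((L, V))
    Ainvs = np.empty((L, p, p))
    for l, lam in enumerate(lam_grid):
        w = 1.0 / (1.0 + lam * evals)
        Xw = Xt * w[:, None]
        A = Xw.T @ Xt
        B = np.linalg.solve(A, Xw.T @ Yt)
        R = Yt - Xt @ B
        rss = np.einsum("i,ij,ij->j", w, R, R)
        s2 = np.maximum(rss / nmp, _TINY)
        _, logdet_a = np.linalg.slogdet(A)
        crit[l] = float(np.log1p(lam * evals).sum()) + logdet_a + nmp * np.log(s2)
        betas[l] = B
        sig2[l] = s2
        Ainvs[l] = np.linalg.inv(A)

    best = np.argmin(crit, axis=0)
    beta_hat = betas[best, :, np.arange(V)].T          # (p, V)
    sigma2 = sig2[best, np.arange(V)]
    tau2 = lam_grid[best] * sigma2

    out = {
        "fixed_effects": beta_hat,
        "sigma2": sigma2,
        "tau2": tau2,
        "lambda": lam_grid[best],
        "tstats": {},
        "pvalues": {},
        "estimates": {},
    }
    for cname, c in contrast_vectors.items():
        est = c @ beta_hat
        cvar = np.einsum("i,lij,j->l", c, Ainvs, c)[best] * sigma2
        se = np.sqrt(np.maximum(cvar, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, est / se, np.where(est == 0, 0.0, np.inf))
        pv = 2.0 * stats.t.sf(np.abs(t), df)
        out["estimates"][cname] = est
        out["tstats"][cname] = t
        out["pvalues"][cname] = pv
    return out


def fit_lme_map(zstack: np.ndarray, labels: Sequence | None = None,
                lam_grid: np.ndarray | None = None) -> dict:
    """Vectorized crossed-random-effects fit over a stack of units.

    ``zstack`` has shape (n_units, n, n). With ``labels`` None a one-group
    intercept model is fit per unit (contrast ``b0``); otherwise the
    two-group pair-type model with the three G contrasts. Returns a dict of
    per-unit arrays (fixed effects, variance components, t and p per
    contrast).
    """
    zstack = np.asarray(zstack, dtype=float)
    if zstack.ndim == 2:
        zstack = zstack[None]
    n = zstack.shape[-1]
    iu, ju, _, _ = _pair_structure(n)
    Y = zstack[:, iu, ju].T  # (pairs, units)
    if labels is None:
        X = np.ones((Y.shape[0], 1))
        contrasts = {"b0": np.array([1.0])}
        df = n - 1
    else:
        X, _ = pair_type_design(labels)
        contrasts = TWO_GROUP_CONTRASTS
        df = n - 3
    return _fit_map_pairs(Y, X, n, contrasts, df, lam_grid=lam_grid)


# ---------------------------------------------------------------------------
# median split
# ---------------------------------------------------------------------------

def median_split(traits: pd.DataFrame) -> pd.DataFrame:
    """Dichotomize the sample at the sample median of the trait score.

    Subjects scoring ≤ the median go to the "low" group, the rest to
    "high" (ties at the threshold therefore fall low). Returns a table with
    columns ``subject_id, group, split_value``. Raises when all scores are
    identical — no split exists.
    """
    if len(traits) < 2:
        raise ValueError("need at least 2 subjects to split")
    scores = traits["trait_score"].to_numpy(dtype=float)
    if np.all(scores == scores[0]):
        raise ValueError("all trait scores identical: no median split possible")
    med = float(np.median(scores))
    group = np.where(scores <= med, "low", "high")
    if (group == "high").sum() == 0:
        # even n with ties straddling: put strictly-below-median low
        group = np.where(scores < med, "low", "high")
    return pd.DataFrame(
        {
            "subject_id": traits["subject_id"].to_numpy(),
            "group": group,
            "split_value": med,
        }
    )


# ---------------------------------------------------------------------------
# multiplicity control
# ---------------------------------------------------------------------------

@dataclass
class CorrectedMap:
    """Benjamini–Hochberg corrected p-value map."""

    pvalues: np.ndarray
    qvalues: np.ndarray
    reject: np.ndarray
    q: float

    @property
    def n_rejected(self) -> int:
        return int(self.reject.sum())


def voxelwise_fdr(pvalues: np.ndarray, q: float = 0.001) -> CorrectedMap:
    """Benjamini–Hochberg step-up FDR control across units."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        raise ValueError("empty p-value array")
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, qvals, _, _ = multipletests(pvalues.ravel(), alpha=q, method="fdr_bh")
    return CorrectedMap(
        pvalues=pvalues,
        qvalues=qvals.reshape(pvalues.shape),
        reject=reject.reshape(pvalues.shape),
        q=q,
    )


# ---------------------------------------------------------------------------
# cluster-extent correction
# ---------------------------------------------------------------------------

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class ClusterResult:
    """Cluster-extent thresholding of a 3-D p-map."""

    labels: np.ndarray
    sizes: np.ndarray          # size of cluster k at labels == k+1
    surviving: np.ndarray      # boolean map of voxels in clusters >= extent
    extent: int
    p_init: float

    @property
    def n_surviving(self) -> int:
        return int(np.sum(self.sizes >= self.extent))


def find_clusters(pmap: np.ndarray, p_init: float,
                  connectivity: int = 6) -> tuple[np.ndarray, np.ndarray]:
    """Connected components of sub-threshold voxels on a 3-D grid."""
    pmap = np.asarray(pmap, dtype=float)
    if pmap.ndim != 3:
        raise ValueError("p-map must be 3-D")
    if not 0 < p_init < 1:
        raise ValueError("p_init must be in (0, 1)")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be one of 6, 18, 26")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n = ndimage.label(pmap < p_init, structure=structure)
    sizes = np.array(
        ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1)),
        dtype=int,
    )
    return labels, sizes


def cluster_correct(pmap: np.ndarray, p_init: float = 0.002,
                    extent: int | None = None,
                    null_max_sizes: np.ndarray | None = None,
                    alpha: float = 0.05,
                    connectivity: int = 6) -> ClusterResult:
    """Family-wise error control by cluster extent.

    Either a fixed ``extent`` (e.g. the 50-voxel convention) or a
    permutation-null distribution of maximum cluster sizes
    (``null_max_sizes``, from which the extent achieving FWE ``alpha`` is
    calibrated) must be supplied.
    """
    if extent is None and null_max_sizes is None:
        raise ValueError("supply either a cluster extent or a permutation null")
    if extent is None:
        extent = calibrate_extent(null_max_sizes, alpha)
    labels, sizes = find_clusters(pmap, p_init, connectivity)
    surviving = np.isin(labels, 1 + np.nonzero(sizes >= extent)[0])
    return ClusterResult(labels=labels, sizes=sizes, surviving=surviving,
                         extent=int(extent), p_init=p_init)


def calibrate_extent(null_max_sizes: np.ndarray, alpha: float = 0.05) -> int:
    """Smallest extent k with P_null(max cluster size >= k) <= alpha."""
    null_max_sizes = np.asarray(null_max_sizes)
    if null_max_sizes.size == 0:
        raise ValueError("empty permutation null")
    for k in range(1, int(null_max_sizes.max()) + 2):
        if np.mean(null_max_sizes >= k) <= alpha:
            return k
    return int(null_max_sizes.max()) + 1


def permutation_cluster_extent(
    zstack: np.ndarray,
    grid_shape: tuple[int, int, int],
    labels: Sequence,
    contrast: str = "G11-G22",
    p_init: float = 0.002,
    alpha: float = 0.05,
    n_perm: int = 1000,
    connectivity: int = 6,
    seed: int = 0,
    lam_grid: np.ndarray | None = None,
) -> tuple[int, np.ndarray]:
    """Calibrate a cluster extent by group-label permutation.

    Subject group labels are shuffled; pair types (and so the fixed-effects
    design) are recomputed for each permutation; the same vectorized LME map
    fit produces the contrast p-map whose max sub-threshold cluster size
    forms the null. Returns (extent, null_max_sizes).
    """
    zstack = np.asarray(zstack, dtype=float)
    n = zstack.shape[-1]
    if int(np.prod(grid_shape)) != zstack.shape[0]:
        raise ValueError("grid_shape does not match the number of units")
    labels = np.asarray(labels)
    iu, ju, evals, evecs = _pair_structure(n)
    Y = zstack[:, iu, ju].T
    Yt = evecs.T @ Y  # shared across permutations
    if lam_grid is None:
        lam_grid = _default_lam_grid()
    rng = np.random.default_rng(seed)
    cvec = {contrast: TWO_GROUP_CONTRASTS[contrast]}
    max_sizes = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        perm = rng.permutation(labels)
        try:
            X, _ = pair_type_design(perm)
        except ValueError:
            max_sizes[b] = 0
            continue
        fit = _fit_map_pairs(Y, X, n, cvec, n - 3, lam_grid=lam_grid, Yt=Yt)
        pmap = fit["pvalues"][contrast].reshape(grid_shape)
        _, sizes = find_clusters(pmap, p_init, connectivity)
        max_sizes[b] = sizes.max() if sizes.size else 0
    return calibrate_extent(max_sizes, alpha), max_sizes


# ---------------------------------------------------------------------------
# rank post-hoc
# ---------------------------------------------------------------------------

def _exact_spearman_p(xr: np.ndarray, yr: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho at tiny n."""
    n = len(xr)
    perms = np.array(list(_iter_permutations(range(n))))
    xp = xr[perms]
    xc = xp - xp.mean(axis=1, keepdims=True)
    yc = yr - yr.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    rhos = (xc @ yc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_test(x: np.ndarray, y: np.ndarray,
                  exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Uses exact permutation enumeration for n ≤ ``exact_max_n`` and the t
    approximation t = rho sqrt((n−2)/(1−rho²)) otherwise. Returns
    (nan, nan) with a warning when either input is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("need two equal-length vectors, n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input: Spearman correlation undefined")
        return float("nan"), float("nan")
    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    rho = float(np.corrcoef(xr, yr)[0, 1])
    if n <= exact_max_n:
        return rho, _exact_spearman_p(xr, yr, rho)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    return rho, 2.0 * stats.t.sf(abs(t), n - 2)


def isc_rank_posthoc(median_values: np.ndarray,
                     traits: pd.DataFrame) -> tuple[float, float]:
    """Spearman correlation of per-subject median ISC against trait rank.

    The rank (rather than the raw score) blunts the influence of the few
    extreme scorers a right-skewed trait produces. Requires n ≥ 5.
    """
    median_values = np.asarray(median_values, dtype=float)
    if len(median_values) < 5:
        raise ValueError("need at least 5 subjects")
    if len(median_values) != len(traits):
        raise ValueError("one median ISC value per subject is required")
    ranks = traits["trait_score"].rank(method="average").to_numpy()
    return spearman_test(median_values, ranks)
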