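"""Behavioral feature analysis: standardization, PLS regression, confounds.

Free-recall speech is summarized as a subjects × word-category percentage
matrix whose columns live on wildly different scales, so each column is
z-scored (zero mean, unit sample variance) before modeling. Partial least
squares regression then finds the direction in feature space with maximal
covariance with the trait score; the share of (centered) trait variance each
component captures and the sorted component loadings are the quantities of
interest. The algorithm is SIMPLS with the response centered but not scaled.

The confound screen mirrors the usual control table for a median-split
design: two-sample t-tests (low vs high) and Spearman correlations against
the raw trait score for continuous covariates, and a 2×2 chi-squared test
(no continuity correction) for binary ones; p-values are reported raw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .inference import spearman_test

__all__ = [
    "PLSResult",
    "zscore_features",
    "plsr_fit",
    "component_loadings",
    "screen_confounds",
]


def zscore_features(matrix: pd.DataFrame) -> pd.DataFrame:
    """Columnwise (x − mean)/sd with the sample (n−1) standard deviation.

    Constant columns cannot be standardized; they are dropped with a
    warning.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 subjects to standardize")
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        dropped = list(matrix.columns[constant])
        warnings.warn(f"dropping constant feature column(s): {dropped}")
    keep = ~constant
    out = (values[:, keep] - values[:, keep].mean(axis=0)) / sd[keep]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns[keep])


@dataclass
class PLSResult:
    """SIMPLS fit of features X against a single response y.

    Components are ordered; ``pctvar_y`` is the percent of centered-y sum of
    squares captured by each component (scores are orthonormal, so the
    per-component shares simply add). ``coef`` uses all fitted components;
    ``coef_k(k)`` truncates to the first k.
    """

    feature_names: list
    x_weights: np.ndarray      # (features, A)
    x_loadings: np.ndarray     # (features, A)
    y_loadings: np.ndarray     # (A,)
    scores: np.ndarray         # (subjects, A), orthonormal columns
    pctvar_y: np.ndarray       # (A,)
    y_mean: float

    @property
    def n_components(self) -> int:
        return self.x_weights.shape[1]

    @property
    def cumulative_pctvar_y(self) -> np.ndarray:
        return np.cumsum(self.pctvar_y)

    @property
    def coef(self) -> np.ndarray:
        return self.coef_k(self.n_components)

    def coef_k(self, k: int) -> np.ndarray:
        if not 0 <= k <= self.n_components:
            raise ValueError(f"k must be in [0, {self.n_components}]")
        return self.x_weights[:, :k] @ self.y_loadings[:k]


def plsr_fit(X: pd.DataFrame | np.ndarray, y: Sequence[float],
             n_components: int = 10) -> PLSResult:
    """Fit a SIMPLS partial least squares regression of y on X.

    X should already be standardized (see :func:`zscore_features`); it is
    re-centered defensively. y is centered, not scaled. ``n_components``
    beyond the rank of X is truncated with a warning; a response orthogonal
    to every column yields zero components (nothing to extract).
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X0 = X.to_numpy(dtype=float)
    else:
        X0 = np.asarray(X, dtype=float)
        names = [f"feat_{j + 1:02d}" for j in range(X0.shape[1])]
    y = np.asarray(y, dtype=float)
    n, f = X0.shape
    if len(y) != n:
        raise ValueError("y must have one value per row of X")
    X0 = X0 - X0.mean(axis=0)
    y_mean = float(y.mean())
    y0 = y - y_mean
    ss_y = float(y0 @ y0)
    max_comp = min(n - 1, f)
    if n_components > max_comp:
        warnings.warn(
            f"n_components={n_components} exceeds min(n-1, n_features)="
            f"{max_comp}; truncating"
        )
        n_components = max_comp

    scale = max(np.abs(X0).max(), 1.0) * max(np.abs(y0).max(), 1.0)
    R = np.zeros((f, n_components))
    P = np.zeros((f, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    V = np.zeros((f, n_components))
    s = X0.T @ y0
    a = 0
    for a in range(n_components):
        if np.linalg.norm(s) < 1e-10 * max(scale, 1.0):
            warnings.warn(
                f"rank exhausted after {a} component(s); truncating"
            )
            break
        r = s.copy()
        t = X0 @ r
        t = t - t.mean()
        nt = np.linalg.norm(t)
        if nt < 1e-12 * max(scale, 1.0):
            warnings.warn(f"rank exhausted after {a} component(s); truncating")
            break
        t /= nt
        r /= nt
        p = X0.T @ t
        q[a] = float(y0 @ t)
        v = p.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p)
        v /= np.linalg.norm(v)
        s = s - v * (v @ s)
        R[:, a], P[:, a], T[:, a], V[:, a] = r, p, t, v
    else:
        a = n_components
    k = a if a < n_components else n_components
    pct = 100.0 * q[:k] ** 2 / ss_y if ss_y > 0 else np.zeros(k)
    return PLSResult(
        feature_names=names,
        x_weights=R[:, :k],
        x_loadings=P[:, :k],
        y_loadings=q[:k],
        scores=T[:, :k],
        pctvar_y=pct,
        y_mean=y_mean,
    )


def component_loadings(fit: PLSResult, k: int = 1) -> pd.Series:
    """Named, sorted, unit-normalized loading vector of component ``k``.

    Loadings are reported as a direction (unit ℓ2 norm) sorted descending,
    with the sign convention that the entry of maximum absolute value is
    positive — PLS components are sign-indeterminate, so a fixed convention
    makes loadings comparable across fits.
    """
    if not 1 <= k <= fit.n_components:
        raise ValueError(
            f"component index {k} out of range 1..{fit.n_components}"
        )
    v = fit.x_loadings[:, k - 1].copy()
    norm = np.linalg.norm(v)
    if norm > 0:
        v /= norm
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    return pd.Series(v, index=fit.feature_names).sort_values(ascending=False)


def screen_confounds(
    traits: pd.DataFrame,
    groups: pd.DataFrame,
    continuous: Sequence[str] | None = None,
    categorical: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Control-table screen of covariates against the trait grouping.

    Continuous covariates get a two-sample t-test between low/high groups
    (reported as low − high) *and* a Spearman correlation against the raw
    trait score. Binary categorical covariates get a Pearson chi-squared on
    the 2×2 contingency table (df = 1, no continuity correction).
    Covariates with a single observed level are skipped with a warning.
    When column lists are not given, numeric covariate columns are treated
    as continuous and non-numeric ones as categorical.
    """
    merged = traits.merge(groups[["subject_id", "group"]], on="subject_id")
    reserved = {"subject_id", "trait_score", "trait_rank", "group"}
    if continuous is None and categorical is None:
        continuous = [
            c for c in merged.columns
            if c not in reserved and pd.api.types.is_numeric_dtype(merged[c])
        ]
        categorical = [
            c for c in merged.columns
            if c not in reserved and not pd.api.types.is_numeric_dtype(merged[c])
        ]
    continuous = list(continuous or [])
    categorical = list(categorical or [])

    low = merged["group"] == "low"
    rows = []
    for col in continuous:
        vals = merged[col].to_numpy(dtype=float)
        if np.all(vals == vals[0]):
            warnings.warn(f"covariate {col!r} has a single level; skipped")
            continue
        t, tp = stats.ttest_ind(vals[low], vals[~low], equal_var=True)
        rho, rp = spearman_test(merged["trait_score"].to_numpy(dtype=float), vals)
        rows.append(
            {
                "variable": col,
                "kind": "continuous",
                "t": float(t),
                "t_p": float(tp),
                "chi2": np.nan,
                "chi2_p": np.nan,
                "spearman_rho": rho,
                "spearman_p": rp,
            }
        )
    for col in categorical:
        levels = merged[col].unique()
        if len(levels) < 2:
            warnings.warn(f"covariate {col!r} has a single level; skipped")
            continue
        if len(levels) > 2:
            warnings.warn(f"covariate {col!r} has >2 levels; skipped")
            continue
        table = pd.crosstab(merged[col], merged["group"]).to_numpy()
        chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
        rows.append(
            {
                "variable": col,
                "kind": "categorical",
                "t": np.nan,
                "t_p": np.nan,
                "chi2": float(chi2),
                "chi2_p": float(p),
                "spearman_rho": np.nan,
                "spearman_p": np.nan,
            }
        )
    return pd.DataFrame(rows)
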