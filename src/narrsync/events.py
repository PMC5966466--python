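"""Event-locked encoding model: consensus events, HRF regressors, ROI GLMs.

Sentences of the narrative are labeled by several raters for the presence of
an ambiguous social interaction or explicit reasoning about others'
intentions ("mentalizing events"). Sentences labeled positive by at least a
consensus count of raters form the event set; the complement forms the
inverse (non-mentalizing) control set. Events are time-locked to the TR of
the last word's offset (listeners integrate at sentence boundaries), or
alternatively modeled as mini-blocks spanning the whole sentence. Impulse
(or boxcar) vectors are convolved with a canonical double-gamma hemodynamic
response function and regressed against ROI-mean time courses, one ordinary
least squares fit per subject per ROI per regressor; the resulting betas are
compared across trait groups and correlated with trait rank.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .inference import spearman_test
from .synthetic import SubjectTimeSeries
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EventSet",
    "ROIDefinition",
    "GLMResult",
    "consensus_events",
    "hrf_kernel",
    "build_regressor",
    "make_sphere_roi",
    "sphere_rois_from_json",
    "extract_roi_timeseries",
    "fit_roi_glm",
    "group_beta_tests",
    "beta_rank_correlation",
    "offset_seconds_to_tr",
]

HRF_MODELS = ("double_gamma",)

#: conventional template-space sphere centers (mm, Talairach sign
#: convention) for the control ROIs: left temporo-parietal junction and
#: left Heschl's gyrus (primary auditory cortex)
TEMPLATE_SPHERE_CENTERS = {
    "l_tpj": (53.0, 55.0, 18.0),
    "l_heschl": (-41.0, -24.0, 9.0),
}


@dataclass(frozen=True)
class EventSet:
    """Consensus-labeled sentences and their complement.

    ``mentalizing`` and ``inverse`` partition all sentence ids: every
    sentence is in exactly one of the two sets.
    """

    mentalizing: tuple
    inverse: tuple
    min_raters: int

    @property
    def n_events(self) -> int:
        return len(self.mentalizing)


def consensus_events(annotations: pd.DataFrame, min_raters: int = 3) -> EventSet:
    """Select sentences labeled positive by at least ``min_raters`` raters."""
    rater_cols = [c for c in annotations.columns if c.startswith("rater_")]
    if not rater_cols:
        raise ValueError("annotation table has no rater_* columns")
    if min_raters > len(rater_cols):
        raise ValueError(
            f"min_raters={min_raters} exceeds the {len(rater_cols)} raters present"
        )
    votes = annotations[rater_cols].to_numpy(dtype=int).sum(axis=1)
    included = votes >= min_raters
    ids = annotations["sentence_id"].to_numpy()
    return EventSet(
        mentalizing=tuple(ids[included]),
        inverse=tuple(ids[~included]),
        min_raters=min_raters,
    )


def hrf_kernel(
    tr_seconds: float,
    model: str = "double_gamma",
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    ratio: float = 6.0,
    length_seconds: float = 32.0,
) -> np.ndarray:
    """Sample a canonical double-gamma HRF at the TR grid, unit peak.

    The kernel is gamma(peak) − gamma(undershoot)/ratio evaluated on
    t = 0, tr, 2·tr, … < length. With the defaults the response peaks at
    (peak_delay − 1)·peak_disp = 5 s and undershoots near 15 s. The value at
    t = 0 is exactly 0.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    if model not in HRF_MODELS:
        raise ValueError(
            f"unknown HRF model {model!r}; available models: {list(HRF_MODELS)}"
        )
    t = np.arange(0.0, length_seconds, tr_seconds)
    h = stats.gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    h = h - stats.gamma.pdf(t, undershoot_delay / undershoot_disp,
                            scale=undershoot_disp) / ratio
    peak = h.max()
    if peak <= 0:
        raise ValueError("degenerate HRF parameters: non-positive peak")
    return h / peak


def offset_seconds_to_tr(offset_seconds: float, tr_seconds: float) -> int:
    """TR index containing a word-offset timestamp (1-based TR grid rounded
    up: an offset anywhere inside TR k maps to k)."""
    return int(math.ceil(offset_seconds / tr_seconds))


def build_regressor(
    events: EventSet,
    annotations: pd.DataFrame,
    n_tr: int,
    tr_seconds: float = 1.0,
    hrf: np.ndarray | None = None,
    mode: str = "offset",
    which: str = "mentalizing",
) -> np.ndarray:
    """Convolve the selected events with the HRF into a per-TR regressor.

    ``mode="offset"`` places a unit impulse at each sentence's offset TR;
    ``mode="block"`` a unit boxcar over [onset_tr, offset_tr]. ``which``
    selects the consensus set or its inverse. The convolution is truncated
    to ``n_tr`` samples; an empty event set yields an all-zero regressor.
    """
    if mode not in ("offset", "block"):
        raise ValueError("mode must be 'offset' or 'block'")
    if which not in ("mentalizing", "inverse"):
        raise ValueError("which must be 'mentalizing' or 'inverse'")
    ids = set(events.mentalizing if which == "mentalizing" else events.inverse)
    rows = annotations[annotations["sentence_id"].isin(ids)]
    impulses = np.zeros(n_tr)
    for _, row in rows.iterrows():
        onset, offset = int(row["onset_tr"]), int(row["offset_tr"])
        if offset >= n_tr:
            raise ValueError(
                f"sentence {row['sentence_id']} ends at TR {offset}, beyond the "
                f"run ({n_tr} TRs)"
            )
        if mode == "offset":
            impulses[offset] += 1.0
        else:
            impulses[onset: offset + 1] += 1.0
    if hrf is None:
        hrf = hrf_kernel(tr_seconds)
    return np.convolve(impulses, np.asarray(hrf, dtype=float))[:n_tr]


@dataclass(frozen=True)
class ROIDefinition:
    """A named set of voxel grid indices, from a sphere or a cluster mask."""

    name: str
    voxels: np.ndarray          # (k, 3) integer grid indices
    source: str = "sphere"
    center_mm: tuple | None = None
    radius_mm: float | None = None

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


def make_sphere_roi(
    name: str,
    center_mm: Sequence[float],
    radius_mm: float,
    affine: np.ndarray,
    shape: tuple[int, int, int],
) -> ROIDefinition:
    """All voxels whose center lies within ``radius_mm`` of a template-space
    coordinate, under an arbitrary grid affine (voxel index → mm)."""
    center_mm = np.asarray(center_mm, dtype=float)
    affine = np.asarray(affine, dtype=float)
    inv = np.linalg.inv(affine)
    center_vox = (inv @ np.append(center_mm, 1.0))[:3]
    # bounding box in voxel space generous enough for anisotropic grids
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    halfwidth = np.ceil(radius_mm / spacing).astype(int) + 1
    lo = np.maximum(np.floor(center_vox).astype(int) - halfwidth, 0)
    hi = np.minimum(np.ceil(center_vox).astype(int) + halfwidth + 1, shape)
    if np.any(lo >= hi):
        raise ValueError(f"sphere center {tuple(center_mm)} lies outside the grid")
    grid = np.stack(
        np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij"), -1
    ).reshape(-1, 3)
    world = grid @ affine[:3, :3].T + affine[:3, 3]
    keep = np.linalg.norm(world - center_mm, axis=1) <= radius_mm
    voxels = grid[keep]
    if len(voxels) == 0:
        raise ValueError(
            f"sphere of radius {radius_mm} mm at {tuple(center_mm)} contains no voxels"
        )
    return ROIDefinition(
        name=name,
        voxels=voxels,
        source="sphere",
        center_mm=tuple(center_mm),
        radius_mm=float(radius_mm),
    )


def sphere_rois_from_json(path, affine: np.ndarray,
                          shape: tuple[int, int, int]) -> list[ROIDefinition]:
    """Read sphere ROI specs from a JSON list of
    ``{"name", "center_mm", "radius_mm"}`` objects and realize them on the
    given grid."""
    import json
    from pathlib import Path

    specs = json.loads(Path(path).read_text())
    return [
        make_sphere_roi(s["name"], s["center_mm"], s["radius_mm"], affine, shape)
        for s in specs
    ]


def extract_roi_timeseries(
    data: np.ndarray | SubjectTimeSeries,
    roi: ROIDefinition,
    grid_shape: tuple[int, int, int] | None = None,
) -> np.ndarray:
    """Unweighted spatial mean of the ROI voxels at each TR.

    ``data`` is either a 4-D (x, y, z, t) array or a SubjectTimeSeries whose
    units enumerate a raveled grid of ``grid_shape`` (C order).
    """
    if isinstance(data, SubjectTimeSeries):
        if grid_shape is None:
            raise ValueError("grid_shape is required for flat unit data")
        flat = np.ravel_multi_index(roi.voxels.T, grid_shape)
        if flat.max() >= data.n_units:
            raise ValueError("ROI voxels fall outside the data grid")
        return data.data[flat].mean(axis=0)
    data = np.asarray(data, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected 4-D (x, y, z, t) data")
    if np.any(roi.voxels >= np.asarray(data.shape[:3])):
        raise ValueError("ROI voxels fall outside the data grid")
    i, j, k = roi.voxels.T
    return data[i, j, k, :].mean(axis=0)


@dataclass(frozen=True)
class GLMResult:
    """OLS fit of an ROI series on [intercept, regressor]."""

    beta: float
    se: float
    intercept: float
    sigma2: float


def fit_roi_glm(series: np.ndarray, regressor: np.ndarray) -> GLMResult:
    """Ordinary least squares of an ROI time course on one event regressor
    (plus intercept); returns the regressor's coefficient and its standard
    error."""
    series = np.asarray(series, dtype=float)
    regressor = np.asarray(regressor, dtype=float)
    if series.shape != regressor.shape:
        raise ValueError("series and regressor must have equal length")
    if np.allclose(regressor, regressor[0]):
        raise ValueError("regressor is constant: collinear with the intercept")
    X = np.column_stack([np.ones_like(regressor), regressor])
    beta, _, rank, _ = np.linalg.lstsq(X, series, rcond=None)
    if rank < 2:
        raise ValueError("collinear design")
    resid = series - X @ beta
    dof = len(series) - 2
    sigma2 = float(resid @ resid) / dof if dof > 0 else float("nan")
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return GLMResult(
        beta=float(beta[1]),
        se=float(np.sqrt(cov[1, 1])),
        intercept=float(beta[0]),
        sigma2=sigma2,
    )


def group_beta_tests(
    betas: pd.DataFrame,
    groups: pd.DataFrame,
    fdr_q: float = 0.05,
    pooled_rois: Sequence[str] = (),
    equal_var: bool = True,
) -> pd.DataFrame:
    """Group comparisons of per-subject event betas, per ROI × regressor.

    For every (roi, mode) cell a two-sample t-test (equal variance by
    default, so df = n1 + n2 − 2) compares high vs low groups, and BH
    adjustment is applied across the ROI family within each mode. ROIs named
    in ``pooled_rois`` additionally get a one-sample t-test of the betas
    pooled over both groups against zero (uncorrected) — the test for a
    trait-independent response.

    ``betas`` columns: subject_id, roi, mode, beta. ``groups`` columns:
    subject_id, group ∈ {low, high}.
    """
    merged = betas.merge(groups[["subject_id", "group"]], on="subject_id")
    rows = []
    for (mode, roi), cell in merged.groupby(["mode", "roi"], sort=False):
        low = cell.loc[cell["group"] == "low", "beta"].to_numpy()
        high = cell.loc[cell["group"] == "high", "beta"].to_numpy()
        if len(low) < 2 or len(high) < 2:
            raise ValueError(f"fewer than 2 subjects per group for ROI {roi}")
        if np.ptp(low) == 0 and np.ptp(high) == 0 and low.var() + high.var() == 0:
            t, p = float("nan"), float("nan")
            warnings.warn(f"degenerate variance in ROI {roi}: t undefined")
        else:
            t, p = stats.ttest_ind(high, low, equal_var=equal_var)
        rows.append(
            {
                "roi": roi,
                "mode": mode,
                "test": "two_sample",
                "t": float(t),
                "df": len(low) + len(high) - 2,
                "p": float(p),
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    table["reject"] = False
    for mode, idx in table.groupby("mode").groups.items():
        pv = table.loc[idx, "p"].to_numpy()
        ok = np.isfinite(pv)
        if ok.any():
            rej, qv, _, _ = multipletests(pv[ok], alpha=fdr_q, method="fdr_bh")
            table.loc[np.asarray(idx)[ok], "q"] = qv
            table.loc[np.asarray(idx)[ok], "reject"] = rej

    pooled_rows = []
    for (mode, roi), cell in merged.groupby(["mode", "roi"], sort=False):
        if roi not in pooled_rois:
            continue
        vals = cell["beta"].to_numpy()
        t, p = stats.ttest_1samp(vals, 0.0)
        pooled_rows.append(
            {
                "roi": roi,
                "mode": mode,
                "test": "one_sample_pooled",
                "t": float(t),
                "df": len(vals) - 1,
                "p": float(p),
                "q": np.nan,
                "reject": bool(p < fdr_q),
            }
        )
    if pooled_rows:
        table = pd.concat([table, pd.DataFrame(pooled_rows)], ignore_index=True)
    return table


def beta_rank_correlation(betas: pd.DataFrame,
                          traits: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of per-subject betas against trait rank, per
    ROI × regressor mode — the continuous post-hoc companion to the group
    tests."""
    ranks = traits[["subject_id"]].copy()
    ranks["trait_rank"] = traits["trait_score"].rank(method="average")
    merged = betas.merge(ranks, on="subject_id")
    if merged["subject_id"].nunique() < 5:
        raise ValueError("need at least 5 subjects")
    rows = []
    for (mode, roi), cell in merged.groupby(["mode", "roi"], sort=False):
        rho, p = spearman_test(cell["beta"].to_numpy(),
                               cell["trait_rank"].to_numpy())
        rows.append({"roi": roi, "mode": mode, "rho": rho, "p": p})
    return pd.DataFrame(rows)
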