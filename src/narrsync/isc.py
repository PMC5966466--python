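"""Pairwise inter-subject correlation (ISC) matrices and summaries.

ISC is the per-unit (voxel or ROI) Pearson correlation between two subjects'
full stimulus-locked time courses. For n subjects there are n(n−1)/2 unique
pairs, stored as a symmetric n × n matrix per unit with a diagonal of 1 that
is excluded from inference. Censored TRs carry zeros and are *included* in
the correlation by default, which preserves temporal alignment across
subjects; a flag can instead mask out the union of a pair's censored TRs.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import SubjectTimeSeries

__all__ = ["pairwise_isc", "fisher_z", "median_isc", "pair_table"]

#: correlations at exactly ±1 are clipped to ±(1 − _CLIP_EPS) before atanh
_CLIP_EPS = 1e-7


def _stack_dataset(dataset: Sequence[SubjectTimeSeries]) -> np.ndarray:
    if len(dataset) < 2:
        raise ValueError("need at least 2 subjects")
    shape = dataset[0].data.shape
    tr = dataset[0].tr_seconds
    for sts in dataset[1:]:
        if sts.data.shape != shape:
            raise ValueError(
                f"subject {sts.subject_id} has shape {sts.data.shape}, "
                f"expected {shape}"
            )
        if sts.tr_seconds != tr:
            raise ValueError(f"subject {sts.subject_id} has a different TR")
    return np.stack([sts.data for sts in dataset])  # (n, units, trs)


def pairwise_isc(
    dataset: Sequence[SubjectTimeSeries],
    units: np.ndarray | None = None,
    mask_censored: bool = False,
) -> np.ndarray:
    """Compute per-unit pairwise Pearson correlation matrices.

    Parameters
    ----------
    dataset : sequence of SubjectTimeSeries with identical shapes/TR.
    units : optional boolean mask or index array selecting units.
    mask_censored : when True, each pair's correlation is computed over the
        TRs retained by *both* subjects instead of over the full series with
        censored zeros included (the default, which matches conventional
        censoring-by-zeroing).

    Returns
    -------
    values : array of shape (n_selected_units, n, n), symmetric per unit,
        diagonal 1. A pair whose series is constant in a unit yields NaN for
        that entry (reported via a warning, excluded downstream).
    """
    stack = _stack_dataset(dataset)
    if units is not None:
        units = np.asarray(units)
        stack = stack[:, units.astype(bool), :] if units.dtype == bool else stack[:, units, :]
    n, n_units, _ = stack.shape

    if not mask_censored:
        values = np.empty((n_units, n, n))
        for v in range(n_units):
            x = stack[:, v, :]
            sd = x.std(axis=1)
            if np.any(sd == 0):
                bad = [dataset[i].subject_id for i in np.nonzero(sd == 0)[0]]
                warnings.warn(
                    f"constant time course for subject(s) {bad} in unit {v}; "
                    "correlations set to NaN"
                )
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.corrcoef(x)
            r[sd == 0, :] = np.nan
            r[:, sd == 0] = np.nan
            np.fill_diagonal(r, 1.0)
            values[v] = r
        return values

    masks = np.stack([sts.censor_mask for sts in dataset])
    values = np.ones((n_units, n, n))
    for i in range(n):
        for j in range(i + 1, n):
            keep = masks[i] & masks[j]
            if keep.sum() < 3:
                values[:, i, j] = values[:, j, i] = np.nan
                continue
            xi = stack[i, :, keep].T  # (units, kept)
            xj = stack[j, :, keep].T
            xi = xi - xi.mean(axis=1, keepdims=True)
            xj = xj - xj.mean(axis=1, keepdims=True)
            denom = np.linalg.norm(xi, axis=1) * np.linalg.norm(xj, axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (xi * xj).sum(axis=1) / denom
            values[:, i, j] = values[:, j, i] = r
    return values


def fisher_z(values: np.ndarray, clip: bool = True) -> np.ndarray:
    """Apply the variance-stabilizing Fisher z = atanh(r) elementwise.

    Off-diagonal entries at |r| = 1 are clipped to 1 − 1e−7 with a warning
    when ``clip`` is True (they arise only in degenerate, noiseless inputs);
    with clipping disabled they raise, naming the offending pair.
    The diagonal of each matrix is set to NaN — it is excluded from
    inference, and atanh(1) is not meaningful.
    """
    values = np.asarray(values, dtype=float)
    matrices = values[None] if values.ndim == 2 else values
    out = np.empty_like(matrices)
    n = matrices.shape[-1]
    off = ~np.eye(n, dtype=bool)
    for v, r in enumerate(matrices):
        r_off = r[off]
        at_one = np.abs(r_off) >= 1.0
        if np.any(at_one & np.isfinite(r_off)):
            i, j = np.nonzero((np.abs(r) >= 1.0) & off & np.isfinite(r))
            if not clip:
                raise ValueError(
                    f"|r| = 1 for pair(s) {list(zip(i.tolist(), j.tolist()))} "
                    "in unit {v} with clipping disabled"
                )
            warnings.warn(
                f"clipping {at_one.sum()} correlation(s) at |r|=1 to "
                f"{1 - _CLIP_EPS}"
            )
        z = np.arctanh(np.clip(r, -1 + _CLIP_EPS, 1 - _CLIP_EPS))
        np.fill_diagonal(z, np.nan)
        out[v] = z
    return out[0] if values.ndim == 2 else out


def median_isc(values: np.ndarray) -> np.ndarray:
    """Per-subject median of its n−1 pairwise correlations (one matrix).

    This is the row-median of the ISC matrix with the diagonal excluded: a
    subject-level summary of how synchronized each participant is with the
    rest of the sample.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("expected a single square ISC matrix")
    n = values.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for a row median")
    off = values[~np.eye(n, dtype=bool)].reshape(n, n - 1)
    return np.nanmedian(off, axis=1)


def pair_table(
    values: np.ndarray,
    subject_ids: Sequence[str],
    unit_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long-format pair table (unit_id, subj_i, subj_j, r, z), one row per
    unique pair per unit — the on-disk interchange format between the ISC
    stage and the mixed-model stage."""
    values = np.asarray(values, dtype=float)
    matrices = values[None] if values.ndim == 2 else values
    n = matrices.shape[-1]
    if len(subject_ids) != n:
        raise ValueError("subject_ids length must match matrix size")
    if unit_ids is None:
        unit_ids = [f"unit_{v:04d}" for v in range(matrices.shape[0])]
    iu, ju = np.triu_indices(n, 1)
    z = fisher_z(matrices)
    frames = []
    for v, uid in enumerate(unit_ids):
        frames.append(
            pd.DataFrame(
                {
                    "unit_id": uid,
                    "subj_i": np.asarray(subject_ids)[iu],
                    "subj_j": np.asarray(subject_ids)[ju],
                    "r": matrices[v, iu, ju],
                    "z": z[v, iu, ju],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
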