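"""Monte Carlo validation studies for the pipeline's statistical machinery.

Each function here runs a self-contained simulation study — generating data
from a known model, pushing it through the package's estimators, and
measuring an operating characteristic (type-I error, bias, rank-recovery,
decision accuracy, family-wise error). They are the computational backbone
of the calibration analyses and of ``scripts/acceptance.py``; the numbered
drivers under ``analysis/`` call them with their default study sizes.

All studies are deterministic given their seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import events as ev
from . import inference as inf
from . import synthetic as syn
from .behavior import component_loadings, plsr_fit, zscore_features
from .isc import median_isc, pairwise_isc

__all__ = [
    "simulate_pair_zmatrix",
    "lme_type1_error",
    "lme_contrast_bias",
    "ak_rank_rho_study",
    "event_pattern_study",
    "cluster_fwe_study",
    "plsr_recovery_study",
]


def simulate_pair_zmatrix(
    n_subjects: int,
    labels: np.ndarray | None = None,
    g11: float = 0.3,
    g22: float = 0.3,
    g12: float = 0.3,
    tau2: float = 0.02,
    sigma2: float = 0.05,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw one symmetric pair z-matrix from the crossed random-effects
    model (the generative model the LME assumes)."""
    rng = rng or np.random.default_rng()
    n = n_subjects
    iu, ju = np.triu_indices(n, 1)
    if labels is None:
        mean = np.full(len(iu), g11)
    else:
        labels = np.asarray(labels)
        levels = sorted(np.unique(labels).tolist())
        if set(levels) == {"low", "high"}:
            levels = ["low", "high"]
        li, lj = labels[iu], labels[ju]
        mean = np.where(
            (li == levels[0]) & (lj == levels[0]), g11,
            np.where((li == levels[1]) & (lj == levels[1]), g22, g12),
        )
    xi = rng.normal(0.0, np.sqrt(tau2), n)
    eps = rng.normal(0.0, np.sqrt(sigma2), len(iu))
    vals = mean + xi[iu] + xi[ju] + eps
    zmat = np.zeros((n, n))
    zmat[iu, ju] = vals
    zmat[ju, iu] = vals
    return zmat


def _half_split_labels(n: int) -> np.ndarray:
    return np.array(["low"] * (n // 2) + ["high"] * (n - n // 2))


def lme_type1_error(
    n_subjects: int = 20,
    n_sims: int = 1000,
    alpha: float = 0.05,
    b0: float = 0.3,
    tau2: float = 0.02,
    sigma2: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the G11 vs G22 Wald contrast under the
    null (no group difference)."""
    rng = np.random.default_rng(seed)
    labels = _half_split_labels(n_subjects)
    hits = 0
    for _ in range(n_sims):
        zmat = simulate_pair_zmatrix(
            n_subjects, labels, g11=b0, g22=b0, g12=b0,
            tau2=tau2, sigma2=sigma2, rng=rng,
        )
        fit = inf.fit_two_group_lme(zmat, labels)
        p = fit.contrasts.set_index("contrast").loc["G11-G22", "p"]
        hits += p < alpha
    return hits / n_sims


def lme_contrast_bias(
    n_subjects: int = 22,
    n_sims: int = 200,
    delta: float = 0.2,
    base: float = 0.2,
    tau2: float = 0.02,
    sigma2: float = 0.05,
    seed: int = 0,
) -> float:
    """Bias of the estimated G11 − G22 contrast when the true z-scale group
    difference is ``delta`` (G11 = base + delta, G22 = base)."""
    rng = np.random.default_rng(seed)
    labels = _half_split_labels(n_subjects)
    estimates = np.empty(n_sims)
    for s in range(n_sims):
        zmat = simulate_pair_zmatrix(
            n_subjects, labels,
            g11=base + delta, g22=base, g12=base + delta / 2.0,
            tau2=tau2, sigma2=sigma2, rng=rng,
        )
        fit = inf.fit_two_group_lme(zmat, labels)
        estimates[s] = fit.contrasts.set_index("contrast").loc["G11-G22", "estimate"]
    return float(estimates.mean() - delta)


def ak_rank_rho_study(
    n_reps: int = 100,
    n_subjects: int = 22,
    n_tr: int = 1310,
    shared_amp: float = 0.5,
    noise_sd: float = 0.5,
    smooth_window: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Spearman rho of median ISC vs trait rank under monotone coupling.

    Each replicate draws a fresh cohort and trait-coupled time series (one
    unit), computes the pairwise ISC matrix, per-subject median ISC, and its
    rank correlation with the trait. Returns the per-replicate rho values.
    """
    rhos = np.empty(n_reps)
    for r in range(n_reps):
        traits = syn.gen_trait_scores(n_subjects, seed=seed * 100003 + 2 * r)
        design = syn.SynthDesign(
            n_subjects=n_subjects,
            n_units=1,
            n_tr=n_tr,
            shared_amp=shared_amp,
            noise_sd=noise_sd,
            smooth_window=smooth_window,
            seed=seed * 100003 + 2 * r + 1,
        )
        dataset, _ = syn.gen_timeseries(traits, design)
        isc = pairwise_isc(dataset)[0]
        med = median_isc(isc)
        rho, _ = inf.isc_rank_posthoc(med, traits)
        rhos[r] = rho
    return rhos


# planted effect sizes for the encoding-model pattern study: a strong,
# clearly detectable configuration (gain difference ~1 between groups at a
# per-subject beta s.d. near 0.4)
_EVENT_ROI_SPECS = {
    "tmp_pole_like": ("trait_scaled", 2.0),
    "mpfc_like": ("trait_scaled", 2.0),
    "tpj_like": ("uniform", 1.0),
    "heschl_like": ("none", 0.0),
}


def event_pattern_study(
    n_reps: int = 200,
    n_subjects: int = 22,
    n_tr: int = 1310,
    n_sentences: int = 60,
    between_sd: float = 0.25,
    noise_sd: float = 2.0,
    fdr_q: float = 0.05,
    mode: str = "offset",
    seed: int = 0,
) -> dict:
    """Decision accuracy of the ROI encoding-model tests on planted data.

    Four synthetic ROIs play the roles of the canonical pattern: two whose
    event response scales with the trait (expect a significant group
    difference), one uniform responder (expect a pooled response with no
    group difference), and one non-responder (expect nothing). Each
    replicate generates fresh annotations, ROI series, per-subject GLM
    betas, and the group/pooled tests; accuracies are reported per decision
    across replicates.
    """
    rng = np.random.default_rng(seed)
    decisions = {
        "tmp_pole_group_diff": 0,
        "mpfc_group_diff": 0,
        "tpj_pooled_response": 0,
        "tpj_no_group_diff": 0,
        "heschl_no_group_diff": 0,
        "heschl_no_pooled_response": 0,
    }
    for _ in range(n_reps):
        sub = int(rng.integers(0, 2**31 - 1))
        traits = syn.gen_trait_scores(n_subjects, seed=sub)
        groups = inf.median_split(traits)
        ann = syn.gen_annotations(n_sentences, seed=sub + 1)
        evset = ev.consensus_events(ann, min_raters=3)
        if evset.n_events < 3:
            continue
        reg = ev.build_regressor(evset, ann, n_tr=n_tr, tr_seconds=1.0, mode=mode)
        rows = []
        for k, (roi, (roi_mode, amp)) in enumerate(_EVENT_ROI_SPECS.items()):
            _, series = syn.gen_roi_responses(
                traits, reg, mode=roi_mode, amplitude=amp,
                between_sd=between_sd, noise_sd=noise_sd, seed=sub + 2 + k,
            )
            for i, sid in enumerate(traits["subject_id"]):
                res = ev.fit_roi_glm(series[i], reg)
                rows.append(
                    {"subject_id": sid, "roi": roi, "mode": mode, "beta": res.beta}
                )
        betas = pd.DataFrame(rows)
        table = ev.group_beta_tests(
            betas, groups, fdr_q=fdr_q,
            pooled_rois=("tpj_like", "heschl_like"),
        )
        two = table[table["test"] == "two_sample"].set_index("roi")
        pooled = table[table["test"] == "one_sample_pooled"].set_index("roi")
        decisions["tmp_pole_group_diff"] += bool(two.loc["tmp_pole_like", "reject"])
        decisions["mpfc_group_diff"] += bool(two.loc["mpfc_like", "reject"])
        decisions["tpj_pooled_response"] += bool(pooled.loc["tpj_like", "reject"])
        decisions["tpj_no_group_diff"] += not bool(two.loc["tpj_like", "reject"])
        decisions["heschl_no_group_diff"] += not bool(
            two.loc["heschl_like", "reject"]
        )
        decisions["heschl_no_pooled_response"] += not bool(
            pooled.loc["heschl_like", "reject"]
        )
    return {k: v / n_reps for k, v in decisions.items()}


def cluster_fwe_study(
    n_datasets: int = 200,
    grid_shape: tuple[int, int, int] = (5, 5, 5),
    n_subjects: int = 16,
    n_perm: int = 100,
    p_init: float = 0.002,
    alpha: float = 0.05,
    b0: float = 0.3,
    tau2: float = 0.02,
    sigma2: float = 0.05,
    seed: int = 0,
) -> float:
    """Family-wise false-positive rate of permutation-calibrated cluster
    correction on null lattices (no group effect, spatially independent
    units)."""
    rng = np.random.default_rng(seed)
    labels = _half_split_labels(n_subjects)
    n_units = int(np.prod(grid_shape))
    contrast = "G11-G22"
    fp = 0
    for d in range(n_datasets):
        zstack = np.stack(
            [
                simulate_pair_zmatrix(
                    n_subjects, labels, g11=b0, g22=b0, g12=b0,
                    tau2=tau2, sigma2=sigma2, rng=rng,
                )
                for _ in range(n_units)
            ]
        )
        extent, _ = inf.permutation_cluster_extent(
            zstack, grid_shape, labels, contrast=contrast,
            p_init=p_init, alpha=alpha, n_perm=n_perm,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        fit = inf.fit_lme_map(zstack, labels)
        pmap = fit["pvalues"][contrast].reshape(grid_shape)
        result = inf.cluster_correct(pmap, p_init=p_init, extent=extent)
        fp += result.n_surviving > 0
    return fp / n_datasets


def plsr_recovery_study(
    n_reps: int = 50,
    n_subjects: int = 22,
    n_features: int = 67,
    noise_sd: float = 1.0,
    loading_scale: float = 5.0,
    seed: int = 0,
) -> dict:
    """Planted-loading recovery of the first PLS component at moderate noise.

    Plants a random loading direction of norm ``loading_scale`` in the
    feature generator and measures (a) the cosine between the recovered
    component-1 loading direction and the planted one, and (b) whether
    component 1 explains more trait variance than the best single-column
    regression.
    """
    rng = np.random.default_rng(seed)
    cosines = np.empty(n_reps)
    beats_single = np.empty(n_reps, dtype=bool)
    for r in range(n_reps):
        sub = int(rng.integers(0, 2**31 - 1))
        traits = syn.gen_trait_scores(n_subjects, seed=sub)
        loading = rng.standard_normal(n_features)
        loading *= loading_scale / np.linalg.norm(loading)
        feats = syn.gen_speech_features(
            traits, n_features=n_features, loading_vector=loading,
            noise_sd=noise_sd, seed=sub + 1,
        )
        Xz = zscore_features(feats)
        y = traits["trait_score"].to_numpy(dtype=float)
        fit = plsr_fit(Xz, y, n_components=1)
        load = component_loadings(fit, 1).reindex(Xz.columns).to_numpy()
        cos = abs(load @ loading) / np.linalg.norm(loading)
        cosines[r] = cos
        yc = y - y.mean()
        r2_cols = (Xz.to_numpy().T @ yc) ** 2 / (
            (Xz.to_numpy() ** 2).sum(axis=0) * (yc @ yc)
        )
        beats_single[r] = fit.pctvar_y[0] / 100.0 > r2_cols.max()
    return {
        "median_cosine": float(np.median(cosines)),
        "frac_beats_single_column": float(beats_single.mean()),
    }
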