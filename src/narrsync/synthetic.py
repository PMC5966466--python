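"""Synthetic cohorts, time series, annotations, and behavioral features.

This module generates every input the analysis pipeline consumes, with known
ground truth so each downstream stage can be validated end to end:

* trait scores on a 16–80 instrument scale drawn from a shifted, rounded
  exponential (trait paranoia in healthy samples is right-skewed, roughly
  exponential, with a hard floor at the minimum possible score);
* multi-subject per-unit time series with a stimulus-locked component shared
  by everyone plus a second shared component whose per-subject weight grows
  with trait score — the "Anna Karenina" structure in which high-trait pairs
  synchronize while low-trait subjects are idiosyncratic;
* i.i.d. per-TR censoring, with censored time points set to exactly zero
  (matching how motion censoring is conventionally handled for ISC, where
  removing frames would destroy cross-subject temporal alignment);
* sentence-level annotations by k raters with tunable agreement around a
  latent binary truth;
* a subjects × features behavioral matrix with a planted rank-one trait
  component.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRAIT_MIN",
    "TRAIT_MAX",
    "SubjectTimeSeries",
    "SynthDesign",
    "linear_coupling",
    "cdf_coupling",
    "gen_trait_scores",
    "gen_timeseries",
    "gen_annotations",
    "gen_speech_features",
    "gen_roi_responses",
]

TRAIT_MIN = 16
TRAIT_MAX = 80


def linear_coupling(score):
    """Map a trait score on the 16–80 instrument scale linearly onto [0, 1]."""
    return (np.asarray(score, dtype=float) - TRAIT_MIN) / (TRAIT_MAX - TRAIT_MIN)


def cdf_coupling(scale: float = 4.6) -> Callable:
    """Coupling weight equal to the trait's population quantile.

    Returns w(score) = 1 − exp(−(score − 16)/scale), the CDF of the shifted
    exponential the trait generator draws from. Because a right-skewed trait
    concentrates most scores just above the floor, a linear-in-score map
    leaves the bulk of the sample with near-zero coupling; the quantile map
    instead spreads coupling weights uniformly over [0, 1] across the
    sample, which is what makes per-subject synchrony rise monotonically
    with trait *rank* (the Anna Karenina pattern) under the additive
    generative model. This is the default coupling for SynthDesign.
    """

    def _coupling(score):
        return 1.0 - np.exp(-(np.asarray(score, dtype=float) - TRAIT_MIN) / scale)

    return _coupling


@dataclass(frozen=True)
class SubjectTimeSeries:
    """One subject's units × TRs signal matrix plus its censor mask.

    ``data`` has shape (n_units, n_tr). Censored TRs carry the value exactly
    0 in every unit; ``censor_mask`` is True where the TR was *retained*.
    """

    subject_id: str
    data: np.ndarray
    censor_mask: np.ndarray
    tr_seconds: float = 1.0

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        mask = np.asarray(self.censor_mask, dtype=bool)
        if data.ndim != 2:
            raise ValueError("data must be 2-D (units × TRs)")
        if mask.shape != (data.shape[1],):
            raise ValueError("censor_mask must have one entry per TR")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "censor_mask", mask)

    @property
    def n_units(self) -> int:
        return self.data.shape[0]

    @property
    def n_tr(self) -> int:
        return self.data.shape[1]


@dataclass
class SynthDesign:
    """Design parameters for the trait-coupled time-series generator.

    Each unit v gets two independent shared processes c_v and d_v, both unit
    variance. Subject i's series at unit v is

        y_iv = shared_amp * c_v + w_i * d_v + noise_sd * e_iv,

    where w_i = coupling_fn(trait_i) ∈ [0, 1] and e_iv is subject noise.
    When ``smooth_window > 1`` every component is convolved with the same
    moving-average kernel normalized to unit ℓ2 norm, which leaves all lag-0
    cross-subject correlations at their white-noise analytic values while
    giving each series BOLD-like autocorrelation.
    """

    n_subjects: int
    n_units: int = 1
    n_tr: int = 1310
    tr_seconds: float = 1.0
    shared_amp: float = 0.5
    coupling_fn: Callable = field(default_factory=cdf_coupling)
    noise_sd: float = 0.5
    censor_rate: float = 0.0
    smooth_window: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.shared_amp < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise s.d. must be >= 0")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")
        grid = np.linspace(TRAIT_MIN, TRAIT_MAX, 65)
        w = np.asarray(self.coupling_fn(grid), dtype=float)
        if np.any(np.diff(w) < -1e-12):
            raise ValueError("coupling_fn must be non-decreasing in trait score")


def gen_trait_scores(n: int, skew: float = 4.6, seed: int = 0) -> pd.DataFrame:
    """Draw a right-skewed trait cohort with null covariates.

    Scores are 16 + round(Exponential(scale=skew)), clipped to the 16–80
    instrument range; ``skew`` is the exponential scale (the mean elevation
    above the floor), so the default reproduces a healthy-sample mean near
    20.6. Covariates (age, sex, motion, censored-frame counts) are drawn
    independently of the trait so the confound screen has a true null.

    Returns a table with columns ``subject_id``, ``trait_score``,
    ``trait_rank`` (average ranks on ties) and the covariates.
    """
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if skew < 0:
        raise ValueError("skew must be >= 0")
    rng = np.random.default_rng(seed)
    scores = TRAIT_MIN + np.round(rng.exponential(scale=skew, size=n))
    scores = np.clip(scores, TRAIT_MIN, TRAIT_MAX).astype(int)
    age = np.clip(np.round(rng.normal(27.0, 4.4, size=n)), 19, 35).astype(int)
    sex = rng.choice(["F", "M"], size=n)
    motion = np.clip(rng.normal(0.075, 0.026, size=n), 0.02, None)
    censored = np.clip(np.round(rng.exponential(scale=20.0, size=n)), 0, 135).astype(int)
    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:02d}" for i in range(n)],
            "trait_score": scores,
            "age": age,
            "sex": sex,
            "motion_mm": motion,
            "frames_censored": censored,
        }
    )
    table["trait_rank"] = table["trait_score"].rank(method="average")
    return table


def _smooth_rows(x: np.ndarray, window: int) -> np.ndarray:
    """Convolve each row with a unit-ℓ2-norm moving-average kernel."""
    if window <= 1:
        return x
    kernel = np.ones(window) / np.sqrt(window)
    out = np.empty_like(x)
    flat = x.reshape(-1, x.shape[-1])
    oflat = out.reshape(-1, x.shape[-1])
    for i in range(flat.shape[0]):
        oflat[i] = np.convolve(flat[i], kernel, mode="same")
    return out


def gen_timeseries(
    traits: pd.DataFrame, design: SynthDesign
) -> tuple[list[SubjectTimeSeries], np.ndarray]:
    """Generate trait-coupled multi-subject time series with ground truth.

    Returns ``(dataset, expected_isc)`` where ``expected_isc`` is the n × n
    matrix of analytic pairwise correlations of the uncensored generative
    model (identical for every unit):

        rho_ij = (a² + w_i w_j) / sqrt((a² + w_i² + s²)(a² + w_j² + s²)).

    Because all components share the smoothing kernel, this value is exact
    whether or not smoothing is on; censoring (zeros) attenuates empirical
    correlations slightly at high censor rates.
    """
    n = design.n_subjects
    if len(traits) != n:
        raise ValueError(
            f"design expects {n} subjects but trait table has {len(traits)}"
        )
    rng = np.random.default_rng(design.seed)
    a, s = design.shared_amp, design.noise_sd
    w = np.clip(np.asarray(design.coupling_fn(traits["trait_score"].to_numpy()),
                           dtype=float), 0.0, 1.0)

    c = _smooth_rows(rng.standard_normal((design.n_units, design.n_tr)),
                     design.smooth_window)
    d = _smooth_rows(rng.standard_normal((design.n_units, design.n_tr)),
                     design.smooth_window)

    dataset = []
    for i, sid in enumerate(traits["subject_id"]):
        noise = _smooth_rows(
            rng.standard_normal((design.n_units, design.n_tr)), design.smooth_window
        )
        data = a * c + w[i] * d + s * noise
        retained = rng.random(design.n_tr) >= design.censor_rate
        data[:, ~retained] = 0.0
        dataset.append(
            SubjectTimeSeries(sid, data, retained, design.tr_seconds)
        )

    var = a**2 + w**2 + s**2
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = (a**2 + np.outer(w, w)) / np.sqrt(np.outer(var, var))
    np.fill_diagonal(expected, 1.0)
    return dataset, expected


def gen_annotations(
    n_sentences: int,
    n_raters: int = 5,
    base_rate: float = 0.25,
    agreement: float = 0.9,
    durations: Sequence[int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate sentence-level rater annotations with tunable agreement.

    Each sentence carries a latent binary truth drawn at ``base_rate``; each
    rater reports the truth with probability ``agreement`` and its flip
    otherwise. Sentences are laid out contiguously in TR space so offset TRs
    are strictly increasing; they are split into three story parts.

    Returns columns ``sentence_id, part, onset_tr, offset_tr, latent,
    rater_1..rater_k``.
    """
    if n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    for name, p in (("base_rate", base_rate), ("agreement", agreement)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if durations is None:
        durations = rng.integers(3, 11, size=n_sentences)
    durations = np.asarray(durations, dtype=int)
    if durations.shape != (n_sentences,):
        raise ValueError("durations must have one span per sentence")
    if np.any(durations < 1):
        raise ValueError(
            "every sentence must span at least one TR (offsets must increase)"
        )

    offsets = np.cumsum(durations)
    onsets = offsets - durations + 1
    latent = rng.random(n_sentences) < base_rate
    agree = rng.random((n_sentences, n_raters)) < agreement
    labels = np.where(agree, latent[:, None], ~latent[:, None]).astype(int)

    thirds = np.array_split(np.arange(n_sentences), 3)
    part = np.empty(n_sentences, dtype=int)
    for k, idx in enumerate(thirds, start=1):
        part[idx] = k

    table = pd.DataFrame(
        {
            "sentence_id": [f"s{i + 1:03d}" for i in range(n_sentences)],
            "part": part,
            "onset_tr": onsets,
            "offset_tr": offsets,
            "latent": latent.astype(int),
        }
    )
    for r in range(n_raters):
        table[f"rater_{r + 1}"] = labels[:, r]
    return table


def gen_speech_features(
    traits: pd.DataFrame,
    n_features: int = 67,
    loading_vector: Sequence[float] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a subjects × features matrix with a planted trait component.

    The matrix is ``column_offsets + outer(latent, loading_vector) + noise``
    with ``latent`` the z-scored trait score, emulating word-category
    percentage tables whose columns live on very different scales. When
    ``loading_vector`` is None a random direction of norm sqrt(n_features)/2
    is planted (seeded).
    """
    n = len(traits)
    rng = np.random.default_rng(seed)
    if loading_vector is None:
        loading_vector = rng.standard_normal(n_features)
        loading_vector *= 0.5 * np.sqrt(n_features) / np.linalg.norm(loading_vector)
    loading_vector = np.asarray(loading_vector, dtype=float)
    if loading_vector.shape != (n_features,):
        raise ValueError("loading_vector length must equal n_features")

    score = traits["trait_score"].to_numpy(dtype=float)
    sd = score.std(ddof=1)
    latent = (score - score.mean()) / sd if sd > 0 else np.zeros(n)

    base = rng.standard_normal(n_features)[None, :]
    matrix = base + np.outer(latent, loading_vector)
    matrix = matrix + noise_sd * rng.standard_normal((n, n_features))
    return pd.DataFrame(
        matrix,
        index=pd.Index(traits["subject_id"], name="subject_id"),
        columns=[f"feat_{j + 1:02d}" for j in range(n_features)],
    )


def gen_roi_responses(
    traits: pd.DataFrame,
    regressor: np.ndarray,
    mode: str = "trait_scaled",
    amplitude: float = 1.0,
    between_sd: float = 0.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one ROI's per-subject time courses as gain × regressor + noise.

    ``mode`` sets how the true gain depends on the trait:

    * ``trait_scaled`` — gain rises linearly with trait rank, from 0 to
      ``amplitude`` (a region whose event response scales with the trait);
    * ``uniform`` — every subject responds with gain ``amplitude`` (a region
      engaged by the events regardless of trait);
    * ``none`` — gain 0 (a region blind to the events).

    ``between_sd`` adds subject-level gain jitter. Returns
    ``(true_gains, series)`` with series shape (n_subjects, n_tr).
    """
    if mode not in ("trait_scaled", "uniform", "none"):
        raise ValueError("mode must be trait_scaled, uniform, or none")
    rng = np.random.default_rng(seed)
    n = len(traits)
    regressor = np.asarray(regressor, dtype=float)
    rank = traits["trait_score"].rank(method="average").to_numpy()
    if mode == "trait_scaled":
        gains = amplitude * (rank - 1) / (n - 1)
    elif mode == "uniform":
        gains = np.full(n, float(amplitude))
    else:
        gains = np.zeros(n)
    gains = gains + between_sd * rng.standard_normal(n)
    series = gains[:, None] * regressor[None, :]
    series = series + noise_sd * rng.standard_normal((n, regressor.size))
    return gains, series
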