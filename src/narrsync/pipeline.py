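"""End-to-end orchestration: synthesize-or-load → ISC → inference → events
→ behavior, with file-based handoff between stages.

Every stage reads its inputs from, and writes its outputs to, a single run
directory, so stages can be executed standalone (the CLI subcommands) or in
sequence (:func:`run_pipeline`). Thresholds default to the conventional
values for this analysis family: voxelwise FDR q = 0.001 for the one-group
map, initial p = 0.002 with a 50-voxel extent for cluster correction of the
group contrasts, ≥3-of-5 rater consensus for events, 4 mm sphere ROIs.

A run is deterministic given its config and seed; the resolved config, a
per-stage report, and a file manifest are written alongside the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import behavior as bh
from . import events as ev
from . import inference as inf
from . import synthetic as syn
from .isc import fisher_z, median_isc, pair_table, pairwise_isc
from .util import n_pairs

__all__ = [
    "RunConfig",
    "RunReport",
    "run_pipeline",
    "save_timeseries",
    "save_timeseries_nifti",
    "load_timeseries",
    "write_results",
    "stage_simulate",
    "stage_isc",
    "stage_infer",
    "stage_events",
    "stage_behavior",
]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (paper-convention defaults)."""

    # cohort / synthesis
    n_subjects: int = 22
    n_units: int = 12
    n_tr: int = 1310
    tr_seconds: float = 1.0
    trait_skew: float = 4.6
    shared_amp: float = 0.5
    noise_sd: float = 0.5
    censor_rate: float = 0.02
    smooth_window: int = 5
    # annotations
    n_sentences: int = 60
    n_raters: int = 5
    base_rate: float = 0.25
    agreement: float = 0.9
    min_raters: int = 3
    # inference thresholds
    fdr_q: float = 0.001
    p_init: float = 0.002
    cluster_extent: int = 50
    sphere_radius_mm: float = 4.0
    # behavior
    n_features: int = 67
    n_pls_components: int = 10
    # run control
    seed: int = 0
    outdir: str = "results/run"
    overwrite: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    """Per-stage provenance and counts for one pipeline run."""

    config: dict
    counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    stages: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "counts": self.counts,
            "warnings": self.warnings,
            "stages": self.stages,
        }


# ---------------------------------------------------------------------------
# array-archive and NIfTI I/O
# ---------------------------------------------------------------------------

def save_timeseries(dataset: Sequence[syn.SubjectTimeSeries],
                    path: str | Path) -> None:
    """Write a dataset as a compressed array archive with a JSON sidecar
    (subject ids, TR seconds) next to it."""
    path = Path(path)
    arrays = {}
    for sts in dataset:
        arrays[sts.subject_id] = sts.data
        arrays[f"{sts.subject_id}__censor"] = sts.censor_mask
    np.savez_compressed(path, **arrays)
    sidecar = {
        "subject_ids": [sts.subject_id for sts in dataset],
        "tr_seconds": dataset[0].tr_seconds,
        "n_units": dataset[0].n_units,
        "n_tr": dataset[0].n_tr,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def save_timeseries_nifti(dataset: Sequence[syn.SubjectTimeSeries],
                          outdir: str | Path,
                          grid_shape: tuple[int, int, int],
                          affine: np.ndarray | None = None) -> None:
    """Write each subject as a 4-D NIfTI volume (units raveled onto
    ``grid_shape`` in C order) plus a per-subject censor TSV."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.eye(4)
    for sts in dataset:
        if sts.n_units != int(np.prod(grid_shape)):
            raise ValueError(
                f"subject {sts.subject_id}: {sts.n_units} units do not fill "
                f"grid {grid_shape}"
            )
        vol = sts.data.reshape(*grid_shape, sts.n_tr)
        img = nib.Nifti1Image(vol, affine)
        img.header.set_zooms((*np.linalg.norm(affine[:3, :3], axis=0),
                              sts.tr_seconds))
        nib.save(img, str(outdir / f"{sts.subject_id}.nii"))
        pd.DataFrame({"retained": sts.censor_mask.astype(int)}).to_csv(
            outdir / f"{sts.subject_id}_censor.tsv", sep="\t", index=False
        )


def load_timeseries(path: str | Path,
                    mask_path: str | Path | None = None
                    ) -> list[syn.SubjectTimeSeries]:
    """Load a dataset from an array archive (+ sidecar) or a directory of
    per-subject NIfTI 4-D volumes.

    For NIfTI input all subjects must share grid shape and affine (an error
    names the offending subjects otherwise); an optional NIfTI mask selects
    the units (voxels, raveled in C order). Censor masks default to
    all-retained when absent.
    """
    path = Path(path)
    if path.is_dir():
        return _load_nifti_dir(path, mask_path)
    archive = np.load(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    dataset = []
    for sid in sidecar["subject_ids"]:
        data = archive[sid]
        key = f"{sid}__censor"
        mask = archive[key].astype(bool) if key in archive.files \
            else np.ones(data.shape[1], dtype=bool)
        dataset.append(
            syn.SubjectTimeSeries(sid, data, mask, sidecar["tr_seconds"])
        )
    return dataset


def _load_nifti_dir(path: Path, mask_path) -> list[syn.SubjectTimeSeries]:
    import nibabel as nib

    files = sorted(path.glob("*.nii")) + sorted(path.glob("*.nii.gz"))
    if not files:
        raise ValueError(f"no NIfTI files found in {path}")
    imgs = [(f.name.split(".")[0], nib.load(str(f))) for f in files]
    ref_sid, ref = imgs[0]
    mismatched = [
        sid for sid, img in imgs[1:]
        if img.shape[:3] != ref.shape[:3]
        or not np.allclose(img.affine, ref.affine)
    ]
    if mismatched:
        raise ValueError(
            f"grid/affine mismatch between {ref_sid} and {mismatched}"
        )
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj).astype(bool)
        if mask.shape != ref.shape[:3]:
            raise ValueError("mask grid does not match the data grid")
        flat = mask.reshape(-1)
    else:
        flat = None
    tr = float(ref.header.get_zooms()[3]) if len(ref.header.get_zooms()) > 3 else 1.0
    dataset = []
    for sid, img in imgs:
        vol = np.asarray(img.dataobj, dtype=float)
        units = vol.reshape(-1, vol.shape[3])
        if flat is not None:
            units = units[flat]
        censor_tsv = path / f"{sid}_censor.tsv"
        if censor_tsv.exists():
            mask_tr = pd.read_csv(censor_tsv, sep="\t")["retained"].to_numpy(bool)
        else:
            mask_tr = np.ones(units.shape[1], dtype=bool)
        dataset.append(syn.SubjectTimeSeries(sid, units, mask_tr, tr))
    return dataset


# ---------------------------------------------------------------------------
# results directory handling
# ---------------------------------------------------------------------------

def _prepare_outdir(cfg: RunConfig) -> Path:
    outdir = Path(cfg.outdir)
    if outdir.exists() and any(outdir.iterdir()) and not cfg.overwrite:
        raise FileExistsError(
            f"output directory {outdir} is not empty; pass overwrite to reuse it"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    return outdir


def write_results(bundle: dict, outdir: str | Path,
                  overwrite: bool = False) -> list[str]:
    """Write a bundle of tables/dicts/arrays and a manifest enumerating
    every file produced. Keys become filenames; DataFrames go to TSV, dicts
    to JSON."""
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite to replace")
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            fname = f"{name}.tsv"
            obj.to_csv(outdir / fname, sep="\t", index=False)
        elif isinstance(obj, (dict, list)):
            fname = f"{name}.json"
            (outdir / fname).write_text(json.dumps(obj, indent=2, default=float))
        elif isinstance(obj, np.ndarray):
            fname = f"{name}.tsv"
            np.savetxt(outdir / fname, obj, delimiter="\t")
        else:
            raise TypeError(f"cannot serialize bundle entry {name!r}")
        written.append(fname)
    manifest_path.write_text(json.dumps({"files": sorted(written)}, indent=2))
    return written


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, outdir: Path, report: RunReport) -> dict:
    traits = syn.gen_trait_scores(cfg.n_subjects, skew=cfg.trait_skew,
                                  seed=cfg.seed)
    design = syn.SynthDesign(
        n_subjects=cfg.n_subjects, n_units=cfg.n_units, n_tr=cfg.n_tr,
        tr_seconds=cfg.tr_seconds, shared_amp=cfg.shared_amp,
        noise_sd=cfg.noise_sd, censor_rate=cfg.censor_rate,
        smooth_window=cfg.smooth_window, seed=cfg.seed + 1,
    )
    dataset, expected = syn.gen_timeseries(traits, design)
    ann = syn.gen_annotations(cfg.n_sentences, cfg.n_raters, cfg.base_rate,
                              cfg.agreement, seed=cfg.seed + 2)
    feats = syn.gen_speech_features(traits, cfg.n_features, seed=cfg.seed + 3)

    traits.to_csv(outdir / "traits.tsv", sep="\t", index=False)
    ann.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    feats.reset_index().to_csv(outdir / "features.tsv", sep="\t", index=False)
    save_timeseries(dataset, outdir / "timeseries.npz")
    np.savetxt(outdir / "expected_isc.tsv", expected, delimiter="\t")

    report.stages.append("simulate")
    report.counts.update(
        n_subjects=cfg.n_subjects,
        n_units=cfg.n_units,
        n_tr=cfg.n_tr,
        n_censored_frames=int(sum((~s.censor_mask).sum() for s in dataset)),
    )
    return {"traits": traits, "dataset": dataset, "annotations": ann,
            "features": feats}


def stage_isc(cfg: RunConfig, outdir: Path, report: RunReport,
              state: dict | None = None) -> dict:
    if state is None or "dataset" not in state:
        dataset = load_timeseries(outdir / "timeseries.npz")
        state = dict(state or {}, dataset=dataset)
    isc = pairwise_isc(state["dataset"])
    subject_ids = [s.subject_id for s in state["dataset"]]
    pairs = pair_table(isc, subject_ids)
    pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
    med = np.stack([median_isc(m) for m in isc])
    med_df = pd.DataFrame(med.T, index=pd.Index(subject_ids, name="subject_id"),
                          columns=[f"unit_{v:04d}" for v in range(isc.shape[0])])
    med_df.reset_index().to_csv(outdir / "median_isc.tsv", sep="\t", index=False)
    report.stages.append("isc")
    report.counts["n_pairs"] = n_pairs(len(subject_ids))
    state.update(isc=isc, subject_ids=subject_ids)
    return state


def stage_infer(cfg: RunConfig, outdir: Path, report: RunReport,
                state: dict | None = None) -> dict:
    if state is None or "isc" not in state:
        state = stage_isc(cfg, outdir, RunReport(cfg.to_dict()), state)
    if "traits" not in state:
        state["traits"] = pd.read_csv(outdir / "traits.tsv", sep="\t")
    traits = state["traits"]
    isc = state["isc"]
    z = fisher_z(isc)
    groups = inf.median_split(traits)
    labels = groups.set_index("subject_id").loc[state["subject_ids"], "group"].to_numpy()

    one = inf.fit_lme_map(z)
    try:
        two = inf.fit_lme_map(z, labels)
    except ValueError as err:
        # degenerate split (a group with <2 subjects): one-group map only
        warnings.warn(f"skipping two-group inference: {err}")
        two = None
    fdr_one = inf.voxelwise_fdr(one["pvalues"]["b0"], q=cfg.fdr_q)

    rows = []
    for v in range(isc.shape[0]):
        row = {
            "unit_id": f"unit_{v:04d}",
            "b0": one["fixed_effects"][0, v],
            "b0_p": one["pvalues"]["b0"][v],
            "b0_q": fdr_one.qvalues[v],
        }
        if two is not None:
            row.update(
                G11=two["fixed_effects"][0, v],
                G22=two["fixed_effects"][1, v],
                G12=two["fixed_effects"][2, v],
            )
            for cname in inf.TWO_GROUP_CONTRASTS:
                row[f"{cname}_est"] = two["estimates"][cname][v]
                row[f"{cname}_p"] = two["pvalues"][cname][v]
        rows.append(row)
    lme_df = pd.DataFrame(rows)
    lme_df.to_csv(outdir / "lme_results.tsv", sep="\t", index=False)
    groups.to_csv(outdir / "groups.tsv", sep="\t", index=False)

    med = np.stack([median_isc(m) for m in isc])
    posthoc = []
    for v in range(isc.shape[0]):
        try:
            rho, p = inf.isc_rank_posthoc(med[v], traits)
        except ValueError as err:
            warnings.warn(f"skipping rank post-hoc: {err}")
            break
        posthoc.append({"unit_id": f"unit_{v:04d}", "rho": rho, "p": p})
    pd.DataFrame(posthoc).to_csv(outdir / "rank_posthoc.tsv", sep="\t", index=False)

    report.stages.append("infer")
    report.counts["n_fdr_significant"] = int(fdr_one.reject.sum())
    state.update(groups=groups, labels=labels, lme=lme_df)
    return state


def stage_events(cfg: RunConfig, outdir: Path, report: RunReport,
                 state: dict | None = None) -> dict:
    state = state or {}
    if "annotations" not in state:
        state["annotations"] = pd.read_csv(outdir / "annotations.tsv", sep="\t")
    if "traits" not in state:
        state["traits"] = pd.read_csv(outdir / "traits.tsv", sep="\t")
    if "groups" not in state:
        state["groups"] = pd.read_csv(outdir / "groups.tsv", sep="\t")
    ann, traits, groups = state["annotations"], state["traits"], state["groups"]

    evset = ev.consensus_events(ann, min_raters=cfg.min_raters)
    regressors = {}
    for which in ("mentalizing", "inverse"):
        regressors[which] = ev.build_regressor(
            evset, ann, n_tr=cfg.n_tr, tr_seconds=cfg.tr_seconds,
            mode="offset", which=which,
        )
    pd.DataFrame(regressors).to_csv(outdir / "regressors.tsv", sep="\t",
                                    index=False)

    roi_specs = {
        "tmp_pole_like": ("trait_scaled", 2.0),
        "mpfc_like": ("trait_scaled", 2.0),
        "tpj_like": ("uniform", 1.0),
        "heschl_like": ("none", 0.0),
    }
    rows = []
    for k, (roi, (roi_mode, amp)) in enumerate(roi_specs.items()):
        _, series = syn.gen_roi_responses(
            traits, regressors["mentalizing"], mode=roi_mode, amplitude=amp,
            between_sd=0.25, noise_sd=2.0, seed=cfg.seed + 10 + k,
        )
        for which, reg in regressors.items():
            for i, sid in enumerate(traits["subject_id"]):
                res = ev.fit_roi_glm(series[i], reg)
                rows.append({"subject_id": sid, "roi": roi, "mode": which,
                             "beta": res.beta})
    betas = pd.DataFrame(rows)
    betas.to_csv(outdir / "roi_betas.tsv", sep="\t", index=False)
    try:
        tests = ev.group_beta_tests(betas, groups, fdr_q=0.05,
                                    pooled_rois=("tpj_like", "heschl_like"))
        tests.to_csv(outdir / "beta_tests.tsv", sep="\t", index=False)
    except ValueError as err:
        warnings.warn(f"skipping group beta tests: {err}")
    try:
        ranks = ev.beta_rank_correlation(betas, traits)
        ranks.to_csv(outdir / "beta_rank_corr.tsv", sep="\t", index=False)
    except ValueError as err:
        warnings.warn(f"skipping beta rank correlations: {err}")

    report.stages.append("events")
    report.counts["n_consensus_events"] = evset.n_events
    state.update(events=evset, betas=betas)
    return state


def stage_behavior(cfg: RunConfig, outdir: Path, report: RunReport,
                   state: dict | None = None) -> dict:
    state = state or {}
    if "features" not in state:
        state["features"] = pd.read_csv(outdir / "features.tsv", sep="\t"
                                        ).set_index("subject_id")
    if "traits" not in state:
        state["traits"] = pd.read_csv(outdir / "traits.tsv", sep="\t")
    if "groups" not in state:
        state["groups"] = pd.read_csv(outdir / "groups.tsv", sep="\t")
    feats, traits, groups = state["features"], state["traits"], state["groups"]

    Xz = bh.zscore_features(feats)
    y = traits["trait_score"].to_numpy(dtype=float)
    fit = bh.plsr_fit(Xz, y, n_components=cfg.n_pls_components)
    loadings = bh.component_loadings(fit, 1)
    loadings.rename("loading").reset_index().rename(
        columns={"index": "feature"}
    ).to_csv(outdir / "pls_loadings.tsv", sep="\t", index=False)
    varexp = {
        "per_component": fit.pctvar_y.tolist(),
        "cumulative": fit.cumulative_pctvar_y.tolist(),
    }
    (outdir / "pls_varexp.json").write_text(json.dumps(varexp, indent=2))
    confounds = bh.screen_confounds(traits, groups)
    confounds.to_csv(outdir / "confounds.tsv", sep="\t", index=False)

    report.stages.append("behavior")
    report.counts["pls_component1_pctvar"] = float(fit.pctvar_y[0]) \
        if fit.n_components else 0.0
    state.update(pls=fit)
    return state


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute all stages in order into ``cfg.outdir``; identical config and
    seed reproduce byte-identical result tables."""
    outdir = _prepare_outdir(cfg)
    report = RunReport(config=cfg.to_dict())
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        state = stage_simulate(cfg, outdir, report)
        state = stage_isc(cfg, outdir, report, state)
        state = stage_infer(cfg, outdir, report, state)
        state = stage_events(cfg, outdir, report, state)
        state = stage_behavior(cfg, outdir, report, state)
    report.warnings = sorted({str(w.message) for w in caught})
    (outdir / "config.json").write_text(json.dumps(cfg.to_dict(), indent=2))
    (outdir / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    files = sorted(
        p.name for p in outdir.iterdir()
        if p.is_file() and p.name != "manifest.json"
    )
    (outdir / "manifest.json").write_text(json.dumps({"files": files}, indent=2))
    return report
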