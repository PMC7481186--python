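"""Configuration-driven orchestration of the full analysis.

``run_pipeline`` executes the enabled stages in dependency order —
simulate -> preprocess -> decode -> rsa -> models -> stats -> fusion ->
report — entirely from one hierarchical config, writing tidy CSV
artifacts, a JSON summary with provenance (config hash, seed, package
version), and a stage log.  One master seed deterministically derives
every stage seed, so re-running an identical config reproduces identical
numeric outputs.

The default config runs the synthetic experiment at desk scale (a few
subjects, reduced exemplar counts and time grid); every knob scales up
to the full empirical design.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import CATEGORIES, ValidationError, make_stimulus_set
from .decoding import decode_roi, decode_timecourse
from .image_models import behavioral_rdm, gist_features, model_rdm, saliency_features
from .io import write_rdm, write_stimulus_manifest
from .preprocess import downsample, pca_reduce
from .rsa import (
    category_average,
    fusion_timecourse,
    mean_rdm,
    model_correlation_timecourse,
    noise_ceiling,
    rdm_timecourse,
)
from .stats import (
    adjust_pvalues,
    significant_windows,
    tfce_signperm_inference,
    ttest_vs_chance,
)
from .synth import (
    RatingConfig,
    SyntheticMEGConfig,
    default_roi_profiles,
    default_trajectory,
    generate_fmri_dataset,
    generate_meg_dataset,
    generate_ratings,
    generate_stimulus_images,
)

ALL_STAGES = (
    "simulate", "preprocess", "decode", "rsa", "models", "stats", "fusion", "report",
)

PAIRS = (
    ("human_face", "illusory_face"),
    ("human_face", "matched_object"),
    ("illusory_face", "matched_object"),
)


def default_config() -> dict:
    """Desk-scale defaults exercising every stage of the analysis."""
    return {
        "seed": 0,
        "stages": list(ALL_STAGES),
        "synth": {
            "meg": {
                "n_subjects": 8,
                "n_channels": 48,
                "n_exemplars_per_category": 8,
                "n_runs": 2,
                "repeats_per_run": 6,
                "sample_rate_hz": 100.0,
                "epoch_ms": [-100.0, 390.0],
                "sensor_noise_sd": 1.0,
                "signal_gain": 1.0,
            },
            "fmri": {"n_subjects": 12, "n_runs": 5, "n_exemplars_per_category": 8},
            "ratings": {"n_raters": 20},
        },
        "preprocess": {"downsample_to_hz": None, "pca_var_retained": 0.99},
        "decode": {"scheme": "paired_exemplar", "classifier": "lda", "shrinkage": 0.05},
        "rsa": {"keyframe_times_ms": [130.0, 160.0, 260.0]},
        "models": {"behavior": True, "image_models": False},
        "stats": {"n_perm": 500, "alpha": 0.05, "tail": "one"},
        "fusion": {"enabled": True},
        "report": {},
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    unknown = set(cfg["stages"]) - set(ALL_STAGES)
    if unknown:
        raise ValidationError(f"stages: unknown stage(s) {sorted(unknown)}")
    return cfg


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministically derive a per-stage seed from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def _require_stage(bundle: dict, key: str, needed_by: str, producer: str) -> None:
    if key not in bundle:
        raise ValidationError(
            f"stage {needed_by!r}: missing upstream artifact {key!r}; "
            f"run stage {producer!r} first"
        )


def run_pipeline(config: dict | None = None, out_dir: str | Path = "results") -> dict:
    """Execute the enabled stages; return the in-memory results bundle.

    Artifacts are written under ``out_dir``; every CSV row carries
    subject/stage/scheme provenance columns, and ``summary.json``
    records the config hash, master seed and stage wall times.
    """
    config = config or default_config()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = list(config["stages"])
    master = int(config["seed"])
    bundle: dict = {"config": config}
    log_lines: list[str] = []
    timings: dict[str, float] = {}

    def log(msg: str) -> None:
        log_lines.append(msg)

    for stage in ALL_STAGES:
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        _STAGE_FNS[stage](bundle, config, master, out_dir, log)
        timings[stage] = round(time.perf_counter() - t0, 3)
        log(f"stage {stage}: done in {timings[stage]} s")

    summary = {
        "config_hash": _config_hash(config),
        "seed": master,
        "version": __version__,
        "stages_run": [s for s in ALL_STAGES if s in stages],
        "stage_wall_time_s": timings,
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    (out_dir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    bundle["summary"] = summary
    return bundle


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(bundle, config, master, out_dir, log) -> None:
    synth_cfg = config["synth"]
    meg_kwargs = dict(synth_cfg["meg"])
    meg_kwargs["epoch_ms"] = tuple(meg_kwargs.get("epoch_ms", (-100.0, 1000.0)))
    meg_cfg = SyntheticMEGConfig(**meg_kwargs, seed=stage_seed(master, "simulate.meg"))
    traj = default_trajectory()
    bundle["trajectory"] = traj
    bundle["meg"] = generate_meg_dataset(meg_cfg, traj)
    bundle["meg_config"] = meg_cfg
    log(f"simulate: MEG {meg_cfg.n_subjects} subjects x {meg_cfg.n_trials} trials")

    fmri_kwargs = dict(synth_cfg["fmri"])
    fmri_data, stimuli_fmri = generate_fmri_dataset(
        **fmri_kwargs, seed=stage_seed(master, "simulate.fmri")
    )
    bundle["fmri"] = fmri_data
    bundle["fmri_stimuli"] = stimuli_fmri
    log(f"simulate: fMRI {len(fmri_data)} subjects x {len(fmri_data[0])} ROIs")

    stimuli = make_stimulus_set(meg_cfg.n_exemplars_per_category)
    bundle["stimuli"] = stimuli
    write_stimulus_manifest(stimuli, out_dir / "manifest.csv")

    rating_cfg = RatingConfig(
        **synth_cfg.get("ratings", {}),
        n_exemplars_per_category=meg_cfg.n_exemplars_per_category,
        seed=stage_seed(master, "simulate.ratings"),
    )
    bundle["ratings"] = generate_ratings(rating_cfg, stimuli)


def _stage_preprocess(bundle, config, master, out_dir, log) -> None:
    _require_stage(bundle, "meg", "preprocess", "simulate")
    pcfg = config["preprocess"]
    processed = []
    for ep in bundle["meg"]:
        if pcfg.get("downsample_to_hz"):
            ep = downsample(ep, float(pcfg["downsample_to_hz"]))
        ep = pca_reduce(ep, float(pcfg.get("pca_var_retained", 0.99)))
        processed.append(ep)
    bundle["meg_proc"] = processed
    log(f"preprocess: {processed[0].n_channels} components retained (subject 0)")


def _stage_decode(bundle, config, master, out_dir, log) -> None:
    _require_stage(bundle, "meg_proc", "decode", "preprocess")
    dcfg = config["decode"]
    clf_kwargs = (
        {"shrinkage": float(dcfg.get("shrinkage", 0.05))}
        if dcfg.get("classifier", "lda") == "lda"
        else {}
    )
    results = {}
    frames = []
    for pair in PAIRS:
        res = decode_timecourse(
            bundle["meg_proc"], bundle["stimuli"], pair,
            scheme=dcfg.get("scheme", "paired_exemplar"),
            classifier=dcfg.get("classifier", "lda"), **clf_kwargs,
        )
        results[pair] = res
        frames.append(res.to_frame())
    bundle["decoding"] = results
    pd.concat(frames).to_csv(out_dir / "decoding_timecourse.csv", index=False)

    roi_results = {}
    roi_frames = []
    for pair in PAIRS:
        res = decode_roi(bundle["fmri"], bundle["fmri_stimuli"], pair)
        roi_results[pair] = res
        roi_frames.append(res.to_frame())
    bundle["roi_decoding"] = roi_results
    pd.concat(roi_frames).to_csv(out_dir / "roi_decoding.csv", index=False)
    log(f"decode: {len(results)} MEG pairs, {len(roi_results)} ROI pairs")


def _stage_rsa(bundle, config, master, out_dir, log) -> None:
    _require_stage(bundle, "meg_proc", "rsa", "preprocess")
    tc = rdm_timecourse(bundle["meg_proc"])
    bundle["rdm_timecourse"] = tc
    cats = [bundle["stimuli"].category_of(s) for s in tc.labels]
    for t_ms in config["rsa"].get("keyframe_times_ms", []):
        t_idx = int(np.argmin(np.abs(tc.times_ms - t_ms)))
        grp = tc.group_rdm(t_idx)
        write_rdm(grp, out_dir / f"rdm_group_{int(tc.times_ms[t_idx])}ms.csv")
        avg = category_average(grp, cats)
        pd.DataFrame(avg.matrix, index=avg.labels, columns=avg.labels).to_csv(
            out_dir / f"rdm_category_{int(tc.times_ms[t_idx])}ms.csv"
        )
    log(f"rsa: {tc.values.shape[1]} timepoints x {len(tc.labels)} stimuli")


def _stage_models(bundle, config, master, out_dir, log) -> None:
    _require_stage(bundle, "rdm_timecourse", "models", "rsa")
    mcfg = config["models"]
    model_rdms = {}
    if mcfg.get("behavior", True):
        model_rdms["behavior"] = behavioral_rdm(bundle["ratings"])
    if mcfg.get("image_models", False):
        images = generate_stimulus_images(
            bundle["stimuli"], seed=stage_seed(master, "models.images")
        )
        model_rdms["gist"] = model_rdm(gist_features(images), "gist")
        model_rdms["saliency"] = model_rdm(saliency_features(images), "saliency")
    bundle["model_rdms"] = model_rdms
    rows = []
    corrs = {}
    for name, rdm in model_rdms.items():
        write_rdm(rdm, out_dir / f"rdm_model_{name}.csv")
        mc = model_correlation_timecourse(
            bundle["rdm_timecourse"], rdm, bundle["stimuli"], model_name=name
        )
        corrs[name] = mc
        for s in range(mc.tau.shape[0]):
            for t, tm in enumerate(mc.times_ms):
                rows.append(
                    {"model": name, "subject": f"meg-{s:02d}", "time_ms": tm,
                     "tau_a": mc.tau[s, t], "stage": "models"}
                )
    bundle["model_correlations"] = corrs
    pd.DataFrame(rows).to_csv(out_dir / "model_correlation.csv", index=False)
    log(f"models: {sorted(model_rdms)}")


def _stage_stats(bundle, config, master, out_dir, log) -> None:
    _require_stage(bundle, "decoding", "stats", "decode")
    scfg = config["stats"]
    n_perm = int(scfg.get("n_perm", 1000))
    alpha = float(scfg.get("alpha", 0.05))
    tail = scfg.get("tail", "one")
    seed = stage_seed(master, "stats")
    masks = {}
    rows = []
    for pair, res in bundle["decoding"].items():
        inf = tfce_signperm_inference(
            res.accuracy_percent - res.chance_percent,
            n_perm=n_perm, alpha=alpha, tail=tail, seed=seed,
        )
        name = f"{pair[0]}_vs_{pair[1]}"
        masks[name] = inf
        for t, tm in enumerate(res.axis_values):
            rows.append(
                {"comparison": name, "time_ms": tm,
                 "mean_accuracy": res.group_mean[t], "sem": res.group_sem[t],
                 "tfce": inf.observed_tfce[t], "z": inf.z_map[t],
                 "significant": bool(inf.significant[t])}
            )
    for name, mc in bundle.get("model_correlations", {}).items():
        inf = tfce_signperm_inference(
            mc.tau, n_perm=n_perm, alpha=alpha, tail=tail, seed=seed
        )
        masks[f"model_{name}"] = inf
        for t, tm in enumerate(mc.times_ms):
            rows.append(
                {"comparison": f"model_{name}", "time_ms": tm,
                 "mean_accuracy": mc.group_mean[t], "sem": mc.group_sem[t],
                 "tfce": inf.observed_tfce[t], "z": inf.z_map[t],
                 "significant": bool(inf.significant[t])}
            )
    bundle["stats"] = masks
    pd.DataFrame(rows).to_csv(out_dir / "stats_timecourses.csv", index=False)
    log(f"stats: TFCE sign-permutation on {len(masks)} timecourses")


def _stage_fusion(bundle, config, master, out_dir, log) -> None:
    if not config["fusion"].get("enabled", True):
        return
    _require_stage(bundle, "rdm_timecourse", "fusion", "rsa")
    _require_stage(bundle, "fmri", "fusion", "simulate")
    from .preprocess import stimulus_patterns  # noqa: F401  (doc pointer)
    from .core import PatternMatrix
    from .rsa import compute_rdm

    # group fMRI RDM per ROI from run-averaged betas
    fmri_rdms = {}
    rois = list(bundle["fmri"][0].keys())
    for roi in rois:
        subject_rdms = []
        for per_roi in bundle["fmri"]:
            stack = per_roi[roi]
            pat = PatternMatrix(stack.run_average(), stack.stimulus_ids, "voxels")
            subject_rdms.append(compute_rdm(pat))
        fmri_rdms[roi] = mean_rdm(subject_rdms)
    bundle["fmri_rdms"] = fmri_rdms

    fus = fusion_timecourse(fmri_rdms, bundle["rdm_timecourse"], bundle["stimuli"])
    bundle["fusion"] = fus
    scfg = config["stats"]
    rows = []
    inference = {}
    for roi, mc in fus.items():
        inf = tfce_signperm_inference(
            mc.tau, n_perm=int(scfg.get("n_perm", 1000)),
            alpha=float(scfg.get("alpha", 0.05)), tail=scfg.get("tail", "one"),
            seed=stage_seed(master, "fusion"),
        )
        inference[roi] = inf
        for t, tm in enumerate(mc.times_ms):
            rows.append(
                {"roi": roi, "time_ms": tm, "tau_a_mean": mc.group_mean[t],
                 "sem": mc.group_sem[t], "significant": bool(inf.significant[t])}
            )
    bundle["fusion_inference"] = inference
    pd.DataFrame(rows).to_csv(out_dir / "fusion.csv", index=False)
    log(f"fusion: {len(fus)} ROIs vs MEG timecourse")


def _stage_report(bundle, config, master, out_dir, log) -> None:
    _require_stage(bundle, "roi_decoding", "report", "decode")
    report = build_report(bundle)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    log("report: written report.json")


def build_report(bundle: dict) -> dict:
    """Summary tables: per-ROI group stats and significant-window listings."""
    report: dict = {"roi_decoding": [], "significant_windows": {}}
    roi_res = bundle["roi_decoding"]
    pvals, keys = [], []
    for pair, res in roi_res.items():
        for r_i, roi in enumerate(res.axis_values):
            tt = ttest_vs_chance(res.accuracy_percent[:, r_i], res.chance_percent)
            report["roi_decoding"].append(
                {"roi": roi, "comparison": f"{pair[0]}_vs_{pair[1]}",
                 "mean_accuracy": float(res.accuracy_percent[:, r_i].mean()),
                 "t": tt.t, "df": tt.df, "p": tt.p, "cohen_d": tt.cohen_d,
                 "ci_lower": tt.ci_lower}
            )
            pvals.append(tt.p)
            keys.append(len(report["roi_decoding"]) - 1)
    adjusted, reject = adjust_pvalues(np.array(pvals), "bh_fdr")
    for k, adj, rej in zip(keys, adjusted, reject):
        report["roi_decoding"][k]["p_fdr"] = float(adj)
        report["roi_decoding"][k]["significant_fdr"] = bool(rej)

    for name, inf in bundle.get("stats", {}).items():
        res = None
        for pair, r in bundle["decoding"].items():
            if name == f"{pair[0]}_vs_{pair[1]}":
                res = r
        times = (
            np.asarray(res.axis_values)
            if res is not None
            else bundle["rdm_timecourse"].times_ms
        )
        report["significant_windows"][name] = significant_windows(
            inf.significant, times
        )
    for roi, inf in bundle.get("fusion_inference", {}).items():
        report["significant_windows"][f"fusion_{roi}"] = significant_windows(
            inf.significant, bundle["fusion"][roi].times_ms
        )
    if "rdm_timecourse" in bundle and bundle["rdm_timecourse"].n_subjects >= 2:
        tc = bundle["rdm_timecourse"]
        t_idx = int(np.argmin(np.abs(tc.times_ms - 160.0)))
        rdms = [tc.subject_rdm(s, t_idx) for s in range(tc.n_subjects)]
        lower, upper = noise_ceiling(rdms)
        report["noise_ceiling_160ms"] = {"lower": lower, "upper": upper}
    return report


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "decode": _stage_decode,
    "rsa": _stage_rsa,
    "models": _stage_models,
    "stats": _stage_stats,
    "fusion": _stage_fusion,
    "report": _stage_report,
}
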