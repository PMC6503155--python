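"""End-to-end pipeline: configuration, orchestration and result files.

``run_pipeline`` reads a YAML config, obtains a cohort (simulated or from
files), and runs the four analyses:

1. parametric-intensity GLM (all stimuli + perceived-intensity modulator),
   second-level sign-flip test on the modulator effect;
2. five-condition GLM on intensity-matched trials, pain/tactile activation
   maps, union-masked difference maps, conjunction map;
3. region-wise model-free AUC comparison (paired sign-flip FWE);
4. intensity-mismatch comparison in modality-preferential regions after a
   pooled median split with count equalization.

All randomness derives from the config seed; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as coh
from . import glm as glm_mod
from . import io as pio
from . import perm as perm_mod
from . import timecourse as tc
from .matching import apply_match_labels, match_trials

logger = logging.getLogger(__name__)

__all__ = ["ConfigurationError", "load_config", "run_pipeline",
           "first_level_contrasts", "analysis2_second_level"]


class ConfigurationError(ValueError):
    pass


def load_config(config_path) -> dict:
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigurationError("config root must be a mapping")
    return cfg


def _cohort_config(cfg: dict) -> coh.CohortConfig:
    sim = dict(cfg.get("simulate") or {})
    sim.pop("enabled", None)
    seed = int(cfg.get("seed", 0))
    known = {f for f in coh.CohortConfig.__dataclass_fields__}
    unknown = set(sim) - known
    if unknown:
        raise ConfigurationError(f"unknown simulate keys: {sorted(unknown)}")
    if "grid_shape" in sim:
        sim["grid_shape"] = tuple(sim["grid_shape"])
    if "noise" in sim:
        nz = sim["noise"]
        if isinstance(nz, dict):
            if "drift_amplitudes" in nz:
                nz["drift_amplitudes"] = tuple(nz["drift_amplitudes"])
            sim["noise"] = coh.NoiseModel(**nz)
    if "region_effects" in sim and sim["region_effects"] is not None:
        sim["region_effects"] = [coh.RegionEffect(**e) for e in sim["region_effects"]]
    return coh.CohortConfig(seed=seed, **sim)


def _load_subjects(cfg: dict):
    """Load subject datasets and parcellation from configured file paths."""
    parc_path = cfg.get("parcellation")
    subs = cfg.get("subjects") or []
    if not subs:
        raise ConfigurationError("no subjects configured and simulate not enabled")
    datasets = []
    for i, sub in enumerate(subs):
        for key in ("bold", "events", "motion"):
            if key not in sub:
                raise ConfigurationError(f"subject {i}: missing {key!r}")
        bold = {int(s): pio.read_bold(p) for s, p in sub["bold"].items()}
        motion = {int(s): pio.read_motion(p) for s, p in sub["motion"].items()}
        events = pio.read_events(sub["events"])
        datasets.append(pio.SubjectDataset(bold=bold, events=events, motion=motion,
                                           subject_id=sub.get("id", f"sub-{i + 1:02d}")))
    shapes = {d.bold[s].shape[:3] for d in datasets for s in d.bold}
    if len(shapes) > 1:
        raise ConfigurationError(f"inconsistent grids across subjects: {shapes}")
    parcellation = pio.read_parcellation(parc_path) if parc_path else None
    return parcellation, datasets


def first_level_contrasts(subject: pio.SubjectDataset, tolerance: float = 0.5,
                          hp_cutoff_s: float = 128.0,
                          smooth_fwhm_mm: float = 0.0):
    """Fit both first-level GLMs for one subject.

    Returns dict with effect maps: ``intensity`` (parametric modulator),
    ``matched_pain``, ``matched_tactile``, ``difference`` (pain - tactile),
    plus the match result.
    """
    mres = match_trials(subject.events, tolerance)
    sessions = sorted(subject.bold)
    n_scans = {s: subject.bold[s].n_scans for s in sessions}
    tr = subject.tr
    # concatenate sessions along time for a single multi-session fit
    vols = [subject.bold[s] for s in sessions]
    if smooth_fwhm_mm > 0:
        vols = [pio.smooth_gaussian(v, smooth_fwhm_mm) for v in vols]
    data = np.concatenate([v.data for v in vols], axis=3)
    mask = np.logical_and.reduce([v.mask for v in vols])
    cat = pio.Volume4D(data=data, tr=tr, voxel_size=vols[0].voxel_size, mask=mask)
    motion = {s: subject.motion[s] for s in sessions}

    out = {"match": mres}
    d5 = glm_mod.build_design_5cond(subject.events, mres, n_scans, tr, motion,
                                    hp_cutoff_s)
    fit5 = glm_mod.fit_glm(cat, d5)
    out["matched_pain"] = glm_mod.contrast_map(fit5, {"matched_pain": 1.0})
    out["matched_tactile"] = glm_mod.contrast_map(fit5, {"matched_tactile": 1.0})
    out["difference"] = glm_mod.contrast_map(
        fit5, {"matched_pain": 1.0, "matched_tactile": -1.0})
    dp = glm_mod.build_design_parametric(subject.events, n_scans, tr, motion,
                                         hp_cutoff_s)
    fitp = glm_mod.fit_glm(cat, dp)
    try:
        out["intensity"] = glm_mod.contrast_map(fitp, {"intensity_modulator": 1.0})
    except ValueError:
        out["intensity"] = None
    return out


def analysis2_second_level(pain_maps, tactile_maps, diff_maps, mask,
                           cfg: perm_mod.PermConfig, level: str = "voxel"):
    """Group-level modality analysis: activation maps, union mask,
    union-masked difference tests (both directions) and conjunction map.

    ``level`` selects voxel- or cluster-extent FWE for the activation maps;
    difference maps are tested one-tailed in both directions inside the
    union of the two thresholded activation maps, which restricts both the
    statistic image and the max-statistic null.
    """
    from dataclasses import replace as _replace

    def _one(maps, tail, use_mask):
        c = _replace(cfg, tail=tail)
        if level == "voxel":
            res = perm_mod.one_sample_signflip(maps, use_mask, c)
            return res, res.sig_mask
        res = perm_mod.cluster_signflip(maps, use_mask, c)
        sig = np.isin(res.cluster_map,
                      [row["id"] for row in res.significant(cfg.alpha)])
        return res, sig
    pain_res, pain_sig = _one(pain_maps, "greater", mask)
    tact_res, tact_sig = _one(tactile_maps, "greater", mask)
    union = perm_mod.union_mask(pain_sig, tact_sig)
    conj = perm_mod.conjunction(pain_sig, tact_sig)
    out = {"pain": pain_res, "tactile": tact_res, "union_mask": union,
           "conjunction": conj, "pain_sig": pain_sig, "tactile_sig": tact_sig,
           "pain_gt_tactile": None, "tactile_gt_pain": None}
    if np.any(union):
        p_res, p_sig = _one(diff_maps, "greater", union)
        n_maps = [-m for m in diff_maps]
        t_res, t_sig = _one(n_maps, "greater", union)
        out["pain_gt_tactile"] = p_res
        out["tactile_gt_pain"] = t_res
        out["pain_gt_tactile_sig"] = p_sig
        out["tactile_gt_pain_sig"] = t_sig
    return out


def _write_statmap(values, mask, path, voxel_size=(1.0, 1.0, 1.0)):
    import nibabel as nib
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float64), affine), str(path))


def _write_cluster_table(res: perm_mod.ClusterFWEResult, path):
    rows = [{"cluster_id": r["id"], "size_voxels": r["size"],
             "peak_t": r["peak_t"],
             "peak_x": r["peak_voxel"][0], "peak_y": r["peak_voxel"][1],
             "peak_z": r["peak_voxel"][2], "p_fwe": r["p_fwe"]}
            for r in res.table]
    cols = ["cluster_id", "size_voxels", "peak_t", "peak_x", "peak_y", "peak_z", "p_fwe"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False,
                                            float_format="%.6g")


def _write_paired_result(res: perm_mod.PairedPermResult, path):
    pd.DataFrame({"region": res.region_ids, "mean_diff": res.mean_diff,
                  "t": res.t, "p_fwe": res.p_fwe}).to_csv(
        path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config_path, out_dir=None) -> Path:
    """Run the configured analyses end to end; returns the results directory."""
    cfg = load_config(config_path) if not isinstance(config_path, dict) else config_path
    out = Path(out_dir or cfg.get("out_dir", "results"))
    analyses = cfg.get("analyses") or {"analysis1": True, "analysis2": True,
                                       "analysis3": True, "analysis4": True}
    simulate = bool((cfg.get("simulate") or {}).get("enabled", bool(cfg.get("simulate"))))

    # --- validate before any computation
    if not simulate:
        if (analyses.get("analysis3") or analyses.get("analysis4")) and \
                not cfg.get("parcellation"):
            raise ConfigurationError("parcellation required for analysis3/analysis4")
        parcellation, subjects = _load_subjects(cfg)
        ccfg = None
    else:
        ccfg = _cohort_config(cfg)
        parcellation, subjects = coh.simulate_cohort(ccfg)

    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    pcfg_kw = dict(cfg.get("perm") or {})
    pcfg = perm_mod.PermConfig(seed=seed, **pcfg_kw)
    tolerance = float((cfg.get("matching") or {}).get("tolerance", 0.5))
    hp_cutoff = float((cfg.get("glm") or {}).get("hp_cutoff_s", 128.0))
    smooth_fwhm = float(cfg.get("smooth_fwhm_mm", 0.0))
    win_kw = cfg.get("window") or {}
    window = tc.TimecourseWindow(**win_kw)
    mask = np.logical_and.reduce(
        [s.bold[ses].mask for s in subjects for ses in s.bold])

    # --- first level (shared by analyses 1 and 2)
    firsts = []
    for subj in subjects:
        fl = first_level_contrasts(subj, tolerance, hp_cutoff, smooth_fwhm)
        firsts.append(fl)
        matched = apply_match_labels(subj.events, fl["match"])
        pio.write_events(matched, out / f"{subj.subject_id}_events_matched.tsv")
        for name in ("intensity", "matched_pain", "matched_tactile", "difference"):
            if fl[name] is not None:
                _write_statmap(fl[name].values, mask,
                               out / f"{subj.subject_id}_effect_{name}.nii.gz")

    log: dict = {"seed": seed, "n_subjects": len(subjects),
                 "tolerance": tolerance, "hp_cutoff_s": hp_cutoff,
                 "smooth_fwhm_mm": smooth_fwhm,
                 "perm": {"n_perm": pcfg.n_perm, "alpha": pcfg.alpha,
                          "cdt_p": pcfg.cdt_p, "connectivity": pcfg.connectivity},
                 "window": {"pre_s": window.pre_s, "post_s": window.post_s},
                 "simulated": simulate}
    if ccfg is not None:
        log["cohort"] = {"n_regions": ccfg.n_regions, "grid_shape": list(ccfg.grid_shape),
                         "tr_s": ccfg.tr_s, "sessions": ccfg.sessions,
                         "trials_per_session": ccfg.trials_per_session}

    if analyses.get("analysis1", True):
        maps = [f["intensity"].values for f in firsts if f["intensity"] is not None]
        if len(maps) >= 2:
            res = perm_mod.one_sample_signflip(maps, mask, pcfg)
            _write_statmap(res.observed_t, mask, out / "analysis1_intensity_t.nii.gz")
            _write_statmap(res.p_fwe, mask, out / "analysis1_intensity_pfwe.nii.gz")
            cres = perm_mod.cluster_signflip(maps, mask, pcfg)
            _write_cluster_table(cres, out / "analysis1_intensity_clusters.tsv")
            log["analysis1"] = {"n_sig_voxels": int(res.sig_mask.sum()),
                                "n_sig_clusters": len(cres.significant(pcfg.alpha))}

    a2 = None
    if analyses.get("analysis2", True):
        a2 = analysis2_second_level(
            [f["matched_pain"].values for f in firsts],
            [f["matched_tactile"].values for f in firsts],
            [f["difference"].values for f in firsts],
            mask, pcfg, level=str((cfg.get("perm") or {}).get("level", "voxel")))
        for name in ("pain", "tactile"):
            _write_statmap(a2[name].observed_t, mask, out / f"analysis2_{name}_t.nii.gz")
        _write_statmap(a2["union_mask"].astype(np.int16), mask,
                       out / "analysis2_union_mask.nii.gz")
        _write_statmap(a2["conjunction"].astype(np.int16), mask,
                       out / "analysis2_conjunction.nii.gz")
        log["analysis2"] = {
            "n_pain_sig": int(a2["pain_sig"].sum()),
            "n_tactile_sig": int(a2["tactile_sig"].sum()),
            "n_union": int(a2["union_mask"].sum()),
            "n_conjunction": int(a2["conjunction"].sum()),
        }
        for direction in ("pain_gt_tactile", "tactile_gt_pain"):
            if a2[direction] is not None:
                sig = a2[f"{direction}_sig"]
                _write_statmap(sig.astype(np.int16), mask,
                               out / f"analysis2_{direction}_sig.nii.gz")
                log["analysis2"][f"n_{direction}"] = int(sig.sum())

    a3 = None
    if analyses.get("analysis3", True):
        if parcellation is None:
            raise ConfigurationError("parcellation required")
        a3 = tc.analysis3(subjects, parcellation, pcfg, window, tolerance)
        a3.auc_table.to_csv(out / "analysis3_auc.tsv", sep="\t", index=False,
                            float_format="%.6g")
        for name, res in a3.results.items():
            _write_paired_result(res, out / f"analysis3_{name}.tsv")
        log["analysis3"] = {name: res.significant(pcfg.alpha)
                            for name, res in a3.results.items()}

    if analyses.get("analysis4", True):
        if parcellation is None:
            raise ConfigurationError("parcellation required")
        a4cfg = cfg.get("analysis4") or {}
        pain_regions = a4cfg.get("pain_regions")
        tact_regions = a4cfg.get("tactile_regions")
        if pain_regions is None and a3 is not None:
            pain_regions = a3.results["pain_gt_tactile"].significant(pcfg.alpha)
        if tact_regions is None and a3 is not None:
            tact_regions = a3.results["tactile_gt_pain"].significant(pcfg.alpha)
        a4 = tc.analysis4(subjects, parcellation, pain_regions or [],
                          tact_regions or [], pcfg, window)
        a4.auc_table.to_csv(out / "analysis4_auc.tsv", sep="\t", index=False,
                            float_format="%.6g")
        for name, res in a4.results.items():
            _write_paired_result(res, out / f"analysis4_{name}.tsv")
        log["analysis4"] = {
            name: {"regions": res.region_ids,
                   "mean_diff": [float(v) for v in res.mean_diff],
                   "significant": res.significant(pcfg.alpha)}
            for name, res in a4.results.items()}

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return out
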