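"""End-to-end study driver on synthetic data.

Reproduces the full workflow with known ground truth: sample a population,
simulate and fit the behavioural tasks, simulate resting-state images, run
QC, nuisance regression and smoothing, obtain group maps (decomposition or
injected templates), dual regression, inter-network FC, and the group
statistics for each attention parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .fc import (dual_regression, group_decompose, internetwork_fc,
                 match_templates, motion_qc, nuisance_regress, smooth, tsnr)
from .group import (GroupGLM, bonferroni_networks, internetwork_group_test,
                    intra_network_scalar, median_split)
from .model import fit_all_subjects
from .simulate import (FMRIScene, PopulationSpec, sample_population,
                       simulate_behavior, simulate_fmri)

__all__ = ["StudyConfig", "run_study"]

logger = logging.getLogger("tvanet")

SPLIT_DIRECTIONS = {"C": True, "K": True, "alpha": False, "w_lat": True}


@dataclass
class StudyConfig:
    """Everything needed to reproduce a run: population, scene, thresholds."""

    seed: int = 0
    population: PopulationSpec = field(default_factory=PopulationSpec)
    scene: FMRIScene = field(default_factory=FMRIScene)
    fit_n_starts: int = 10
    smooth_fwhm_mm: float = 4.0
    decompose: bool = False          # False: inject the true templates
    n_components: int = 20
    height_p: float = 0.001
    fwe_p: float = 0.05
    n_perm: int = 500
    connectivity: int = 26
    split_params: tuple[str, ...] = ("C", "K", "alpha", "w_lat")
    use_fitted_params: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scene"]["group_effects"] = [asdict(e)
                                       for e in self.scene.group_effects]
        return d


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> dict:
    """Run the whole pipeline; returns a structured report bundle."""
    rng_seed = config.seed
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "stages": {}}

    def stage(name: str):
        logger.info("stage: %s", name)
        return name

    try:
        stage("sample_population")
        pop_spec = config.population
        pop_spec.seed = rng_seed
        subjects = sample_population(pop_spec)
        report["stages"]["population"] = {
            "n_subjects": len(subjects),
            "means": {p: float(subjects[p].mean())
                      for p in ("C", "K", "alpha", "w_lat")},
        }

        stage("simulate_behavior")
        trials = simulate_behavior(subjects, seed=rng_seed + 1)

        stage("fit_tva")
        fits = fit_all_subjects(trials, n_starts=config.fit_n_starts,
                                seed=rng_seed + 2)
        fits = fits.rename(columns={"K_mean": "K"})
        report["stages"]["tva_fit"] = {
            "converged": int(fits["converged"].sum()),
            "means": {p: float(fits[p].mean())
                      for p in ("C", "K", "alpha", "w_lat")},
            "recovery_r": {
                p: float(np.corrcoef(subjects[p], fits[p])[0, 1])
                for p in ("C", "K", "alpha", "w_lat")},
        }

        stage("simulate_fmri")
        sim = simulate_fmri(subjects, config.scene, seed=rng_seed + 3)
        G = config.scene.n_networks

        stage("qc")
        qc_rows = []
        for i, img in enumerate(sim.images):
            rec = motion_qc(sim.motion[i])
            scalar, _, _ = tsnr(img)
            qc_rows.append({"subject_id": sim.subject_ids[i],
                            "tsnr": scalar, "excluded": rec.excluded,
                            "mean_translation_mm": rec.mean_translation_mm})
        qc = pd.DataFrame(qc_rows)
        low5, high5 = np.percentile(qc["tsnr"], [5, 95])
        qc["tsnr_flag"] = (qc["tsnr"] < low5) | (qc["tsnr"] > high5)
        report["stages"]["qc"] = {
            "n_excluded": int(qc["excluded"].sum()),
            "tsnr_mean": float(qc["tsnr"].mean()),
            "n_tsnr_flagged": int(qc["tsnr_flag"].sum()),
        }

        stage("preprocess")
        cleaned = []
        for i, img in enumerate(sim.images):
            global_signal = img.reshape(-1, img.shape[3]).mean(axis=0)
            confounds = np.column_stack([sim.motion[i], global_signal])
            res = nuisance_regress(img, confounds)
            cleaned.append(smooth(res, config.smooth_fwhm_mm,
                                  config.scene.voxel_size_mm))

        stage("group_maps")
        if config.decompose:
            comps = group_decompose(cleaned, n_components=config.n_components,
                                    seed=rng_seed + 4)
            matches = match_templates(comps, sim.templates)
            order = sorted(matches, key=lambda m: m["template"])
            group_maps = np.stack([comps.maps[m["component"]]
                                   * np.sign(m["r"]) for m in order])
            report["stages"]["decomposition"] = {
                "match_r": [m["r"] for m in order]}
        else:
            group_maps = sim.templates
            report["stages"]["decomposition"] = {"injected_templates": True}

        stage("dual_regression")
        zmaps = np.empty((len(cleaned), G) + config.scene.shape)
        fcz = np.empty((len(cleaned), G, G))
        for i, img in enumerate(cleaned):
            dr = dual_regression(img, group_maps)
            zmaps[i] = dr.zmaps
            fcz[i] = internetwork_fc(dr.timecourses)

        stage("group_analysis")
        params_df = fits if config.use_fitted_params else subjects
        net_masks = sim.templates > 0.5
        intra_results = {}
        for split_on in config.split_params:
            labels = median_split(params_df[split_on].to_numpy(float),
                                  higher_is_better=SPLIT_DIRECTIONS[split_on])
            others = [p for p in ("C", "K", "alpha", "w_lat") if p != split_on]
            cov = np.column_stack([params_df[p] for p in others]
                                  + [subjects["education"], subjects["gender"]])
            per_net = []
            for g in range(G):
                glm = GroupGLM(zmaps[:, g], labels, cov)
                res = glm.fit()
                clu = res.cluster_inference(
                    height_p=config.height_p, fwe_p=config.fwe_p,
                    n_perm=config.n_perm, seed=rng_seed + 5 + g,
                    connectivity=config.connectivity, n_networks=G)
                best_p = min(clu.corrected_ps, default=1.0)
                survives, thr = bonferroni_networks(best_p, n_networks=G,
                                                    fwe_p=config.fwe_p)
                per_net.append({
                    "network": g, "df": res.df,
                    "n_clusters": len(clu.sizes),
                    "min_p_fwe": best_p, "survives_bonferroni": survives,
                    "mean_intra_z": float(np.mean([
                        intra_network_scalar(zmaps[:, g], net_masks[g]).mean()
                    ])),
                })
            intra_results[split_on] = {"groups": labels.tolist(),
                                       "networks": per_net,
                                       "bonferroni_threshold": thr}
        inter_results = {}
        for split_on in ("C", "alpha"):
            if split_on not in intra_results:
                continue
            labels = np.array(intra_results[split_on]["groups"])
            pairs = []
            for i in range(G):
                for j in range(i + 1, G):
                    res = internetwork_group_test(fcz[:, i, j], labels)
                    pairs.append({"pair": [i, j], "t": res.t, "df": res.df,
                                  "p_one_tailed": res.p})
            inter_results[split_on] = pairs
        report["stages"]["intra_network"] = intra_results
        report["stages"]["inter_network"] = inter_results
        report["ground_truth"] = sim.ground_truth()
    except Exception as exc:  # persist partial outputs with the stage name
        report["error"] = f"{type(exc).__name__}: {exc}"
        if out is not None:
            io.save_json(report, out / "report.json")
        raise

    if out is not None:
        io.save_json(report, out / "report.json")
        io.write_trial_table(trials, out / "trials.tsv")
        fits.to_csv(out / "tva_fits.tsv", sep="\t", index=False)
        qc.to_csv(out / "qc.tsv", sep="\t", index=False)
    return report
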