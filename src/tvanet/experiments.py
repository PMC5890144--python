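"""Validation experiments: the study-scale property checks.

Each function runs a self-contained experiment against the generator's
ground truth and returns plain numbers:

* race-model exact enumeration vs. a brute-force Monte-Carlo race oracle on
  every condition of the behavioural design;
* TVA parameter recovery at the design trial counts (192 + 288) over
  replicate subjects generated at the reference cohort means;
* dual-regression recovery of planted spatial maps and time courses on a
  noisy scene;
* permutation cluster-FWE type-I calibration over null replicate scenes;
* end-to-end sign recovery of a planted intra-network group effect.

Replicate experiments run on a reduced grid (16 x 16 x 8, 150 volumes,
4 networks) so hundreds of replicates complete in minutes on one CPU; the
subject count (31) and effect size (d = 1.2) stay at study scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import (calibrate_exposures, partial_report_conditions,
                     whole_report_conditions)
from .fc import dual_regression, smooth
from .group import GroupGLM, median_split
from .model import fit_all_subjects
from .params import TVAParams
from .race import (monte_carlo_race, monte_carlo_scores, partial_report_prob,
                   report_distribution)
from .simulate import (FMRIScene, GroupEffect, PopulationSpec,
                       sample_population, simulate_behavior, simulate_fmri)

__all__ = [
    "race_mc_agreement", "parameter_recovery", "dualreg_recovery",
    "cluster_fwe_calibration", "sign_recovery", "reduced_scene",
]

REFERENCE_PARAMS = TVAParams(C=25.89, K_mean=3.03, t0=10.0, mu=150.0,
                             alpha=0.52, w_lat=0.49)


def race_mc_agreement(seed: int = 0, n_mc: int = 1_000_000,
                      params: TVAParams = REFERENCE_PARAMS) -> dict:
    """Exact race enumeration vs. Monte-Carlo oracle on all 28 conditions.

    Returns the maximum absolute deviation in units of the Monte-Carlo
    standard error across every probability of every design condition
    (12 whole-report score distributions + 16 partial-report target
    probabilities).
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    n_checked = 0
    exposures = calibrate_exposures(params, "whole")
    cap = params.capacity_pmf(n_max=8)
    for cond in whole_report_conditions(exposures):
        exact = report_distribution(cond, params)
        from .race import effective_exposure
        tau = effective_exposure(cond.exposure_ms, params.t0, params.mu,
                                 cond.masked)
        mc = monte_carlo_scores(cond.rates(params), tau,
                                cap[:cond.n_items + 1] / cap[:cond.n_items + 1].sum(),
                                n_mc, rng)
        se = np.sqrt(np.maximum(exact * (1 - exact), 1e-12) / n_mc)
        dev = np.abs(mc - exact) / se
        worst = max(worst, float(dev.max()))
        n_checked += 1
    t_partial = calibrate_exposures(params, "partial")["single"]
    for cond in partial_report_conditions(t_partial):
        exact = partial_report_prob(cond, params)
        from .race import effective_exposure
        tau = effective_exposure(cond.exposure_ms, params.t0, 0.0, True)
        retained = monte_carlo_race(cond.rates(params), tau,
                                    params.capacity_pmf(n_max=cond.n_items),
                                    n_mc, rng)
        mc = retained[:, list(cond.target_indices)].mean(axis=0)
        se = np.sqrt(np.maximum(exact * (1 - exact), 1e-12) / n_mc)
        dev = np.abs(mc - exact) / se
        worst = max(worst, float(dev.max()))
        n_checked += 1
    return {"max_dev_in_se": worst, "n_conditions": n_checked, "n_mc": n_mc}


def parameter_recovery(n_subjects: int = 50, seed: int = 0,
                       n_starts: int = 10) -> dict:
    """Fit replicate subjects generated at the reference cohort means.

    Every subject is generated at the same known parameter values with the
    full design (192 whole + 288 partial trials) and fitted by ML; returns
    median relative errors for C/K/alpha, median absolute error for w_lat,
    and mean signed biases.
    """
    p = REFERENCE_PARAMS
    spec = PopulationSpec(
        n_subjects=n_subjects, seed=seed,
        C=(p.C, 0.0), K=(p.K_mean, 0.0), t0=(p.t0, 0.0), mu=(p.mu, 0.0),
        alpha=(p.alpha, 0.0), w_lat=(p.w_lat, 0.0))
    subjects = sample_population(spec)
    trials = simulate_behavior(subjects, seed=seed + 1)
    fits = fit_all_subjects(trials, n_starts=n_starts, seed=seed + 2)
    fits = fits.rename(columns={"K_mean": "K"})
    out: dict = {"n_subjects": n_subjects}
    for name in ("C", "K", "alpha"):
        err = fits[name].to_numpy() - subjects[name].to_numpy()
        out[f"median_rel_err_{name}"] = float(
            np.median(np.abs(err) / subjects[name].to_numpy()))
        out[f"bias_{name}"] = float(err.mean())
        out[f"bias_se_{name}"] = float(err.std(ddof=1) / np.sqrt(len(err)))
    for name in ("t0", "mu", "w_lat"):
        err = fits[name].to_numpy() - subjects[name].to_numpy()
        out[f"median_abs_err_{name}"] = float(np.median(np.abs(err)))
        out[f"bias_{name}"] = float(err.mean())
        out[f"bias_se_{name}"] = float(err.std(ddof=1) / np.sqrt(len(err)))
    return out


def reduced_scene(n_networks: int = 4,
                  effects: list[GroupEffect] | None = None) -> FMRIScene:
    """The reduced-grid scene used for replicate experiments."""
    if effects is None:
        effects = []
    return FMRIScene(shape=(16, 16, 8), n_volumes=150, n_networks=n_networks,
                     group_effects=effects, template_seed=77)


def dualreg_recovery(seed: int = 0, scene: FMRIScene | None = None,
                     n_subjects: int = 31,
                     smooth_fwhm_mm: float = 4.0) -> dict:
    """Dual regression against the planted templates on a noisy scene.

    Images pass through the standard preprocessing (nuisance regression of
    motion parameters + global signal, then smoothing) before dual
    regression.  Returns per-network mean spatial correlation of stage-2
    Z-maps with the planted maps and mean temporal correlation of stage-1
    time courses with the planted time courses, across subjects.
    """
    from .fc import nuisance_regress
    scene = scene or FMRIScene(group_effects=[])
    spec = PopulationSpec(n_subjects=n_subjects, seed=seed)
    subjects = sample_population(spec)
    sim = simulate_fmri(subjects, scene, seed=seed + 1)
    G = scene.n_networks
    r_spatial = np.zeros((n_subjects, G))
    r_temporal = np.zeros((n_subjects, G))
    tflat = sim.templates.reshape(G, -1)
    for i, img in enumerate(sim.images):
        global_signal = img.reshape(-1, img.shape[3]).mean(axis=0)
        confounds = np.column_stack([sim.motion[i], global_signal])
        img = nuisance_regress(img, confounds)
        if smooth_fwhm_mm > 0:
            img = smooth(img, smooth_fwhm_mm, scene.voxel_size_mm)
        dr = dual_regression(img, sim.templates)
        zflat = dr.zmaps.reshape(G, -1)
        for g in range(G):
            r_spatial[i, g] = np.corrcoef(zflat[g], tflat[g])[0, 1]
            r_temporal[i, g] = np.corrcoef(dr.timecourses[:, g],
                                           sim.timecourses[i][:, g])[0, 1]
    return {
        "mean_spatial_r": r_spatial.mean(axis=0).tolist(),
        "mean_temporal_r": r_temporal.mean(axis=0).tolist(),
        "min_network_spatial_r": float(r_spatial.mean(axis=0).min()),
        "min_network_temporal_r": float(r_temporal.mean(axis=0).min()),
    }


def _null_zmaps(shape: tuple[int, int, int], n_subjects: int,
                rng: np.random.Generator, smooth_sigma: float = 1.0
                ) -> np.ndarray:
    """Spatially smooth Gaussian Z-maps with no group structure."""
    from scipy import ndimage
    z = rng.standard_normal((n_subjects,) + shape)
    if smooth_sigma > 0:
        z = ndimage.gaussian_filter(z, sigma=(0,) + (smooth_sigma,) * 3)
    return z


def cluster_fwe_calibration(n_replicates: int = 200, n_subjects: int = 31,
                            shape: tuple[int, int, int] = (16, 16, 8),
                            n_perm: int = 500, seed: int = 0,
                            fwe_p: float = 0.05) -> dict:
    """Type-I error of permutation cluster-extent FWE on null scenes.

    Each replicate draws smooth null Z-maps and an independent performance
    variable, median-splits, fits the GLM with nuisance covariates and runs
    cluster inference; a replicate counts as a rejection if any cluster has
    corrected p < fwe_p.  Returns the rejection rate and its binomial CI.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for rep in range(n_replicates):
        zmaps = _null_zmaps(shape, n_subjects, rng)
        perf = rng.standard_normal(n_subjects)
        labels = median_split(perf)
        cov = rng.standard_normal((n_subjects, 5))
        res = GroupGLM(zmaps, labels, cov).fit()
        clu = res.cluster_inference(n_perm=n_perm,
                                    seed=int(rng.integers(2**31 - 1)),
                                    fwe_p=fwe_p)
        if clu.any_significant:
            rejections += 1
    rate = rejections / n_replicates
    half = 1.96 * np.sqrt(fwe_p * (1 - fwe_p) / n_replicates)
    return {"rejection_rate": rate, "n_replicates": n_replicates,
            "nominal": fwe_p, "ci_low": fwe_p - half, "ci_high": fwe_p + half}


def sign_recovery(n_replicates: int = 100, n_subjects: int = 31,
                  d: float = 1.2, seed: int = 0) -> dict:
    """End-to-end recovery of a planted intra-network effect's direction.

    Each replicate: sample a population, simulate a reduced scene in which
    the high-speed group has *lower* coupling in one network (Cohen's
    d = 1.2 on the gain), run dual regression against the group maps,
    median-split on processing speed, fit the voxelwise GLM with the other
    parameters + education + gender as covariates, and read the sign of the
    mean in-template contrast.  Returns the fraction of replicates whose
    sign matches the planted direction.
    """
    target_net = 1
    hits = 0
    rng = np.random.default_rng(seed)
    for rep in range(n_replicates):
        rep_seed = int(rng.integers(2**31 - 1))
        spec = PopulationSpec(n_subjects=n_subjects, seed=rep_seed)
        subjects = sample_population(spec)
        scene = reduced_scene(effects=[
            GroupEffect("intra", (target_net,), split_on="C",
                        effect=d, sign=-1)])
        sim = simulate_fmri(subjects, scene, seed=rep_seed + 1)
        G = scene.n_networks
        zmaps = np.empty((n_subjects,) + scene.shape)
        for i, img in enumerate(sim.images):
            dr = dual_regression(img, sim.templates)
            zmaps[i] = dr.zmaps[target_net]
        labels = median_split(subjects["C"].to_numpy(float))
        others = ["K", "alpha", "w_lat"]
        cov = np.column_stack([subjects[p] for p in others]
                              + [subjects["education"], subjects["gender"]])
        res = GroupGLM(zmaps, labels, cov).fit()
        in_net = sim.templates[target_net] > 0.5
        contrast = float(res.tmap[in_net].mean())
        if contrast < 0:  # planted: high performers lower intra-network FC
            hits += 1
    return {"sign_recovery_rate": hits / n_replicates,
            "n_replicates": n_replicates, "d": d}
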