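"""Synthetic data with known ground truth.

Behavioural side: subjects are drawn from independent truncated-normal
population distributions of the six TVA parameters, exposures are calibrated
per subject exactly as in the pretest procedure, and trial outcomes are
sampled from the race model itself under the full design (192 whole-report
trials in 12 conditions, 288 partial-report trials in 16 conditions).

Imaging side: small 4D "resting-state" images are composed of planted
network spatial maps times network time courses with configurable
inter-network correlation, group-dependent coupling effects, slow drift,
motion-locked artifact and Gaussian noise.  The generator serialises its
ground truth so every downstream estimate can be checked against it.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from . import reference
from .design import (PARTIAL_BLOCKS, WHOLE_BLOCKS, WHOLE_N_ITEMS,
                     calibrate_exposures, partial_report_conditions,
                     whole_report_conditions)
from .params import TVAParams
from .race import partial_report_joint, report_distribution

__all__ = [
    "PopulationSpec", "FMRIScene", "GroupEffect", "SimulatedFMRI",
    "sample_population", "simulate_behavior", "make_network_templates",
    "simulate_fmri",
]

_PARAM_BOUNDS = {
    "C": (1.0, 100.0), "K": (0.5, 6.0), "t0": (0.0, 60.0),
    "mu": (0.0, 500.0), "alpha": (0.02, 4.0), "w_lat": (0.05, 0.95),
}


@dataclass
class PopulationSpec:
    """Population distributions of TVA parameters (means/SDs of the cohort)."""

    n_subjects: int = reference.N_SUBJECTS
    C: tuple[float, float] = reference.POPULATION["C"]
    K: tuple[float, float] = reference.POPULATION["K"]
    t0: tuple[float, float] = (10.0, 5.0)
    mu: tuple[float, float] = (150.0, 50.0)
    alpha: tuple[float, float] = reference.POPULATION["alpha"]
    w_lat: tuple[float, float] = reference.POPULATION["w_lat"]
    education_range: tuple[int, int] = (9, 13)
    seed: int = 0


def _truncnorm(mean: float, sd: float, lo: float, hi: float, size: int,
               rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        if not lo <= mean <= hi:
            raise ValueError(f"mean {mean} outside truncation bounds [{lo}, {hi}]")
        return np.full(size, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    if a >= b:
        raise ValueError(f"infeasible truncation region [{lo}, {hi}]")
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def sample_population(spec: PopulationSpec) -> pd.DataFrame:
    """Draw per-subject TVA parameters and covariates; parameters independent.

    Independence across parameters mirrors the empirical finding that the
    four attention parameters are uncorrelated traits.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    cols: dict[str, np.ndarray] = {
        "subject_id": np.array([f"sub-{i + 1:03d}" for i in range(n)]),
    }
    for name in ("C", "K", "t0", "mu", "alpha", "w_lat"):
        mean, sd = getattr(spec, name)
        lo, hi = _PARAM_BOUNDS[name]
        cols[name] = _truncnorm(mean, sd, lo, hi, n, rng)
    lo_e, hi_e = spec.education_range
    cols["education"] = rng.integers(lo_e, hi_e + 1, size=n)
    gender = np.zeros(n, int)
    gender[rng.permutation(n)[: n // 2]] = 1
    cols["gender"] = gender
    return pd.DataFrame(cols)


def _subject_params(row: pd.Series) -> TVAParams:
    return TVAParams(C=float(row["C"]), K_mean=float(row["K"]),
                     t0=float(row["t0"]), mu=float(row["mu"]),
                     alpha=float(row["alpha"]), w_lat=float(row["w_lat"]))


def simulate_behavior(subjects: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Simulate full whole- plus partial-report sessions for every subject.

    Returns a combined long trial table (one row per trial).  Within each
    block the conditions appear equally often in a random order, as in the
    balanced design.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for _, subj in subjects.iterrows():
        params = _subject_params(subj)
        sid = str(subj["subject_id"])
        exposures = calibrate_exposures(params, "whole")
        wconds = whole_report_conditions(exposures)
        per_block = 48 // len(wconds)  # 4 repeats of each of 12 conditions
        for block in range(WHOLE_BLOCKS):
            order = rng.permutation(np.repeat(np.arange(len(wconds)), per_block))
            for trial, ci in enumerate(order):
                cond = wconds[ci]
                pmf = report_distribution(cond, params)
                score = int(rng.choice(len(pmf), p=pmf / pmf.sum()))
                rows.append({
                    "subject_id": sid, "task": "whole", "block": block,
                    "trial": trial, "cond_id": cond.cond_id,
                    "exposure_ms": cond.exposure_ms, "masked": cond.masked,
                    "hemifield": cond.items[0].hemifield,
                    "n_targets": cond.n_items, "n_distractors": 0,
                    "score": score,
                    "target1_reported": "", "target2_reported": "",
                })
        t_partial = calibrate_exposures(params, "partial")["single"]
        pconds = partial_report_conditions(t_partial)
        per_block = 48 // len(pconds)  # 3 repeats of each of 16 conditions
        for block in range(PARTIAL_BLOCKS):
            order = rng.permutation(np.repeat(np.arange(len(pconds)), per_block))
            for trial, ci in enumerate(order):
                cond = pconds[ci]
                joint = partial_report_joint(cond, params)
                keys = list(joint)
                probs = np.array([joint[k] for k in keys])
                reported = keys[rng.choice(len(keys), p=probs / probs.sum())]
                targets = cond.target_indices
                rows.append({
                    "subject_id": sid, "task": "partial", "block": block,
                    "trial": trial, "cond_id": cond.cond_id,
                    "exposure_ms": cond.exposure_ms, "masked": True,
                    "hemifield": cond.items[0].hemifield,
                    "n_targets": len(targets),
                    "n_distractors": cond.n_items - len(targets),
                    "score": "",
                    "target1_reported": int(targets[0] in reported),
                    "target2_reported": (int(targets[1] in reported)
                                         if len(targets) > 1 else ""),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# imaging side
# ---------------------------------------------------------------------------

def make_network_templates(
    shape: tuple[int, int, int],
    n_networks: int,
    seed: int = 0,
    smooth_sigma: float = 1.2,
    max_pairwise_corr: float = 0.3,
    max_tries: int = 50,
) -> np.ndarray:
    """Synthetic network spatial maps: smoothed blobs, unit peak, low overlap.

    Stand-ins for canonical resting-state network templates; each map is a
    small set of Gaussian blobs.  Pairwise spatial correlation is constrained
    below ``max_pairwise_corr``.
    """
    if n_networks < 2:
        raise ValueError("need at least 2 networks")
    rng = np.random.default_rng(seed)
    shape = tuple(shape)
    grid = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), -1)
    for _ in range(max_tries):
        # farthest-point placement of blob centres keeps overlap low
        cands = np.column_stack([rng.uniform(0.15 * s, 0.85 * s,
                                             size=64) for s in shape])
        centers = [cands[0]]
        while len(centers) < n_networks:
            d = np.min([np.linalg.norm(cands - c, axis=1) for c in centers],
                       axis=0)
            centers.append(cands[int(np.argmax(d))])
        maps = np.zeros((n_networks,) + shape, dtype=np.float64)
        r_scale = 0.13 * min(shape)
        for g in range(n_networks):
            radii = rng.uniform(0.8 * r_scale, 1.4 * r_scale, size=3)
            d2 = (((grid - centers[g]) / radii) ** 2).sum(-1)
            maps[g] = np.exp(-0.5 * d2)
            if smooth_sigma > 0:
                maps[g] = ndimage.gaussian_filter(maps[g], smooth_sigma)
            peak = maps[g].max()
            if peak > 0:
                maps[g] /= peak
        flat = maps.reshape(n_networks, -1)
        corr = np.corrcoef(flat)
        off = corr[~np.eye(n_networks, dtype=bool)]
        if np.all(np.abs(off) < max_pairwise_corr):
            return maps
    raise RuntimeError(
        f"could not place {n_networks} templates with pairwise |r| < "
        f"{max_pairwise_corr} on grid {shape}")


@dataclass
class GroupEffect:
    """A planted group difference in the scene.

    kind="intra": the coupling gain of ``networks[0]`` differs between the
    high/low groups of ``split_on`` by Cohen's d (``effect``) in units of the
    between-subject gain SD, signed (+1: high group larger).
    kind="inter": the time-course correlation of the pair ``networks``
    differs between groups by ``effect`` (an absolute correlation shift,
    +1 sign meaning larger in the high group).
    """

    kind: str  # "intra" | "inter"
    networks: tuple[int, ...]
    split_on: str = "C"
    effect: float = 1.2
    sign: int = -1
    higher_is_better: bool = True


def default_group_effects() -> list[GroupEffect]:
    # high processing speed -> lower intra-FC in a ventral-attention-like
    # network and higher ventral-attention <-> right-frontoparietal coupling;
    # efficient top-down control (low alpha) -> higher dorsal-attention
    # intra-FC, lower visual intra-FC, higher visual <-> executive coupling.
    return [
        GroupEffect("intra", (4,), split_on="C", effect=1.2, sign=-1),
        GroupEffect("inter", (4, 2), split_on="C", effect=0.15, sign=+1),
        GroupEffect("intra", (5,), split_on="alpha", effect=1.2, sign=+1,
                    higher_is_better=False),
        GroupEffect("intra", (0,), split_on="alpha", effect=1.2, sign=-1,
                    higher_is_better=False),
        GroupEffect("inter", (0, 1), split_on="alpha", effect=0.15, sign=+1,
                    higher_is_better=False),
    ]


@dataclass
class FMRIScene:
    """Specification of the synthetic resting-state scene."""

    shape: tuple[int, int, int] = (24, 24, 12)
    n_volumes: int = reference.N_VOLUMES
    tr: float = reference.TR_SECONDS
    n_networks: int = reference.N_NETWORKS
    voxel_size_mm: float = 3.0
    base_corr: float = 0.1
    gain_mean: float = 1.0
    gain_sd: float = 0.2
    noise_sd: float = 1.0
    baseline: float = 100.0
    drift_amp: float = 1.0
    motion_step_mm: float = 0.02
    motion_step_deg: float = 0.015
    artifact_amp: float = 0.5
    group_effects: list[GroupEffect] = field(default_factory=default_group_effects)
    template_seed: int = 1234

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.group_effects = [
            e if isinstance(e, GroupEffect) else GroupEffect(**{
                **e, "networks": tuple(e["networks"])})
            for e in self.group_effects]


@dataclass
class SimulatedFMRI:
    """Bundle of simulated images plus the generating ground truth."""

    images: list[np.ndarray]          # per subject, (x, y, z, t) float32
    motion: list[np.ndarray]          # per subject, (t, 6)
    templates: np.ndarray             # (G, x, y, z)
    timecourses: list[np.ndarray]     # per subject, (t, G) noise-free
    gains: np.ndarray                 # (n_subjects, G)
    groups: dict[str, np.ndarray]     # split_on -> high/low labels
    scene: FMRIScene
    subject_ids: list[str]

    def ground_truth(self) -> dict:
        d = asdict(self.scene)
        d["group_effects"] = [asdict(e) for e in self.scene.group_effects]
        d["gains"] = self.gains.tolist()
        d["groups"] = {k: v.tolist() for k, v in self.groups.items()}
        return d


def _split_high_low(values: np.ndarray, higher_is_better: bool) -> np.ndarray:
    """Median-split labels used by the generator to plant group effects."""
    from .group import median_split
    return median_split(values, higher_is_better=higher_is_better)


def _cov_for_subject(scene: FMRIScene, effects_r: np.ndarray) -> np.ndarray:
    G = scene.n_networks
    cov = np.full((G, G), scene.base_corr)
    np.fill_diagonal(cov, 1.0)
    cov = cov + effects_r
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ValueError("inter-network covariance not positive definite "
                         "after group shift") from None
    return cov


def simulate_fmri(subjects: pd.DataFrame, scene: FMRIScene | None = None,
                  seed: int = 0) -> SimulatedFMRI:
    """Generate per-subject 4D images with planted networks and effects.

    Voxel series: baseline + sum_g template_g(v) * gain_{s,g} * tc_{s,g}(t)
    + drift + motion-locked global artifact + white Gaussian noise.
    """
    scene = scene or FMRIScene()
    G, T = scene.n_networks, scene.n_volumes
    rng = np.random.default_rng(seed)
    templates = make_network_templates(scene.shape, G, seed=scene.template_seed)
    flat_templates = templates.reshape(G, -1)
    n = len(subjects)

    groups: dict[str, np.ndarray] = {}
    for eff in scene.group_effects:
        if eff.split_on not in groups:
            groups[eff.split_on] = _split_high_low(
                subjects[eff.split_on].to_numpy(float), eff.higher_is_better)

    # per-subject coupling gains, with planted intra-network group shifts
    gains = rng.normal(scene.gain_mean, scene.gain_sd, size=(n, G))
    for eff in scene.group_effects:
        if eff.kind != "intra":
            continue
        is_high = groups[eff.split_on] == "high"
        shift = 0.5 * eff.sign * eff.effect * scene.gain_sd
        gains[is_high, eff.networks[0]] += shift
        gains[~is_high, eff.networks[0]] -= shift
    gains = np.abs(gains)  # gains are couplings, keep positive

    images, motions, tcs = [], [], []
    tgrid = np.arange(T)
    for s in range(n):
        effects_r = np.zeros((G, G))
        for eff in scene.group_effects:
            if eff.kind != "inter":
                continue
            i, j = eff.networks
            sgn = 1.0 if groups[eff.split_on][s] == "high" else -1.0
            delta = 0.5 * sgn * eff.sign * eff.effect
            effects_r[i, j] += delta
            effects_r[j, i] += delta
        cov = _cov_for_subject(scene, effects_r)
        L = np.linalg.cholesky(cov)
        tc = rng.standard_normal((T, G)) @ L.T  # (t, G), unit variance
        tcs.append(tc)

        # motion: slow random walks, 3 translations mm + 3 rotations deg
        steps = np.concatenate([
            rng.normal(0, scene.motion_step_mm, size=(T, 3)),
            rng.normal(0, scene.motion_step_deg, size=(T, 3))], axis=1)
        steps[0] = 0.0
        motion = np.cumsum(steps, axis=0)
        motions.append(motion)

        signal = (flat_templates.T * gains[s]) @ tc.T  # (V, t)
        drift = scene.drift_amp * (tgrid / max(T - 1, 1) - 0.5)
        dmotion = np.zeros(T)
        dmotion[1:] = np.linalg.norm(np.diff(motion[:, :3], axis=0), axis=1)
        if dmotion.std() > 0:
            artifact = scene.artifact_amp * (dmotion - dmotion.mean()) / dmotion.std()
        else:
            artifact = np.zeros(T)
        series = (scene.baseline + signal + drift[None, :] + artifact[None, :]
                  + rng.normal(0, scene.noise_sd, size=signal.shape))
        images.append(series.reshape(*scene.shape, T).astype(np.float32))

    return SimulatedFMRI(
        images=images, motion=motions, templates=templates,
        timecourses=tcs, gains=gains, groups=groups, scene=scene,
        subject_ids=[str(s) for s in subjects["subject_id"]])
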