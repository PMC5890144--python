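"""Image-side computation: nuisance regression, smoothing, QC, group
decomposition, template matching, dual regression and inter-network FC.

The processing order follows the original pipeline: per-voxel nuisance
regression (motion parameters plus global-signal-type confounds and an
intercept), then spatial smoothing, then a group decomposition of the
temporally concatenated data into spatially independent maps (PCA +
fixed-point ICA standing in for probabilistic ICA), template matching by
spatial cross-correlation, and two-stage dual regression per subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from sklearn.decomposition import FastICA
from sklearn.utils.extmath import randomized_svd

__all__ = [
    "nuisance_regress", "smooth", "motion_qc", "tsnr",
    "group_decompose", "match_templates", "dual_regression",
    "internetwork_fc", "fisher_z",
    "ComponentSet", "DualRegressionResult", "QCRecord", "QCThresholds",
]

_FISHER_CAP = 1.0 - 1e-15


def _flatten(img: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
    """(x, y, z, t) -> (V, t) plus the spatial shape."""
    if img.ndim != 4:
        raise ValueError(f"expected a 4D image, got shape {img.shape}")
    shape = img.shape[:3]
    return img.reshape(-1, img.shape[3]), shape


def nuisance_regress(img: np.ndarray, confounds: np.ndarray | None) -> np.ndarray:
    """Regress confound time series (plus intercept) out of every voxel.

    Residuals are exactly orthogonal to the confound columns.  Rank-deficient
    confound matrices are rejected with the offending columns named.
    """
    data, shape = _flatten(img)
    T = data.shape[1]
    if confounds is None:
        X = np.ones((T, 1))
    else:
        confounds = np.asarray(confounds, float)
        if confounds.shape[0] != T:
            raise ValueError(
                f"confounds have {confounds.shape[0]} rows, image has {T} volumes")
        X = np.column_stack([np.ones(T), confounds])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # identify offending columns by incremental rank
            bad = []
            kept = np.ones((T, 1))
            for j in range(confounds.shape[1]):
                cand = np.column_stack([kept, confounds[:, j]])
                if np.linalg.matrix_rank(cand) == kept.shape[1]:
                    bad.append(j)
                else:
                    kept = cand
            raise ValueError(f"confound matrix is rank deficient; "
                             f"offending columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, data.T.astype(np.float64), rcond=None)
    resid = data.T - X @ beta
    return resid.T.reshape(*shape, T).astype(img.dtype, copy=False)


def smooth(img: np.ndarray, fwhm_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Volume-wise separable Gaussian smoothing (reflective boundary).

    sigma = FWHM / (2 sqrt(2 ln 2)) per axis, in voxel units.  The reflective
    boundary conserves the total image sum.
    """
    if voxel_size_mm <= 0:
        raise ValueError("voxel size must be positive")
    if fwhm_mm < 0:
        raise ValueError("FWHM must be >= 0")
    if fwhm_mm == 0:
        return img
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    if img.ndim == 4:
        sig = (sigma_vox, sigma_vox, sigma_vox, 0.0)
    else:
        sig = sigma_vox
    return ndimage.gaussian_filter(img.astype(np.float64), sigma=sig,
                                   mode="reflect").astype(img.dtype, copy=False)


@dataclass(frozen=True)
class QCThresholds:
    """Head-motion exclusion rules (defaults: the standard 3 mm / 3 deg
    cumulative and 0.15 mm / 0.1 deg mean volume-to-volume criteria)."""

    cumulative_translation_mm: float = 3.0
    cumulative_rotation_deg: float = 3.0
    mean_translation_mm: float = 0.15
    mean_rotation_deg: float = 0.1


@dataclass
class QCRecord:
    cumulative_translation_mm: float
    cumulative_rotation_deg: float
    mean_translation_mm: float
    mean_rotation_deg: float
    excluded: bool
    reasons: tuple[str, ...] = ()
    tsnr: float = float("nan")
    outlier_proportion: float = float("nan")


def motion_qc(motion: np.ndarray, thresholds: QCThresholds | None = None) -> QCRecord:
    """Motion summary metrics and the exclusion decision.

    ``motion`` is (t, 6): three translations in mm then three rotations in
    degrees, relative to the first volume.  Cumulative metrics are the max
    over time of the Euclidean norm from the first volume; point-to-point
    metrics are the mean volume-to-volume norm.
    """
    motion = np.asarray(motion, float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion table must have 6 columns, got {motion.shape}")
    thresholds = thresholds or QCThresholds()
    rel = motion - motion[0]
    cum_t = float(np.linalg.norm(rel[:, :3], axis=1).max())
    cum_r = float(np.linalg.norm(rel[:, 3:], axis=1).max())
    d = np.diff(motion, axis=0)
    if len(d):
        mean_t = float(np.linalg.norm(d[:, :3], axis=1).mean())
        mean_r = float(np.linalg.norm(d[:, 3:], axis=1).mean())
    else:
        mean_t = mean_r = 0.0
    reasons = []
    if cum_t > thresholds.cumulative_translation_mm:
        reasons.append("cumulative_translation")
    if cum_r > thresholds.cumulative_rotation_deg:
        reasons.append("cumulative_rotation")
    if mean_t > thresholds.mean_translation_mm:
        reasons.append("mean_translation")
    if mean_r > thresholds.mean_rotation_deg:
        reasons.append("mean_rotation")
    return QCRecord(cum_t, cum_r, mean_t, mean_r,
                    excluded=bool(reasons), reasons=tuple(reasons))


def tsnr(img: np.ndarray, mask: np.ndarray | None = None
         ) -> tuple[float, np.ndarray, int]:
    """Temporal SNR: voxelwise mean/SD over time; scalar = mask average.

    Returns (scalar, tSNR map, number of zero-variance voxels excluded).
    """
    data, shape = _flatten(img)
    mean = data.mean(axis=1)
    sd = data.std(axis=1, ddof=1)
    tsnr_map = np.full(mean.shape, np.nan)
    ok = sd > 0
    tsnr_map[ok] = mean[ok] / sd[ok]
    if mask is not None:
        in_mask = np.asarray(mask, bool).reshape(-1)
    else:
        in_mask = np.ones(mean.shape, bool)
    usable = in_mask & ok
    n_excluded = int(in_mask.sum() - usable.sum())
    if not usable.any():
        raise ValueError("no voxel with positive temporal variance in mask")
    return float(tsnr_map[usable].mean()), tsnr_map.reshape(shape), n_excluded


@dataclass
class ComponentSet:
    """Group decomposition output: G spatial maps + concatenated time courses."""

    maps: np.ndarray          # (G, x, y, z)
    timecourses: np.ndarray   # (T_total, G)
    n_components: int
    converged: bool = True


def group_decompose(images: list[np.ndarray], n_components: int = 20,
                    seed: int = 0, max_iter: int = 500,
                    tol: float = 1e-4) -> ComponentSet:
    """Temporal-concatenation group decomposition into spatial sources.

    Per-voxel variance normalisation, temporal concatenation across subjects,
    reduction to ``n_components`` principal components, then rotation to
    spatially independent maps by fixed-point negentropy maximisation
    (FastICA).  Component sign is fixed so every map has positive skewness.
    """
    flats_raw = []
    shape = images[0].shape[:3]
    for img in images:
        data, shp = _flatten(img)
        if shp != shape:
            raise ValueError("all images must share one grid")
        data = data.astype(np.float64)
        data = data - data.mean(axis=1, keepdims=True)
        flats_raw.append(data.T)
    X_raw = np.concatenate(flats_raw, axis=0)  # (T_total, V)
    del flats_raw
    if X_raw.shape[0] <= n_components:
        raise ValueError("total timepoints must exceed the dimensionality")
    # variance-normalise each voxel by its *residual* noise SD: project out
    # a first-pass signal subspace, so that signal-carrying voxels keep
    # their prominence instead of being flattened to unit variance
    U0, S0, Vt0 = randomized_svd(X_raw, n_components=n_components,
                                 random_state=seed)
    total_var = (X_raw ** 2).sum(axis=0)
    signal_var = ((S0[:, None] * Vt0) ** 2).sum(axis=0)
    noise_sd = np.sqrt(np.maximum(total_var - signal_var, 0.0)
                       / max(X_raw.shape[0] - 1, 1))
    floor = max(np.median(noise_sd) * 1e-3, 1e-12)
    X_vn = X_raw / np.maximum(noise_sd, floor)
    U, S, Vt = randomized_svd(X_vn, n_components=n_components,
                              random_state=seed)
    # spatial ICA on the PCA-reduced spatial eigenmaps: voxels are samples
    reduced = (S[:, None] * Vt).T  # (V, G)
    ica = FastICA(n_components=n_components, whiten="unit-variance",
                  max_iter=max_iter, tol=tol, random_state=seed)
    import warnings as _warnings
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        sources = ica.fit_transform(reduced)  # (V, G) independent spatial maps
    converged = not any("did not converge" in str(w.message) for w in caught)
    maps_vn = sources.T  # (G, V)
    # component time courses from the normalised data, then graded maps in
    # the data's own units by regressing the unnormalised series on them
    tcs, *_ = np.linalg.lstsq(maps_vn.T, X_vn.T, rcond=None)  # (G, T_total)
    maps, *_ = np.linalg.lstsq(tcs.T, X_raw, rcond=None)      # (G, V)
    sign = np.where(stats.skew(maps, axis=1) < 0, -1.0, 1.0)
    maps = maps * sign[:, None]
    tcs, *_ = np.linalg.lstsq(maps.T, X_raw.T, rcond=None)
    return ComponentSet(maps=maps.reshape((n_components,) + shape),
                        timecourses=tcs.T, n_components=n_components,
                        converged=converged)


def match_templates(components: ComponentSet | np.ndarray,
                    templates: np.ndarray,
                    mask: np.ndarray | None = None) -> list[dict]:
    """Greedy assignment of components to templates by spatial correlation.

    Returns one record per template: {"template", "component", "r"}; sorted
    by descending |r| of the assignment.
    """
    maps = components.maps if isinstance(components, ComponentSet) else components
    if maps.shape[1:] != templates.shape[1:]:
        raise ValueError(f"grid mismatch: components {maps.shape[1:]} vs "
                         f"templates {templates.shape[1:]}")
    mflat = maps.reshape(maps.shape[0], -1)
    tflat = templates.reshape(templates.shape[0], -1)
    if mask is not None:
        keep = np.asarray(mask, bool).reshape(-1)
        mflat, tflat = mflat[:, keep], tflat[:, keep]
    mz = (mflat - mflat.mean(1, keepdims=True))
    tz = (tflat - tflat.mean(1, keepdims=True))
    mz /= np.linalg.norm(mz, axis=1, keepdims=True)
    tz /= np.linalg.norm(tz, axis=1, keepdims=True)
    R = tz @ mz.T  # (n_templates, n_components)
    order = np.dstack(np.unravel_index(np.argsort(np.abs(R), axis=None)[::-1],
                                       R.shape))[0]
    used_t, used_c, out = set(), set(), []
    for ti, ci in order:
        if ti in used_t or ci in used_c:
            continue
        used_t.add(ti)
        used_c.add(ci)
        out.append({"template": int(ti), "component": int(ci),
                    "r": float(R[ti, ci])})
        if len(used_t) == len(tflat):
            break
    return out


@dataclass
class DualRegressionResult:
    timecourses: np.ndarray   # (t, G) stage-1
    zmaps: np.ndarray         # (G, x, y, z) stage-2 standardized coefficients
    betas: np.ndarray         # (G, x, y, z) raw stage-2 coefficients


def dual_regression(img: np.ndarray, group_maps: np.ndarray,
                    demean: bool = True,
                    cond_limit: float = 1e8) -> DualRegressionResult:
    """Two-stage dual regression of one subject against the group maps.

    Stage 1 (spatial): each volume is regressed on all G maps jointly,
    giving a t x G matrix of network time courses.  Stage 2 (temporal):
    each voxel's series is regressed on all G variance-normalised time
    courses jointly; coefficients are standardised by the residual noise SD
    (t-statistics), giving G Z-maps.
    """
    data, shape = _flatten(img)
    data = data.astype(np.float64)
    G = group_maps.shape[0]
    M = group_maps.reshape(G, -1).T  # (V, G)
    if data.shape[1] <= G:
        raise ValueError("need more timepoints than components")
    if np.linalg.cond(M) > cond_limit:
        raise ValueError("group maps are collinear (condition number "
                         f"> {cond_limit:g})")
    if demean:
        data = data - data.mean(axis=1, keepdims=True)
    tc, *_ = np.linalg.lstsq(M, data, rcond=None)  # (G, t)
    tc = tc.T  # (t, G)
    # stage 2: variance-normalise time courses, add intercept
    sd = tc.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("a stage-1 time course is constant")
    X = np.column_stack([np.ones(len(tc)), tc / sd])
    beta, *_ = np.linalg.lstsq(X, data.T, rcond=None)  # (G+1, V)
    resid = data.T - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    return DualRegressionResult(
        timecourses=tc,
        zmaps=z[1:].reshape((G,) + shape),
        betas=beta[1:].reshape((G,) + shape))


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilising Fisher transform atanh(r), capped near |r| = 1."""
    r = np.clip(r, -_FISHER_CAP, _FISHER_CAP)
    return np.arctanh(r)


def internetwork_fc(timecourses: np.ndarray,
                    selection: list[int] | None = None) -> np.ndarray:
    """Network x network Fisher-z connectivity from stage-1 time courses.

    Diagonal is NaN by convention.  Correlations of +/-1 are capped at
    +/-atanh(1 - 1e-15).
    """
    tc = np.asarray(timecourses, float)
    if selection is not None:
        tc = tc[:, selection]
    if tc.shape[0] < 3:
        raise ValueError("need at least 3 timepoints")
    if np.any(tc.std(axis=0) == 0):
        raise ValueError("constant time course")
    z = fisher_z(np.corrcoef(tc.T))
    np.fill_diagonal(z, np.nan)
    return z
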