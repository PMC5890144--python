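"""Group-level statistics: median splits, voxelwise GLM with permutation
cluster-extent FWE, Bonferroni across networks, inter-network Fisher-z group
tests, summary t-tests and partial correlation.

The voxelwise model follows the cell-means design of the original analysis:
two group columns (high, low) plus five zero-mean covariates (the three
remaining attention parameters, education, gender) — seven parameters, so
the residual degrees of freedom are n - 7 (24 at n = 31).  Cluster-level
family-wise error is controlled by permutation of the group labels
(max-cluster-size null distribution), with clusters formed by 26-connectivity
above the one-sided p < 0.001 height threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "median_split", "group_ttest_summary", "GroupGLM", "GroupGLMResults",
    "cluster_inference", "bonferroni_networks", "internetwork_group_test",
    "intra_network_scalar", "partial_correlation", "ClusterTable",
]


def median_split(values: np.ndarray, higher_is_better: bool = True,
                 ids: np.ndarray | None = None) -> np.ndarray:
    """Split subjects into "high" and "low" performers at the median.

    Subjects are ranked by performance (direction given by
    ``higher_is_better``); the top ceil(n/2) are labelled "high".  Ties are
    broken deterministically by subject id (or by index).
    """
    values = np.asarray(values, float)
    n = len(values)
    if n < 4:
        raise ValueError("need at least 4 subjects for a median split")
    if ids is None:
        ids = np.arange(n)
    perf = values if higher_is_better else -values
    if np.all(perf == perf[0]):
        raise ValueError("all values tied; median split impossible")
    order = np.lexsort((np.asarray(ids), -perf))  # best first, ties by id
    labels = np.empty(n, dtype=object)
    n_high = int(np.ceil(n / 2))
    labels[order[:n_high]] = "high"
    labels[order[n_high:]] = "low"
    return labels.astype(str)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mean_diff: float = float("nan")


def group_ttest_summary(mean1: float, sd1: float, n1: int,
                        mean2: float, sd2: float, n2: int,
                        variant: str = "welch") -> TTestResult:
    """Two-sample t-test from group summary statistics.

    variant="welch": unequal-variance t with Welch–Satterthwaite df;
    variant="pooled": Student t with df = n1 + n2 - 2.  Two-sided p.
    """
    if sd1 <= 0 or sd2 <= 0 or n1 < 2 or n2 < 2:
        raise ValueError("need sds > 0 and group sizes >= 2")
    diff = mean1 - mean2
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    if variant == "welch":
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    elif variant == "pooled":
        sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = float(n1 + n2 - 2)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    t = diff / se if se > 0 else 0.0
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p), mean_diff=diff)


def _design_matrix(labels: np.ndarray, covariates: np.ndarray | None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Cell-means design: [high, low] + zero-mean covariates; contrast high-low."""
    high = (np.asarray(labels) == "high").astype(float)
    cols = [high, 1.0 - high]
    if covariates is not None:
        covariates = np.asarray(covariates, float)
        cov = covariates - covariates.mean(axis=0, keepdims=True)
        cols.extend(cov.T)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    contrast = np.zeros(X.shape[1])
    contrast[0], contrast[1] = 1.0, -1.0
    return X, contrast


def _glm_tmap(Y: np.ndarray, X: np.ndarray, contrast: np.ndarray
              ) -> tuple[np.ndarray, int]:
    """Voxelwise OLS contrast t-map. Y is (n_subjects, V)."""
    n, k = X.shape
    df = n - k
    if df < 1:
        raise ValueError("need more subjects than design columns")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y  # (k, V)
    resid = Y - X @ beta
    sigma2 = (resid ** 2).sum(axis=0) / df
    c_var = float(contrast @ XtX_inv @ contrast)
    se = np.sqrt(c_var * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, contrast @ beta / se, 0.0)
    return t, df


@dataclass
class ClusterTable:
    """Cluster-extent inference output, one row per suprathreshold cluster."""

    sizes: list[int]
    peak_ts: list[float]
    peak_voxels: list[tuple[int, int, int]]
    corrected_ps: list[float]
    survives_bonferroni: list[bool]
    height_threshold_t: float
    height_p: float
    fwe_p: float
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cluster_size": self.sizes,
            "peak_t": self.peak_ts,
            "peak_x": [v[0] for v in self.peak_voxels],
            "peak_y": [v[1] for v in self.peak_voxels],
            "peak_z": [v[2] for v in self.peak_voxels],
            "p_fwe": self.corrected_ps,
            "survives_bonferroni": self.survives_bonferroni,
        })

    @property
    def any_significant(self) -> bool:
        return any(p < self.fwe_p for p in self.corrected_ps)


_STRUCTURES = {26: np.ones((3, 3, 3)),
               18: ndimage.generate_binary_structure(3, 2),
               6: ndimage.generate_binary_structure(3, 1)}


def _clusters(tmap: np.ndarray, thr: float, connectivity: int
              ) -> tuple[np.ndarray, int]:
    labeled, n = ndimage.label(tmap > thr, structure=_STRUCTURES[connectivity])
    return labeled, n


def _max_cluster_size(tmap: np.ndarray, thr: float, connectivity: int) -> int:
    labeled, n = _clusters(tmap, thr, connectivity)
    if n == 0:
        return 0
    return int(np.bincount(labeled.ravel())[1:].max())


@dataclass
class GroupGLMResults:
    """Voxelwise group contrast: t-map, df and cluster-level inference."""

    tmap: np.ndarray
    df: int
    labels: np.ndarray
    covariates: np.ndarray | None
    _Y: np.ndarray = field(repr=False)
    _shape: tuple[int, ...] = field(repr=False)
    clusters: ClusterTable | None = None

    def cluster_inference(self, height_p: float = 0.001, fwe_p: float = 0.05,
                          n_perm: int = 1000, seed: int = 0,
                          connectivity: int = 26,
                          n_networks: int = 6,
                          tail: str = "high>low") -> ClusterTable:
        """Permutation cluster-extent FWE on the group contrast.

        Group labels are permuted (covariates held fixed), the GLM refitted
        and the maximal suprathreshold cluster size recorded; a cluster's
        corrected p is the proportion of permutations whose maximum size
        reaches its own.  One-sided height threshold t_{height_p, df} in the
        direction given by ``tail``.
        """
        if n_perm < 100:
            warnings.warn(f"n_perm={n_perm} is small; corrected p-values "
                          "will be coarse", stacklevel=2)
        if tail not in ("high>low", "low>high"):
            raise ValueError(f"unknown tail {tail!r}")
        sign = 1.0 if tail == "high>low" else -1.0
        thr = float(stats.t.isf(height_p, self.df))
        tvol = sign * self.tmap.reshape(self._shape)
        labeled, n_clu = _clusters(tvol, thr, connectivity)
        sizes, peaks, peak_vox = [], [], []
        for c in range(1, n_clu + 1):
            in_c = labeled == c
            sizes.append(int(in_c.sum()))
            idx = np.unravel_index(np.argmax(np.where(in_c, tvol, -np.inf)),
                                   tvol.shape)
            peak_vox.append(tuple(int(i) for i in idx))
            peaks.append(float(tvol[idx]))
        rng = np.random.default_rng(seed)
        null_max = np.empty(n_perm)
        n_sub = len(self.labels)
        for b in range(n_perm):
            # redraw permutations whose relabelling makes the design
            # singular (e.g. group exactly aligned with a binary covariate)
            for _ in range(100):
                perm = rng.permutation(n_sub)
                try:
                    Xp, cp = _design_matrix(self.labels[perm], self.covariates)
                    break
                except ValueError:
                    continue
            else:
                raise ValueError("could not find a non-singular permutation")
            tp, _ = _glm_tmap(self._Y, Xp, cp)
            null_max[b] = _max_cluster_size(sign * tp.reshape(self._shape), thr,
                                            connectivity)
        ps = [float((1 + np.sum(null_max >= s)) / (1 + n_perm)) for s in sizes]
        bonf_thr = fwe_p / n_networks
        self.clusters = ClusterTable(
            sizes=sizes, peak_ts=peaks, peak_voxels=peak_vox,
            corrected_ps=ps,
            survives_bonferroni=[p < bonf_thr for p in ps],
            height_threshold_t=thr, height_p=height_p, fwe_p=fwe_p,
            n_perm=n_perm)
        return self.clusters

    def summary(self) -> str:
        lines = [f"Voxelwise group GLM: df = {self.df}, "
                 f"peak t = {np.nanmax(self.tmap):.3f}"]
        if self.clusters is not None:
            lines.append(self.clusters.to_frame().to_string(index=False))
        return "\n".join(lines)


class GroupGLM:
    """Voxelwise GLM of subject Z-maps on performance group + covariates.

    ``zmaps`` is (n_subjects, x, y, z) (or (n_subjects, V)); ``labels`` the
    high/low median-split labels; ``covariates`` an optional (n_subjects, k)
    array of nuisance variables, standardised to zero mean internally.
    """

    def __init__(self, zmaps: np.ndarray, labels: np.ndarray,
                 covariates: np.ndarray | None = None):
        zmaps = np.asarray(zmaps, float)
        self._shape = zmaps.shape[1:]
        self.Y = zmaps.reshape(zmaps.shape[0], -1)
        self.labels = np.asarray(labels)
        self.covariates = covariates

    @classmethod
    def from_dataframe(cls, zmaps: np.ndarray, design: pd.DataFrame,
                       split_on: str = "group",
                       covariate_cols: list[str] | None = None) -> "GroupGLM":
        cov = design[covariate_cols].to_numpy(float) if covariate_cols else None
        return cls(zmaps, design[split_on].to_numpy(), cov)

    def fit(self) -> GroupGLMResults:
        X, contrast = _design_matrix(self.labels, self.covariates)
        t, df = _glm_tmap(self.Y, X, contrast)
        return GroupGLMResults(tmap=t.reshape(self._shape), df=df,
                               labels=self.labels, covariates=self.covariates,
                               _Y=self.Y, _shape=self._shape)


def cluster_inference(tmap: np.ndarray, zmaps: np.ndarray, labels: np.ndarray,
                      covariates: np.ndarray | None = None,
                      height_p: float = 0.001, fwe_p: float = 0.05,
                      n_perm: int = 1000, seed: int = 0,
                      connectivity: int = 26,
                      n_networks: int = 6) -> ClusterTable:
    """Functional wrapper around :meth:`GroupGLMResults.cluster_inference`."""
    res = GroupGLM(zmaps, labels, covariates).fit()
    if tmap is not None and not np.allclose(res.tmap, tmap, atol=1e-8):
        raise ValueError("supplied t-map does not match the refitted GLM")
    return res.cluster_inference(height_p=height_p, fwe_p=fwe_p,
                                 n_perm=n_perm, seed=seed,
                                 connectivity=connectivity,
                                 n_networks=n_networks)


def bonferroni_networks(p: float, n_networks: int = 6,
                        fwe_p: float = 0.05) -> tuple[bool, float]:
    """Bonferroni across networks: survives iff p < fwe_p / n_networks."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    threshold = round(fwe_p / n_networks, 4)
    return p < threshold, threshold


def internetwork_group_test(z_values: np.ndarray, labels: np.ndarray,
                            tail: str = "high>low") -> TTestResult:
    """One-tailed pooled two-sample t-test of per-subject Fisher-z values."""
    z_values = np.asarray(z_values, float)
    labels = np.asarray(labels)
    hi, lo = z_values[labels == "high"], z_values[labels == "low"]
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError("both groups need >= 2 subjects")
    n1, n2 = len(hi), len(lo)
    sp2 = ((n1 - 1) * hi.var(ddof=1) + (n2 - 1) * lo.var(ddof=1)) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    t = (hi.mean() - lo.mean()) / se if se > 0 else 0.0
    df = n1 + n2 - 2
    if tail == "high>low":
        p = stats.t.sf(t, df)
    elif tail == "low>high":
        p = stats.t.cdf(t, df)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return TTestResult(t=float(t), df=float(df), p=float(p),
                       mean_diff=float(hi.mean() - lo.mean()))


def intra_network_scalar(zmaps: np.ndarray, mask: np.ndarray,
                         method: str = "mean") -> np.ndarray:
    """Per-subject scalar summary of intra-network FC within a mask.

    method="mean": average Z in the mask.  method="eigenvariate": first
    principal-component score of the subjects x voxels matrix restricted to
    the mask, sign-aligned with the mean scalar.
    """
    zmaps = np.asarray(zmaps, float)
    flat = zmaps.reshape(zmaps.shape[0], -1)
    keep = np.asarray(mask, bool).reshape(-1)
    if not keep.any():
        raise ValueError("empty network mask")
    sub = flat[:, keep]
    means = sub.mean(axis=1)
    if method == "mean":
        return means
    if method == "eigenvariate":
        centered = sub - sub.mean(axis=0, keepdims=True)
        U, S, Vt = np.linalg.svd(centered, full_matrices=False)
        scores = U[:, 0] * S[0]
        if np.corrcoef(scores, means)[0, 1] < 0:
            scores = -scores
        return scores + means.mean()
    raise ValueError(f"unknown method {method!r}")


def partial_correlation(x: np.ndarray, y: np.ndarray,
                        control: np.ndarray) -> tuple[float, float]:
    """Pearson correlation of x and y after removing control (+ intercept).

    Two-sided p from t = r sqrt(df / (1 - r^2)) with df = n - 2 - k_controls.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    control = np.atleast_2d(np.asarray(control, float))
    if control.shape[0] != len(x):
        control = control.T
    n = len(x)
    k = control.shape[1]
    if n <= k + 3:
        raise ValueError("too few observations for partial correlation")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input")
    X = np.column_stack([np.ones(n), control])
    rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
    ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    # a variable fully explained by the controls has no partial association
    if rx.std() < 1e-10 * x.std() or ry.std() < 1e-10 * y.std():
        return 0.0, 1.0
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    t = r * np.sqrt(df / max(1e-300, 1.0 - r ** 2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p
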