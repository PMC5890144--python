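"""Maximum-likelihood estimation of TVA parameters from trial tables.

Follows the statsmodels idiom: a Model is constructed from data, ``fit()``
returns a Results object carrying estimates, standard errors (inverse
observed-information), diagnostics and a ``summary()`` table.

Two sub-models:

* :class:`WholeReportModel` -- score counts from the 12-condition whole
  report task; estimates (C, K_mean, t0, mu).
* :class:`PartialReportModel` -- per-target report indicators from the
  16-condition partial-report task; estimates its own sensory rate and
  minimum effective exposure plus the weighting parameters (alpha, w_lat),
  with VSTM capacity fixed (normally from the whole-report fit).

:class:`TVAModel` chains the two and assembles a full six-parameter
:class:`~tvanet.params.TVAParams`.

Optimisation is bounded L-BFGS-B from a deterministic Latin-hypercube of
multi-starts (default 10); the per-subject seed makes fits reproducible.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from .design import partial_report_conditions, whole_report_conditions
from .params import DisplayCondition, TVAParams, capacity_pmf
from .race import effective_exposure, partial_report_joint, score_distribution

__all__ = [
    "WholeReportModel", "PartialReportModel", "TVAModel",
    "WholeReportResults", "PartialReportResults", "TVAResults",
    "loglik_whole", "loglik_partial",
]

WHOLE_BOUNDS = {"C": (1.0, 100.0), "K_mean": (0.5, 6.0),
                "t0": (0.0, 60.0), "mu": (0.0, 500.0)}
PARTIAL_BOUNDS = {"C": (1.0, 100.0), "t0": (0.0, 60.0),
                  "alpha": (1e-3, 4.0), "w_lat": (0.01, 0.99)}
DEFAULT_EPS = 1e-12


def _floored_log(p: np.ndarray | float, eps: float, counter: list[int]) -> np.ndarray:
    p = np.asarray(p, float)
    bad = p < eps
    if np.any(bad):
        counter[0] += int(np.sum(bad))
    return np.log(np.maximum(p, eps))


def loglik_whole(trials: pd.DataFrame, params: TVAParams,
                 n_items: int = 6, eps: float = DEFAULT_EPS) -> float:
    """Log-likelihood of observed whole-report scores under the race model."""
    counter = [0]
    ll = 0.0
    cap = params.capacity_pmf(n_max=n_items)
    for (t, masked), grp in trials.groupby(["exposure_ms", "masked"]):
        tau = effective_exposure(float(t), params.t0, params.mu, bool(masked))
        rates = np.full(n_items, params.C / n_items)
        pmf = score_distribution(rates, tau, cap)
        counts = np.bincount(grp["score"].to_numpy(int), minlength=n_items + 1)
        ll += float(counts @ _floored_log(pmf, eps, counter))
    return ll


def loglik_partial(trials: pd.DataFrame, params: TVAParams,
                   conditions: dict[str, DisplayCondition],
                   eps: float = DEFAULT_EPS) -> float:
    """Log-likelihood of per-target report indicators in partial report."""
    counter = [0]
    ll = 0.0
    for cond_id, grp in trials.groupby("cond_id"):
        cond = conditions[cond_id]
        joint = partial_report_joint(cond, params)
        targets = cond.target_indices
        for _, row in grp.iterrows():
            reported = frozenset(
                t for j, t in enumerate(targets)
                if bool(row[f"target{j + 1}_reported"]))
            ll += float(_floored_log(joint.get(reported, 0.0), eps, counter))
    return ll


def _multistart(neg_ll, bounds: list[tuple[float, float]], n_starts: int,
                seed: int, extra_starts: list[np.ndarray] | None = None):
    """Bounded quasi-Newton from a Latin-hypercube of starts.

    The objective is optimised in box-normalised coordinates (all parameters
    mapped to [0, 1]) so the finite-difference gradient is equally scaled in
    C (tens) and mu (hundreds of ms).
    """
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    span = hi - lo

    def neg_norm(u: np.ndarray) -> float:
        return neg_ll(lo + span * u)

    sampler = qmc.LatinHypercube(d=len(bounds), seed=seed)
    starts = list(sampler.random(n_starts))
    if extra_starts:
        starts = [(np.asarray(x) - lo) / span for x in extra_starts] + starts
    unit = [(0.0, 1.0)] * len(bounds)
    best, best_idx = None, -1
    n_converged = 0
    for i, u0 in enumerate(starts):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(neg_norm, u0, method="L-BFGS-B",
                                    bounds=unit,
                                    options={"maxiter": 200, "ftol": 1e-12,
                                             "gtol": 1e-8})
        if res.success:
            n_converged += 1
        if best is None or res.fun < best.fun:
            best, best_idx = res, i
    best.x = lo + span * best.x
    return best, best_idx, n_converged


def _numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.eye(n)[i] * h[i]
            ej = np.eye(n)[j] * h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def _bse_from_hessian(neg_ll, x: np.ndarray,
                      bounds: list[tuple[float, float]] | None = None
                      ) -> np.ndarray:
    try:
        if bounds is not None:
            # evaluate just inside the box so boundary estimates still get
            # a (one-sided) curvature estimate
            h = 2e-4 * np.maximum(np.abs(x), 1.0)
            lo = np.array([b[0] for b in bounds]) + h
            hi = np.array([b[1] for b in bounds]) - h
            x = np.clip(x, lo, hi)
        H = _numeric_hessian(neg_ll, x)
        cov = np.linalg.pinv(H)
        var = np.diag(cov)
        return np.where(var > 0, np.sqrt(np.maximum(var, 0.0)), np.nan)
    except Exception:  # SEs are a diagnostic nicety, never fatal
        return np.full(len(x), np.nan)


@dataclass
class _FitResultsBase:
    param_names: tuple[str, ...]
    x: np.ndarray
    bse: np.ndarray
    llf: float
    converged: bool
    n_converged: int
    best_start: int
    nobs: int

    @property
    def params_dict(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.x))

    def summary(self) -> str:
        lines = [
            f"{type(self).__name__}",
            "=" * 46,
            f"{'parameter':<12}{'estimate':>12}{'std err':>12}",
            "-" * 46,
        ]
        for name, val, se in zip(self.param_names, self.x, self.bse):
            lines.append(f"{name:<12}{val:>12.4f}{se:>12.4f}")
        lines += [
            "-" * 46,
            f"log-likelihood {self.llf:.3f}   nobs {self.nobs}",
            f"converged {self.converged} ({self.n_converged} starts), "
            f"best start #{self.best_start}",
        ]
        return "\n".join(lines)


class WholeReportResults(_FitResultsBase):
    pass


class PartialReportResults(_FitResultsBase):
    pass


class WholeReportModel:
    """ML model of whole-report score counts; parameters (C, K_mean, t0, mu)."""

    param_names = ("C", "K_mean", "t0", "mu")

    def __init__(self, trials: pd.DataFrame, n_items: int = 6,
                 eps: float = DEFAULT_EPS):
        required = {"exposure_ms", "masked", "score"}
        missing = required - set(trials.columns)
        if missing:
            raise ValueError(f"whole-report table missing columns: {sorted(missing)}")
        self.n_items = n_items
        self.eps = eps
        self.floor_count = 0
        # collapse to per-(exposure, masked) score counts once
        self._cells = []
        for (t, masked), grp in trials.groupby(["exposure_ms", "masked"]):
            counts = np.bincount(grp["score"].to_numpy(int), minlength=n_items + 1)
            self._cells.append((float(t), bool(masked), counts))
        self.nobs = int(len(trials))

    def loglike(self, x: np.ndarray) -> float:
        C, K, t0, mu = x
        cap = capacity_pmf(K, n_max=self.n_items)
        rates = np.full(self.n_items, C / self.n_items)
        counter = [0]
        ll = 0.0
        for t, masked, counts in self._cells:
            tau = effective_exposure(t, t0, mu, masked)
            pmf = score_distribution(rates, tau, cap)
            ll += float(counts @ _floored_log(pmf, self.eps, counter))
        self.floor_count += counter[0]
        return ll

    def fit(self, n_starts: int = 10, seed: int = 0) -> WholeReportResults:
        bounds = [WHOLE_BOUNDS[p] for p in self.param_names]
        neg = lambda x: -self.loglike(x)
        # moment-based warm start: mean score at longest exposure ~ K
        mean_long = max(0.6, min(5.9, self._moment_K()))
        warm = np.array([20.0, mean_long, 10.0, 100.0])
        best, idx, n_conv = _multistart(neg, bounds, n_starts, seed, [warm])
        return WholeReportResults(
            param_names=self.param_names, x=best.x,
            bse=_bse_from_hessian(neg, best.x, bounds), llf=-best.fun,
            converged=bool(best.success or n_conv > 0),
            n_converged=n_conv, best_start=idx, nobs=self.nobs)

    def _moment_K(self) -> float:
        longest = max(self._cells, key=lambda c: c[0] + (0 if c[1] else 1e6))
        counts = longest[2]
        return float(counts @ np.arange(len(counts)) / max(1, counts.sum()))


class PartialReportModel:
    """ML model of partial-report target reports; capacity held fixed.

    Parameters: own sensory rate C and minimum exposure t0 (the task is
    always masked, so mu does not enter), plus alpha and w_lat.
    """

    param_names = ("C", "t0", "alpha", "w_lat")

    def __init__(self, trials: pd.DataFrame, k_mean: float,
                 eps: float = DEFAULT_EPS):
        required = {"exposure_ms", "cond_id", "target1_reported"}
        missing = required - set(trials.columns)
        if missing:
            raise ValueError(f"partial-report table missing columns: {sorted(missing)}")
        self.k_mean = float(k_mean)
        self.eps = eps
        self.floor_count = 0
        exposure = float(trials["exposure_ms"].iloc[0])
        self._conditions = {c.cond_id: c for c in partial_report_conditions(exposure)}
        unknown = set(trials["cond_id"]) - set(self._conditions)
        if unknown:
            raise ValueError(f"unknown partial-report conditions: {sorted(unknown)}")
        # collapse to per-(condition, report-pattern) counts
        self._cells: list[tuple[DisplayCondition, dict[frozenset, int]]] = []
        for cond_id, grp in trials.groupby("cond_id"):
            cond = self._conditions[cond_id]
            targets = cond.target_indices
            patterns: dict[frozenset, int] = {}
            t1 = grp["target1_reported"].to_numpy()
            t2 = (grp["target2_reported"].to_numpy()
                  if "target2_reported" in grp and len(targets) > 1 else
                  np.zeros(len(grp)))
            for a, b in zip(t1, t2):
                key = frozenset(
                    t for j, t in enumerate(targets)
                    if (a if j == 0 else b))
                patterns[key] = patterns.get(key, 0) + 1
            self._cells.append((cond, patterns))
        self.nobs = int(len(trials))

    def loglike(self, x: np.ndarray) -> float:
        C, t0, alpha, w_lat = x
        params = TVAParams(C=C, K_mean=self.k_mean, t0=t0, mu=0.0,
                           alpha=alpha, w_lat=w_lat)
        counter = [0]
        ll = 0.0
        for cond, patterns in self._cells:
            joint = partial_report_joint(cond, params)
            for key, count in patterns.items():
                ll += count * float(_floored_log(joint.get(key, 0.0),
                                                 self.eps, counter))
        self.floor_count += counter[0]
        return ll

    def fit(self, n_starts: int = 10, seed: int = 0) -> PartialReportResults:
        bounds = [PARTIAL_BOUNDS[p] for p in self.param_names]
        neg = lambda x: -self.loglike(x)
        warm = np.array([20.0, 10.0, 0.5, 0.5])
        best, idx, n_conv = _multistart(neg, bounds, n_starts, seed, [warm])
        return PartialReportResults(
            param_names=self.param_names, x=best.x,
            bse=_bse_from_hessian(neg, best.x, bounds), llf=-best.fun,
            converged=bool(best.success or n_conv > 0),
            n_converged=n_conv, best_start=idx, nobs=self.nobs)


@dataclass
class TVAResults:
    """Joint whole+partial fit of one subject."""

    params: TVAParams
    whole: WholeReportResults
    partial: PartialReportResults
    subject_id: str = ""

    @property
    def converged(self) -> bool:
        return self.whole.converged and self.partial.converged

    @property
    def llf(self) -> float:
        return self.whole.llf + self.partial.llf

    def to_dict(self) -> dict:
        d = {"subject_id": self.subject_id}
        d.update(self.params.to_dict())
        d.update({
            "C_partial": self.partial.params_dict["C"],
            "t0_partial": self.partial.params_dict["t0"],
            "llf_whole": self.whole.llf, "llf_partial": self.partial.llf,
            "converged": self.converged,
        })
        return d

    def summary(self) -> str:
        hdr = f"TVA fit — subject {self.subject_id or '<unnamed>'}"
        return "\n".join([hdr, "=" * len(hdr),
                          self.whole.summary(), "", self.partial.summary()])


class TVAModel:
    """Joint TVA model for one subject: whole report then partial report.

    Whole report yields the capacity parameters (C, K_mean, t0, mu); partial
    report, with capacity fixed at the whole-report K_mean, yields the
    weighting parameters (alpha, w_lat).
    """

    def __init__(self, whole_trials: pd.DataFrame, partial_trials: pd.DataFrame,
                 subject_id: str = "", n_items: int = 6):
        self.whole_trials = whole_trials
        self.partial_trials = partial_trials
        self.subject_id = subject_id
        self.n_items = n_items

    @classmethod
    def from_trial_table(cls, trials: pd.DataFrame, subject_id: str | None = None,
                         n_items: int = 6) -> "TVAModel":
        """Build from a combined long table with a ``task`` column."""
        if subject_id is not None:
            trials = trials[trials["subject_id"].astype(str) == str(subject_id)]
            if trials.empty:
                raise ValueError(f"no trials for subject {subject_id!r}")
        else:
            ids = trials["subject_id"].unique()
            if len(ids) != 1:
                raise ValueError("table holds several subjects; pass subject_id")
            subject_id = str(ids[0])
        return cls(trials[trials["task"] == "whole"],
                   trials[trials["task"] == "partial"],
                   subject_id=str(subject_id), n_items=n_items)

    def fit(self, n_starts: int = 10, seed: int | None = None) -> TVAResults:
        if seed is None:
            # deterministic per-subject seed (hash() is salted per process)
            seed = zlib.crc32(self.subject_id.encode()) % (2**31 - 3)
        whole = WholeReportModel(self.whole_trials, n_items=self.n_items)
        wres = whole.fit(n_starts=n_starts, seed=seed)
        partial = PartialReportModel(self.partial_trials,
                                     k_mean=wres.params_dict["K_mean"])
        pres = partial.fit(n_starts=n_starts, seed=seed + 1)
        w, p = wres.params_dict, pres.params_dict
        params = TVAParams(C=w["C"], K_mean=w["K_mean"], t0=w["t0"], mu=w["mu"],
                           alpha=p["alpha"], w_lat=p["w_lat"])
        return TVAResults(params=params, whole=wres, partial=pres,
                          subject_id=self.subject_id)


def fit_all_subjects(trials: pd.DataFrame, n_starts: int = 10,
                     seed: int = 0) -> pd.DataFrame:
    """Fit every subject in a combined trial table; one row per subject."""
    rows = []
    for i, (sid, grp) in enumerate(trials.groupby("subject_id", sort=True)):
        model = TVAModel.from_trial_table(grp, subject_id=str(sid))
        res = model.fit(n_starts=n_starts, seed=seed + 17 * i)
        rows.append(res.to_dict())
    return pd.DataFrame(rows)
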