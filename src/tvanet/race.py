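"""Exact and Monte-Carlo evaluation of the fixed-capacity exponential race.

Each item *i* finishes at an independent Exp(v_i) time.  Items finishing
within the effective exposure ``tau`` are *encoded*; of those, only the first
``K`` finishers are *retained* in VSTM.  For whole report the observable is
the number of retained items; for partial report it is which targets were
retained (distractors occupy capacity but are never reported).

Two exact computations are provided:

* :func:`score_distribution` -- distribution of the retained count.  Race
  order is irrelevant for the count, so this reduces to a Poisson-binomial
  of the per-item finish probabilities, capped at capacity.
* :func:`encoded_set_distribution` -- joint distribution over the retained
  *set*, by enumeration over finisher subsets and finishing orders.  The
  probability that a subset finishes in a given order within ``tau`` has a
  closed form: the sequential-minimum decomposition gives the order
  probability times a hypoexponential CDF with strictly decreasing stage
  rates (the partial sums of the remaining rates).

Enumeration is exact up to ``ENUMERATION_LIMIT`` items; beyond that the
Monte-Carlo sampler :func:`monte_carlo_race` is the oracle of choice.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np

from .params import DisplayCondition, TVAParams, capacity_pmf

__all__ = [
    "ENUMERATION_LIMIT",
    "effective_exposure",
    "score_distribution",
    "report_distribution",
    "encoded_set_distribution",
    "partial_report_joint",
    "partial_report_prob",
    "monte_carlo_race",
    "monte_carlo_scores",
]

ENUMERATION_LIMIT = 8
_MIN_RATE = 1e-12


class EnumerationLimitError(ValueError):
    """Raised when a display is too large for exact enumeration.

    Signals that the Monte-Carlo oracle should be used instead.
    """


def effective_exposure(t: float, t0: float, mu: float = 0.0, masked: bool = True) -> float:
    """Effective exposure duration tau in seconds.

    Masked displays are processed for t - t0; unmasked displays gain an
    additional mu milliseconds of iconic-memory buffering: t - t0 + mu.
    Negative effective durations clamp to zero.
    """
    if t < 0 or t0 < 0 or mu < 0:
        raise ValueError("t, t0 and mu must all be >= 0")
    eff = t - t0 if masked else t - t0 + mu
    return max(0.0, eff) / 1000.0


def _finish_probs(rates: np.ndarray, tau: float) -> np.ndarray:
    return -np.expm1(-np.asarray(rates, float) * tau)


def _poisson_binomial(p: np.ndarray) -> np.ndarray:
    """PMF of a sum of independent Bernoulli(p_i), by dynamic programming."""
    pmf = np.array([1.0])
    for pi in p:
        pmf = np.convolve(pmf, [1.0 - pi, pi])
    return pmf


def score_distribution(
    rates: np.ndarray,
    tau: float,
    cap_pmf: np.ndarray,
) -> np.ndarray:
    """Exact PMF of the number of retained items (whole-report score).

    ``cap_pmf`` is a probability vector over integer capacities 0..len-1.
    The retained count is min(#finishers, K) marginalised over K, and does
    not depend on *which* items finish first.
    """
    rates = np.asarray(rates, float)
    if tau < 0:
        raise ValueError("tau must be >= 0")
    cap_pmf = np.asarray(cap_pmf, float)
    if abs(cap_pmf.sum() - 1.0) > 1e-9:
        raise ValueError("capacity pmf must sum to 1")
    n = len(rates)
    count_pmf = _poisson_binomial(_finish_probs(rates, tau))
    out = np.zeros(n + 1)
    for k, pk in enumerate(cap_pmf):
        if pk == 0.0:
            continue
        capped = np.zeros(n + 1)
        kk = min(k, n)
        capped[:kk] = count_pmf[:kk]
        capped[kk] = count_pmf[kk:].sum()
        out += pk * capped
    return out


def report_distribution(cond: DisplayCondition, params: TVAParams,
                        C: float | None = None,
                        cap_pmf: np.ndarray | None = None) -> np.ndarray:
    """Whole-report score distribution for a display condition."""
    if cond.n_items > ENUMERATION_LIMIT:
        raise EnumerationLimitError(
            f"{cond.n_items} items exceed the exact-enumeration limit "
            f"({ENUMERATION_LIMIT}); use the Monte-Carlo oracle")
    tau = effective_exposure(cond.exposure_ms, params.t0, params.mu, cond.masked)
    if cap_pmf is None:
        cap_pmf = params.capacity_pmf(n_max=cond.n_items)
    return score_distribution(cond.rates(params, C=C), tau, cap_pmf)


def _hypoexp_cdf(lams: np.ndarray, tau: float) -> float:
    """CDF at tau of a sum of independent exponentials with distinct rates."""
    lams = np.asarray(lams, float)
    m = len(lams)
    if m == 0:
        return 1.0
    s = 0.0
    for k in range(m):
        num = 1.0
        for j in range(m):
            if j != k:
                num *= lams[j] / (lams[j] - lams[k])
        s += num * np.exp(-lams[k] * tau)
    return float(np.clip(1.0 - s, 0.0, 1.0))


def _order_prob(rates_in_order: np.ndarray, tau: float) -> float:
    """P(T_{i1} < ... < T_{im} <= tau) for independent exponentials.

    Sequential-minimum decomposition: the probability of the order is the
    product of v_{ik} / V_k with V_k the sum of not-yet-finished rates, and
    the time of the final finisher is hypoexponential with stage rates V_k
    (strictly decreasing, hence distinct).
    """
    v = np.asarray(rates_in_order, float)
    tails = np.cumsum(v[::-1])[::-1]
    sel = float(np.prod(v / tails))
    return sel * _hypoexp_cdf(tails, tau)


def encoded_set_distribution(
    rates: np.ndarray,
    tau: float,
    capacity: int,
) -> dict[frozenset, float]:
    """Exact distribution over the retained item set at fixed capacity.

    Enumerates finisher subsets (independent finish events) and, where the
    subset exceeds capacity, finishing orders of its members to determine
    the first-K finishers.
    """
    rates = np.asarray(rates, float)
    n = len(rates)
    if n > ENUMERATION_LIMIT:
        raise EnumerationLimitError(
            f"{n} items exceed the exact-enumeration limit ({ENUMERATION_LIMIT})")
    active = [i for i in range(n) if rates[i] > _MIN_RATE]
    p = _finish_probs(rates, tau)
    out: dict[frozenset, float] = {}

    def add(s: frozenset, prob: float) -> None:
        if prob > 0.0:
            out[s] = out.get(s, 0.0) + prob

    for m in range(len(active) + 1):
        for subset in combinations(active, m):
            others = [i for i in active if i not in subset]
            p_not = float(np.prod([1.0 - p[i] for i in others])) if others else 1.0
            if p_not == 0.0:
                continue
            if m <= capacity:
                p_all = float(np.prod([p[i] for i in subset])) if subset else 1.0
                add(frozenset(subset), p_all * p_not)
            else:
                # race order decides which `capacity` members are retained
                for perm in permutations(subset):
                    prob = _order_prob(rates[list(perm)], tau) * p_not
                    add(frozenset(perm[:capacity]), prob)
    return out


def partial_report_joint(
    cond: DisplayCondition,
    params: TVAParams,
    C: float | None = None,
    cap_pmf: np.ndarray | None = None,
) -> dict[frozenset, float]:
    """Joint distribution over the set of *reported targets*.

    Distractors consume VSTM capacity when they win the race but are never
    reported.  Keys are frozensets of target indices (into cond.items).
    """
    rates = cond.rates(params, C=C)
    tau = effective_exposure(cond.exposure_ms, params.t0, params.mu, cond.masked)
    if cap_pmf is None:
        cap_pmf = params.capacity_pmf(n_max=cond.n_items)
    targets = set(cond.target_indices)
    out: dict[frozenset, float] = {}
    for k, pk in enumerate(np.asarray(cap_pmf, float)):
        if pk == 0.0:
            continue
        for retained, prob in encoded_set_distribution(rates, tau, k).items():
            key = frozenset(retained & targets)
            out[key] = out.get(key, 0.0) + pk * prob
    return out


def partial_report_prob(cond: DisplayCondition, params: TVAParams,
                        C: float | None = None,
                        cap_pmf: np.ndarray | None = None) -> np.ndarray:
    """Marginal report probability of each target in the display."""
    joint = partial_report_joint(cond, params, C=C, cap_pmf=cap_pmf)
    targets = cond.target_indices
    probs = np.zeros(len(targets))
    for reported, prob in joint.items():
        for j, t in enumerate(targets):
            if t in reported:
                probs[j] += prob
    return probs


def monte_carlo_race(
    rates: np.ndarray,
    tau: float,
    cap_pmf: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate the race directly: returns (n_samples, n_items) retention bools.

    This is the brute-force oracle against which the exact enumeration is
    validated: draw exponential finishing times, apply the exposure cut-off,
    retain the first-K finishers.
    """
    rates = np.asarray(rates, float)
    n = len(rates)
    safe = np.where(rates > _MIN_RATE, rates, _MIN_RATE)
    times = rng.exponential(1.0 / safe, size=(n_samples, n))
    times[:, rates <= _MIN_RATE] = np.inf
    finished = times <= tau
    caps = rng.choice(len(cap_pmf), size=n_samples, p=np.asarray(cap_pmf, float))
    # rank finishing times; an item is retained iff finished and rank < K
    order = np.argsort(times, axis=1)
    ranks = np.empty_like(order)
    rows = np.arange(n_samples)[:, None]
    ranks[rows, order] = np.arange(n)[None, :]
    return finished & (ranks < caps[:, None])


def monte_carlo_scores(
    rates: np.ndarray,
    tau: float,
    cap_pmf: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Monte-Carlo whole-report score PMF estimate (with the race oracle)."""
    retained = monte_carlo_race(rates, tau, cap_pmf, n_samples, rng)
    scores = retained.sum(axis=1)
    return np.bincount(scores, minlength=len(rates) + 1) / n_samples
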