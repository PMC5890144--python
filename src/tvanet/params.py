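"""Domain types for the fixed-capacity exponential race model of visual attention.

The model (Bundesen's Theory of Visual Attention, TVA) describes brief-display
letter report as a race: every item in the display is encoded into visual
short-term memory (VSTM) after an exponentially distributed processing time
with rate

    v_i = C * w_i / sum_j w_j          [items/second]

where ``C`` is the total processing rate and ``w_i`` the attentional weight of
item *i*.  Items whose processing completes within the effective exposure
duration are encoded, but at most ``K`` items (the VSTM capacity) are retained
-- the first ``K`` finishers of the race.

Six behavioural quantities summarise a subject:

``C``       processing speed, items/s
``K_mean``  VSTM storage capacity, items (mean of an integer capacity mixture)
``t0``      minimum effective exposure duration, ms
``mu``      additional effective exposure for unmasked displays, ms
``alpha``   top-down control: distractor/target weight ratio (lower = more
            selective)
``w_lat``   spatial laterality: left-hemifield share of attentional weight
            (0.5 = balanced)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TVAParams",
    "Item",
    "DisplayCondition",
    "alpha_from_weights",
    "w_lat_from_weights",
    "weights_from_alpha_wlat",
    "capacity_pmf",
]


def capacity_pmf(k_mean: float, n_max: int = 8) -> np.ndarray:
    """Two-point integer capacity mixture on {floor(K), ceil(K)} with mean K.

    Returns a probability vector over capacities 0..n_max.  A real-valued
    asymptote such as K = 3.03 is realised as P(K=3) = 0.97, P(K=4) = 0.03.
    """
    if k_mean < 0:
        raise ValueError(f"K_mean must be >= 0, got {k_mean}")
    pmf = np.zeros(n_max + 1)
    lo = int(np.floor(k_mean))
    frac = k_mean - lo
    if lo >= n_max:
        pmf[n_max] = 1.0
        return pmf
    pmf[lo] = 1.0 - frac
    pmf[lo + 1] = frac
    return pmf


def alpha_from_weights(w_targets: Sequence[float], w_distractors: Sequence[float]) -> float:
    """Top-down control: ratio of summed distractor to summed target weights."""
    wt = float(np.sum(w_targets))
    wd = float(np.sum(w_distractors))
    if wt <= 0:
        raise ValueError("total target weight must be positive")
    return wd / wt


def w_lat_from_weights(w_left: float, w_right: float) -> float:
    """Spatial laterality: left share of attentional weight, w_l/(w_l+w_r)."""
    total = w_left + w_right
    if total <= 0:
        raise ValueError("w_left + w_right must be positive")
    return w_left / total


def weights_from_alpha_wlat(alpha: float, w_lat: float) -> dict[str, float]:
    """Reconstruct the four hemifield/role weights from (alpha, w_lat).

    Weights are scale-invariant; the target weights are normalised to sum to 1.
    """
    if not 0.0 < w_lat < 1.0:
        raise ValueError(f"w_lat must be in (0, 1), got {w_lat}")
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    return {
        "w_target_left": w_lat,
        "w_target_right": 1.0 - w_lat,
        "w_distractor_left": alpha * w_lat,
        "w_distractor_right": alpha * (1.0 - w_lat),
    }


@dataclass(frozen=True)
class TVAParams:
    """The six TVA parameters of one subject, plus the underlying weights."""

    C: float
    K_mean: float
    t0: float = 0.0
    mu: float = 0.0
    alpha: float = 1.0
    w_lat: float = 0.5

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError(f"C must be > 0, got {self.C}")
        if self.K_mean <= 0:
            raise ValueError(f"K_mean must be > 0, got {self.K_mean}")
        if self.t0 < 0 or self.mu < 0:
            raise ValueError("t0 and mu must be >= 0")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if not 0.0 < self.w_lat < 1.0:
            raise ValueError(f"w_lat must be in (0, 1), got {self.w_lat}")

    @property
    def weights(self) -> dict[str, float]:
        return weights_from_alpha_wlat(self.alpha, self.w_lat)

    def weight(self, hemifield: str, role: str) -> float:
        side = self.w_lat if hemifield == "left" else 1.0 - self.w_lat
        return side * (self.alpha if role == "distractor" else 1.0)

    def capacity_pmf(self, n_max: int = 8) -> np.ndarray:
        return capacity_pmf(self.K_mean, n_max=n_max)

    def to_dict(self) -> dict[str, float]:
        d = {"C": self.C, "K_mean": self.K_mean, "t0": self.t0, "mu": self.mu,
             "alpha": self.alpha, "w_lat": self.w_lat}
        d.update(self.weights)
        return d


@dataclass(frozen=True)
class Item:
    """One display item: screen position, hemifield and task role."""

    position: str
    hemifield: str  # "left" | "right"
    role: str = "target"  # "target" | "distractor"

    def __post_init__(self) -> None:
        if self.hemifield not in ("left", "right"):
            raise ValueError(f"hemifield must be left/right, got {self.hemifield}")
        if self.role not in ("target", "distractor"):
            raise ValueError(f"role must be target/distractor, got {self.role}")


@dataclass(frozen=True)
class DisplayCondition:
    """A display layout plus exposure: what raced on a given trial type."""

    items: tuple[Item, ...]
    exposure_ms: float
    masked: bool
    cond_id: str = ""

    def __post_init__(self) -> None:
        if not any(it.role == "target" for it in self.items):
            raise ValueError("display must contain at least one target")
        positions = [it.position for it in self.items]
        if len(set(positions)) != len(positions):
            raise ValueError("item positions must be unique")
        if self.exposure_ms < 0:
            raise ValueError("exposure must be >= 0")

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def target_indices(self) -> tuple[int, ...]:
        return tuple(i for i, it in enumerate(self.items) if it.role == "target")

    def rates(self, params: TVAParams, C: float | None = None) -> np.ndarray:
        """Per-item encoding rates v_i = C * w_i / sum(w), items/second."""
        C = params.C if C is None else C
        w = np.array([params.weight(it.hemifield, it.role) for it in self.items])
        total = w.sum()
        if total <= 0:
            raise ValueError("total attentional weight must be positive")
        return C * w / total
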