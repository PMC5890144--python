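"""Experimental designs for the whole- and partial-report tasks.

Whole report: 6-letter single-hemifield columns, 12 conditions =
2 masking x 3 exposure durations x 2 hemifields; 192 trials in 4 blocks of
48 (each condition 4x per block).

Partial report: letters at the corners of an imaginary square, always
masked, 16 conditions = 4 single-target + 8 target-plus-distractor
(horizontal or vertical neighbour) + 4 dual-target (row or column pairs);
288 trials in 6 blocks of 48 (each condition 3x per block).

Exposure durations are individually calibrated: the whole-report middle
duration is the masked exposure at which the expected score is one letter,
and the partial-report duration is where single-target accuracy is 80%.
"""

from __future__ import annotations

import numpy as np

from .params import DisplayCondition, Item, TVAParams
from .race import effective_exposure, report_distribution, score_distribution

__all__ = [
    "whole_report_conditions",
    "partial_report_conditions",
    "expected_whole_score",
    "calibrate_exposures",
    "WHOLE_N_ITEMS",
    "WHOLE_TRIALS",
    "PARTIAL_TRIALS",
    "WHOLE_BLOCKS",
    "PARTIAL_BLOCKS",
]

WHOLE_N_ITEMS = 6
WHOLE_TRIALS = 192
WHOLE_BLOCKS = 4
PARTIAL_TRIALS = 288
PARTIAL_BLOCKS = 6

# corners of the imaginary partial-report square
_CORNERS = {
    "TL": "left", "BL": "left", "TR": "right", "BR": "right",
}
_H_NEIGHBOUR = {"TL": "TR", "TR": "TL", "BL": "BR", "BR": "BL"}
_V_NEIGHBOUR = {"TL": "BL", "BL": "TL", "TR": "BR", "BR": "TR"}


def whole_report_conditions(
    exposures: dict[str, float],
    n_items: int = WHOLE_N_ITEMS,
) -> list[DisplayCondition]:
    """The 12 whole-report conditions: masking x {short,middle,long} x hemifield."""
    if set(exposures) != {"short", "middle", "long"}:
        raise ValueError("exposures must have keys short/middle/long")
    conds = []
    for masked in (True, False):
        for dur_name in ("short", "middle", "long"):
            for hemi in ("left", "right"):
                items = tuple(
                    Item(position=f"{hemi[0].upper()}{i}", hemifield=hemi, role="target")
                    for i in range(n_items)
                )
                conds.append(DisplayCondition(
                    items=items,
                    exposure_ms=float(exposures[dur_name]),
                    masked=masked,
                    cond_id=f"W-{'m' if masked else 'u'}-{dur_name}-{hemi}",
                ))
    return conds


def partial_report_conditions(exposure_ms: float) -> list[DisplayCondition]:
    """The 16 masked partial-report conditions on the imaginary square."""
    conds: list[DisplayCondition] = []
    for corner, hemi in _CORNERS.items():  # 4 single-target
        conds.append(DisplayCondition(
            items=(Item(corner, hemi, "target"),),
            exposure_ms=exposure_ms, masked=True, cond_id=f"P-T{corner}",
        ))
    for corner, hemi in _CORNERS.items():  # 8 target + distractor
        for axis, nb_map in (("h", _H_NEIGHBOUR), ("v", _V_NEIGHBOUR)):
            nb = nb_map[corner]
            conds.append(DisplayCondition(
                items=(Item(corner, hemi, "target"),
                       Item(nb, _CORNERS[nb], "distractor")),
                exposure_ms=exposure_ms, masked=True,
                cond_id=f"P-T{corner}-D{nb}",
            ))
    for pair in (("TL", "TR"), ("BL", "BR"), ("TL", "BL"), ("TR", "BR")):  # 4 dual
        conds.append(DisplayCondition(
            items=tuple(Item(c, _CORNERS[c], "target") for c in pair),
            exposure_ms=exposure_ms, masked=True,
            cond_id=f"P-T{pair[0]}-T{pair[1]}",
        ))
    assert len(conds) == 16
    return conds


def expected_whole_score(
    params: TVAParams,
    t_ms: float,
    masked: bool = True,
    n_items: int = WHOLE_N_ITEMS,
) -> float:
    """Expected number of correctly reported letters at nominal exposure t."""
    tau = effective_exposure(t_ms, params.t0, params.mu, masked)
    rates = np.full(n_items, params.C / n_items)
    pmf = score_distribution(rates, tau, params.capacity_pmf(n_max=n_items))
    return float(pmf @ np.arange(n_items + 1))


class CalibrationError(RuntimeError):
    """The calibration criterion is unreachable for these parameters."""


def _bisect(f, lo: float, hi: float, tol: float) -> float:
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise CalibrationError("criterion not bracketed by the exposure range")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrate_exposures(
    params: TVAParams,
    task: str,
    factors: tuple[float, float] = (0.5, 2.0),
    accuracy: float = 0.80,
    tol_ms: float = 0.1,
    t_max_ms: float = 5000.0,
) -> dict[str, float]:
    """Individualised exposure durations, as in the pretest procedure.

    Whole report: the middle duration t* solves E[masked score](t*) = 1
    letter; short/long are factors*t* (defaults 0.5 and 2).  Partial report:
    t* solves single-target accuracy = ``accuracy`` (default 80%).
    """
    if task == "whole":
        asymptote = min(WHOLE_N_ITEMS, params.K_mean)
        if asymptote <= 1.0:
            raise CalibrationError(
                f"expected score asymptote {asymptote:.2f} never reaches 1 letter")
        t_star = _bisect(
            lambda t: expected_whole_score(params, t, masked=True) - 1.0,
            params.t0, params.t0 + t_max_ms, tol_ms)
        return {"short": factors[0] * t_star, "middle": t_star,
                "long": factors[1] * t_star}
    if task == "partial":
        # single target receives the whole rate C; accuracy = 1 - exp(-C tau)
        def acc(t: float) -> float:
            tau = effective_exposure(t, params.t0, 0.0, masked=True)
            return -float(np.expm1(-params.C * tau))
        t_star = _bisect(lambda t: acc(t) - accuracy, params.t0,
                         params.t0 + t_max_ms, tol_ms)
        return {"single": t_star}
    raise ValueError(f"unknown task {task!r}")
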