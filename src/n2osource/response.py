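"""Paired control-vs-acidified response statistics.

Pairing is by (station, depth, substrate, replicate).  Percent change is
100 * (treated - control) / control, so negative values mean inhibition
under acidification.  Summaries are medians with IQRs (linear
interpolation between order statistics), percentile-bootstrap CIs for
the median, and a leave-one-station-out robustness check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .records import RateRecord

__all__ = [
    "PairedResponse",
    "METRICS",
    "percent_change",
    "median_iqr",
    "bootstrap_median_ci",
    "leave_one_station_out",
    "build_paired_responses",
    "summarize_metric",
]

METRICS = ("nitrification", "n2o_production", "yield")

_METRIC_ATTR = {
    "nitrification": "r_nitr",
    "n2o_production": "r_n2o",
    "yield": "yield_n2o",
}
_METRIC_LOD_FLAG = {
    "nitrification": "below_lod_nitr",
    "n2o_production": "below_lod_n2o",
    # a yield is unusable if either underlying rate is censored
    "yield": None,
}


@dataclass(frozen=True)
class PairedResponse:
    """One control/acidified pair with its percent change."""

    station_id: str
    depth: float
    substrate: str
    metric: str
    replicate: int
    control_value: float
    treated_value: float
    pct_change: float  # %


def percent_change(control: float, treated: float) -> float:
    """100 * (treated - control) / control; control must be positive."""
    if not control > 0:
        raise ValueError(f"control must be > 0 for a defined percent change, "
                         f"got {control}")
    return 100.0 * (treated - control) / control


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, q1, q3) with linear interpolation between order statistics."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("median_iqr requires at least one value")
    q1, med, q3 = np.percentile(v, [25.0, 50.0, 75.0], method="linear")
    return float(med), float(q1), float(q3)


def bootstrap_median_ci(
    values: Sequence[float],
    n_resamples: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the median; reproducible given seed."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("bootstrap_median_ci requires at least 2 values")
    if n_resamples < 100:
        raise ValueError(f"n_resamples must be >= 100, got {n_resamples}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_resamples, v.size))
    meds = np.median(v[idx], axis=1)
    lo = (1.0 - level) / 2.0 * 100.0
    qlo, qhi = np.percentile(meds, [lo, 100.0 - lo])
    return float(qlo), float(qhi)


def leave_one_station_out(
    responses: Sequence[PairedResponse],
) -> dict[str, float]:
    """Median percent change recomputed with each station excluded.

    Returns {station_id: leave-out median}; use min/max of the values
    for the robustness spread.
    """
    stations = sorted({r.station_id for r in responses})
    if len(stations) < 2:
        raise ValueError("leave_one_station_out requires >= 2 distinct stations")
    out = {}
    for st in stations:
        vals = [r.pct_change for r in responses if r.station_id != st]
        out[st] = float(np.median(vals))
    return out


def build_paired_responses(
    rates: Sequence[RateRecord],
    metric: str,
    pool_depths: bool = True,
) -> tuple[list[PairedResponse], int]:
    """Pair control and acidified bottles and compute percent changes.

    Pairs on (station, depth, substrate, replicate).  A pair is dropped
    when either member is censored for the metric (for yields: when any
    underlying rate of either member is censored), when the metric value
    is undefined, or when the control is non-positive.  Returns the
    responses and the number of dropped/unpaired candidates.

    ``pool_depths`` is accepted for signature symmetry with
    :func:`summarize_metric`; pairing itself is always per depth.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    attr = _METRIC_ATTR[metric]
    by_key: dict[tuple, dict[str, RateRecord]] = {}
    for rec in rates:
        key = (rec.station_id, rec.depth, rec.substrate, rec.replicate)
        by_key.setdefault(key, {})[rec.treatment] = rec

    def censored(rec: RateRecord) -> bool:
        if metric == "yield":
            return rec.below_lod_nitr or rec.below_lod_n2o
        return getattr(rec, _METRIC_LOD_FLAG[metric])

    responses = []
    dropped = 0
    for key, members in sorted(by_key.items()):
        if "control" not in members or "acidified" not in members:
            dropped += 1
            continue
        ctrl, trt = members["control"], members["acidified"]
        if censored(ctrl) or censored(trt):
            dropped += 1
            continue
        c, t = getattr(ctrl, attr), getattr(trt, attr)
        if c is None or t is None or not (math.isfinite(c) and math.isfinite(t)):
            dropped += 1
            continue
        if not c > 0:
            dropped += 1
            continue
        responses.append(
            PairedResponse(
                station_id=key[0],
                depth=key[1],
                substrate=key[2],
                metric=metric,
                replicate=key[3],
                control_value=c,
                treated_value=t,
                pct_change=percent_change(c, t),
            )
        )
    return responses, dropped


def summarize_metric(
    responses: Sequence[PairedResponse],
    n_resamples: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
    per_station_first: bool = False,
) -> dict:
    """Median (IQR), bootstrap CI and LOSO spread for a response set.

    With ``per_station_first`` the pairs are collapsed to per-station
    medians before the across-station summary (the default pools all
    pairs).
    """
    if len(responses) == 0:
        raise ValueError("no paired responses to summarize")
    if per_station_first:
        by_st: dict[str, list[float]] = {}
        for r in responses:
            by_st.setdefault(r.station_id, []).append(r.pct_change)
        values = [float(np.median(v)) for _, v in sorted(by_st.items())]
    else:
        values = [r.pct_change for r in responses]
    med, q1, q3 = median_iqr(values)
    summary = {
        "n_pairs": len(responses),
        "median_pct": med,
        "q1_pct": q1,
        "q3_pct": q3,
    }
    if len(values) >= 2:
        lo, hi = bootstrap_median_ci(values, n_resamples, level, seed)
        summary["boot_ci_low"] = lo
        summary["boot_ci_high"] = hi
    stations = {r.station_id for r in responses}
    if len(stations) >= 2:
        loso = leave_one_station_out(responses)
        summary["loso_min"] = min(loso.values())
        summary["loso_max"] = max(loso.values())
    return summary
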