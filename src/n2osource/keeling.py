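"""Site preference, Keeling regression and atmospheric correction.

Under two-pool mixing of a fixed atmospheric background with microbially
produced N2O,

    C_obs = C_atm + C_micro
    d_obs * C_obs = d_atm * C_atm + d_micro * C_micro,

the observed signal is exactly linear in 1/C_obs and the y-intercept of
an ordinary least squares fit of signal against 1/C_obs estimates the
microbial endmember d_micro.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .records import IsotopomerRecord

__all__ = [
    "SIGNALS",
    "KeelingFit",
    "AtmosphericEndmember",
    "site_preference",
    "fit_keeling",
    "keeling_significance_gate",
    "correct_atmospheric",
    "corrected_sigma",
]

SIGNALS = ("d15n_bulk", "d18o", "sp")


class InsufficientDataError(ValueError):
    """Fewer usable records than the regression requires."""


class DegenerateDesignError(ValueError):
    """Zero variance in the regressor (1/c_n2o)."""


@dataclass(frozen=True)
class KeelingFit:
    """OLS fit of an isotope signal against inverse N2O concentration."""

    signal: str
    n: int
    slope: float  # permil * nmol L-1
    intercept: float  # permil, microbial endmember estimate
    intercept_ci95: tuple[float, float]  # permil
    pearson_r: float
    p_value: float


@dataclass(frozen=True)
class AtmosphericEndmember:
    """Fixed atmospheric pool used for per-sample correction."""

    c_n2o: float  # nmol L-1 at equilibrium with the atmosphere
    d15n_bulk: float  # permil
    d18o: float  # permil
    sp: float  # permil

    def signal(self, name: str) -> float:
        return getattr(self, name)


def site_preference(d15n_alpha: float, d15n_beta: float) -> float:
    """Intramolecular 15N site preference: alpha minus beta (permil)."""
    if d15n_alpha is None or d15n_beta is None:
        raise ValueError("both d15n_alpha and d15n_beta are required")
    if not (math.isfinite(d15n_alpha) and math.isfinite(d15n_beta)):
        raise ValueError("d15n_alpha and d15n_beta must be finite")
    return d15n_alpha - d15n_beta


def _usable(records: Iterable[IsotopomerRecord], signal: str, layer: str):
    xs, ys = [], []
    for rec in records:
        if rec.layer != layer:
            continue
        y = getattr(rec, signal)
        if y is None or not math.isfinite(y):
            continue
        if rec.c_n2o is None or not math.isfinite(rec.c_n2o) or rec.c_n2o <= 0:
            continue
        xs.append(1.0 / rec.c_n2o)
        ys.append(y)
    return np.asarray(xs, dtype=float), np.asarray(ys, dtype=float)


def fit_keeling(
    records: Sequence[IsotopomerRecord], signal: str, layer: str
) -> KeelingFit:
    """OLS of ``signal`` against 1/c_n2o for records in ``layer``.

    The intercept estimates the microbial endmember; its 95% CI uses the
    t distribution with n-2 degrees of freedom on the OLS intercept
    standard error.
    """
    if signal not in SIGNALS:
        raise ValueError(f"signal must be one of {SIGNALS}, got {signal!r}")
    x, y = _usable(records, signal, layer)
    n = len(x)
    if n < 3:
        raise InsufficientDataError(
            f"need >= 3 usable records for layer {layer!r} signal {signal!r}, got {n}"
        )
    if np.ptp(x) == 0:
        raise DegenerateDesignError("zero variance in 1/c_n2o")
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, n - 2)
    half = tcrit * res.intercept_stderr
    return KeelingFit(
        signal=signal,
        n=n,
        slope=float(res.slope),
        intercept=float(res.intercept),
        intercept_ci95=(float(res.intercept - half), float(res.intercept + half)),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
    )


def keeling_significance_gate(fit: KeelingFit, alpha: float = 0.05) -> str:
    """Classify a layer as microbially or atmospherically dominated.

    ``microbial_dominated`` iff p < alpha (strict; a tie at p == alpha is
    classified atmosphere_dominated).
    """
    return "microbial_dominated" if fit.p_value < alpha else "atmosphere_dominated"


def correct_atmospheric(
    record: IsotopomerRecord, atm: AtmosphericEndmember, signal: str
) -> float:
    """Per-sample inversion of the two-pool mass balance.

    Returns the microbial signal
    ``(d_obs C_obs - d_atm C_atm) / (C_obs - C_atm)``; requires the
    observed concentration to exceed the atmospheric pool.
    """
    if signal not in SIGNALS:
        raise ValueError(f"signal must be one of {SIGNALS}, got {signal!r}")
    c_micro = record.c_n2o - atm.c_n2o
    if c_micro <= 0:
        raise ValueError(
            f"c_n2o={record.c_n2o} does not exceed atmospheric pool {atm.c_n2o}; "
            "no microbial excess to correct"
        )
    d_obs = getattr(record, signal)
    if d_obs is None or not math.isfinite(d_obs):
        raise ValueError(f"record has no finite {signal}")
    return (d_obs * record.c_n2o - atm.signal(signal) * atm.c_n2o) / c_micro


def corrected_sigma(
    record: IsotopomerRecord, atm: AtmosphericEndmember, sigma_obs: float
) -> float:
    """Uncertainty of the per-sample corrected signal.

    The inversion multiplies the observed signal by C_obs / C_micro, so
    analytical noise is amplified by the same factor (atmospheric
    endmember and concentrations treated as exact).
    """
    c_micro = record.c_n2o - atm.c_n2o
    if c_micro <= 0:
        raise ValueError("record has no microbial excess over the atmospheric pool")
    return sigma_obs * record.c_n2o / c_micro
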