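"""Bayesian apportionment of N2O among production pathways.

The model mixes four microbial sources — archaeal nitrification (aN),
bacterial nitrification (bN), nitrifier denitrification (nD) and
denitrification (bD) — and lets a closed-system Rayleigh term shift the
residual pool when a fraction of the N2O has been reduced:

    F_s = sum_i f_i E_{i,s} + mu_s ln(r)        for s in {d15n_bulk, d18o, sp}

with f on the 4-simplex, residual fraction r in (0, 1], per-pathway
endmember signatures E and net reduction isotope effects mu.  E and mu
carry literature uncertainty (Gaussian, from the endmember table); f has
a flat Dirichlet prior and r a uniform prior on (r_min, 1].

Because F is linear in (E, mu) and everything Gaussian, the latent
endmembers are marginalised analytically: the likelihood of an observed
signal is Gaussian with variance

    sigma_s^2 + sum_i f_i^2 sd_{i,s}^2 + (ln r)^2 sd_{mu,s}^2.

Sampling is random-walk Metropolis on stick-breaking-transformed f and a
logit-transformed r, vectorised across chains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PATHWAYS",
    "SIGNALS",
    "EndmemberTable",
    "MixingObservation",
    "McmcConfig",
    "MixingPosterior",
    "forward_model",
    "log_posterior",
    "sample_posterior",
    "grid_posterior_oracle",
    "apportion_dataset",
]

PATHWAYS = ("aN", "bN", "nD", "bD")
SIGNALS = ("d15n_bulk", "d18o", "sp")

_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class EndmemberTable:
    """Per-pathway endmember means/sds and reduction isotope effects.

    ``means[s]`` and ``sds[s]`` are arrays aligned with ``pathways``;
    ``mu_mean[s]``/``mu_sd[s]`` are the net isotope effect of N2O
    reduction per signal, in the convention of the forward model (the
    residual pool at r < 1 shifts by ``mu ln r``; a negative mu enriches
    it).  All values in permil.
    """

    pathways: tuple[str, ...]
    means: Mapping[str, np.ndarray]
    sds: Mapping[str, np.ndarray]
    mu_mean: Mapping[str, float]
    mu_sd: Mapping[str, float]

    def __post_init__(self):
        k = len(self.pathways)
        for s in SIGNALS:
            if s not in self.means or s not in self.sds:
                raise ValueError(f"endmember table missing signal {s!r}")
            if len(self.means[s]) != k or len(self.sds[s]) != k:
                raise ValueError(f"signal {s!r}: need one value per pathway")
            if np.any(np.asarray(self.sds[s]) < 0):
                raise ValueError(f"signal {s!r}: negative endmember sd")
            if self.mu_sd[s] < 0:
                raise ValueError(f"signal {s!r}: negative mu sd")

    @property
    def n_pathways(self) -> int:
        return len(self.pathways)

    def collapse(self) -> "EndmemberTable":
        """Copy with all endmember/mu uncertainty set to zero."""
        zero = {s: np.zeros(self.n_pathways) for s in SIGNALS}
        return EndmemberTable(
            pathways=self.pathways,
            means={s: np.asarray(self.means[s], dtype=float) for s in SIGNALS},
            sds=zero,
            mu_mean=dict(self.mu_mean),
            mu_sd={s: 0.0 for s in SIGNALS},
        )

    def permute(self, order: Sequence[int]) -> "EndmemberTable":
        """Reorder pathways; posterior summaries permute identically."""
        idx = np.asarray(order)
        return EndmemberTable(
            pathways=tuple(self.pathways[i] for i in idx),
            means={s: np.asarray(self.means[s])[idx] for s in SIGNALS},
            sds={s: np.asarray(self.sds[s])[idx] for s in SIGNALS},
            mu_mean=dict(self.mu_mean),
            mu_sd=dict(self.mu_sd),
        )

    def subset(self, keep: Sequence[str]) -> "EndmemberTable":
        idx = [self.pathways.index(p) for p in keep]
        return self.permute(idx)

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "EndmemberTable":
        pathways = tuple(cfg["pathways"].keys())
        means = {
            s: np.array([cfg["pathways"][p][s]["mean"] for p in pathways], float)
            for s in SIGNALS
        }
        sds = {
            s: np.array([cfg["pathways"][p][s]["sd"] for p in pathways], float)
            for s in SIGNALS
        }
        mu_mean = {s: float(cfg["reduction"][s]["mean"]) for s in SIGNALS}
        mu_sd = {s: float(cfg["reduction"][s]["sd"]) for s in SIGNALS}
        return cls(pathways, means, sds, mu_mean, mu_sd)

    @classmethod
    def from_yaml(cls, path) -> "EndmemberTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "EndmemberTable":
        """Packaged literature-default table (editable; see data/endmembers.yaml)."""
        text = resources.files("n2osource").joinpath("data/endmembers.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class MixingObservation:
    """Atmosphere-corrected microbial isotope signals with uncertainties."""

    values: Mapping[str, float]  # signal -> permil
    sigmas: Mapping[str, float]  # signal -> permil, > 0
    label: str = ""

    def __post_init__(self):
        for s in SIGNALS:
            if s not in self.values or s not in self.sigmas:
                raise ValueError(f"observation missing signal {s!r}")
            if not self.sigmas[s] > 0:
                raise ValueError(f"sigma for {s!r} must be > 0")


@dataclass
class McmcConfig:
    """Random-walk Metropolis settings."""

    n_chains: int = 4
    n_iter: int = 20_000  # iterations per chain
    burn_frac: float = 0.5
    seed: int = 0
    r_min: float = 0.1  # lower bound of the uniform prior on r
    step: float = 0.5  # initial proposal sd (adapted during burn-in)
    rhat_threshold: float = 1.05
    target_acceptance: float = 0.30


@dataclass
class MixingPosterior:
    """Retained posterior draws plus summaries and sampler diagnostics."""

    pathways: tuple[str, ...]
    draws: np.ndarray  # (n_draws, K+1): f columns then r
    summaries: pd.DataFrame  # index f_<pathway>, r; cols mean, sd, q2.5, q97.5
    acceptance_rate: float
    rhat: dict[str, float]
    converged: bool

    @property
    def param_names(self) -> list[str]:
        return [f"f_{p}" for p in self.pathways] + ["r"]


def _check_simplex(f: np.ndarray, tol: float = _SIMPLEX_TOL) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if np.any(f < -tol) or abs(f.sum() - 1.0) > tol:
        raise ValueError(f"f must lie on the simplex (sum={f.sum()}, min={f.min()})")
    return f


def forward_model(
    f: Sequence[float], r: float, table: EndmemberTable
) -> dict[str, float]:
    """Mixture-plus-Rayleigh prediction per signal, at point endmembers.

    Uses the table's mean endmember and mu values.
    """
    f = _check_simplex(np.asarray(f, dtype=float))
    if not 0 < r <= 1:
        raise ValueError(f"r must be in (0, 1], got {r}")
    lnr = math.log(r)
    return {
        s: float(f @ np.asarray(table.means[s], dtype=float) + table.mu_mean[s] * lnr)
        for s in SIGNALS
    }


def _marginal_loglik(
    f: np.ndarray, lnr: np.ndarray, obs: MixingObservation, table: EndmemberTable
) -> np.ndarray:
    """Gaussian log likelihood with latent endmembers marginalised.

    ``f``: (..., K); ``lnr``: (...,); returns (...,).
    """
    out = np.zeros(lnr.shape)
    for s in SIGNALS:
        m = np.asarray(table.means[s], dtype=float)
        sd = np.asarray(table.sds[s], dtype=float)
        mean = f @ m + table.mu_mean[s] * lnr
        var = (
            obs.sigmas[s] ** 2
            + (f * f) @ (sd * sd)
            + (lnr * lnr) * table.mu_sd[s] ** 2
        )
        resid = obs.values[s] - mean
        out += -0.5 * (resid * resid / var + np.log(2.0 * math.pi * var))
    return out


def log_posterior(
    f: Sequence[float],
    r: float,
    obs: MixingObservation,
    table: EndmemberTable,
    r_min: float = 0.1,
    latent: Optional[Mapping] = None,
) -> float:
    """Unnormalised log posterior density of (f, r[, latent endmembers]).

    With ``latent`` (a mapping with ``"E"``: signal -> per-pathway array
    and ``"mu"``: signal -> float) the Gaussian likelihood is evaluated
    at those endmember values and their Gaussian priors (table means and
    sds) are added.  Without it the latents are marginalised.  The flat
    Dirichlet prior on f and uniform prior on r contribute constants;
    points outside the support return -inf.
    """
    f = np.asarray(f, dtype=float)
    if (
        np.any(f < 0)
        or abs(f.sum() - 1.0) > _SIMPLEX_TOL
        or not r_min < r <= 1.0
    ):
        return -math.inf
    lnr = math.log(r)
    if latent is None:
        return float(_marginal_loglik(f, np.asarray(lnr), obs, table))
    lp = 0.0
    for s in SIGNALS:
        e = np.asarray(latent["E"][s], dtype=float)
        mu = float(latent["mu"][s])
        pred = float(f @ e + mu * lnr)
        lp += _norm_logpdf(obs.values[s], pred, obs.sigmas[s])
        m = np.asarray(table.means[s], dtype=float)
        sd = np.asarray(table.sds[s], dtype=float)
        if np.any(sd == 0):
            if np.any(e[sd == 0] != m[sd == 0]):
                return -math.inf
        mask = sd > 0
        lp += float(np.sum(_norm_logpdf(e[mask], m[mask], sd[mask])))
        if table.mu_sd[s] > 0:
            lp += _norm_logpdf(mu, table.mu_mean[s], table.mu_sd[s])
        elif mu != table.mu_mean[s]:
            return -math.inf
    return lp


def _norm_logpdf(x, loc, scale):
    z = (x - loc) / scale
    return -0.5 * z * z - np.log(scale) - 0.5 * math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# sampling


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _stick_break(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map unconstrained (..., K-1) to simplex (..., K); return (f, log|J|)."""
    v = _sigmoid(y)
    shape = y.shape[:-1]
    k = y.shape[-1] + 1
    f = np.empty(shape + (k,))
    stick = np.ones(shape)
    logj = np.zeros(shape)
    for i in range(k - 1):
        f[..., i] = stick * v[..., i]
        logj += np.log(stick) + np.log(v[..., i]) + np.log1p(-v[..., i])
        stick = stick * (1.0 - v[..., i])
    f[..., -1] = stick
    return f, logj


def _transform(theta: np.ndarray, r_min: float):
    """theta (..., K): K-1 stick coords + logit-r coord -> (f, r, log|J|)."""
    f, logj_f = _stick_break(theta[..., :-1])
    z = theta[..., -1]
    srz = _sigmoid(z)
    r = r_min + (1.0 - r_min) * srz
    logj_r = math.log(1.0 - r_min) + np.log(srz) + np.log1p(-srz)
    return f, r, logj_f + logj_r


def _split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction for one parameter.

    ``chains``: (n_chains, n_draws_per_chain).
    """
    m, n = chains.shape
    half = n // 2
    if half < 2:
        return math.nan
    split = chains[:, : 2 * half].reshape(m * 2, half)
    means = split.mean(axis=1)
    w = split.var(axis=1, ddof=1).mean()
    b = half * means.var(ddof=1)
    if w == 0:
        return 1.0
    var_plus = (half - 1) / half * w + b / half
    return float(math.sqrt(var_plus / w))


def sample_posterior(
    obs: MixingObservation, table: EndmemberTable, config: McmcConfig
) -> MixingPosterior:
    """Sample the (f, r) posterior; reproducible for a fixed seed.

    Latent endmember uncertainty is marginalised analytically (exact for
    this linear-Gaussian model), so the walk is over K+... dimensions:
    K-1 stick-breaking coordinates for f and one logit coordinate for r.
    Proposal scale is adapted per chain during burn-in only.
    """
    rng = np.random.default_rng(config.seed)
    k = table.n_pathways
    dim = k  # (k-1) + 1
    n_chains, n_iter = config.n_chains, config.n_iter
    burn = int(config.burn_frac * n_iter)

    theta = rng.normal(scale=0.5, size=(n_chains, dim))
    f, r, logj = _transform(theta, config.r_min)
    logp = _marginal_loglik(f, np.log(r), obs, table) + logj

    step = np.full(n_chains, config.step)
    kept = np.empty((n_chains, n_iter - burn, k + 1))
    n_accept = 0
    n_post = 0
    accept_window = np.zeros(n_chains)
    window = 100

    for it in range(n_iter):
        prop = theta + step[:, None] * rng.normal(size=(n_chains, dim))
        f_p, r_p, logj_p = _transform(prop, config.r_min)
        logp_p = _marginal_loglik(f_p, np.log(r_p), obs, table) + logj_p
        accept = np.log(rng.random(n_chains)) < logp_p - logp
        theta[accept] = prop[accept]
        logp[accept] = logp_p[accept]
        f[accept] = f_p[accept]
        r = np.where(accept, r_p, r)
        accept_window += accept
        if it < burn:
            if (it + 1) % window == 0:
                rate = accept_window / window
                step *= np.exp(rate - config.target_acceptance)
                accept_window[:] = 0.0
        else:
            kept[:, it - burn, :k] = f
            kept[:, it - burn, k] = r
            n_accept += int(accept.sum())
            n_post += n_chains

    names = [f"f_{p}" for p in table.pathways] + ["r"]
    rhat = {
        name: _split_rhat(kept[:, :, j]) for j, name in enumerate(names)
    }
    draws = kept.reshape(-1, k + 1)
    q = np.quantile(draws, [0.025, 0.975], axis=0)
    summaries = pd.DataFrame(
        {
            "mean": draws.mean(axis=0),
            "sd": draws.std(axis=0, ddof=1),
            "q2.5": q[0],
            "q97.5": q[1],
        },
        index=names,
    )
    finite_rhat = [v for v in rhat.values() if math.isfinite(v)]
    converged = bool(finite_rhat) and max(finite_rhat) <= config.rhat_threshold
    return MixingPosterior(
        pathways=table.pathways,
        draws=draws,
        summaries=summaries,
        acceptance_rate=n_accept / max(n_post, 1),
        rhat=rhat,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# brute-force oracle (tests only)


def _simplex_grid(k: int, n: int) -> np.ndarray:
    """All compositions of n into k parts, divided by n: (M, k) array."""
    if k == 1:
        return np.array([[n]], dtype=float) / n
    rows = []

    def rec(prefix, remaining, parts_left):
        if parts_left == 1:
            rows.append(prefix + [remaining])
            return
        for v in range(remaining + 1):
            rec(prefix + [v], remaining - v, parts_left - 1)

    rec([], n, k)
    return np.asarray(rows, dtype=float) / n


def grid_posterior_oracle(
    obs: MixingObservation,
    table: EndmemberTable,
    grid_step: float,
    r_min: float = 0.1,
    fix_r: Optional[float] = None,
) -> dict[str, float]:
    """Exhaustive-grid posterior means at point endmember values.

    Precondition: endmember uncertainty collapsed to points (all sds
    zero; use :meth:`EndmemberTable.collapse`).  Normalises the
    likelihood over a regular simplex grid for f crossed with a regular
    grid over (r_min, 1] for r (or a fixed r).  Verification oracle.
    """
    if grid_step > 0.05:
        raise ValueError(f"grid too coarse: {grid_step} > 0.05")
    if any(np.any(np.asarray(table.sds[s]) > 0) for s in SIGNALS) or any(
        table.mu_sd[s] > 0 for s in SIGNALS
    ):
        raise ValueError("collapse endmember uncertainty before grid evaluation")
    k = table.n_pathways
    n = round(1.0 / grid_step)
    fgrid = _simplex_grid(k, n)  # (M, k)
    if fix_r is not None:
        rgrid = np.array([float(fix_r)])
    else:
        n_r = n
        edges = np.linspace(r_min, 1.0, n_r + 1)
        rgrid = 0.5 * (edges[:-1] + edges[1:])
    ll = np.zeros((len(fgrid), len(rgrid)))
    lnr = np.log(rgrid)
    for s in SIGNALS:
        m = np.asarray(table.means[s], dtype=float)
        pred = (fgrid @ m)[:, None] + table.mu_mean[s] * lnr[None, :]
        z = (obs.values[s] - pred) / obs.sigmas[s]
        ll += -0.5 * z * z
    ll -= ll.max()
    w = np.exp(ll)
    w /= w.sum()
    means = {
        f"f_{p}": float((w.sum(axis=1) * fgrid[:, i]).sum())
        for i, p in enumerate(table.pathways)
    }
    means["r"] = float((w.sum(axis=0) * rgrid).sum())
    return means


# ---------------------------------------------------------------------------
# dataset-level apportionment


@dataclass
class ApportionmentResult:
    """Per-sample posterior summaries plus the across-sample aggregate."""

    per_sample: pd.DataFrame
    overall_mean: dict[str, float]  # across-sample mean of posterior-mean f
    overall_sd: dict[str, float]
    all_converged: bool


def apportion_dataset(
    observations: Sequence[MixingObservation],
    table: EndmemberTable,
    config: McmcConfig,
) -> ApportionmentResult:
    """Run the sampler per observation and aggregate across samples.

    The across-sample mean and sd of the posterior-mean aN fraction is
    the headline aggregation; it is reported for every pathway.  Each
    observation gets its own derived seed (config.seed + index) so the
    result is reproducible and order-stable.
    """
    if len(observations) == 0:
        raise ValueError("apportion_dataset requires at least one observation")
    rows = []
    converged = True
    for i, obs in enumerate(observations):
        cfg = McmcConfig(**{**config.__dict__, "seed": config.seed + i})
        post = sample_posterior(obs, table, cfg)
        converged &= post.converged
        row = {"label": obs.label or str(i)}
        for name in post.param_names:
            row[f"{name}_mean"] = post.summaries.loc[name, "mean"]
            row[f"{name}_sd"] = post.summaries.loc[name, "sd"]
            row[f"{name}_q2.5"] = post.summaries.loc[name, "q2.5"]
            row[f"{name}_q97.5"] = post.summaries.loc[name, "q97.5"]
        row["converged"] = post.converged
        rows.append(row)
    df = pd.DataFrame(rows)
    overall_mean = {}
    overall_sd = {}
    for p in table.pathways:
        col = df[f"f_{p}_mean"].to_numpy(dtype=float)
        overall_mean[p] = float(col.mean())
        overall_sd[p] = float(col.std(ddof=1)) if len(col) > 1 else 0.0
    return ApportionmentResult(
        per_sample=df,
        overall_mean=overall_mean,
        overall_sd=overall_sd,
        all_converged=converged,
    )
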