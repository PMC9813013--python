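"""Deterministic and probabilistic sensitivity analysis.

One-way DSA varies a single dot-addressed parameter to the ends of its range
(95% CI where a source reports one, otherwise +/-20% of base) and records the
resulting ICER; the tornado table is sorted by bar width.  PSA draws all
parameters jointly — beta for probabilities and utilities, log-normal for
costs, multivariate normal for the log-scale DFS curve parameters — reruns
the full comparison per draw, and summarises the (delta-cost, delta-QALY)
cloud as a CE plane and an acceptability curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .economics import run_cea
from .params import ModelParameters, ParameterError, get_path, set_path

__all__ = [
    "DSAParameterRange",
    "TornadoTable",
    "run_dsa",
    "default_dsa_ranges",
    "fit_beta",
    "fit_lognormal",
    "PSADistribution",
    "default_psa_distributions",
    "PSAResult",
    "run_psa",
    "ceac",
    "ce_plane_export",
]


# ---------------------------------------------------------------------------
# Deterministic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class DSAParameterRange:
    """One-way range for a dot-addressed parameter."""

    path: str
    low: float
    high: float
    provenance: str = "pm20"  # ci95 | pm20 | custom

    def __post_init__(self):
        if self.low > self.high:
            raise ParameterError(f"{self.path}: low {self.low} > high {self.high}")
        if self.provenance not in ("ci95", "pm20", "custom"):
            raise ParameterError(f"{self.path}: unknown provenance {self.provenance!r}")

    @classmethod
    def pm20(cls, path: str, base: float) -> "DSAParameterRange":
        lo, hi = sorted((0.8 * base, 1.2 * base))
        return cls(path=path, low=lo, high=hi, provenance="pm20")


@dataclass
class TornadoTable:
    """One-way DSA results: ICER at each range end, sorted by bar width."""

    base_icer: float
    perspective: str
    table: pd.DataFrame  # columns: path, low, high, icer_low, icer_high, width

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def _icer_for(params: ModelParameters, perspective: str, horizon=None) -> float:
    frag = run_cea(params, horizon=horizon)[perspective].icer
    if frag.icer_per_qaly is None:
        return math.nan
    return frag.icer_per_qaly


def run_dsa(
    params: ModelParameters,
    ranges: list[DSAParameterRange],
    perspective: str = "public_payer",
) -> TornadoTable:
    """One-way DSA: each parameter in turn to its low then high value.

    The base value must lie inside each range.  Rows are sorted by bar width
    (|ICER_high - ICER_low|) descending, ties broken by path.
    """
    params.validate()
    base_icer = _icer_for(params, perspective)
    rows = []
    for r in ranges:
        base = get_path(params, r.path)
        if not (r.low - 1e-12 <= base <= r.high + 1e-12):
            raise ParameterError(
                f"{r.path}: base value {base} outside DSA range [{r.low}, {r.high}]"
            )
        icer_low = _icer_for(set_path(params, r.path, r.low), perspective)
        icer_high = _icer_for(set_path(params, r.path, r.high), perspective)
        rows.append({
            "path": r.path, "low": r.low, "high": r.high,
            "icer_low": icer_low, "icer_high": icer_high,
            "width": abs(icer_high - icer_low),
        })
    df = pd.DataFrame(rows, columns=["path", "low", "high", "icer_low", "icer_high", "width"])
    if len(df):
        df = df.sort_values(["width", "path"], ascending=[False, True], kind="mergesort")
        df = df.reset_index(drop=True)
    return TornadoTable(base_icer=base_icer, perspective=perspective, table=df)


def default_dsa_ranges(params: ModelParameters) -> list[DSAParameterRange]:
    """The packaged one-way ranges: reported 95% CIs where available, else +/-20%."""
    R = DSAParameterRange
    ranges = [
        R("start_dfs_no_screening", 0.724, 0.874, "ci95"),
        R("dfs.mbc_split", 0.576, 0.864, "ci95"),
        R("dfs.cure_threshold", 96.0, 180.0, "custom"),
        R("dfs.max_cure_rate", 0.0, 1.0, "custom"),
        R("remission_to_mbc", 0.0061, 0.0091, "ci95"),
        R("settings.discount_rate", 0.0, 0.035, "custom"),
        R("settings.horizon_months", 360, 720, "custom"),
        R.pm20("settings.start_age", params.settings.start_age),
        R.pm20("costs.detection_rate", params.costs.detection_rate),
    ]
    for side in ("patient", "public_payer"):
        ci = getattr(params.costs, side)
        for name in ("cbe_per_person", "diagnosis", "monthly_chemo", "monthly_targeted",
                     "monthly_followup", "mbc_targeted_monthly", "mbc_supportive_monthly"):
            ranges.append(R.pm20(f"costs.{side}.{name}", getattr(ci, name)))
    for group in ("on_treatment", "off_treatment", "mbc"):
        base = get_path(params, f"utilities.{group}.pooled")
        lo, hi = 0.8 * base, min(1.2 * base, 1.0)
        ranges.append(R(f"utilities.{group}.pooled", lo, hi, "pm20"))
    for yr in ("year1", "year2", "year3", "year4", "year5plus"):
        ranges.append(R.pm20(f"mbc_mortality.{yr}", get_path(params, f"mbc_mortality.{yr}")))
    return ranges


# ---------------------------------------------------------------------------
# Distribution fitting for PSA
# ---------------------------------------------------------------------------

def fit_beta(mean: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Beta(a, b) matching the mean exactly and the 95% CI as well as possible.

    Parametrised by the concentration a + b; the mean pins a/(a+b) so a
    one-dimensional search minimises the squared distance between the 2.5/97.5
    percent quantiles and the CI endpoints.
    """
    if not (0.0 < mean < 1.0):
        raise ParameterError(f"beta mean must be in (0, 1), got {mean!r}")
    for name, v in (("ci_low", ci_low), ("ci_high", ci_high)):
        if not (0.0 <= v <= 1.0):
            raise ParameterError(f"{name} must be in [0, 1], got {v!r}")
    if not (ci_low < mean < ci_high):
        raise ParameterError(f"CI ({ci_low}, {ci_high}) must bracket the mean {mean}")

    def loss(log_kappa: float) -> float:
        kappa = math.exp(log_kappa)
        a, b = mean * kappa, (1.0 - mean) * kappa
        q = stats.beta.ppf([0.025, 0.975], a, b)
        return (q[0] - ci_low) ** 2 + (q[1] - ci_high) ** 2

    res = optimize.minimize_scalar(loss, bounds=(math.log(1e-2), math.log(1e8)),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    kappa = math.exp(res.x)
    return mean * kappa, (1.0 - mean) * kappa


def fit_lognormal(mean: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Log-normal (mu, sigma) matching the mean exactly, CI by least squares.

    The arithmetic mean exp(mu + sigma^2/2) pins mu given sigma; a
    one-dimensional search on sigma matches the 2.5/97.5 percent quantiles.
    A degenerate CI collapses to near-zero dispersion.
    """
    if mean <= 0 or ci_low <= 0 or ci_high <= 0:
        raise ParameterError("lognormal mean and CI must be positive")
    if ci_low > ci_high:
        raise ParameterError("ci_low must not exceed ci_high")

    def loss(log_sigma: float) -> float:
        sigma = math.exp(log_sigma)
        mu = math.log(mean) - sigma * sigma / 2.0
        q = stats.lognorm.ppf([0.025, 0.975], s=sigma, scale=math.exp(mu))
        return (q[0] - ci_low) ** 2 + (q[1] - ci_high) ** 2

    res = optimize.minimize_scalar(loss, bounds=(math.log(1e-8), math.log(5.0)),
                                   method="bounded", options={"xatol": 1e-12})
    sigma = math.exp(res.x)
    mu = math.log(mean) - sigma * sigma / 2.0
    return mu, sigma


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PSADistribution:
    """Sampling distribution for one parameter (or block of parameters).

    families:
      beta      — hyper {'a','b'}; for probabilities and utilities
      lognormal — hyper {'mu','sigma'}; for costs (million VND)
      multivariate_normal — hyper {'mean','cov'} on the log-scale DFS curve
                  parameters; ``path`` then names the two fields it fills,
                  comma-separated.
    """

    path: str
    family: str
    hyper: dict
    coupled: dict = field(default_factory=dict)  # path -> offset from the draw

    def __post_init__(self):
        if self.family not in ("beta", "lognormal", "multivariate_normal"):
            raise ParameterError(f"unknown PSA family {self.family!r}")

    @classmethod
    def beta_from_ci(cls, path: str, mean: float, lo: float, hi: float) -> "PSADistribution":
        a, b = fit_beta(mean, lo, hi)
        return cls(path=path, family="beta", hyper={"a": a, "b": b})

    @classmethod
    def lognormal_from_ci(cls, path: str, mean: float, lo: float, hi: float) -> "PSADistribution":
        mu, sigma = fit_lognormal(mean, lo, hi)
        return cls(path=path, family="lognormal", hyper={"mu": mu, "sigma": sigma})

    def sample(self, rng: np.random.Generator):
        if self.family == "beta":
            return float(rng.beta(self.hyper["a"], self.hyper["b"]))
        if self.family == "lognormal":
            return float(rng.lognormal(self.hyper["mu"], self.hyper["sigma"]))
        draw = rng.multivariate_normal(self.hyper["mean"], self.hyper["cov"])
        return np.exp(draw)  # log-scale parameters back to natural scale

    def apply(self, params: ModelParameters, rng: np.random.Generator) -> ModelParameters:
        value = self.sample(rng)
        if self.family == "multivariate_normal":
            out = params
            for p, v in zip(self.path.split(","), np.atleast_1d(value)):
                out = set_path(out, p.strip(), float(v))
            return out
        out = set_path(params, self.path, value)
        for path, offset in self.coupled.items():
            out = set_path(out, path, min(value + offset, 1.0))
        return out


def default_psa_distributions(
    params: ModelParameters, dfs_log_cv: float = 0.10
) -> list[PSADistribution]:
    """The packaged PSA specification.

    Betas on probabilities/utilities from their 95% CIs (+/-20% ranges treated
    as the 95% interval), log-normals on every cost component of the patient
    and payer perspectives (the sector perspective inherits additivity), and a
    multivariate normal on the log Weibull shape and scale with a diagonal
    covariance at the given coefficient of variation.
    """
    B, L = PSADistribution.beta_from_ci, PSADistribution.lognormal_from_ci
    # The starting distributions move together: the uncertain quantity is the
    # no-screening stage mix, while screening shifts it by the programme's
    # fixed downstaging gap (the screening start has no independent CI).
    start = B("start_dfs_no_screening", params.start_dfs_no_screening, 0.724, 0.874)
    start.coupled = {
        "start_dfs_screening": params.start_dfs_screening - params.start_dfs_no_screening
    }
    dists = [
        start,
        B("dfs.mbc_split", params.dfs.mbc_split, 0.576, 0.864),
        B("remission_to_mbc", params.remission_to_mbc, 0.0061, 0.0091),
    ]
    dr = params.costs.detection_rate
    dists.append(B("costs.detection_rate", dr, 0.8 * dr, 1.2 * dr))
    for yr in ("year1", "year2", "year3", "year4", "year5plus"):
        v = get_path(params, f"mbc_mortality.{yr}")
        dists.append(B(f"mbc_mortality.{yr}", v, 0.8 * v, 1.2 * v))
    for group in ("on_treatment", "off_treatment", "mbc"):
        v = get_path(params, f"utilities.{group}.pooled")
        dists.append(B(f"utilities.{group}.pooled", v, 0.8 * v, min(1.2 * v, 1.0)))
    for side in ("patient", "public_payer"):
        ci = getattr(params.costs, side)
        for name in ("cbe_per_person", "diagnosis", "monthly_chemo", "monthly_targeted",
                     "monthly_followup", "mbc_targeted_monthly", "mbc_supportive_monthly"):
            v = getattr(ci, name)
            dists.append(L(f"costs.{side}.{name}", v, 0.8 * v, 1.2 * v))
    log_mean = np.log([params.dfs.shape, params.dfs.scale])
    cov = np.diag((dfs_log_cv * np.ones(2)) ** 2)
    dists.append(PSADistribution(
        path="dfs.shape,dfs.scale", family="multivariate_normal",
        hyper={"mean": log_mean, "cov": cov},
    ))
    return dists


@dataclass
class PSAResult:
    """Per-iteration incremental results and their provenance."""

    iterations: pd.DataFrame  # columns: delta_cost, delta_qaly, delta_ly
    seed: int
    n_iterations: int
    perspective: str
    wtp_highly: float
    wtp_cost_effective: float


def run_psa(
    params: ModelParameters,
    distributions: list[PSADistribution] | None = None,
    n_iterations: int = 2000,
    seed: int = 0,
    perspective: str = "public_payer",
    horizon: int | None = None,
) -> PSAResult:
    """Monte-Carlo resampling of all parameters, one full comparison per draw."""
    if n_iterations < 1:
        raise ParameterError("n_iterations must be at least 1")
    params.validate()
    if distributions is None:
        distributions = default_psa_distributions(params)
    rng = np.random.default_rng(seed)
    rows = np.empty((n_iterations, 3))
    for i in range(n_iterations):
        draw = params
        for dist in distributions:
            draw = dist.apply(draw, rng)
        frag = run_cea(draw, horizon=horizon)[perspective].icer
        rows[i] = (frag.delta_cost, frag.delta_qaly, frag.delta_ly)
    df = pd.DataFrame(rows, columns=["delta_cost", "delta_qaly", "delta_ly"])
    return PSAResult(
        iterations=df, seed=seed, n_iterations=n_iterations, perspective=perspective,
        wtp_highly=params.settings.wtp_highly,
        wtp_cost_effective=params.settings.wtp_cost_effective,
    )


def ceac(psa: PSAResult, wtp_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    For each willingness-to-pay value the probability is the fraction of
    iterations with strictly positive net monetary benefit
    ``wtp * delta_qaly - delta_cost``.
    """
    if len(psa.iterations) == 0:
        raise ParameterError("PSA has no iterations")
    if wtp_grid is None:
        wtp_grid = np.linspace(0.0, 2.0 * psa.wtp_cost_effective, 77)
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    dq = psa.iterations["delta_qaly"].to_numpy()
    dc = psa.iterations["delta_cost"].to_numpy()
    nmb = wtp_grid[:, None] * dq[None, :] - dc[None, :]
    prob = (nmb > 0).mean(axis=1)
    return pd.DataFrame({"wtp_million_vnd": wtp_grid, "probability_cost_effective": prob})


def ce_plane_export(psa: PSAResult) -> pd.DataFrame:
    """Cost-effectiveness plane points with quadrant labels.

    Threshold slopes (million VND per QALY) travel in ``DataFrame.attrs``
    under ``'thresholds'``.
    """
    if len(psa.iterations) == 0:
        raise ParameterError("PSA has no iterations")
    df = psa.iterations[["delta_qaly", "delta_cost"]].copy()
    quad = np.where(
        df["delta_qaly"] > 0,
        np.where(df["delta_cost"] > 0, "NE", "SE"),
        np.where(df["delta_cost"] > 0, "NW", "SW"),
    )
    df["quadrant"] = quad
    df.attrs["thresholds"] = (psa.wtp_highly, psa.wtp_cost_effective)
    return df
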