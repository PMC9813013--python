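"""Model/results front-end.

:class:`CEAModel` wraps a validated parameter set; ``fit()`` evaluates the
Markov cohort comparison and returns :class:`CEAResults`, which carries the
per-perspective estimates and a printable summary.  Sensitivity analyses and
the microsimulation check hang off the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import economics, sensitivity
from .economics import CEAResult, run_cea, vnd_to_usd
from .microsim import MicrosimResult, microsim_oracle
from .params import PERSPECTIVES, ModelParameters, set_path
from .sensitivity import PSAResult, TornadoTable

__all__ = ["CEAModel", "CEAResults"]


class CEAModel:
    """Markov cohort cost-effectiveness model of CBE screening vs no screening.

    Parameters
    ----------
    params
        Complete model parameter set; see
        :func:`cbescreen.synthetic.default_parameters` for the packaged base
        case.

    Examples
    --------
    >>> from cbescreen import CEAModel
    >>> res = CEAModel.from_defaults().fit()
    >>> print(res.summary())        # doctest: +SKIP
    """

    def __init__(self, params: ModelParameters):
        self.params = params.validate()

    @classmethod
    def from_defaults(cls, **overrides) -> "CEAModel":
        """Model on the packaged base case, with optional dot-path overrides."""
        from .synthetic import default_parameters

        params = default_parameters()
        for path, value in overrides.items():
            params = set_path(params, path.replace("__", "."), value)
        return cls(params)

    @classmethod
    def from_config(cls, path) -> "CEAModel":
        from .config import load_config

        params, _ = load_config(path)
        return cls(params)

    def fit(self, horizon: int | None = None) -> "CEAResults":
        """Evaluate both scenarios and all perspectives."""
        return CEAResults(self, run_cea(self.params, horizon=horizon))

    def run_dsa(self, ranges=None, perspective: str = "public_payer") -> TornadoTable:
        """One-way deterministic sensitivity analysis (tornado table)."""
        if ranges is None:
            ranges = sensitivity.default_dsa_ranges(self.params)
        return sensitivity.run_dsa(self.params, ranges, perspective=perspective)

    def run_psa(
        self,
        n_iterations: int = 2000,
        seed: int = 0,
        perspective: str = "public_payer",
        distributions=None,
        horizon: int | None = None,
    ) -> PSAResult:
        """Probabilistic sensitivity analysis (Monte-Carlo parameter resampling)."""
        return sensitivity.run_psa(
            self.params, distributions=distributions, n_iterations=n_iterations,
            seed=seed, perspective=perspective, horizon=horizon,
        )

    def microsimulate(
        self,
        n_individuals: int = 20000,
        seed: int = 0,
        scenario: str = "screening",
        perspective: str = "healthcare_sector",
        horizon: int | None = None,
    ) -> MicrosimResult:
        """Individual-level simulation under identical probabilities (a check
        on the cohort algebra, not the production path)."""
        from .engine import DEFAULT_SPACE

        p = self.params
        H = horizon if horizon is not None else p.settings.horizon_months
        dfs = (
            p.start_dfs_screening if scenario == "screening" else p.start_dfs_no_screening
        )
        start = DEFAULT_SPACE.start_distribution(dfs)
        return microsim_oracle(
            start, p, H, n_individuals, seed,
            perspective=perspective, scenario=scenario,
        )


class CEAResults:
    """Fitted cost-effectiveness comparison.

    Wraps :class:`cbescreen.economics.CEAResult`; exposes the per-perspective
    estimates, the cohort traces, and a printable summary shaped like a
    standard base-case CEA table (life-years, QALYs, total cost, ICERs in
    million VND and USD, threshold classification).
    """

    def __init__(self, model: CEAModel, raw: CEAResult):
        self.model = model
        self.raw = raw

    def __getitem__(self, perspective: str):
        return self.raw[perspective]

    @property
    def trace_screening(self):
        return self.raw.trace_screening

    @property
    def trace_no_screening(self):
        return self.raw.trace_no_screening

    def summary_frame(self) -> pd.DataFrame:
        return self.raw.summary_frame()

    def summary(self) -> str:
        s = self.model.params.settings
        lines = [
            "Cost-effectiveness of CBE screening vs no screening",
            f"  start age {s.start_age:.0f} y, horizon {s.horizon_months} months, "
            f"discount {100 * s.discount_rate:.1f}%/y",
            f"  WTP thresholds {s.wtp_highly:g} / {s.wtp_cost_effective:g} million VND per QALY",
            "",
            f"{'perspective':<18}{'ΔLY':>8}{'ΔQALY':>8}{'ΔCost':>10}"
            f"{'ICER/LY':>10}{'ICER/QALY':>11}{'USD':>8}  class",
        ]
        for p in PERSPECTIVES:
            r = self.raw[p]
            f = r.icer
            usd = r.icer_per_qaly_usd(s.exchange_rate)
            lines.append(
                f"{p:<18}{f.delta_ly:>8.2f}{f.delta_qaly:>8.2f}{f.delta_cost:>10.1f}"
                f"{(f.icer_per_ly if f.icer_per_ly is not None else float('nan')):>10.1f}"
                f"{(f.icer_per_qaly if f.icer_per_qaly is not None else float('nan')):>11.1f}"
                f"{(usd if usd is not None else float('nan')):>8}  {r.classification}"
            )
        lines.append("")
        lines.append("  costs in million VND; ICERs are screening vs no screening")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return f"<CEAResults: {len(self.raw.perspectives)} perspectives>"
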