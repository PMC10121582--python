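"""Nested-model likelihood-ratio tests and sensitivity / power analysis.

A hypothesis about a single latent process — e.g. "culprit-presence
detection does not differ between instruction conditions" — is tested by
adding an equality restriction to the base model and comparing fits:
``ΔG² = G²(restricted) − G²(base)`` is asymptotically chi-square with
``Δdf`` equal to the number of free parameters removed.

Sensitivity and power calculations use the noncentral chi-square
distribution with noncentrality ``λ = N · w²``, where ``w`` is Cohen's
effect size for chi-square tests and ``N`` the total number of
identification decisions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import optimize, stats

from .data_io import ResponseTable
from .estimation import FitOptions, FitResult, fit
from .model import Equal, Fix, ModelSpec

__all__ = [
    "ComparisonResult",
    "compare",
    "sensitivity_w",
    "power_of_test",
]

#: ΔG² more negative than this is treated as an error, not rounding noise.
_NUMERICAL_SLACK = 1e-6


@dataclass(frozen=True)
class ComparisonResult:
    """Likelihood-ratio test of a parameter restriction."""

    delta_g_squared: float
    delta_df: int
    p_value: float
    base_fit: FitResult
    restricted_fit: FitResult
    restriction_description: str
    clamped: bool = False

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha

    def to_dict(self) -> dict:
        return {
            "restriction": self.restriction_description,
            "delta_g_squared": float(self.delta_g_squared),
            "delta_df": int(self.delta_df),
            "p_value": float(self.p_value),
            "base_g_squared": float(self.base_fit.g_squared),
            "restricted_g_squared": float(self.restricted_fit.g_squared),
            "converged": bool(self.base_fit.converged and self.restricted_fit.converged),
        }


def compare(
    spec: ModelSpec,
    data: ResponseTable,
    restriction: Equal | Fix | Iterable[Equal | Fix],
    base_fit: FitResult | None = None,
    options: FitOptions | Mapping | None = None,
) -> ComparisonResult:
    """Test additional restriction(s) on top of ``spec`` with a ΔG² test.

    The restricted model must be strictly nested in the base model: the added
    constraints must remove at least one free parameter, which the
    restriction map guarantees by rejecting constraints on already-constrained
    parameter instances.  A ``base_fit`` computed earlier is reused.
    """
    extra = (restriction,) if isinstance(restriction, (Equal, Fix)) else tuple(restriction)
    if not extra:
        raise ValueError("no restriction supplied")
    restricted_spec = spec.with_restrictions(extra)  # raises if not nested/new
    delta_df = restricted_spec.df - spec.df
    if delta_df < 1:
        raise ValueError("restriction does not reduce the number of free parameters")
    if base_fit is None:
        base_fit = fit(spec, data, options, compute_se=False)
    elif base_fit.spec.to_dict() != spec.to_dict():
        raise ValueError("base_fit was computed for a different model")
    restricted_fit = fit(restricted_spec, data, options, compute_se=False)
    delta = restricted_fit.g_squared - base_fit.g_squared
    clamped = False
    if delta < 0:
        if delta < -_NUMERICAL_SLACK:
            raise RuntimeError(
                f"restricted model fits better than the base model (ΔG² = {delta:.3g}); "
                "base fit likely not at the global maximum"
            )
        delta, clamped = 0.0, True
    p = float(stats.chi2.sf(delta, delta_df))
    return ComparisonResult(
        delta_g_squared=delta,
        delta_df=delta_df,
        p_value=p,
        base_fit=base_fit,
        restricted_fit=restricted_fit,
        restriction_description="; ".join(con.describe() for con in extra),
        clamped=clamped,
    )


def _critical_value(alpha: float, df: int) -> float:
    return float(stats.chi2.ppf(1.0 - alpha, df))


def power_of_test(alpha: float, n_total: int, df: int, w: float) -> float:
    """Power of the chi-square LR test against an alternative of size ``w``.

    The test statistic is noncentral chi-square with ``λ = n_total · w²``
    under the alternative; at ``w = 0`` the power equals ``alpha``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_total < 1 or df < 1 or w < 0:
        raise ValueError("need n_total >= 1, df >= 1, w >= 0")
    crit = _critical_value(alpha, df)
    lam = n_total * w * w
    if lam == 0.0:
        return alpha
    return float(stats.ncx2.sf(crit, df, lam))


def solve_noncentrality(alpha: float, power: float, df: int) -> float:
    """Noncentrality λ* at which the chi-square test reaches the target power."""
    if not 0.0 < alpha < 1.0 or not 0.0 < power < 1.0:
        raise ValueError("alpha and power must be in (0, 1)")
    if power <= alpha:
        raise ValueError(
            f"target power {power} not attainable: must exceed alpha {alpha}"
        )
    crit = _critical_value(alpha, df)

    def gap(lam: float) -> float:
        return stats.ncx2.sf(crit, df, lam) - power

    hi = 1.0
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e8:  # pragma: no cover - defensive
            raise RuntimeError("noncentrality search did not bracket a root")
    return float(optimize.brentq(gap, 1e-12, hi, xtol=1e-12, rtol=1e-14))


def sensitivity_w(alpha: float, power: float, n_total: int, df: int = 1) -> float:
    """Minimal detectable effect size (Cohen's w) of the ΔG² test.

    Solves the noncentral chi-square power equation for λ* and returns
    ``w = sqrt(λ* / n_total)``; decreasing in ``n_total``, increasing in the
    target power.
    """
    if n_total < 1 or df < 1:
        raise ValueError("need n_total >= 1 and df >= 1")
    lam = solve_noncentrality(alpha, power, df)
    return float(np.sqrt(lam / n_total))
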