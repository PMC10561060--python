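"""Closed-form stationary analysis of sequential multisite methylation.

A receptor carries n (four for Tar) modifiable sites that are methylated
and demethylated strictly in sequence, one modification per enzyme
encounter.  Under the global-adaptation assumptions (site-independent CheB
concentration and catalytic equilibrium constant, site-dependent CheR
concentration [R_i] = [R_tot] P_i), detailed balance of the reaction chain
gives the stationary occupancies in closed form:

    P_{m=i}  proportional to  theta^i * P_1 P_2 ... P_i,

where theta = Keq [R_tot]/[B_tot] is the composite dose coupling catalytic
equilibrium and enzyme expression.  The saturation probability P_{m=n} is a
sigmoidal function of theta whose steepness (Hill coefficient) and onset
threshold quantify how robust the methylation state is to fluctuations in
kinase activity or CheR/CheB expression.  Encounter probabilities matched
to the tethered-CheR Gaussian tail (strongly decreasing along the
sequential sites) yield the shallowest saturation curve, the largest
theta threshold and the narrowest methylation-level distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "MultisiteCase",
    "CASES",
    "ThetaScan",
    "stationary_distribution",
    "pm_top",
    "pm4",
    "theta_at_pm4",
    "hill_coefficient",
    "mean_and_sigma",
    "m_threshold",
    "theta_at_mean",
    "scan_cases",
    "case_summary",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MultisiteCase:
    """Encounter probabilities of CheR for the sequential sites."""

    P: Tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        P = tuple(float(p) for p in self.P)
        if len(P) < 1 or any(p < 0 for p in P):
            raise ValueError("encounter probabilities must be >= 0")
        total = sum(P)
        if abs(total - 1.0) > 1e-9:
            logger.warning(
                "encounter probabilities of %r sum to %.12g; renormalising",
                self.label, total)
            P = tuple(p / total for p in P)
        object.__setattr__(self, "P", P)

    @property
    def n_sites(self) -> int:
        return len(self.P)


#: The four canonical encounter-probability scenarios for Tar.
CASES: Dict[str, MultisiteCase] = {
    "case1": MultisiteCase((0.25, 0.25, 0.25, 0.25), "constant"),
    "case2": MultisiteCase((7 / 16, 5 / 16, 3 / 16, 1 / 16),
                           "linearly decreasing"),
    "case3": MultisiteCase((1 / 16, 3 / 16, 5 / 16, 7 / 16),
                           "linearly increasing"),
    "case4": MultisiteCase((0.7809, 0.1856, 0.0309, 0.0026),
                           "tether-matched"),
}


def stationary_distribution(theta: float, case: MultisiteCase) -> np.ndarray:
    """Stationary occupancies P_{m=0..n} at composite dose theta.

    The unnormalised weight of level i is the product of theta*P_j over the
    first i sites; level 0 has weight 1.  Computed in log space so extreme
    theta never overflows.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    P = np.asarray(case.P, dtype=float)
    if theta == 0.0:
        out = np.zeros(case.n_sites + 1)
        out[0] = 1.0
        return out
    with np.errstate(divide="ignore"):
        logw = np.concatenate(
            ([0.0], np.cumsum(np.log(theta) + np.log(P))))
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def pm_top(theta: float, case: MultisiteCase) -> float:
    """Probability that all sites are methylated, P_{m=n}(theta).

    Strictly increasing in theta whenever every encounter probability is
    positive, from 0 at theta = 0 to 1 as theta -> infinity.
    """
    return float(stationary_distribution(theta, case)[-1])


def pm4(theta: float, case: MultisiteCase) -> float:
    """Saturation probability P_{m=4} for a four-site receptor."""
    if case.n_sites != 4:
        raise ValueError("pm4 requires a four-site case; use pm_top")
    return pm_top(theta, case)


def theta_at_pm4(target: float, case: MultisiteCase,
                 bracket: Tuple[float, float] = (1e-9, 1e12)) -> float:
    """Composite dose theta at which the saturation probability hits target.

    P_{m=n} is strictly monotone in theta, so the root is unique; it is
    located with Brent's method at relative tolerance 1e-12.
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target probability must be inside (0, 1)")
    if any(p == 0 for p in case.P):
        raise ValueError("saturation is unreachable when some P_i = 0")
    lo, hi = bracket
    return float(brentq(lambda t: pm_top(t, case) - target, lo, hi,
                        xtol=1e-12, rtol=1e-14, maxiter=200))


def hill_coefficient(case: MultisiteCase) -> float:
    """Hill coefficient of the saturation curve by the 10-90 rule.

    H = ln(81) / ln(theta_0.9 / theta_0.1), the steepness a Hill function
    would need to rise from 10% to 90% over the same dose ratio.  A single
    site gives exactly 1 (a hyperbola); tether-matched probabilities give
    values near 1, i.e. maximal robustness to dose fluctuations.
    """
    t01 = theta_at_pm4(0.1, case)
    t09 = theta_at_pm4(0.9, case)
    return float(np.log(81.0) / np.log(t09 / t01))


def mean_and_sigma(theta: float, case: MultisiteCase) -> Tuple[float, float]:
    """Mean and standard deviation of the stationary methylation level."""
    pm = stationary_distribution(theta, case)
    levels = np.arange(pm.size, dtype=float)
    mean = float(levels @ pm)
    sigma = float(np.sqrt(pm @ (levels - mean) ** 2))
    return mean, sigma


def m_threshold(case: MultisiteCase, target: float = 0.1) -> float:
    """Mean methylation level at which P_{m=n} reaches the target.

    <m>_0.1, the headroom before saturation: large values mean the
    receptor population approaches full methylation only when nearly all
    sites are already used, the desirable regime.
    """
    theta = theta_at_pm4(target, case)
    return mean_and_sigma(theta, case)[0]


def theta_at_mean(target_mean: float, case: MultisiteCase,
                  bracket: Tuple[float, float] = (1e-9, 1e12)) -> float:
    """Theta at which the mean methylation level equals ``target_mean``."""
    n = case.n_sites
    if not 0.0 < target_mean < n:
        raise ValueError(f"target mean must be inside (0, {n})")
    lo, hi = bracket
    return float(brentq(
        lambda t: mean_and_sigma(t, case)[0] - target_mean, lo, hi,
        xtol=1e-12, rtol=1e-14, maxiter=200))


@dataclass
class ThetaScan:
    """Tabulated stationary statistics over a theta grid for one case."""

    case: MultisiteCase
    theta: np.ndarray
    pm: np.ndarray  # shape (len(theta), n_sites + 1)
    mean_m: np.ndarray
    sigma_m: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = {f"pm{i}": self.pm[:, i] for i in range(self.pm.shape[1])}
        return pd.DataFrame({"theta": self.theta, **cols,
                             "mean_m": self.mean_m, "sigma_m": self.sigma_m})


def scan_cases(theta_grid: Sequence[float],
               cases: Dict[str, MultisiteCase] = CASES
               ) -> Dict[str, ThetaScan]:
    """Evaluate the stationary distribution over a theta grid per case."""
    theta_grid = np.asarray(theta_grid, dtype=float)
    out: Dict[str, ThetaScan] = {}
    for name, case in cases.items():
        pm = np.vstack([stationary_distribution(t, case) for t in theta_grid])
        levels = np.arange(pm.shape[1], dtype=float)
        mean = pm @ levels
        sigma = np.sqrt(np.einsum("ij,ij->i", pm, (levels - mean[:, None]) ** 2))
        out[name] = ThetaScan(case=case, theta=theta_grid, pm=pm,
                              mean_m=mean, sigma_m=sigma)
    return out


def case_summary(cases: Dict[str, MultisiteCase] = CASES) -> pd.DataFrame:
    """Robustness metrics per case: theta_0.1, theta_0.9, H and <m>_0.1."""
    rows = []
    for name, case in cases.items():
        t01 = theta_at_pm4(0.1, case)
        t09 = theta_at_pm4(0.9, case)
        rows.append({
            "case": name,
            "label": case.label,
            "theta_01": t01,
            "theta_09": t09,
            "hill_H": float(np.log(81.0) / np.log(t09 / t01)),
            "mean_m_01": mean_and_sigma(t01, case)[0],
        })
    return pd.DataFrame(rows)
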