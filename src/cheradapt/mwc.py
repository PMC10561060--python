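"""Monod-Wyman-Changeux model of chemoreceptor-cluster kinase activity.

A cluster of ``N`` receptors switches between an active and an inactive
conformation as a single allosteric unit.  The probability of being active,

    a = 1 / (1 + exp(N * (f_m + f_L))),

is set by two free-energy contributions per receptor monomer (both in kT):
the methylation-dependent term ``f_m = alpha * (m - m0)`` and the
ligand-dependent term ``f_L = ln((1 + L/Koff) / (1 + L/Kon))``.  With the
attractant convention ``Kon > Koff``, ligand binding (L in mM) raises the
free energy of the active state and lowers activity, while methylation
(``alpha < 0``) compensates.

Energies are in kT units throughout and concentrations in mM; nothing is
ever converted.  The default parameter set is the MeAsp/Tar calibration
used for the Tar-only strain (``alpha = -1.875``, ``m0 = 1.0``,
``Koff = 0.0182 mM``, ``Kon = 3 mM``, cluster size ``N = 8.7``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "MWCParams",
    "TAR_ONLY_PARAMS",
    "WILD_TYPE_PARAMS",
    "ligand_free_energy",
    "methylation_free_energy",
    "activity",
    "invert_activity_to_m",
    "ClusterSizeFit",
    "fit_cluster_size",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MWCParams:
    """Allosteric receptor-cluster parameter set.

    Attributes
    ----------
    N : float
        Receptor-cluster size (number of cooperative monomers), > 0.
    alpha : float
        Free energy per methyl group in kT; negative for E. coli receptors.
    m0 : float
        Methylation offset at which the methylation free energy vanishes.
    Koff : float
        Ligand dissociation constant of the inactive state, mM, > 0.
    Kon : float
        Ligand dissociation constant of the active state, mM, > Koff.
    """

    N: float = 8.7
    alpha: float = -1.875
    m0: float = 1.0
    Koff: float = 0.0182
    Kon: float = 3.0

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError(f"cluster size N must be > 0, got {self.N}")
        if self.Koff <= 0:
            raise ValueError(f"Koff must be > 0, got {self.Koff}")
        if self.Kon <= self.Koff:
            raise ValueError(
                f"attractant convention requires Kon > Koff, got "
                f"Kon={self.Kon}, Koff={self.Koff}"
            )

    def with_N(self, N: float) -> "MWCParams":
        return replace(self, N=N)


#: MeAsp parameters for the Tar-only strain (cluster size fitted at 8.7).
TAR_ONLY_PARAMS = MWCParams(N=8.7)
#: MeAsp parameters for the wild-type strain (cluster size fitted at 5.9).
WILD_TYPE_PARAMS = MWCParams(N=5.9)


def ligand_free_energy(L, params: MWCParams = TAR_ONLY_PARAMS):
    """Ligand-dependent free energy f_L = ln((1+L/Koff)/(1+L/Kon)) in kT.

    Monotonically increases from 0 at L=0 to ln(Kon/Koff) at saturating
    ligand.  Accepts scalars or arrays; L is in mM and must be >= 0.
    """
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("ligand concentration must be >= 0")
    fL = np.log1p(L / params.Koff) - np.log1p(L / params.Kon)
    return fL if fL.ndim else float(fL)


def methylation_free_energy(m, params: MWCParams = TAR_ONLY_PARAMS):
    """Methylation-dependent free energy f_m = alpha * (m - m0) in kT."""
    m = np.asarray(m, dtype=float)
    fm = params.alpha * (m - params.m0)
    return fm if fm.ndim else float(fm)


def _logistic(x):
    """Numerically stable 1/(1+exp(x)) for |x| up to ~1e3."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = np.exp(-x[pos]) / (1.0 + np.exp(-x[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(x[~pos]))
    return out


def activity(m, L, params: MWCParams = TAR_ONLY_PARAMS):
    """Receptor-kinase activity a = 1/(1 + exp(N (f_m + f_L))) in (0, 1).

    Strictly increasing in m (for alpha < 0) and strictly decreasing in L.
    """
    f = methylation_free_energy(m, params) + ligand_free_energy(L, params)
    a = _logistic(params.N * np.asarray(f, dtype=float))
    return a if a.ndim else float(a)


def invert_activity_to_m(a, L, params: MWCParams = TAR_ONLY_PARAMS):
    """Methylation level consistent with an observed activity.

    Exact algebraic inverse of :func:`activity` at ligand concentration L:

        m = m0 + (ln((1-a)/a)/N - f_L(L)) / alpha

    The result is intentionally not clamped to the physical range [0, 4]:
    measurement noise legitimately pushes fitted levels slightly outside.
    A warning is logged when m falls outside [-0.2, 4.2].
    """
    a_arr = np.asarray(a, dtype=float)
    if np.any(a_arr <= 0.0) or np.any(a_arr >= 1.0):
        raise ValueError("activity must lie strictly inside (0, 1)")
    fL = ligand_free_energy(L, params)
    m = params.m0 + (np.log((1.0 - a_arr) / a_arr) / params.N - fL) / params.alpha
    if np.any((np.asarray(m) < -0.2) | (np.asarray(m) > 4.2)):
        logger.warning("inverted methylation level outside [-0.2, 4.2]: %s", m)
    return m if np.asarray(m).ndim else float(m)


@dataclass(frozen=True)
class ClusterSizeFit:
    """Result of a dose-response fit of the cluster size."""

    N: float
    m_pre: float
    N_stderr: float
    m_pre_stderr: float
    rss: float
    converged: bool
    message: str = ""


def fit_cluster_size(
    doses: Sequence[float],
    activities: Sequence[float],
    params_fixed: MWCParams = TAR_ONLY_PARAMS,
    N_guess: float = 6.0,
    m_pre_guess: float = 1.0,
) -> ClusterSizeFit:
    """Fit the cluster size N and pre-stimulus methylation from a dose response.

    The instantaneous response to a dose L at fixed pre-stimulus methylation
    m_pre is a(L) = 1/(1+exp(N(alpha(m_pre-m0)+f_L(L)))).  alpha, m0, Koff
    and Kon are held at their calibrated values and only (N, m_pre) are
    estimated by unweighted least squares.

    Requires at least 4 dose points spanning the transition.
    """
    doses = np.asarray(doses, dtype=float)
    activities = np.asarray(activities, dtype=float)
    if doses.shape != activities.shape:
        raise ValueError("doses and activities must have equal length")
    if doses.size < 4:
        raise ValueError("need at least 4 dose points to fit (N, m_pre)")

    def model(L, N, m_pre):
        p = replace(params_fixed, N=N)
        return np.asarray(activity(m_pre, L, p), dtype=float)

    try:
        popt, pcov = curve_fit(
            model,
            doses,
            activities,
            p0=(N_guess, m_pre_guess),
            bounds=((1e-3, -2.0), (1e3, 6.0)),
            maxfev=20000,
        )
    except RuntimeError as exc:  # non-convergence is reported, never silent
        return ClusterSizeFit(
            N=math.nan, m_pre=math.nan, N_stderr=math.nan,
            m_pre_stderr=math.nan, rss=math.nan,
            converged=False, message=str(exc),
        )
    resid = activities - model(doses, *popt)
    stderr = np.sqrt(np.diag(pcov))
    return ClusterSizeFit(
        N=float(popt[0]),
        m_pre=float(popt[1]),
        N_stderr=float(stderr[0]),
        m_pre_stderr=float(stderr[1]),
        rss=float(resid @ resid),
        converged=True,
    )
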