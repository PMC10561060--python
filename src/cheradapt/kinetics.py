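"""Adaptation kinetics of receptor methylation.

The methylation level m of a receptor evolves under the competing action of
the methyltransferase CheR (acting on inactive receptors) and the
methylesterase CheB (acting on active ones):

    dm/dt = kR * (1 - a) - kB * a        (linear demethylation)
    dm/dt = kR * (1 - a) - kB * a**3     (cubic demethylation)

with the activity a recomputed from (m, L) through the MWC model at every
instant.  Perfect adaptation corresponds to rates independent of m; a
methylation-dependent kR (the tethered-CheR modifier) produces imprecise
adaptation.  An optional scarce-sites correction multiplies each rate by
M/(M + M_sat) where M is the number of sites still available to that
reaction (4 - m for methylation, m for demethylation).

Absolute rate constants are not pinned down by steady-state measurements
(only their ratio is); defaults kR = kB = 0.03 /s make full-range
adaptation take a few hundred seconds, the timescale of typical FRET step
responses, and are freely overridable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .mwc import MWCParams, TAR_ONLY_PARAMS, activity, invert_activity_to_m

__all__ = [
    "AdaptationParams",
    "ScarceSites",
    "ZeroActivityResult",
    "Trajectory",
    "methylation_rate",
    "steady_state_activity",
    "simulate_adaptation",
    "zero_activity_rate",
]

logger = logging.getLogger(__name__)

N_SITES = 4  # modifiable glutamates per Tar monomer


@dataclass(frozen=True)
class ScarceSites:
    """Scarce-sites rate correction: multiply rates by M/(M + M_sat)."""

    M_sat: float
    enabled: bool = True


@dataclass(frozen=True)
class AdaptationParams:
    """Methylation/demethylation rate constants (1/s) and model variant."""

    kR: float = 0.03
    kB: float = 0.03
    variant: str = "linear"  # "linear" or "cubic"
    scarce_sites: Optional[ScarceSites] = None

    def __post_init__(self) -> None:
        if self.kR < 0 or self.kB < 0:
            raise ValueError("rate constants must be >= 0")
        if self.kR == 0 and self.kB == 0:
            raise ValueError("at least one of kR, kB must be positive")
        if self.variant not in ("linear", "cubic"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass(frozen=True)
class ZeroActivityResult:
    """Derived quantities of one zero-activity adaptation assay."""

    delta_t: float  # duration of the zero-activity interval, s
    a_r: float  # peak activity right after stimulus removal
    m_r: float  # methylation level inferred from a_r at L=0
    rate: float  # average net methylation rate (m_r - m_pre)/delta_t, 1/s
    a_r_capped: bool = False  # True when a_r >= 0.9 (estimator unreliable)


@dataclass
class Trajectory:
    """Simulated adaptation time course."""

    t: np.ndarray
    m: np.ndarray
    a: np.ndarray
    L: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "m": self.m, "a": self.a,
                             "L_mM": self.L})


def _site_factors(m: float, scarce: Optional[ScarceSites]):
    """(methylation, demethylation) scarce-site factors at level m."""
    if scarce is None or not scarce.enabled:
        return 1.0, 1.0
    m = np.clip(m, 0.0, N_SITES)
    f_meth = (N_SITES - m) / (N_SITES - m + scarce.M_sat)
    f_demeth = m / (m + scarce.M_sat)
    return f_meth, f_demeth


def methylation_rate(a: float, m: float, params: AdaptationParams,
                     rate_modifier: Optional[Callable[[float], float]] = None
                     ) -> float:
    """Net methylation rate dm/dt at activity a and level m (1/s).

    ``rate_modifier`` multiplies kR as a function of m; this is how the
    tethered-CheR positional distribution enters the kinetics.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"activity must be in [0, 1], got {a}")
    kR = params.kR * (rate_modifier(m) if rate_modifier is not None else 1.0)
    f_meth, f_demeth = _site_factors(m, params.scarce_sites)
    demeth = a if params.variant == "linear" else a ** 3
    return kR * f_meth * (1.0 - a) - params.kB * f_demeth * demeth


def steady_state_activity(params: AdaptationParams) -> float:
    """Adapted activity a* solving dm/dt = 0 for m-independent rates.

    Linear variant: a* = kR/(kR + kB) in closed form.  Cubic variant: the
    unique root in (0, 1) of a^3/(1-a) = kR/kB (the left-hand side grows
    strictly from 0 to infinity, so the root is bracketed and unique).
    """
    if params.kB == 0:
        logger.warning("kB = 0: steady-state activity pinned at 1")
        return 1.0
    ratio = params.kR / params.kB
    if params.variant == "linear":
        return params.kR / (params.kR + params.kB)
    if ratio == 0:
        return 0.0
    return brentq(lambda a: a ** 3 / (1.0 - a) - ratio, 1e-16, 1.0 - 1e-16,
                  xtol=1e-15, rtol=8.9e-16)


def _segment_bounds(protocol: Sequence[tuple], t_end: float):
    times = [float(t) for t, _ in protocol]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("protocol times must be strictly increasing")
    if t_end <= times[-1]:
        raise ValueError("t_end must exceed the last protocol switch time")
    doses = [float(L) for _, L in protocol]
    edges = times + [t_end]
    return edges, doses


def simulate_adaptation(
    protocol: Sequence[tuple],
    mwc: MWCParams = TAR_ONLY_PARAMS,
    kin: AdaptationParams = AdaptationParams(),
    m_init: float = 1.0,
    t_end: Optional[float] = None,
    dt: float = 1.0,
    rate_modifier: Optional[Callable[[float], float]] = None,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> Trajectory:
    """Integrate the adaptation ODE under a piecewise-constant ligand protocol.

    ``protocol`` is a list of (time_s, L_mM) pairs with strictly increasing
    times; each entry switches the ligand concentration, held constant until
    the next switch.  Integration restarts at every switch so the
    discontinuity never straddles an internal step.  m is clamped to the
    physical range [0, 4]: rates pushing past a boundary are zeroed there.

    Returns the trajectory sampled on a uniform grid of spacing ``dt``.
    """
    if not np.isfinite(m_init):
        raise ValueError("m_init must be finite")
    if t_end is None:
        t_end = protocol[-1][0] + 600.0
    edges, doses = _segment_bounds(protocol, t_end)

    def rhs(L):
        def f(t, y):
            m = float(np.clip(y[0], 0.0, N_SITES))
            a = activity(m, L, mwc)
            dm = methylation_rate(a, m, kin, rate_modifier)
            if (y[0] >= N_SITES and dm > 0) or (y[0] <= 0.0 and dm < 0):
                dm = 0.0
            return [dm]
        return f

    t_all, m_all, L_all = [], [], []
    m_cur = float(np.clip(m_init, 0.0, N_SITES))
    for (t0, t1), L in zip(zip(edges, edges[1:]), doses):
        t_eval = np.arange(t0, t1, dt)
        if t_eval.size == 0 or t_eval[0] > t0:
            t_eval = np.insert(t_eval, 0, t0)
        n_keep = t_eval.size  # samples kept; t1 itself belongs to the next segment
        t_solve = np.append(t_eval, t1) if t_eval[-1] < t1 else t_eval
        sol = solve_ivp(rhs(L), (t0, t1), [m_cur], method="LSODA",
                        t_eval=t_solve, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(
                f"ODE integration failed on segment [{t0}, {t1}] s "
                f"(L={L} mM): {sol.message}")
        t_all.append(sol.t[:n_keep])
        m_all.append(np.clip(sol.y[0][:n_keep], 0.0, N_SITES))
        L_all.append(np.full(n_keep, L))
        m_cur = float(np.clip(sol.y[0][-1], 0.0, N_SITES))

    t = np.concatenate(t_all)
    m = np.concatenate(m_all)
    L = np.concatenate(L_all)
    a = np.array([activity(mi, Li, mwc) for mi, Li in zip(m, L)])
    return Trajectory(t=t, m=m, a=a, L=L)


def zero_activity_rate(m_pre: float, a_r: float, delta_t: float,
                       mwc: MWCParams = TAR_ONLY_PARAMS) -> ZeroActivityResult:
    """Average net methylation rate from one zero-activity assay.

    During a saturating stimulus of duration ``delta_t`` the kinase is
    silent and methyl groups accumulate; the post-removal activity peak
    ``a_r`` is mapped back to the recovered methylation level m_r through
    the MWC inverse at L = 0, and the net rate estimated as
    (m_r - m_pre) / delta_t.  Peaks at or above 0.9 are flagged: there the
    activity-to-methylation mapping is too flat for a reliable estimate.
    """
    if delta_t <= 0:
        raise ValueError("delta_t must be > 0")
    if not 0.0 < a_r < 1.0:
        raise ValueError("a_r must be strictly inside (0, 1)")
    capped = a_r >= 0.9
    if capped:
        logger.warning("a_r=%.3f >= 0.9: rate estimate unreliable", a_r)
    m_r = invert_activity_to_m(a_r, 0.0, mwc)
    return ZeroActivityResult(
        delta_t=float(delta_t), a_r=float(a_r), m_r=float(m_r),
        rate=(m_r - m_pre) / delta_t, a_r_capped=capped,
    )
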