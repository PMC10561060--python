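"""Synthetic FRET-style experiments with the statistical structure the
analysis assumes.

Ground truth is the full forward model: MWC activity, adaptation ODE with
a tethered-CheR rate modifier (the translated-Gaussian density evaluated
along the linear site geometry R(m) = k m + R0), an affine map from
activity to a ratio signal, and additive iid Gaussian measurement noise.
Every generator is a pure function of (ground truth, protocol, seed):
identical inputs give identical outputs, and each emitted trace comes with
a hidden-truth record sufficient to score any downstream estimator.

Noise defaults to 2% of the full ratio range; the ratio transform is
ratio = 0.8 + 0.2*a (signal increases with kinase activity, so that a
saturating attractant step, which silences the kinase, drops the signal
to its calibration minimum).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .fret import FretTrace, StimulusEvent
from .kinetics import AdaptationParams, N_SITES, methylation_rate, \
    simulate_adaptation
from .mwc import MWCParams, TAR_ONLY_PARAMS, activity
from .tpm import TPMParams

__all__ = [
    "RATIO_BASELINE",
    "RATIO_SPAN",
    "GroundTruth",
    "default_tar_truth",
    "make_tpm_modifier",
    "steady_state_m",
    "generate_step_experiment",
    "generate_zero_activity_assay",
    "generate_dose_response",
]

RATIO_BASELINE = 0.8  # ratio at zero activity
RATIO_SPAN = 0.2  # ratio = RATIO_BASELINE + RATIO_SPAN * a


@dataclass(frozen=True)
class GroundTruth:
    """Complete forward-model parameterisation of a synthetic experiment."""

    mwc: MWCParams = TAR_ONLY_PARAMS
    kin: AdaptationParams = AdaptationParams()
    tpm: TPMParams = TPMParams(L_total=12.24, b=0.76, x0=10.5, c=1.0)
    k: float = -1.10  # site-distance slope, nm per methylation level
    R0: float = 7.86  # site-distance intercept, nm
    noise_sd: float = 0.02 * RATIO_SPAN  # ratio-scale Gaussian sd
    seed: int = 0
    sampling_dt: float = 1.0  # s

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sampling_dt <= 0:
            raise ValueError("sampling_dt must be > 0")


def default_tar_truth(seed: int = 0, **overrides) -> GroundTruth:
    """Ground truth with the Tar-only calibration (wild-type 34-aa tether)."""
    return GroundTruth(seed=seed, **overrides)


def make_tpm_modifier(truth: GroundTruth) -> Callable[[float], float]:
    """Methylation-rate modifier kR(m)/kR(0) from the tethered-CheR density.

    The local CheR concentration at the active site is the translated
    Gaussian evaluated at R(m) = k m + R0; the modifier is normalised so
    that it equals 1 at m = 0.  A flat geometry (k = 0) gives the constant
    modifier 1, i.e. perfect adaptation.
    """
    tpm, k, R0 = truth.tpm, truth.k, truth.R0
    scale = 2.0 * tpm.L_total * tpm.b

    def density(m):
        R = k * m + R0
        return np.exp(-3.0 * (R - tpm.x0) ** 2 / scale)

    norm = density(0.0)

    def modifier(m: float) -> float:
        return density(m) / norm

    return modifier


def steady_state_m(truth: GroundTruth, L: float = 0.0) -> float:
    """Adapted methylation level at ligand concentration L under the truth.

    Root of kR(m)(1-a(m,L)) = kB a(m,L)^p in m over [0, 4]; the net rate
    decreases monotonically through the fixed point, so bisection applies.
    """
    modifier = make_tpm_modifier(truth)

    def net(m):
        a = activity(m, L, truth.mwc)
        return methylation_rate(a, m, truth.kin, modifier)

    lo, hi = 1e-9, N_SITES - 1e-9
    if net(lo) <= 0:
        return 0.0
    if net(hi) >= 0:
        return float(N_SITES)
    return float(brentq(net, lo, hi, xtol=1e-12, rtol=8.9e-16))


def _rng(truth: GroundTruth, *salt: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([truth.seed & 0x7FFFFFFF, *salt]))


def _emit_trace(truth: GroundTruth, t, a, events, rng) -> FretTrace:
    ratio = RATIO_BASELINE + RATIO_SPAN * np.asarray(a)
    if truth.noise_sd > 0:
        ratio = ratio + rng.normal(0.0, truth.noise_sd, size=ratio.shape)
    return FretTrace(t=np.asarray(t), ratio=ratio, events=events,
                     strain="tar-only")


def generate_step_experiment(
    truth: GroundTruth,
    L_step: float,
    durations: Tuple[float, float, float] = (200.0, 900.0, 300.0),
) -> Tuple[FretTrace, Dict]:
    """One step-response experiment: baseline, attractant step, removal.

    The default protocol mirrors a typical step response: baseline for
    200 s, attractant added at t = 200 s and removed at t = 1100 s, then a
    300 s recovery tail.  Returns the noisy trace and a hidden-truth record
    (pre-stimulus activity a0, adapted state, zero-activity signal level).
    """
    if L_step <= 0:
        raise ValueError("L_step must be > 0")
    t_pre, t_hold, t_tail = durations
    m_init = steady_state_m(truth, 0.0)
    a0 = activity(m_init, 0.0, truth.mwc)
    protocol = [(0.0, 0.0), (t_pre, L_step), (t_pre + t_hold, 0.0)]
    traj = simulate_adaptation(
        protocol, truth.mwc, truth.kin, m_init=m_init,
        t_end=t_pre + t_hold + t_tail, dt=truth.sampling_dt,
        rate_modifier=make_tpm_modifier(truth))
    events = [StimulusEvent(t_pre, "add", L_step),
              StimulusEvent(t_pre + t_hold, "remove", 0.0)]
    rng = _rng(truth, 1, int(round(L_step * 1e9)))
    trace = _emit_trace(truth, traj.t, traj.a, events, rng)
    m_star = steady_state_m(truth, L_step)
    record = {
        "kind": "step",
        "L_mM": float(L_step),
        "a0": float(a0),
        "m_pre": float(m_init),
        "a_star": float(activity(m_star, L_step, truth.mwc)),
        "m_star": float(m_star),
        "f_sat": RATIO_BASELINE,
        "noise_sd": truth.noise_sd,
        "seed": truth.seed,
    }
    return trace, record


def generate_zero_activity_assay(
    truth: GroundTruth,
    delta_t_list: Sequence[float],
    L_sat: float = 0.25,
    t_pre: float = 200.0,
    t_tail: float = 300.0,
) -> List[Tuple[FretTrace, Dict]]:
    """Zero-activity assays: saturating stimulus held for each duration.

    ``L_sat`` must actually silence the kinase at the pre-stimulus
    methylation level (activity < 1e-3), otherwise the assay premise that
    methyl groups accrue at the pure CheR rate fails.
    """
    m_init = steady_state_m(truth, 0.0)
    if activity(m_init, L_sat, truth.mwc) >= 1e-3:
        raise ValueError(
            f"L_sat={L_sat} mM is not saturating at m_pre={m_init:.2f}")
    a0 = activity(m_init, 0.0, truth.mwc)
    modifier = make_tpm_modifier(truth)
    out = []
    for j, dt_hold in enumerate(delta_t_list):
        if dt_hold < 0:
            raise ValueError("durations must be >= 0")
        if dt_hold == 0:
            # degenerate assay: removal at the moment of addition, a_r = a0
            traj = simulate_adaptation(
                [(0.0, 0.0)], truth.mwc, truth.kin, m_init=m_init,
                t_end=t_pre + t_tail, dt=truth.sampling_dt,
                rate_modifier=modifier)
            trace = _emit_trace(truth, traj.t, traj.a, [], _rng(truth, 2, j))
            m_r = m_init
        else:
            protocol = [(0.0, 0.0), (t_pre, L_sat), (t_pre + dt_hold, 0.0)]
            traj = simulate_adaptation(
                protocol, truth.mwc, truth.kin, m_init=m_init,
                t_end=t_pre + dt_hold + t_tail, dt=truth.sampling_dt,
                rate_modifier=modifier)
            events = [StimulusEvent(t_pre, "add", L_sat),
                      StimulusEvent(t_pre + dt_hold, "remove", 0.0)]
            trace = _emit_trace(truth, traj.t, traj.a, events,
                                _rng(truth, 2, j))
            i_rem = np.searchsorted(traj.t, t_pre + dt_hold)
            m_r = float(traj.m[min(i_rem, traj.m.size - 1)])
        out.append((trace, {
            "kind": "zero_activity",
            "delta_t": float(dt_hold),
            "L_sat_mM": float(L_sat),
            "a0": float(a0),
            "m_pre": float(m_init),
            "m_r": m_r,
            "a_r": float(activity(m_r, 0.0, truth.mwc)),
            "f_sat": RATIO_BASELINE,
            "seed": truth.seed,
        }))
    return out


def generate_dose_response(
    truth: GroundTruth,
    doses: Sequence[float],
    noise_sd_activity: float = 0.0,
    m_pre: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray, Dict]:
    """Instantaneous dose-response table at fixed pre-stimulus methylation.

    Responses are the immediate (pre-adaptation) activities to each dose,
    optionally with iid Gaussian noise on the activity scale (clipped to
    [0, 1]).  Used to exercise the receptor cluster-size fit.
    """
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0:
        raise ValueError("dose list must not be empty")
    if np.any(doses < 0):
        raise ValueError("doses must be >= 0")
    if m_pre is None:
        m_pre = steady_state_m(truth, 0.0)
    a = np.array([activity(m_pre, L, truth.mwc) for L in doses])
    if noise_sd_activity > 0:
        rng = _rng(truth, 3, doses.size)
        a = np.clip(a + rng.normal(0.0, noise_sd_activity, a.shape), 0.0, 1.0)
    record = {"kind": "dose_response", "m_pre": float(m_pre),
              "N": truth.mwc.N, "noise_sd_activity": noise_sd_activity,
              "seed": truth.seed}
    return doses, a, record
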