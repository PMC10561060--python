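"""Conversion of FRET-style ratio traces into kinase activity and
extraction of the per-assay derived quantities.

The raw observable is a ratio signal F(t) that is an (unknown) affine
function of kinase activity.  Calibration uses two anchor points: the
pre-stimulus baseline, which corresponds to the pre-stimulus activity a0,
and the lowest signal after stepwise addition of a saturating attractant
concentration, which corresponds to zero activity:

    a(t) = a0 * (F(t) - F_sat) / (F_pre - F_sat).

a0 itself comes from a full add/adapt/remove cycle with saturating
attractant, during which activity sweeps the full 0-to-1 range.  From the
calibrated activity the adapted activity a* (steady-state plateau before
removal), the post-removal peak a_r and the zero-activity duration are
extracted; a_r maps back to a methylation level through the MWC inverse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .geometry import LinearFit
from .mwc import MWCParams, TAR_ONLY_PARAMS, invert_activity_to_m, \
    ligand_free_energy

__all__ = [
    "DELTA_T_CAPS",
    "SATURATING_L_MM",
    "ZERO_ACTIVITY_THRESHOLD",
    "StimulusEvent",
    "FretTrace",
    "CalibrationError",
    "calibrate_activity",
    "extract_a0",
    "AdaptedActivity",
    "adapted_activity",
    "RemovalPeak",
    "removal_peak",
    "StepResponseResult",
    "precision_pairs",
]

logger = logging.getLogger(__name__)

#: Zero-activity duration caps (s) beyond which rate estimates are suspect.
DELTA_T_CAPS = {"wild-type": 114.0, "tar-only": 257.0}
#: Stimulus concentrations at or above this count as saturating (mM).
SATURATING_L_MM = 0.03
#: Calibrated activity below this counts as zero.
ZERO_ACTIVITY_THRESHOLD = 0.02


class CalibrationError(ValueError):
    """Raised when a trace cannot be calibrated to activity."""


@dataclass(frozen=True)
class StimulusEvent:
    t: float  # s
    kind: str  # "add" or "remove"
    L: float = 0.0  # mM, concentration added (0 for remove)

    def __post_init__(self) -> None:
        if self.kind not in ("add", "remove"):
            raise ValueError(f"event kind must be add/remove, got {self.kind!r}")


@dataclass
class FretTrace:
    """Time-stamped ratio signal with its stimulus events."""

    t: np.ndarray
    ratio: np.ndarray
    events: List[StimulusEvent]
    strain: str = "tar-only"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.t.shape != self.ratio.shape:
            raise ValueError("t and ratio must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("times must be strictly increasing")
        times = [e.t for e in self.events]
        if times != sorted(times):
            raise ValueError("events must be sorted by time")
        kinds = [e.kind for e in self.events]
        if any(k1 == k2 for k1, k2 in zip(kinds, kinds[1:])):
            raise ValueError("add/remove events must alternate")
        if self.events and (times[0] < self.t[0] or times[-1] > self.t[-1]):
            raise ValueError("trace does not cover all event times")

    def window(self, t0: float, t1: float) -> np.ndarray:
        return self.ratio[(self.t >= t0) & (self.t < t1)]

    def delta_t_cap(self) -> Optional[float]:
        return DELTA_T_CAPS.get(self.strain)


def _pre_stimulus_value(trace: FretTrace, pre_window: float) -> float:
    t_first = trace.events[0].t if trace.events else trace.t[-1]
    w = trace.window(max(trace.t[0], t_first - pre_window), t_first)
    if w.size == 0:
        raise CalibrationError("no pre-stimulus samples")
    return float(np.mean(w))


def _saturating_add(trace: FretTrace) -> Tuple[int, StimulusEvent]:
    for i, ev in enumerate(trace.events):
        if ev.kind == "add" and ev.L >= SATURATING_L_MM:
            return i, ev
    raise CalibrationError(
        f"no saturating addition (L >= {SATURATING_L_MM} mM) in trace")


def _post_event_window(trace: FretTrace, index: int) -> np.ndarray:
    t0 = trace.events[index].t
    t1 = (trace.events[index + 1].t if index + 1 < len(trace.events)
          else trace.t[-1] + 1.0)
    return trace.window(t0, t1)


def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    if n <= 1 or x.size < n:
        return x
    kernel = np.ones(n) / n
    out = np.convolve(x, kernel, mode="same")
    # repair the convolution edges with partial averages
    half = n // 2
    for i in range(half):
        out[i] = x[: i + half + 1].mean()
        out[-1 - i] = x[-(i + half + 1):].mean()
    return out


def _f_sat(trace: FretTrace, skip: float = 5.0, window: float = 40.0) -> float:
    """Signal level at zero activity, averaged after a saturating addition.

    A saturating attractant step silences the kinase for well over a
    minute, so the mean over a short window starting ``skip`` seconds after
    the addition estimates the zero-activity level without the downward
    bias an extreme-value statistic would have on a noisy signal.  When the
    window holds too few samples the 2nd percentile of the whole
    post-addition stretch is used as a fallback.
    """
    idx, ev = _saturating_add(trace)
    t1 = (trace.events[idx + 1].t if idx + 1 < len(trace.events)
          else trace.t[-1] + 1.0)
    w = trace.window(min(ev.t + skip, t1), min(ev.t + skip + window, t1))
    if w.size >= 5:
        return float(np.mean(w))
    w = _post_event_window(trace, idx)
    if w.size == 0:
        raise CalibrationError("empty post-addition window")
    return float(np.percentile(w, 2.0))


def _peak_value(t: np.ndarray, x: np.ndarray, smooth_n: int = 9,
                avg_half: float = 10.0) -> Tuple[float, float]:
    """Peak of a noisy series: locate on a smoothed copy, average around it.

    Returns (value, time).  Averaging raw samples within ``avg_half``
    seconds of the smoothed-peak location removes most of the upward bias
    of a pointwise maximum.
    """
    i = int(np.argmax(_moving_average(x, smooth_n)))
    sel = np.abs(t - t[i]) <= avg_half
    return float(np.mean(x[sel])), float(t[i])


def extract_a0(trace: FretTrace, pre_window: float = 100.0,
               peak_window: float = 200.0) -> float:
    """Pre-stimulus activity a0 from a full add/adapt/remove cycle.

    Saturating addition drives the activity to 0 (lowest signal); after
    full adaptation, removal overshoots to activity 1 (peak signal).  Then
    a0 = (F_pre - F_sat)/(F_peak - F_sat).  A peak no higher than the
    baseline (a0 >= 1) is flagged as suspicious.
    """
    add_idx, add_ev = _saturating_add(trace)
    removes = [e for e in trace.events[add_idx:] if e.kind == "remove"]
    if not removes:
        raise CalibrationError("full cycle requires a removal event")
    rem = removes[0]
    f_pre = _pre_stimulus_value(trace, pre_window)
    f_sat = _f_sat(trace)
    sel = (trace.t >= rem.t) & (trace.t <= rem.t + peak_window)
    if not np.any(sel):
        raise CalibrationError("empty post-removal window")
    f_peak, _ = _peak_value(trace.t[sel], trace.ratio[sel])
    if f_peak <= f_sat:
        raise CalibrationError("post-removal peak below zero-activity level")
    a0 = (f_pre - f_sat) / (f_peak - f_sat)
    if a0 >= 1.0:
        logger.warning("a0=%.3f >= 1: peak does not exceed baseline; "
                       "suspicious full cycle", a0)
    return a0


def calibrate_activity(trace: FretTrace, a0: Optional[float] = None,
                       f_sat: Optional[float] = None,
                       pre_window: float = 100.0) -> np.ndarray:
    """Convert the ratio signal to kinase activity.

    ``a0`` is the pre-stimulus activity (from :func:`extract_a0` on a full
    saturating cycle; if omitted it is extracted from this trace, which
    must then contain such a cycle).  ``f_sat`` is the zero-activity signal
    level; if omitted it is measured after the first saturating addition in
    this trace.  The calibration is affine-invariant: rescaling or shifting
    the raw ratio leaves a(t) unchanged.
    """
    if a0 is None:
        a0 = extract_a0(trace, pre_window=pre_window)
    if f_sat is None:
        f_sat = _f_sat(trace)
    f_pre = _pre_stimulus_value(trace, pre_window)
    if f_pre <= f_sat:
        raise CalibrationError(
            f"pre-stimulus level {f_pre:.4g} not above zero-activity "
            f"level {f_sat:.4g}")
    a = a0 * (trace.ratio - f_sat) / (f_pre - f_sat)
    out_of_band = (a < -0.05) | (a > 1.05)
    if np.any(out_of_band):
        logger.warning("%d calibrated samples outside [-0.05, 1.05]",
                       int(out_of_band.sum()))
    return a


@dataclass(frozen=True)
class AdaptedActivity:
    """Steady-state plateau estimate before stimulus removal."""

    a_star: float
    slope: float  # linear drift of the plateau, 1/s
    steady: bool  # True when |slope| is below the threshold


def adapted_activity(trace: FretTrace, event_index: int,
                     a0: Optional[float] = None,
                     f_sat: Optional[float] = None,
                     window: float = 100.0,
                     slope_threshold: float = 1e-4) -> AdaptedActivity:
    """Adapted activity a*: mean calibrated activity in the window ending
    at the removal event ``event_index``.

    The plateau must be steady: a linear drift above ``slope_threshold``
    (1/s) flags the estimate rather than rejecting it.
    """
    ev = trace.events[event_index]
    if ev.kind != "remove":
        raise ValueError("event_index must point at a removal event")
    a = calibrate_activity(trace, a0=a0, f_sat=f_sat)
    sel = (trace.t >= ev.t - window) & (trace.t < ev.t)
    if sel.sum() < 3:
        raise ValueError("steady-state window contains too few samples")
    tw, aw = trace.t[sel], a[sel]
    slope = float(np.polyfit(tw, aw, 1)[0])
    steady = abs(slope) < slope_threshold
    if not steady:
        logger.warning("plateau drifting at %.2e /s before removal", slope)
    return AdaptedActivity(a_star=float(np.mean(aw)), slope=slope,
                           steady=steady)


@dataclass(frozen=True)
class RemovalPeak:
    """Post-removal activity peak and the preceding zero-activity spell."""

    a_r: float
    t_peak: float
    zero_activity_duration: float  # s the activity stayed ~0 before removal
    cap_exceeded: bool  # duration beyond the strain's validity cap
    a_r_capped: bool  # a_r >= 0.9, estimator unreliable


def removal_peak(trace: FretTrace, event_index: int,
                 a0: Optional[float] = None,
                 f_sat: Optional[float] = None,
                 window: float = 200.0,
                 zero_threshold: float = ZERO_ACTIVITY_THRESHOLD
                 ) -> RemovalPeak:
    """Peak calibrated activity after the removal event at ``event_index``
    and the duration the activity stayed at ~0 immediately before it."""
    ev = trace.events[event_index]
    if ev.kind != "remove":
        raise ValueError("event_index must point at a removal event")
    a = calibrate_activity(trace, a0=a0, f_sat=f_sat)
    sel = (trace.t >= ev.t) & (trace.t <= ev.t + window)
    if not np.any(sel):
        raise ValueError("empty post-removal window")
    # the peak decays as demethylation resumes, so average only a narrow
    # neighbourhood of the smoothed maximum
    a_r, t_peak = _peak_value(trace.t[sel], a[sel], smooth_n=5, avg_half=2.0)

    before = trace.t < ev.t
    zero = (a < zero_threshold) & before
    duration = 0.0
    idx = np.flatnonzero(before)
    for i in idx[::-1]:  # walk back through the contiguous zero block
        if not zero[i]:
            break
        duration = ev.t - trace.t[i]

    cap = trace.delta_t_cap()
    cap_exceeded = cap is not None and duration > cap
    if cap_exceeded:
        logger.warning("zero-activity duration %.0f s exceeds %s cap %.0f s",
                       duration, trace.strain, cap)
    capped = a_r >= 0.9
    if capped:
        logger.warning("a_r=%.3f >= 0.9: methylation readout saturating", a_r)
    return RemovalPeak(a_r=a_r, t_peak=t_peak,
                       zero_activity_duration=float(duration),
                       cap_exceeded=cap_exceeded, a_r_capped=capped)


@dataclass(frozen=True)
class StepResponseResult:
    """Derived quantities of one step-response experiment."""

    L: float  # step concentration, mM
    a0: float
    a_star: float
    m: float  # adapted methylation level from the MWC inverse
    fm: float  # methylation free energy at m, kT
    fL: float  # ligand free energy at L, kT


def precision_pairs(results: Sequence[StepResponseResult]
                    ) -> Tuple[np.ndarray, LinearFit]:
    """(f_m, f_L) pairs across step responses and the OLS precision slope.

    Fits f_m = slope * f_L + const; perfect adaptation gives slope -1,
    the tethered-CheR mechanism a magnitude slightly below 1.
    Requires at least 3 steps at distinct concentrations.
    """
    if len(results) < 3 or len({r.L for r in results}) < 3:
        raise ValueError("need at least 3 step responses at distinct L")
    pairs = np.array([(r.fm, r.fL) for r in results])
    from scipy import stats
    res = stats.linregress(pairs[:, 1], pairs[:, 0])
    fit = LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                    slope_stderr=float(res.stderr),
                    intercept_stderr=float(res.intercept_stderr),
                    r_value=float(res.rvalue))
    return pairs, fit
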