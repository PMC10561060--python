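"""Translated-Gaussian model of tethered CheR motion.

A CheR molecule docked at the receptor C-terminus explores space like a
ball on a flexible polymer.  For an ideal (freely jointed) chain the
end-to-end density is Gaussian, exp(-3 R^2 / (2 L_total b)), with contour
length L_total and Kuhn length b.  Volume exclusion by the receptor wall
and the ball shifts the peak outward, giving the translated Gaussian

    P_CheR(R) = c * exp(-3 (R - x0)^2 / (2 L_total b)).

Since the methylation rate kR is proportional to the local CheR
concentration at the site being modified, the steady-state activity ratio
obeys a*/(1-a*) = kR/kB = c * exp(-3 (R - x0)^2 / (2 L_total b)), which is
fitted to measured (R, ratio) points to extract the translation x0 and the
amplitude c.  The Kuhn length defaults to b = 0.76 nm, twice the 0.38 nm
persistence length of an unstructured polypeptide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .geometry import LinearFit, contour_length
from .mwc import MWCParams

__all__ = [
    "KUHN_LENGTH_NM",
    "TPMParams",
    "TPMDataset",
    "TPMFit",
    "chain_end_pdf",
    "tpm_density",
    "fit_tpm",
    "encounter_probabilities",
    "fit_x0_vs_chain_length",
    "FlFmRelation",
    "fl_fm_relation",
    "fl_of_fm",
]

KUHN_LENGTH_NM = 0.76  # twice the 0.38 nm persistence length


@dataclass(frozen=True)
class TPMParams:
    """Parameters of the translated-Gaussian CheR density."""

    L_total: float  # tether contour length, nm
    b: float = KUHN_LENGTH_NM  # Kuhn length, nm
    x0: float = 10.5  # translation of the Gaussian peak, nm
    c: float = 1.0  # amplitude (absorbs normalisation and kB)

    def __post_init__(self) -> None:
        if self.L_total <= 0 or self.b <= 0:
            raise ValueError("L_total and b must be > 0")
        if self.c <= 0:
            raise ValueError("amplitude c must be > 0")
        if self.x0 < 0:
            raise ValueError("translation x0 must be >= 0")


@dataclass
class TPMDataset:
    """Steady-state activity-ratio measurements versus site distance.

    ``ratio`` holds a*/(1-a*) for the linear adaptation variant or
    a*^3/(1-a*) for the cubic one; the functional form fitted to R is the
    same translated Gaussian either way.
    """

    R: np.ndarray  # site distances, nm
    ratio: np.ndarray  # activity ratios, > 0
    sd: Optional[np.ndarray] = None  # per-point spread (optional)
    variant: str = "linear"
    construct: Optional[str] = None

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
        if self.R.shape != self.ratio.shape:
            raise ValueError("R and ratio must have equal length")
        if np.any(self.R <= 0) or np.any(self.ratio <= 0):
            raise ValueError("R and ratio must be positive")
        if self.variant not in ("linear", "cubic"):
            raise ValueError(f"unknown variant {self.variant!r}")


def chain_end_pdf(R, L_total: float, b: float = KUHN_LENGTH_NM):
    """Unnormalised ideal-chain end-to-end density exp(-3R^2/(2 L_total b))."""
    if L_total <= 0 or b <= 0:
        raise ValueError("L_total and b must be > 0")
    R = np.asarray(R, dtype=float)
    out = np.exp(-3.0 * R ** 2 / (2.0 * L_total * b))
    return out if out.ndim else float(out)


def tpm_density(R, params: TPMParams):
    """Translated-Gaussian CheR density c * exp(-3(R-x0)^2/(2 L_total b))."""
    R = np.asarray(R, dtype=float)
    out = params.c * np.exp(
        -3.0 * (R - params.x0) ** 2 / (2.0 * params.L_total * params.b))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class TPMFit:
    """Fitted translated-Gaussian parameters with standard errors."""

    c: float
    x0: float
    c_stderr: float
    x0_stderr: float
    rss: float
    converged: bool
    x0_in_range: bool  # False when x0 falls outside [0, 3 L_total]
    message: str = ""

    def params(self, L_total: float, b: float = KUHN_LENGTH_NM) -> TPMParams:
        return TPMParams(L_total=L_total, b=b, x0=self.x0, c=self.c)


def fit_tpm(data: TPMDataset, L_total: float, b: float = KUHN_LENGTH_NM,
            log_ratio: bool = False) -> TPMFit:
    """Nonlinear least-squares fit of (c, x0) with L_total and b fixed.

    The loss is unweighted least squares on the ratio scale by default
    (matching how the ratios are plotted and fitted); ``log_ratio=True``
    switches to least squares on ln(ratio).  Requires at least 3 distinct
    R values.  The initial x0 guess is max(R) + 2 nm, outside the data
    range, since volume exclusion pushes the peak past the farthest site.
    """
    if np.unique(data.R).size < 3:
        raise ValueError("need at least 3 distinct R values to fit (c, x0)")
    scale = 2.0 * L_total * b

    if log_ratio:
        # ln ratio = ln c - 3 (R - x0)^2 / scale: linear in (ln c, x0, x0^2)
        def model(R, c, x0):
            return np.log(c) - 3.0 * (R - x0) ** 2 / scale
        y = np.log(data.ratio)
    else:
        def model(R, c, x0):
            return c * np.exp(-3.0 * (R - x0) ** 2 / scale)
        y = data.ratio

    p0 = (float(np.max(data.ratio)), float(np.max(data.R)) + 2.0)
    try:
        popt, pcov = curve_fit(model, data.R, y, p0=p0,
                               bounds=((1e-12, 0.0), (np.inf, np.inf)),
                               xtol=1e-12, ftol=1e-12, maxfev=20000)
    except RuntimeError as exc:
        return TPMFit(c=math.nan, x0=math.nan, c_stderr=math.nan,
                      x0_stderr=math.nan, rss=math.nan, converged=False,
                      x0_in_range=False, message=str(exc))
    resid = y - model(data.R, *popt)
    stderr = np.sqrt(np.diag(pcov))
    x0 = float(popt[1])
    return TPMFit(
        c=float(popt[0]), x0=x0,
        c_stderr=float(stderr[0]), x0_stderr=float(stderr[1]),
        rss=float(resid @ resid), converged=True,
        x0_in_range=0.0 <= x0 <= 3.0 * L_total,
    )


def encounter_probabilities(distances: Sequence[float],
                            params: TPMParams) -> np.ndarray:
    """Normalised probabilities of CheR encountering each site.

    P_i is the translated-Gaussian density at distance R_i, normalised over
    the given sites; the amplitude c cancels.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.size < 1:
        raise ValueError("need at least one site distance")
    w = tpm_density(distances, params)
    return np.asarray(w) / np.sum(w)


def fit_x0_vs_chain_length(
        points: Sequence[Tuple[float, float]]) -> LinearFit:
    """OLS fit of the fitted translation x0 against tether residue count.

    Returns slope (nm per residue) and intercept (nm, the zero-length
    offset attributable to the CheR molecule size) with standard errors.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 (n_residues, x0) pairs")
    if np.unique(pts[:, 0]).size < 2:
        raise ValueError("degenerate design: all chain lengths identical")
    from scipy import stats
    res = stats.linregress(pts[:, 0], pts[:, 1])
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     slope_stderr=float(res.stderr),
                     intercept_stderr=float(res.intercept_stderr),
                     r_value=float(res.rvalue))


@dataclass(frozen=True)
class FlFmRelation:
    """Quadratic relation f_L = q2 f_m^2 + q1 f_m + f0 implied by the model."""

    q2: float
    q1: float

    @property
    def precision_slope(self) -> float:
        """Implied slope of f_m versus f_L over the linear regime, 1/q1."""
        return 1.0 / self.q1


def fl_fm_relation(mwc: MWCParams, k: float, R0: float,
                   tpm: TPMParams) -> FlFmRelation:
    """Closed-form coefficients of the adapted f_L(f_m) relation.

    At steady state ln(a*/(1-a*)) = -N (f_m + f_L) equals the logarithm of
    the translated Gaussian evaluated at R(m) = k m + R0 with
    m = f_m/alpha + m0.  Eliminating m gives a quadratic in f_m:

        q2 = 3 k^2 / (2 L_total b alpha^2 N)
        q1 = -1 + 3 (k/alpha) (R0 + k m0 - x0) / (L_total b N)

    Perfect adaptation is the flat-geometry limit k = 0: q2 = 0, q1 = -1.
    """
    if mwc.alpha == 0:
        raise ValueError("alpha must be nonzero")
    Lb = tpm.L_total * tpm.b
    q2 = 3.0 * k ** 2 / (2.0 * Lb * mwc.alpha ** 2 * mwc.N)
    q1 = -1.0 + 3.0 * (k / mwc.alpha) * (R0 + k * mwc.m0 - tpm.x0) / (Lb * mwc.N)
    return FlFmRelation(q2=q2, q1=q1)


def fl_of_fm(fm, mwc: MWCParams, k: float, R0: float, tpm: TPMParams):
    """Pointwise f_L(f_m) from the full model (up to the constant f0).

    Used as an independent check of :func:`fl_fm_relation`: m is recovered
    from f_m, mapped to R(m), the ratio ln is evaluated from the translated
    Gaussian, and f_L solved from -N (f_m + f_L) = ln ratio.
    """
    fm = np.asarray(fm, dtype=float)
    m = fm / mwc.alpha + mwc.m0
    R = k * m + R0
    ln_ratio = (np.log(tpm.c)
                - 3.0 * (R - tpm.x0) ** 2 / (2.0 * tpm.L_total * tpm.b))
    fL = -fm - ln_ratio / mwc.N
    return fL if fL.ndim else float(fL)
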