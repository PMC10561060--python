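# Methods

## Receptor activity model

Receptor-kinase activity follows the two-state Monod-Wyman-Changeux
picture: a cluster of `N` receptor monomers switches as one unit, active
with probability `a = 1/(1 + exp(N(f_m + f_L)))`. The methylation free
energy is linear, `f_m = α(m − m0)`, and the ligand free energy is
`f_L = ln((1 + L/Koff)/(1 + L/Kon))`. All energies are in kT and all
concentrations in mM; nothing is converted. The MeAsp/Tar calibration
(`α = −1.875`, `m0 = 1`, `Koff = 0.0182 mM`, `Kon = 3 mM`) is fixed;
dose-response fitting estimates only `(N, m_pre)` by unweighted least
squares, because the other parameters are calibrated quantities rather
than free parameters of any one experiment. No weighting is applied to
dose points; there is no principled per-point variance available for the
synthetic curves, and the estimates are insensitive to it at the noise
levels used.

The logistic is evaluated with a sign-branched form so exponents up to
~±700 never overflow. The inverse map from activity to methylation,
`m = m0 + (ln((1−a)/a)/N − f_L)/α`, is exact and intentionally not
clamped to the physical range [0, 4]: noisy activity estimates may land
slightly outside, and clamping would bias downstream fits. A warning is
logged outside [−0.2, 4.2]. The simulator, by contrast, clamps m to
[0, 4] — it represents physical receptors, not fit residuals.

## Adaptation kinetics

`dm/dt = kR(1 − a) − kB aᵖ`, with `p = 1` (canonical) or `p = 3` (a
variant with stronger activity dependence of demethylation). The
steady-state activity solves `aᵖ/(1 − a) = kR/kB`; the linear case is
closed-form, the cubic case is found by bracketed root finding (the
left-hand side is strictly increasing from 0 to ∞, so the root is unique
in (0, 1); Brent at ~machine tolerance).

Steady-state measurements constrain only the ratio `kR/kB`. The absolute
defaults are `kR = kB = 0.03 /s`, chosen so that full-range adaptation
under the tether modifier completes within a few hundred seconds — the
timescale of typical step-response recordings — while leaving the
steady states untouched; both are configurable.

An optional scarce-sites correction multiplies each rate by
`M/(M + M_sat)`. `M` is interpreted as the number of sites still
available to the reaction in question — `4 − m` for methylation, `m` for
demethylation — which makes the net rate vanish at the appropriate
boundary. This reading is an assumption: the source formulation says
only that `M` counts "available sites" without fixing the direction.

The ODE is integrated per protocol segment with LSODA (rtol 1e-7,
atol 1e-9 by default), restarting at every ligand switch so the
discontinuity never straddles an internal step. At the m = 0 and 4
boundaries, outward rates are zeroed (a reflecting clamp).

## Geometry

Tether contour length is `n_residues × 0.36 nm` (peptide bond length);
site-to-tether distances follow the α-helix rise of 0.15 nm/residue.
The Tar distances in sequential methylation order (#3 → #2 → #1 → #4)
are stored as the printed two-decimal values 6.75/5.70/4.65/3.45 nm:
the axial projection for the sites on the non-tether helix is not
rederivable from first principles here (the relative geometry of the two
helices would be needed), so the published values are authoritative.
Only site #4 is independently checkable (23 residues × 0.15 nm =
3.45 nm). The five Tsr distances are handled the same way.

Residue counting for tether constructs excludes the terminal NWETF
pentapeptide (the CheR docking motif is not part of the flexible
spacer) and skips dash deletion markers; the counter reproduces the
chain lengths 34/29/22/46 (and 30 for the Tsr tail) of the cloned
constructs exactly.

## Translated-Gaussian TPM model

An ideal-chain end-to-end density `exp(−3R²/(2 L_total b))` is translated
by `x0` to account for volume exclusion of the CheR ball and the
receptor wall: `P_CheR(R) = c·exp(−3(R − x0)²/(2 L_total b))`. The Kuhn
length is `b = 0.76 nm`, twice the 0.38 nm persistence length of an
unstructured polypeptide. (The alternative reading — 0.38 nm being
already the Kuhn length — fails to reproduce the tether-matched
encounter probabilities at the Tar site distances; the choice is pinned
by a test.)

Because `kR ∝ [CheR](R)`, the steady state obeys
`a*/(1 − a*) = c·exp(−3(R − x0)²/(2 L_total b))` (or `a*³/(1 − a*)` for
the cubic variant — same functional form, different left-hand side).
`(c, x0)` are fitted by unweighted nonlinear least squares on the ratio
scale, matching how such data are plotted; a log-ratio loss is available
but off by default, since it over-weights the smallest ratios. The
initial guess `x0 = max(R) + 2 nm` starts outside the data range, where
volume exclusion places the peak; fits with `x0` outside `[0, 3 L_total]`
are flagged. Encounter probabilities are the normalised densities at the
site distances; the amplitude cancels.

Eliminating m between the MWC steady state and the Gaussian gives the
quadratic `f_L = q2 f_m² + q1 f_m + f0` with
`q2 = 3k²/(2 L_total b α² N)` and
`q1 = −1 + 3(k/α)(R0 + k m0 − x0)/(L_total b N)`; the perfect-adaptation
limit is `k = 0` (`q2 = 0`, `q1 = −1`). Over the observed `f_m` range the
quadratic term is negligible and the precision slope is `1/q1` ≈ −0.93.

## Sequential multisite model

Under global adaptation (site-independent CheB and equilibrium constant,
site-dependent CheR via encounter probabilities `P_i`), detailed balance
gives stationary weights `w_i = ∏_{j≤i} θ P_j` with
`θ = Keq[R_tot]/[B_tot]`. The implementation works in log space (no
overflow at extreme θ) and generalises to any number of sites, so the
five-site Tsr geometry can be explored with the same code. Thresholds
`θ` at a given saturation probability are found by Brent root finding
(relative tolerance 1e-12; the curve is strictly monotone). The Hill
coefficient uses the standard 10–90 rule `H = ln 81/ln(θ_0.9/θ_0.1)`,
which reproduces the published per-case values; a single-site system
gives exactly H = 1. The methylation-level spread `σ_m` is returned as a
standard deviation (square root of the variance); the source prints the
variance expression without the root while calling it a standard
deviation — a typesetting slip, resolved in favour of the name.

Encounter probabilities handed in with `|ΣP − 1| > 1e-9` are
renormalised defensively with a logged warning.

## FRET-style trace processing

The raw observable is a ratio signal affine in activity. Calibration
anchors are the pre-stimulus baseline (activity `a0`) and the
zero-activity level after a saturating addition (≥ 0.03 mM);
`a0` itself comes from a full saturating add/adapt/remove cycle in which
activity spans 0 to 1. The calibration is affine-invariant by
construction.

Estimator choices, made for unbiasedness under iid Gaussian noise:

- the zero-activity level is the **mean over a 40-s window starting 5 s
  after the saturating addition** (the kinase is silent there), not an
  extreme-value statistic — a low percentile of a long window is biased
  by about two noise standard deviations, which propagates into a
  systematic overestimate of `a0` and an underestimate of the fitted
  `x0`. The 2nd percentile remains as a fallback for traces whose
  post-addition window is too short.
- peaks are located on a 9-sample moving average and reported as the
  mean of raw samples near that location (±10 s for the slow
  full-cycle overshoot; ±2 s for post-removal peaks, which decay as
  demethylation resumes).

Steady plateaus are the mean over the trailing 100 s before removal; a
linear drift above 1e-4 /s flags (not rejects) the estimate. Activity
below 0.02 counts as "zero" for the zero-activity duration, whose
strain-specific validity caps (114 s wild type, 257 s Tar-only) and the
`a_r < 0.9` reliability cap are enforced as warnings. Event times come
from the events sidecar, never inferred from the signal.

## Synthetic-data generator

The generator is the full forward model: MWC activity, adaptation ODE
with the tether modifier `kR(m) ∝ P_CheR(R(m))` normalised to 1 at
m = 0, affine ratio transform `ratio = 0.8 + 0.2·a`, and additive iid
Gaussian noise with sd defaulting to 2% of the full ratio range,
sampled at 1 s. The signal increases with activity so that a saturating
step (which silences the kinase) drops it to the calibration minimum, as
in CheY/CheZ FRET recordings. Every generator is a pure function of
(ground truth, protocol, seed); per-trace noise streams are derived from
the seed plus call-specific salts, so batches are reproducible
trace-by-trace. Hidden-truth sidecars accompany every trace; no
estimator reads them.

What the generator does **not** emulate: photobleaching and baseline
drift, cell-to-cell variability (each trace is an ensemble average),
signal-correlated noise, and stochastic single-receptor methylation
(the ODE is deterministic). Passing recovery tests therefore show the
estimators are correct and unbiased under the assumed noise model, not
that they are robust to every artefact of real recordings.

Default study conditions: Tar-only MWC parameters (N = 8.7), wild-type
34-residue tether (L_total = 12.24 nm, b = 0.76 nm, x0 = 10.5 nm), site
line k = −1.10 nm/level, R0 = 7.86 nm, dose ladder 5–250 μM, 200 s
baseline / 900 s hold / 300 s tail protocol.

## Problem sizes

Everything is desk-scale: the multisite analysis is closed-form
(milliseconds); one pipeline run simulates six ~1400-s experiments at
1-s sampling and completes in about a second; the property suites use
1000 random draws for the birth-death oracle and 50 replicates for the
noisy-fit recovery.

## Known limitations

- Tethered CheB motion is not modelled; only CheR feels the tether.
- The local-adaptation coupling and lattice (Ising-type) dose-response
  simulations are out of scope; only the global-adaptation closed form
  is implemented.
- The cubic-variant chain-length parameters are validated as a
  parameter-recovery property only, since they derive from data that
  cannot be regenerated.
- Mixed-receptor (assistance-neighbourhood) clusters are not simulated;
  the wild-type contrast appears only as the flat-modifier limit.
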