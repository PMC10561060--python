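# cheradapt

Quantitative analysis of chemotactic adaptation kinetics in *Escherichia
coli* driven by tethered particle motion (TPM) of the methyltransferase
CheR.

## The problem

Chemoreceptors (Tar, Tsr) adapt to sustained attractant by sequential
methylation of four to five glutamate sites, catalysed by CheR, which
docks at a C-terminal pentapeptide (NWETF) and reaches the sites through a
flexible ~30-residue tether. In Tar-only strains adaptation is imprecise:
the net methylation rate falls sharply with the methylation level. This
package implements, end to end, the modelling chain that explains that
observation by the polymer statistics of the tethered enzyme:

1. **MWC receptor-cluster model** — a cluster of `N` receptors is active
   with probability `a = 1/(1 + exp(N(f_m + f_L)))`, where
   `f_m = α(m − m0)` and `f_L = ln((1 + L/Koff)/(1 + L/Kon))` (kT units;
   MeAsp/Tar calibration `α = −1.875`, `m0 = 1`, `Koff = 0.0182 mM`,
   `Kon = 3 mM`).
2. **Adaptation kinetics** — `dm/dt = kR(1 − a) − kB aᵖ` (p = 1 or 3),
   simulated under piecewise-constant ligand protocols, with the
   zero-activity assay estimator `⟨dm/dt⟩ = (m_r − m_pre)/Δt`.
3. **Receptor geometry** — site-to-tether distances from the helix rise
   (0.15 nm/residue), tether contour lengths (0.36 nm/residue), and the
   linear map `R = k·m + R0` between methylation level and site distance.
4. **Translated-Gaussian TPM model** — the tethered CheR density
   `P(R) = c·exp(−3(R − x0)²/(2 L_total b))` (Kuhn length `b = 0.76 nm`),
   fitted to steady-state activity ratios `a*/(1 − a*)` to extract the
   peak translation `x0`, plus the implied quadratic `f_L(f_m)` relation.
5. **Sequential multisite model** — closed-form stationary distribution
   `P_{m=i} ∝ θⁱ·P1⋯Pi` with composite dose `θ = Keq[R_tot]/[B_tot]`,
   with saturation thresholds `θ_0.1`, Hill coefficients
   `H = ln 81 / ln(θ_0.9/θ_0.1)` and methylation-level statistics.
6. **FRET-style trace processing and a synthetic-data generator** — the
   raw observable is an affine ratio signal; calibration, plateau and
   peak extraction recover `a0`, `a*`, `a_r`, and the generator produces
   noisy traces from the full forward model for validation.

## Worked example

`python examples/04_multisite_robustness.py` prints:

```
 case               label  theta_01  theta_09  hill_H  mean_m_01
case1            constant     2.958    39.996   1.687      1.419
case2 linearly decreasing     5.208   149.257   1.310      2.144
case3 linearly increasing     3.155    24.272   2.154      0.888
case4      tether-matched    65.588  3493.653   1.105      2.762
```

Each row is one encounter-probability scenario for the four sequential
sites. `theta_01`/`theta_09` are the composite doses at which the fully
methylated fraction reaches 10%/90%, `hill_H` the steepness of that
saturation curve, and `mean_m_01` the mean methylation level when
saturation sets in. The tether-matched probabilities (the ones produced
by the translated-Gaussian CheR density at the Tar site distances,
P ≈ 0.78/0.19/0.03/0.003) give the shallowest curve (H ≈ 1.1) and the
largest safety margin before saturation — the robustness benefit of
encounter-rate matching.

`python examples/05_end_to_end_pipeline.py` runs the full chain on
synthetic noisy traces and prints, among other lines:

```
fitted CheR peak x0 = 10.44 +- 0.15 nm (truth 10.5 nm)
precision slope d(f_m)/d(f_L) = -0.916 +- 0.001
```

i.e. the analysis recovers the generating tether-peak position within a
few percent, and the adaptation-precision slope sits just below 1 in
magnitude, the signature of tether-limited (imprecise) adaptation.

The other examples cover the MWC dose-response fit, the adaptation ODE,
and the geometry/encounter-probability calculations. A thin CLI exposes
the same workflows: `cheradapt multisite`, `cheradapt tpm-fit`,
`cheradapt geometry`, `cheradapt synthesize`, `cheradapt pipeline`.

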