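"""Site geometry, tether statistics, encounter probabilities and the
free-energy relation they imply.
"""

import numpy as np

from cheradapt import geometry as geo
from cheradapt import mwc, tpm

# tether contour lengths from the construct residue counts
for name, construct in geo.TAR_CONSTRUCTS.items():
    print(f"{name:8s} {construct.n_residues:2d} residues -> "
          f"L_total = {construct.L_total:5.2f} nm")

# distance of each site from the tether point, in methylation order
dists = geo.tar_site_distances()
fit = geo.fit_R_of_m(sorted(dists.items()))
print(f"Tar site distances (m=1..4): {list(dists.values())} nm, "
      f"mean {np.mean(list(dists.values())):.2f} nm")
print(f"linear fit R(m) = k*m + R0: k = {fit.slope:.3f} nm/level, "
      f"R0 = {fit.intercept:.3f} nm")

# translated-Gaussian CheR density over the sites
params = tpm.TPMParams(L_total=12.24, b=0.76, x0=10.5)
P = tpm.encounter_probabilities(list(dists.values()), params)
print("encounter probabilities P1..P4:", np.round(P, 4))

# the quadratic f_L(f_m) relation implied by the model
rel = tpm.fl_fm_relation(mwc.TAR_ONLY_PARAMS, k=fit.slope,
                         R0=fit.intercept, tpm=params)
print(f"f_L = {rel.q2:.4f} f_m^2 {rel.q1:+.3f} f_m + f0; implied "
      f"precision slope {rel.precision_slope:.3f}")
print("A slope magnitude below 1 quantifies how far adaptation falls "
      "short of perfect (slope -1).")
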