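"""Principal components of the sensitivity operator and the power spectrum.

The sensitivity time series dg/dk_j form a linear operator from parameter
space into periodic time series; its SVD gives singular values sigma_i,
principal parameter directions V_i and principal time series U_i.  The
power sensitivity spectrum ranks parameters by max_i |sigma_i W_ij| and is
how influential (hence plausibly temperature-sensitive) parameters are
selected.
"""

import numpy as np

import clockbalance as cb

model = cb.build_demo("damped")
orbit = cb.find_entrained_orbit(model)
sens = cb.compute_sensitivities(orbit, method="variational")
pc = cb.principal_components(sens, mode="relative")

print("singular values:", np.array2string(pc.sigma, precision=3))
print(f"decay sigma_1/sigma_s = {pc.sigma[0] / pc.sigma[-1]:.0f}x")

spectrum = cb.power_spectrum(pc, top_i=4, threshold=0.3)
print("\nparameters above 30% of the maximum sensitivity:")
print(spectrum[["rank", "parameter", "max_sigma_w", "log10_max"]].to_string(index=False))

# A fast sigma decay is what makes balancing worthwhile: zeroing the balance
# sums of only the first few components already removes most of the response.
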